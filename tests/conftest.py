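import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcurrent.protocols import VoltageProtocol, default_protocol
from mcurrent.records import CellCovariates, CellRecording
from mcurrent.simulate import CovariateDistributions, LogNormal, SimConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def proto_1ms() -> VoltageProtocol:
    """The standard activation protocol, sampled at 1 ms for speed."""
    return default_protocol(1.0)


@pytest.fixture(scope="session")
def fixed_covariates() -> CovariateDistributions:
    """Degenerate covariate laws: every cell is the median cell."""
    return CovariateDistributions(
        capacitance=LogNormal(8.0, 0.0),
        seal_resistance=LogNormal(1.0, 0.0),
        series_resistance=LogNormal(8.0, 0.0),
        leak_conductance=LogNormal(0.3, 0.0),
        expression=LogNormal(1.0, 0.0),
    )


@pytest.fixture(scope="session")
def noiseless_config(proto_1ms, fixed_covariates) -> SimConfig:
    return SimConfig(protocol=proto_1ms, covariates=fixed_covariates,
                     noise_rms=0.0, n_cells=1, seed=1)


@pytest.fixture(scope="session")
def tiny_protocol() -> VoltageProtocol:
    """A short three-step protocol for hand-built recordings."""
    return VoltageProtocol(step_voltages=(-40.0, -20.0, 0.0),
                           step_duration=100.0, tail_duration=50.0,
                           sampling_interval=1.0, holding_duration=60.0)


def make_recording(protocol: VoltageProtocol, *, cell_id="c0",
                   condition="pre_xe991", capacitance=5.0, seal=0.6,
                   rs=15.0, leak=0.3, expression=1.0,
                   sweep_values=None) -> CellRecording:
    """Recording whose sweeps are constant at the given per-sweep values
    (defaults to zero), handy for exercising QC and feature contracts."""
    if sweep_values is None:
        sweep_values = [0.0] * len(protocol.step_voltages)
    sweeps = {v: np.full(protocol.n_samples, float(val))
              for v, val in zip(protocol.step_voltages, sweep_values)}
    cov = CellCovariates(capacitance=capacitance, seal_resistance=seal,
                         series_resistance=rs, leak_conductance=leak,
                         expression_factor=expression)
    return CellRecording(cell_id=cell_id, group="G", zygosity="homozygous",
                         drug="none", condition=condition, covariates=cov,
                         protocol=protocol, sweeps=sweeps)


@pytest.fixture
def recording_factory(tiny_protocol):
    def factory(**kwargs):
        return make_recording(tiny_protocol, **kwargs)
    return factory
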