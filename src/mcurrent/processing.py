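"""From raw paired recordings to M-current densities and activation data.

The M-current is operationally the XE991-sensitive current: the trace
recorded after XE991 is digitally subtracted, pointwise, from the paired
drug-free trace of the same cell.  No leak subtraction is applied at any
other point -- leak and endogenous background cancel in the pairing.

Features per sweep follow the measurement convention of the assay: peak
current is read 999 ms into the depolarizing step, tail current 5 ms after
the membrane is stepped to 0 mV.  Densities are currents divided by the
cell's capacitance (pA/pF).  Tail currents are normalized per cell: the
tail after the most negative (fully deactivated) prepulse is taken as the
tail-step baseline -- it reflects channels opening during the tail step
itself, not activation by the prepulse -- and tails are scaled between
that baseline and the maximal tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import CellRecording, PairingError

__all__ = ["SweepFeatures", "FeatureError", "subtract_background",
           "extract_features", "cohort_iv"]


class FeatureError(ValueError):
    """Raised when features cannot be extracted from a recording."""


@dataclass(frozen=True)
class SweepFeatures:
    """Per-voltage scalar features for one cell.

    Arrays are aligned with ``voltages``.  ``fittable`` is False when the
    maximal tail does not rise above ``tail_floor_mult`` times the noise
    floor, i.e. when the cell's current is not distinguishable from
    background and a voltage-dependence fit would be meaningless;
    ``normalized_tail`` is then NaN.
    """

    cell_id: str
    voltages: np.ndarray
    peak_current: np.ndarray       # pA at the peak measurement point
    tail_current: np.ndarray       # pA at the tail measurement point
    current_density: np.ndarray    # pA/pF
    normalized_tail: np.ndarray    # dimensionless in [0, 1] (NaN if unfittable)
    capacitance: float
    noise_floor: float             # pA, residual RMS during holding
    fittable: bool

    def density_at(self, voltage: float) -> float:
        i = np.nonzero(np.isclose(self.voltages, voltage))[0]
        if len(i) != 1:
            raise KeyError(f"voltage {voltage} mV not in feature set")
        return float(self.current_density[i[0]])


def subtract_background(pre: CellRecording, post: CellRecording) -> CellRecording:
    """Digitally subtract the post-XE991 recording from the paired
    drug-free recording, isolating the XE991-sensitive (M) current."""
    if pre.cell_id != post.cell_id:
        raise PairingError(
            f"cannot pair different cells: {pre.cell_id!r} vs {post.cell_id!r}")
    if pre.protocol != post.protocol:
        raise PairingError("pre/post recordings use different protocols")
    if set(pre.sweeps) != set(post.sweeps):
        raise PairingError("pre/post recordings have different sweep sets")
    sweeps = {}
    for v, trace in pre.sweeps.items():
        other = post.sweeps[v]
        if len(trace) != len(other):
            raise PairingError(f"sweep length mismatch at {v} mV")
        sweeps[v] = trace - other
    return CellRecording(
        cell_id=pre.cell_id, group=pre.group, zygosity=pre.zygosity,
        drug=pre.drug, condition=pre.condition, covariates=pre.covariates,
        protocol=pre.protocol, sweeps=sweeps, plate=pre.plate)


def _window_mean(trace: np.ndarray, center_idx: int, half_width: int,
                 seg_lo: int, seg_hi: int) -> float:
    """Mean over a +/- half_width window, clamped to [seg_lo, seg_hi) so a
    measurement never mixes samples from adjacent voltage segments."""
    lo = max(seg_lo, center_idx - half_width)
    hi = min(seg_hi, center_idx + half_width + 1)
    return float(np.mean(trace[lo:hi]))


def extract_features(cell: CellRecording, peak_offset_ms: float = 999.0,
                     tail_offset_ms: float = 5.0, window_ms: float = 1.0,
                     tail_floor_mult: float = 3.0) -> SweepFeatures:
    """Measure peak and tail currents and derive densities and normalized
    tails.

    Measurements are means over a +/- ``window_ms`` window centred on the
    stated offset (pass ``window_ms=0`` for single-sample exactness).  The
    noise floor is the RMS of the holding-segment residual (final 50 ms
    before the step, mean-subtracted per sweep).
    """
    p = cell.protocol
    if p.n_tail == 0:
        raise FeatureError("protocol has no tail step; tail features undefined")
    if peak_offset_ms > p.step_duration or tail_offset_ms > p.tail_duration:
        raise FeatureError("measurement offset lies outside its segment")
    if cell.covariates.capacitance is None or cell.covariates.capacitance <= 0:
        raise FeatureError("capacitance must be known and positive")

    half = round(window_ms / p.sampling_interval)
    peak_idx = p.step_sample_index(peak_offset_ms)
    tail_idx = p.tail_sample_index(tail_offset_ms)

    voltages = np.array(p.step_voltages)
    peaks = np.empty(len(voltages))
    tails = np.empty(len(voltages))
    resid = []
    n_base = max(2, round(50.0 / p.sampling_interval))
    step_lo, step_hi = p.n_holding, p.n_holding + p.n_step
    tail_lo, tail_hi = step_hi, p.n_samples
    for j, v in enumerate(voltages):
        trace = cell.sweeps[v]
        peaks[j] = _window_mean(trace, peak_idx, half, step_lo, step_hi)
        tails[j] = _window_mean(trace, tail_idx, half, tail_lo, tail_hi)
        base = trace[max(0, p.n_holding - n_base):p.n_holding]
        if len(base) >= 2:
            resid.append(base - np.mean(base))
    noise_floor = float(np.sqrt(np.mean(np.concatenate(resid) ** 2))) if resid else 0.0

    density = peaks / cell.covariates.capacitance

    tail_span = float(tails.max() - tails.min())
    fittable = tail_span > tail_floor_mult * noise_floor and tail_span > 0
    if fittable:
        normalized = (tails - tails.min()) / tail_span
    else:
        normalized = np.full(len(voltages), np.nan)

    return SweepFeatures(
        cell_id=cell.cell_id, voltages=voltages, peak_current=peaks,
        tail_current=tails, current_density=density,
        normalized_tail=normalized, capacitance=cell.covariates.capacitance,
        noise_floor=noise_floor, fittable=fittable)


def cohort_iv(features: list[SweepFeatures]):
    """Mean +/- SEM current density per voltage across cells.

    Returns a ``pandas.DataFrame`` with columns voltage_mV, mean_density,
    sem_density, n.  SEM is reported as 0 when n = 1.
    """
    import pandas as pd

    if not features:
        raise ValueError("cohort_iv requires at least one cell")
    voltages = features[0].voltages
    for f in features[1:]:
        if not np.array_equal(f.voltages, voltages):
            raise ValueError("all cells must share the same voltage grid")
    dens = np.vstack([f.current_density for f in features])
    n = dens.shape[0]
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(voltages))
    return pd.DataFrame({
        "voltage_mV": voltages, "mean_density": mean,
        "sem_density": sem, "n": n,
    })
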