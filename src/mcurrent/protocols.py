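"""Voltage-clamp stimulus protocols.

The standard activation protocol holds the membrane at -80 mV, applies a
family of 1000 ms depolarizing steps (-80 .. +40 mV in 10 mV increments)
and finishes each sweep with a 250 ms repolarization to 0 mV used to read
tail currents.  Sweeps are delivered at 0.05 Hz so that gating fully
re-equilibrates at the holding potential between sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VoltageProtocol", "default_protocol"]


def _is_multiple(duration: float, dt: float) -> bool:
    n = round(duration / dt)
    return n > 0 and abs(n * dt - duration) < 1e-9 * max(1.0, duration)


@dataclass(frozen=True)
class VoltageProtocol:
    """Step/tail activation protocol shared by the simulator and feature code.

    All durations are in milliseconds, voltages in mV.  Each sweep is laid
    out as [holding segment][depolarizing step][tail step]; time 0 is the
    start of the sweep, the step begins at ``holding_duration``.
    """

    holding_potential: float = -80.0
    step_voltages: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(v) for v in range(-80, 50, 10))
    )
    step_duration: float = 1000.0
    tail_voltage: float = 0.0
    tail_duration: float = 250.0
    sampling_interval: float = 0.1
    inter_sweep_frequency: float = 0.05
    holding_duration: float = 100.0

    def __post_init__(self) -> None:
        sv = tuple(float(v) for v in self.step_voltages)
        object.__setattr__(self, "step_voltages", sv)
        if len(sv) < 1:
            raise ValueError("protocol needs at least one step voltage")
        if any(b <= a for a, b in zip(sv, sv[1:])):
            raise ValueError("step_voltages must be strictly increasing")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        for name in ("step_duration", "tail_duration", "holding_duration"):
            if not _is_multiple(getattr(self, name), self.sampling_interval):
                raise ValueError(
                    f"{name} must be a positive integer multiple of sampling_interval"
                )

    # -- sample bookkeeping -------------------------------------------------

    @property
    def n_holding(self) -> int:
        return round(self.holding_duration / self.sampling_interval)

    @property
    def n_step(self) -> int:
        return round(self.step_duration / self.sampling_interval)

    @property
    def n_tail(self) -> int:
        return round(self.tail_duration / self.sampling_interval)

    @property
    def n_samples(self) -> int:
        return self.n_holding + self.n_step + self.n_tail

    @property
    def sweep_duration(self) -> float:
        return self.holding_duration + self.step_duration + self.tail_duration

    def times(self) -> np.ndarray:
        """Sample times (ms) from sweep start."""
        return np.arange(self.n_samples) * self.sampling_interval

    def index_at(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms`` from sweep start."""
        i = round(t_ms / self.sampling_interval)
        if not 0 <= i < self.n_samples:
            raise ValueError(f"time {t_ms} ms outside sweep (0..{self.sweep_duration})")
        return i

    def step_sample_index(self, t_after_onset_ms: float) -> int:
        """Index of the step sample at ``t_after_onset_ms`` after step onset.

        Step sample k (1-based, time k*dt after the voltage change) sits at
        array index ``n_holding + k - 1``.
        """
        k = round(t_after_onset_ms / self.sampling_interval)
        if not 1 <= k <= self.n_step:
            raise ValueError(f"{t_after_onset_ms} ms is outside the step")
        return self.n_holding + k - 1

    def tail_sample_index(self, t_after_tail_onset_ms: float) -> int:
        """Index of the tail sample at ``t_after_tail_onset_ms`` after the
        membrane steps to the tail voltage."""
        k = round(t_after_tail_onset_ms / self.sampling_interval)
        if not 1 <= k <= self.n_tail:
            raise ValueError(f"{t_after_tail_onset_ms} ms is outside the tail")
        return self.n_holding + self.n_step + k - 1

    @property
    def step_onset(self) -> float:
        """Time (ms) at which the depolarizing step begins."""
        return self.holding_duration

    @property
    def tail_onset(self) -> float:
        """Time (ms) at which the tail step begins."""
        return self.holding_duration + self.step_duration

    def with_sampling(self, dt_ms: float) -> "VoltageProtocol":
        return replace(self, sampling_interval=dt_ms)


def default_protocol(sampling_interval: float = 0.1) -> VoltageProtocol:
    """The standard activation protocol at the requested sampling interval."""
    return VoltageProtocol(sampling_interval=sampling_interval)
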