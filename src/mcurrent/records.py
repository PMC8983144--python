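"""In-memory containers for whole-cell recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import VoltageProtocol

__all__ = ["CellCovariates", "CellRecording", "PairingError", "pair_by_cell"]

PRE = "pre_xe991"
POST = "post_xe991"


class PairingError(ValueError):
    """Raised when pre/post-XE991 recordings cannot be paired."""


@dataclass(frozen=True)
class CellCovariates:
    """Per-cell quality covariates and expression state.

    capacitance in pF, seal_resistance in GOhm, series_resistance in MOhm,
    leak_conductance in nS; expression_factor is a dimensionless scaling of
    the cell's channel complement (0 for nontransfected cells).
    """

    capacitance: float
    seal_resistance: float
    series_resistance: float
    leak_conductance: float
    expression_factor: float

    def __post_init__(self) -> None:
        for name in ("capacitance", "seal_resistance", "series_resistance",
                     "leak_conductance"):
            v = getattr(self, name)
            if v is None:
                continue  # validated at QC time with an explicit error
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.expression_factor is not None and self.expression_factor < 0:
            raise ValueError("expression_factor must be >= 0")


@dataclass
class CellRecording:
    """One cell's sweep family under one recording condition.

    ``sweeps`` maps each protocol step voltage (mV) to the current trace
    (pA) sampled over the full sweep (holding + step + tail segments).
    ``condition`` distinguishes recordings made before ("pre_xe991") and
    after ("post_xe991") application of the M-current blocker.
    """

    cell_id: str
    group: str
    zygosity: str
    drug: str
    condition: str
    covariates: CellCovariates
    protocol: VoltageProtocol
    sweeps: dict[float, np.ndarray] = field(default_factory=dict)
    plate: str = "plate0"

    def __post_init__(self) -> None:
        if self.condition not in (PRE, POST):
            raise ValueError(f"condition must be {PRE!r} or {POST!r}")
        want = set(self.protocol.step_voltages)
        have = set(self.sweeps)
        if have != want:
            raise ValueError(
                f"sweeps must cover exactly the protocol step voltages; "
                f"missing {sorted(want - have)}, extra {sorted(have - want)}"
            )
        n = self.protocol.n_samples
        for v, trace in self.sweeps.items():
            if len(trace) != n:
                raise ValueError(
                    f"sweep at {v} mV has {len(trace)} samples, expected {n}"
                )

    def baseline_currents(self, window_ms: float = 50.0) -> np.ndarray:
        """Mean holding current (pA) over the final ``window_ms`` of the
        pre-step holding segment, one value per sweep (in step order)."""
        p = self.protocol
        n_win = max(1, round(window_ms / p.sampling_interval))
        stop = p.n_holding
        start = max(0, stop - n_win)
        return np.array(
            [float(np.mean(self.sweeps[v][start:stop])) for v in p.step_voltages]
        )


def pair_by_cell(recordings: list[CellRecording]) -> list[tuple[CellRecording, CellRecording]]:
    """Group a flat recording list into (pre, post) XE991 pairs by cell id."""
    pre = {r.cell_id: r for r in recordings if r.condition == PRE}
    post = {r.cell_id: r for r in recordings if r.condition == POST}
    missing = sorted(set(pre) ^ set(post))
    if missing:
        raise PairingError(f"unpaired cell ids: {missing}")
    return [(pre[cid], post[cid]) for cid in pre]
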