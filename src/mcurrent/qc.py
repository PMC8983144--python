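"""Per-cell inclusion criteria applied before any analysis.

A recording enters analysis only if the seal resistance meets the
condition-specific threshold (0.5 GOhm for drug-free recordings, relaxed
to 0.3 GOhm after XE991, and >50 MOhm on multi-hole chips), series
resistance is at most 20 MOhm, apparent capacitance is at least 1 pF, and
the holding-potential baseline is stable across sweeps (relative standard
error of the per-sweep baseline current below 10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import POST, PRE, CellRecording

__all__ = ["QCConfig", "QCVerdict", "InsufficientDataError",
           "MissingCovariateError", "stability_fraction", "passes_qc"]


class InsufficientDataError(ValueError):
    """Raised when a QC statistic is requested on too little data."""


class MissingCovariateError(ValueError):
    """Raised when a QC covariate required by a criterion is absent."""


@dataclass(frozen=True)
class QCConfig:
    """Inclusion thresholds.  Boundary values are inclusive exactly as
    worded: seal >= min_seal, Rs <= max_series_resistance, Cm >=
    min_capacitance; the multi-hole seal criterion is strictly greater
    than; baseline relative SE must be strictly below the cap."""

    min_seal: float = 0.5                 # GOhm, drug-free recordings
    min_seal_post_xe991: float = 0.3      # GOhm, after XE991
    min_seal_multihole: float = 50.0      # MOhm, 4-hole chips (strict >)
    max_series_resistance: float = 20.0   # MOhm
    min_capacitance: float = 1.0          # pF
    max_baseline_se_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_seal", "min_seal_post_xe991", "min_seal_multihole",
                     "max_series_resistance", "min_capacitance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.max_baseline_se_fraction < 1.0:
            raise ValueError("max_baseline_se_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    failed_criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must be equivalent to empty failed_criteria")


def stability_fraction(baseline_currents) -> float:
    """Relative standard error of the per-sweep baseline current.

    Returns SE(baseline) / |mean(baseline)| where SE uses the sample
    standard deviation (ddof=1) over sweeps.  A zero mean yields +inf so
    that the stability criterion fails rather than passing vacuously.
    """
    x = np.asarray(baseline_currents, float)
    if x.ndim != 1 or len(x) < 2:
        raise InsufficientDataError("need at least 2 sweeps for baseline stability")
    mean = float(np.mean(x))
    if mean == 0.0:
        return math.inf
    se = float(np.std(x, ddof=1)) / math.sqrt(len(x))
    return se / abs(mean)


def passes_qc(cell: CellRecording, qc: QCConfig | None = None,
              chip_mode: str = "single", condition: str | None = None) -> QCVerdict:
    """Evaluate every inclusion criterion for one recording.

    ``condition`` defaults to the recording's own condition label; the
    seal threshold is selected by condition (pre vs post XE991) and chip
    mode.  A missing covariate raises ``MissingCovariateError`` -- it is
    never treated as a pass.
    """
    qc = qc or QCConfig()
    if chip_mode not in ("single", "multi"):
        raise ValueError("chip_mode must be 'single' or 'multi'")
    condition = condition or cell.condition
    if condition not in (PRE, POST):
        raise ValueError(f"condition must be {PRE!r} or {POST!r}")

    cov = cell.covariates
    for name in ("seal_resistance", "series_resistance", "capacitance"):
        if getattr(cov, name) is None:
            raise MissingCovariateError(f"covariate {name!r} is missing")

    failed: list[str] = []
    if chip_mode == "multi":
        # multi-hole seal threshold is stated in MOhm
        if not cov.seal_resistance * 1000.0 > qc.min_seal_multihole:
            failed.append("seal_resistance")
    else:
        threshold = qc.min_seal if condition == PRE else qc.min_seal_post_xe991
        if not cov.seal_resistance >= threshold:
            failed.append("seal_resistance")
    if not cov.series_resistance <= qc.max_series_resistance:
        failed.append("series_resistance")
    if not cov.capacitance >= qc.min_capacitance:
        failed.append("capacitance")
    if not stability_fraction(cell.baseline_currents()) < qc.max_baseline_se_fraction:
        failed.append("baseline_stability")

    return QCVerdict(passed=not failed, failed_criteria=tuple(failed))
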