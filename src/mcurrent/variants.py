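"""Parallel-WT relative metrics, significance testing, functional
classification, and retigabine response quantification.

Every variant is assayed against the WT cohort recorded on the same plate.
The headline metrics are (i) peak current density at +40 mV expressed as a
percentage of the parallel WT mean, (ii) the shift in activation V1/2
relative to WT, and (iii) the ratio of activation time constants
(variant/WT) per voltage.  Group differences use a two-tailed t test (one
comparison) or one-way ANOVA (several variants), with P <= 0.01 considered
significant.

Homozygous classification bins peak current density: <= 10% of WT is
profound loss-of-function, (10, 25)% severe, [25, 75)% partial (all
requiring statistical significance); otherwise a significant activation
shift of at least 5 mV classifies the variant as a gating gain-of-function
(hyperpolarizing) or loss-of-function (depolarizing), and anything else is
WT-like.  Heterozygous (1:1 co-expression) classification: significantly
below 50% of WT is dominant-negative (DN), significantly below WT but at
least 50% is partial rescue (pR, haploinsufficiency-like), no significant
difference is full rescue (fR), and significantly above WT is enhanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SIGNIFICANCE_LEVEL", "VariantResult", "RelativeMetrics",
           "PharmacologyResponse", "relative_metrics", "compare_groups",
           "classify_homozygous", "classify_heterozygous", "classify_variant",
           "retigabine_response", "ClassificationError", "PlatePairingError"]

SIGNIFICANCE_LEVEL = 0.01
VHALF_SHIFT_THRESHOLD = 5.0  # mV

HOMOZYGOUS_CLASSES = ("profound_LOF", "severe_LOF", "partial_LOF",
                      "WT_like", "GOF_shift", "LOF_shift")
HETEROZYGOUS_CLASSES = ("DN", "pR", "fR", "enhanced")


class ClassificationError(ValueError):
    """Raised when classification is requested without the required inputs."""


class PlatePairingError(ValueError):
    """Raised when variant and WT cohorts come from different plates."""


@dataclass(frozen=True)
class RelativeMetrics:
    percent_wt_density: float          # % of parallel WT at +40 mV
    delta_vhalf: float                 # mV, variant minus WT
    tau_ratio: dict[float, float] | None  # per voltage, variant/WT
    n_variant: int
    n_wt: int


@dataclass
class VariantResult:
    """Relative metrics, p-values and class labels for one variant/zygosity."""

    variant: str
    zygosity: str
    percent_wt_density: float = float("nan")
    delta_vhalf: float = float("nan")
    tau_ratio: dict[float, float] | None = None
    p_density: float | None = None
    p_vhalf: float | None = None
    n_variant: int = 0
    n_wt: int = 0
    class_homozygous: str | None = None
    class_heterozygous: str | None = None
    retigabine_response_pct: float = float("nan")


_REQUIRED_COLUMNS = ("density_40", "v_half")


def _check_table(df: pd.DataFrame, who: str) -> None:
    if len(df) == 0:
        raise ValueError(f"{who} cohort is empty")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{who} cohort table lacks columns {missing}")


def _check_plates(variant_df: pd.DataFrame, wt_df: pd.DataFrame) -> None:
    if "plate" not in variant_df.columns or "plate" not in wt_df.columns:
        return
    vp, wp = set(variant_df["plate"]), set(wt_df["plate"])
    if not vp & wp:
        raise PlatePairingError(
            f"variant plates {sorted(vp)} share no plate with WT {sorted(wp)}; "
            "relative metrics require a parallel WT cohort")


def relative_metrics(variant_cells: pd.DataFrame, wt_cells: pd.DataFrame,
                     include_tau: bool = True) -> RelativeMetrics:
    """Variant metrics relative to the WT cohort assayed in parallel.

    Both inputs are per-cell summary tables (one row per QC-passed cell)
    with columns ``density_40`` (pA/pF at +40 mV), ``v_half`` (mV, NaN for
    unfittable cells), optional ``tau_<v>`` columns and a ``plate`` label.
    """
    _check_table(variant_cells, "variant")
    _check_table(wt_cells, "WT")
    _check_plates(variant_cells, wt_cells)

    wt_mean = float(wt_cells["density_40"].mean())
    if wt_mean <= 0:
        raise ValueError("parallel WT mean density at +40 mV must be positive")
    percent = 100.0 * float(variant_cells["density_40"].mean()) / wt_mean

    dv = float(variant_cells["v_half"].mean() - wt_cells["v_half"].mean())

    tau_ratio = None
    if include_tau:
        tau_cols = [c for c in variant_cells.columns
                    if c.startswith("tau_") and c in wt_cells.columns]
        if tau_cols:
            tau_ratio = {}
            for c in tau_cols:
                wt_tau = float(wt_cells[c].mean())
                tau_ratio[float(c[4:].replace("m", "-"))] = (
                    float(variant_cells[c].mean()) / wt_tau if wt_tau > 0
                    else float("nan"))
    return RelativeMetrics(percent, dv, tau_ratio,
                           n_variant=len(variant_cells), n_wt=len(wt_cells))


def compare_groups(*groups, mode: str = "ttest") -> float:
    """Two-tailed p-value for a difference among groups of per-cell values.

    ``mode='ttest'`` runs a two-sample two-tailed t test (exactly two
    groups); ``mode='anova'`` a one-way ANOVA F test (two or more groups).
    Degenerate input (zero variance everywhere with equal means) returns
    p = 1 by convention.  NaN values are dropped.
    """
    arrays = [np.asarray(g, float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2 finite values")

    means = [a.mean() for a in arrays]
    if all(a.std(ddof=1) == 0 for a in arrays):
        if all(np.isclose(m, means[0]) for m in means):
            return 1.0
        return 0.0

    if mode == "ttest":
        if len(arrays) != 2:
            raise ValueError("ttest mode requires exactly two groups")
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return float(res.pvalue)
    if mode == "anova":
        if len(arrays) < 2:
            raise ValueError("anova mode requires at least two groups")
        res = stats.f_oneway(*arrays)
        return float(res.pvalue)
    raise ValueError("mode must be 'ttest' or 'anova'")


def is_significant(p: float | None, alpha: float = SIGNIFICANCE_LEVEL) -> bool:
    return p is not None and math.isfinite(p) and p <= alpha


def classify_homozygous(percent_wt_density: float, delta_vhalf: float,
                        p_density: float | None,
                        p_vhalf: float | None) -> str:
    """Functional class of a variant expressed without WT KCNQ2.

    Density bins (all requiring p <= 0.01 vs parallel WT): <= 10% profound
    LOF, < 25% severe LOF, [25, 75)% partial LOF.  Failing those, a
    significant |delta V1/2| >= 5 mV gives GOF_shift (hyperpolarizing) or
    LOF_shift (depolarizing); otherwise WT_like.
    """
    if not math.isfinite(percent_wt_density):
        raise ClassificationError("percent_wt_density is not available")
    sig_density = is_significant(p_density)
    if sig_density and percent_wt_density <= 10.0:
        return "profound_LOF"
    if sig_density and percent_wt_density < 25.0:
        return "severe_LOF"
    if sig_density and 25.0 <= percent_wt_density < 75.0:
        return "partial_LOF"
    if (is_significant(p_vhalf) and math.isfinite(delta_vhalf)
            and abs(delta_vhalf) >= VHALF_SHIFT_THRESHOLD):
        return "GOF_shift" if delta_vhalf < 0 else "LOF_shift"
    return "WT_like"


def classify_heterozygous(percent_wt_density: float,
                          p_density: float | None) -> str:
    """Rescue class of a variant co-expressed 1:1 with WT KCNQ2.

    Significantly below 50% of WT: dominant-negative (DN); significantly
    below WT but >= 50%: partial rescue (pR); significantly above WT:
    enhanced; otherwise full rescue (fR).
    """
    if not math.isfinite(percent_wt_density):
        raise ClassificationError("percent_wt_density is not available")
    if not is_significant(p_density):
        return "fR"
    if percent_wt_density < 50.0:
        return "DN"
    if percent_wt_density <= 100.0:
        return "pR"
    return "enhanced"


def classify_variant(result: VariantResult) -> VariantResult:
    """Assign class labels on a populated ``VariantResult`` (in place and
    returned).  Refuses to classify when p-values are missing or either
    cohort has n < 2."""
    if result.p_density is None:
        raise ClassificationError("p_density missing; classification refused")
    if result.n_variant < 2 or result.n_wt < 2:
        raise ClassificationError("classification requires n >= 2 per group")
    if result.zygosity == "homozygous":
        result.class_homozygous = classify_homozygous(
            result.percent_wt_density, result.delta_vhalf,
            result.p_density, result.p_vhalf)
    elif result.zygosity == "heterozygous":
        result.class_heterozygous = classify_heterozygous(
            result.percent_wt_density, result.p_density)
    else:
        raise ClassificationError(
            f"no classification defined for zygosity {result.zygosity!r}")
    return result


@dataclass(frozen=True)
class PharmacologyResponse:
    """Retigabine response of one heterozygous variant, as percentages of
    the untreated parallel WT current density."""

    variant: str
    voltage: float
    retigabine_pct: float
    control_pct: float | None
    table: pd.DataFrame | None = None  # per-voltage percentages


def retigabine_response(variant_treated: pd.DataFrame,
                        wt_untreated: pd.DataFrame,
                        variant_control: pd.DataFrame | None = None,
                        voltage: float = -20.0,
                        variant: str = "variant") -> PharmacologyResponse:
    """Current density of a drug-treated heterozygous variant cohort as a
    percentage of the untreated WT cohort, at ``voltage`` (default -20 mV,
    near the foot of the WT activation curve where M-current shapes
    neuronal excitability).

    Inputs are per-cell summary tables with ``density_<v>`` columns for
    every step voltage (negative voltages encoded as e.g. ``density_m20``).
    Also reports the no-drug control percentage when given, and a
    per-voltage percentage table for the full I-V comparison.
    """
    col = _density_col(voltage)
    for df, who in ((variant_treated, "treated variant"), (wt_untreated, "untreated WT")):
        if col not in df.columns:
            raise ValueError(f"{who} table lacks column {col!r}")
        if len(df) == 0:
            raise ValueError(f"{who} cohort is empty")
    wt_ref = float(wt_untreated[col].mean())
    if wt_ref <= 0:
        raise ValueError(f"untreated WT density at {voltage} mV must be positive")

    pct = 100.0 * float(variant_treated[col].mean()) / wt_ref
    control_pct = None
    if variant_control is not None and col in variant_control.columns:
        control_pct = 100.0 * float(variant_control[col].mean()) / wt_ref

    rows = []
    for c in wt_untreated.columns:
        if not c.startswith("density_"):
            continue
        v = _col_voltage(c)
        wt_v = float(wt_untreated[c].mean())
        if wt_v == 0 or c not in variant_treated.columns:
            continue
        row = {"voltage_mV": v,
               "retigabine_pct": 100.0 * float(variant_treated[c].mean()) / wt_v}
        if variant_control is not None and c in variant_control.columns:
            row["control_pct"] = 100.0 * float(variant_control[c].mean()) / wt_v
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("voltage_mV").reset_index(drop=True) \
        if rows else None

    return PharmacologyResponse(variant=variant, voltage=voltage,
                                retigabine_pct=pct, control_pct=control_pct,
                                table=table)


def _density_col(voltage: float) -> str:
    v = int(round(voltage))
    return f"density_{'m' if v < 0 else ''}{abs(v)}"


def _col_voltage(col: str) -> float:
    tag = col[len("density_"):]
    sign = -1.0 if tag.startswith("m") else 1.0
    return sign * float(tag.lstrip("m"))
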