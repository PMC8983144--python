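"""Calibration experiments: end-to-end synthetic reproductions of the
assay's headline results.

Each function simulates cohorts with the default calibration, runs them
through the full pipeline (QC -> XE991 subtraction -> features -> per-cell
fits) and returns the summary quantities a bench scientist would report:
WT activation parameters, the retigabine gating shift and current
increase, the TEA concentration-response IC50, and the WT-vs-
nontransfected expression contrast.

Cohort sizes default to the scales of the source assay (hundreds of cells
for gating, ~60 per drug concentration, ~120 for the expression contrast);
the activation protocol is sampled at 1 ms, which leaves the 999 ms / 5 ms
measurement points and the 50-1000 ms kinetics window unchanged while
keeping an n=900 cohort comfortably in memory.  Drug comparisons use
paired cohorts that share one seed lineage, so the same virtual cells are
recorded with and without drug -- the in-silico analogue of applying the
drug to each recorded cell.
"""

from __future__ import annotations

import numpy as np

from .fitting import fit_hill
from .pipeline import analyze_cohort, qc_filter
from .processing import extract_features
from .protocols import default_protocol
from .simulate import DrugModel, SimConfig, simulate_cohort

__all__ = ["wt_activation", "retigabine_effects",
           "tea_concentration_response", "expression_contrast"]

_MOD = 2 ** 31


def _config(seed: int, n_cells: int, sampling_ms: float = 1.0) -> SimConfig:
    return SimConfig(protocol=default_protocol(sampling_ms),
                     n_cells=n_cells, seed=seed % _MOD)


def _gating_summary(df) -> dict:
    ok = df[df["fit_converged"]]
    return {"v_half": float(ok["v_half"].mean()),
            "slope": float(ok["slope"].mean()),
            "n": int(len(ok))}


def wt_activation(seed: int = 11, n_attempted: int = 900) -> dict:
    """Control WT cohort through the full pipeline; cohort-mean per-cell
    Boltzmann parameters (expected V1/2 ~ -18.9 mV, k ~ 7.6 mV)."""
    df = analyze_cohort(_config(seed, n_attempted), None, "homozygous",
                        group="WT")
    return _gating_summary(df)


def retigabine_effects(seed: int = 11, n_attempted: int = 900,
                       concentration_uM: float = 10.0) -> dict:
    """Paired control/retigabine WT cohorts (shared seed lineage).

    Reports cohort-mean fitted V1/2 under both conditions, the activation
    shift (treated minus control, expected ~ -29 mV), and the fold change
    in mean peak current density at +40 mV (expected ~ 1.4)."""
    cfg = _config(seed, n_attempted)
    ctrl = analyze_cohort(cfg, None, "homozygous", group="WT")
    trt = analyze_cohort(cfg, None, "homozygous", group="WT",
                         drugs=((DrugModel(kind="retigabine"), concentration_uM),))
    s_ctrl, s_trt = _gating_summary(ctrl), _gating_summary(trt)
    return {
        "v_half_control": s_ctrl["v_half"], "v_half_retigabine": s_trt["v_half"],
        "slope_control": s_ctrl["slope"], "slope_retigabine": s_trt["slope"],
        "delta_vhalf": s_trt["v_half"] - s_ctrl["v_half"],
        "density_fold": float(trt["density_40"].mean() / ctrl["density_40"].mean()),
        "n_control": s_ctrl["n"], "n_retigabine": s_trt["n"],
    }


def tea_concentration_response(seed: int = 11, n_attempted: int = 75,
                               concentrations_mM: tuple[float, ...] =
                               (1.0, 3.0, 10.0, 30.0, 100.0)) -> dict:
    """TEA block concentration-response through the pipeline.

    One drug-free cohort plus one cohort per concentration, all sharing a
    seed lineage; fractional block of the cohort-mean +40 mV density is
    fit to a Hill function (expected IC50 ~ 10.7 mM)."""
    cfg = _config(seed, n_attempted)
    tea = DrugModel(kind="tea")
    ref = analyze_cohort(cfg, None, "homozygous", group="WT")
    d0 = float(ref["density_40"].mean())
    block = {}
    n_min = len(ref)
    for c in concentrations_mM:
        df = analyze_cohort(cfg, None, "homozygous", group="WT",
                            drugs=((tea, c),))
        block[c] = 1.0 - float(df["density_40"].mean()) / d0
        n_min = min(n_min, len(df))
    fit = fit_hill(block)
    return {"ic50": fit.ic50, "hill_coeff": fit.hill_coeff,
            "converged": fit.converged, "block": block, "n_per_conc": n_min}


def expression_contrast(seed: int = 11, n_attempted: int = 150) -> dict:
    """Ratio of mean raw (unsubtracted) peak current density at +40 mV,
    WT-transfected vs nontransfected cohorts (expected ~ 20-fold)."""

    def raw_mean_density(zygosity: str, seed_: int) -> tuple[float, int]:
        recs = simulate_cohort(_config(seed_, n_attempted), None, zygosity)
        pairs = qc_filter(recs)
        dens = [extract_features(pre).density_at(40.0) for pre, _ in pairs]
        return float(np.mean(dens)), len(dens)

    wt, n_wt = raw_mean_density("homozygous", seed)
    nt, n_nt = raw_mean_density("nontransfected", seed + 1)
    return {"fold": wt / nt, "wt_density": wt, "nt_density": nt,
            "n_wt": n_wt, "n_nt": n_nt}
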