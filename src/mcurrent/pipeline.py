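"""End-to-end orchestration: simulate -> QC -> subtract -> features -> fits
-> per-cell summary tables -> classification and pharmacology.

The central intermediate is the per-cell summary ``DataFrame`` (one row
per cell that passed QC) with columns::

    cell_id, group, zygosity, drug, plate, capacitance_pF,
    density_<v> ... (pA/pF per step voltage, negative v as 'm<v>'),
    density_40, v_half, slope, fit_converged, fittable [, tau_<v> ...]

Downstream variant analysis consumes these tables directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .fitting import fit_activation_tau, fit_boltzmann
from .processing import extract_features, subtract_background
from .protocols import VoltageProtocol, default_protocol
from .records import CellRecording, pair_by_cell
from .simulate import (DrugModel, SimConfig, VariantEffect, simulate_cohort)
from .variants import (VariantResult, classify_variant, compare_groups,
                       relative_metrics)

__all__ = ["StageCounts", "RunConfig", "analyze_cohort", "summarize_cells",
           "qc_filter", "run_pipeline", "density_col"]

logger = logging.getLogger("mcurrent")


def density_col(voltage: float) -> str:
    v = int(round(voltage))
    return f"density_{'m' if v < 0 else ''}{abs(v)}"


@dataclass
class StageCounts:
    simulated: int = 0
    qc_passed: int = 0
    fittable: int = 0
    fit_converged: int = 0


def qc_filter(recordings: list[CellRecording],
              qc_config: qc_mod.QCConfig | None = None,
              chip_mode: str = "single") -> list[tuple[CellRecording, CellRecording]]:
    """Pair pre/post-XE991 recordings and keep cells where both
    recordings pass QC under their own condition-specific thresholds."""
    pairs = pair_by_cell(recordings)
    kept = []
    for pre, post in pairs:
        if (qc_mod.passes_qc(pre, qc_config, chip_mode).passed
                and qc_mod.passes_qc(post, qc_config, chip_mode).passed):
            kept.append((pre, post))
    return kept


def summarize_cells(pairs: Sequence[tuple[CellRecording, CellRecording]],
                    include_tau: bool = False,
                    tau_voltages: tuple[float, ...] | None = None,
                    counts: StageCounts | None = None) -> pd.DataFrame:
    """XE991-subtract each pair, extract features, fit the per-cell
    Boltzmann, and return the per-cell summary table."""
    rows = []
    for pre, post in pairs:
        m = subtract_background(pre, post)
        feats = extract_features(m)
        row: dict = {
            "cell_id": m.cell_id, "group": m.group, "zygosity": m.zygosity,
            "drug": m.drug, "plate": m.plate,
            "capacitance_pF": m.covariates.capacitance,
            "fittable": feats.fittable,
        }
        for v, d in zip(feats.voltages, feats.current_density):
            row[density_col(v)] = d
        if feats.fittable:
            fit = fit_boltzmann(
                (feats.voltages, feats.normalized_tail),
                span_voltages=(float(feats.voltages.min()),
                               float(feats.voltages.max())))
            row["v_half"] = fit.v_half if fit.converged else np.nan
            row["slope"] = fit.slope if fit.converged else np.nan
            row["fit_converged"] = fit.converged
        else:
            row["v_half"] = np.nan
            row["slope"] = np.nan
            row["fit_converged"] = False
        if include_tau:
            voltages = tau_voltages or tuple(
                v for v in m.protocol.step_voltages if -30.0 <= v <= 40.0)
            taufit = fit_activation_tau(m, voltage_range=(min(voltages), max(voltages)))
            for e in taufit.entries:
                if e.voltage in voltages:
                    row[f"tau_{'m' if e.voltage < 0 else ''}{abs(int(e.voltage))}"] = (
                        e.tau if e.converged else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    if counts is not None and len(df):
        counts.fittable += int(df["fittable"].sum())
        counts.fit_converged += int(df["fit_converged"].sum())
    return df


def analyze_cohort(config: SimConfig, effect: VariantEffect | None = None,
                   zygosity: str = "homozygous",
                   drugs: Sequence[tuple[DrugModel, float]] = (),
                   group: str = "WT", plate: str = "plate0",
                   qc_config: qc_mod.QCConfig | None = None,
                   include_tau: bool = False,
                   counts: StageCounts | None = None) -> pd.DataFrame:
    """Simulate one cohort and run it through the full per-cell pipeline."""
    recordings = simulate_cohort(config, effect, zygosity, drugs,
                                 group=group, plate=plate)
    if counts is not None:
        counts.simulated += len(recordings) // 2
    pairs = qc_filter(recordings, qc_config)
    if counts is not None:
        counts.qc_passed += len(pairs)
    return summarize_cells(pairs, include_tau=include_tau, counts=counts)


# ---------------------------------------------------------------------------
# Run configuration and the demo end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class VariantSpec:
    """One variant to assay: its generative effect and label."""

    label: str
    g_scale: float = 1.0
    delta_vhalf: float = 0.0
    slope_scale: float = 1.0
    tau_scale: float = 1.0
    dominance: float = 0.0

    def effect(self) -> VariantEffect:
        return VariantEffect(self.g_scale, self.delta_vhalf, self.slope_scale,
                             self.tau_scale, self.dominance)


@dataclass
class RunConfig:
    """Fully serializable configuration of an end-to-end run."""

    n_cells: int = 40
    seed: int = 0
    noise_rms: float = 5.0
    sampling_interval: float = 1.0
    zygosities: tuple[str, ...] = ("homozygous", "heterozygous")
    variants: list[VariantSpec] = field(default_factory=lambda: [
        VariantSpec("VAR_DN", g_scale=0.0, dominance=1.0),
        VariantSpec("VAR_HAPLO", g_scale=0.0, dominance=0.0),
        VariantSpec("VAR_SHIFT", g_scale=1.0, delta_vhalf=10.0),
    ])
    retigabine_uM: float = 10.0
    include_tau: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.variants = [v if isinstance(v, VariantSpec) else VariantSpec(**v)
                         for v in self.variants]

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self, seed_offset: int = 0) -> SimConfig:
        return SimConfig(
            protocol=default_protocol(self.sampling_interval),
            noise_rms=self.noise_rms, n_cells=self.n_cells,
            seed=(self.seed + seed_offset) % (2 ** 31))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulate -> qc -> process -> fit -> classify -> pharm for a
    WT cohort plus the configured variants, in both zygosity states, with
    and without retigabine.  Returns a run report dict; when ``out_dir``
    is given, writes the per-cell table, the per-variant result table and
    the retigabine heat-map matrix as tab-separated text stamped with the
    config hash and seed."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    counts = StageCounts()
    rtg = DrugModel(kind="retigabine")
    drug_arms: list[tuple[str, tuple]] = [("none", ())]
    if config.retigabine_uM > 0:
        drug_arms.append(("retigabine", ((rtg, config.retigabine_uM),)))

    tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    offset = 0
    for drug_label, drugs in drug_arms:
        sim = config.sim_config(seed_offset=offset)
        offset += 1
        tables[("WT", "homozygous", drug_label)] = analyze_cohort(
            sim, None, "homozygous", drugs, group="WT",
            include_tau=config.include_tau, counts=counts)
        logger.info("stage=simulate group=WT drug=%s cells=%d qc_passed=%d",
                    drug_label, config.n_cells,
                    len(tables[("WT", "homozygous", drug_label)]))
        for spec in config.variants:
            for zyg in config.zygosities:
                sim = config.sim_config(seed_offset=offset)
                offset += 1
                df = analyze_cohort(sim, spec.effect(), zyg, drugs,
                                    group=spec.label,
                                    include_tau=config.include_tau,
                                    counts=counts)
                tables[(spec.label, zyg, drug_label)] = df
                logger.info("stage=simulate group=%s zygosity=%s drug=%s "
                            "qc_passed=%d", spec.label, zyg, drug_label, len(df))

    wt_ctrl = tables[("WT", "homozygous", "none")]
    results: list[VariantResult] = []
    heatmap_rows = []
    for spec in config.variants:
        for zyg in config.zygosities:
            df = tables[(spec.label, zyg, "none")]
            if len(df) < 2 or len(wt_ctrl) < 2:
                raise RuntimeError(
                    f"cohort too small after QC for {spec.label}/{zyg}")
            metrics = relative_metrics(df, wt_ctrl, include_tau=config.include_tau)
            res = VariantResult(
                variant=spec.label, zygosity=zyg,
                percent_wt_density=metrics.percent_wt_density,
                delta_vhalf=metrics.delta_vhalf, tau_ratio=metrics.tau_ratio,
                p_density=compare_groups(df["density_40"], wt_ctrl["density_40"]),
                n_variant=metrics.n_variant, n_wt=metrics.n_wt)
            if df["v_half"].notna().sum() >= 2 and wt_ctrl["v_half"].notna().sum() >= 2:
                res.p_vhalf = compare_groups(df["v_half"], wt_ctrl["v_half"])
            classify_variant(res)
            results.append(res)

        if "heterozygous" in config.zygosities and config.retigabine_uM > 0:
            from .variants import retigabine_response
            resp = retigabine_response(
                tables[(spec.label, "heterozygous", "retigabine")], wt_ctrl,
                variant_control=tables[(spec.label, "heterozygous", "none")],
                variant=spec.label)
            heatmap_rows.append({"variant": spec.label,
                                 "control_pct": resp.control_pct,
                                 "retigabine_pct": resp.retigabine_pct})
            for res in results:
                if res.variant == spec.label and res.zygosity == "heterozygous":
                    res.retigabine_response_pct = resp.retigabine_pct

    result_table = pd.DataFrame([{
        "variant": r.variant, "zygosity": r.zygosity,
        "percent_wt_density": r.percent_wt_density,
        "delta_vhalf": r.delta_vhalf, "p_density": r.p_density,
        "p_vhalf": r.p_vhalf, "n_variant": r.n_variant, "n_wt": r.n_wt,
        "class": r.class_homozygous or r.class_heterozygous,
        "retigabine_response_pct": r.retigabine_response_pct,
    } for r in results])
    heatmap = pd.DataFrame(heatmap_rows)
    if len(heatmap):
        heatmap = heatmap.sort_values("control_pct").reset_index(drop=True)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": asdict(counts),
        "n_variants": len(config.variants),
        "results": result_table.to_dict(orient="records"),
        "heatmap": heatmap.to_dict(orient="records"),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"# config_hash={config.config_hash()} seed={config.seed}\n"
        cells = pd.concat(tables.values(), ignore_index=True)
        for name, df in (("cells.tsv", cells), ("variants.tsv", result_table),
                         ("retigabine_heatmap.tsv", heatmap)):
            path = out / name
            with open(path, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
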