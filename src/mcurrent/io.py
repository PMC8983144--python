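"""Delimited-text interchange for cohorts and configurations.

Traces travel as a long-format table (one row per sample) and a per-cell
metadata table; both are plain tab-separated text so that cohorts can be
inspected, diffed and versioned.  Schema violations are reported with the
offending column names rather than failing silently.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocols import VoltageProtocol
from .records import CellCovariates, CellRecording

__all__ = ["SchemaError", "write_cohort", "read_cohort",
           "write_table", "load_run_config", "save_run_config"]

TRACE_COLUMNS = ["cell_id", "group", "zygosity", "drug", "condition",
                 "step_mV", "time_ms", "current_pA"]
META_COLUMNS = ["cell_id", "plate", "capacitance_pF", "seal_GOhm", "rs_MOhm",
                "leak_nS", "expression_factor"]


class SchemaError(ValueError):
    """A table does not conform to the documented column schema."""


def write_cohort(recordings: list[CellRecording], out_dir: str | Path) -> None:
    """Write traces.tsv, metadata.tsv and protocol.yaml for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not recordings:
        raise ValueError("refusing to write an empty cohort")

    protocol = recordings[0].protocol
    times = protocol.times()
    frames = []
    for r in recordings:
        if r.protocol != protocol:
            raise ValueError("all recordings in a cohort must share a protocol")
        for v in protocol.step_voltages:
            frames.append(pd.DataFrame({
                "cell_id": r.cell_id, "group": r.group, "zygosity": r.zygosity,
                "drug": r.drug, "condition": r.condition, "step_mV": v,
                "time_ms": times, "current_pA": r.sweeps[v],
            }))
    pd.concat(frames, ignore_index=True).to_csv(
        out / "traces.tsv", sep="\t", index=False, float_format="%.17g")

    meta_rows = {}
    for r in recordings:
        c = r.covariates
        meta_rows[r.cell_id] = {
            "cell_id": r.cell_id, "plate": r.plate,
            "capacitance_pF": c.capacitance, "seal_GOhm": c.seal_resistance,
            "rs_MOhm": c.series_resistance, "leak_nS": c.leak_conductance,
            "expression_factor": c.expression_factor,
        }
    pd.DataFrame(meta_rows.values()).to_csv(
        out / "metadata.tsv", sep="\t", index=False, float_format="%.17g")

    proto = asdict(protocol)
    proto["step_voltages"] = list(protocol.step_voltages)
    with open(out / "protocol.yaml", "w") as fh:
        yaml.safe_dump(proto, fh)


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_cohort(in_dir: str | Path) -> list[CellRecording]:
    """Read a cohort written by :func:`write_cohort` (or any external data
    following the same schema)."""
    src = Path(in_dir)
    traces_path = src / "traces.tsv"
    meta_path = src / "metadata.tsv"
    with open(src / "protocol.yaml") as fh:
        proto_dict = yaml.safe_load(fh)
    proto_dict["step_voltages"] = tuple(proto_dict["step_voltages"])
    protocol = VoltageProtocol(**proto_dict)

    traces = pd.read_csv(traces_path, sep="\t", float_precision="round_trip")
    if len(traces) == 0:
        raise SchemaError(f"{traces_path}: file contains no rows")
    _require_columns(traces, TRACE_COLUMNS, traces_path)
    meta = pd.read_csv(meta_path, sep="\t", float_precision="round_trip")
    _require_columns(meta, META_COLUMNS, meta_path)
    meta = meta.set_index("cell_id")

    recordings = []
    for (cell_id, condition), sub in traces.groupby(["cell_id", "condition"],
                                                   sort=True):
        if cell_id not in meta.index:
            raise SchemaError(f"{meta_path}: no metadata row for cell {cell_id!r}")
        m = meta.loc[cell_id]
        cov = CellCovariates(
            capacitance=float(m["capacitance_pF"]),
            seal_resistance=float(m["seal_GOhm"]),
            series_resistance=float(m["rs_MOhm"]),
            leak_conductance=float(m["leak_nS"]),
            expression_factor=float(m["expression_factor"]))
        sweeps = {}
        for v, sweep in sub.groupby("step_mV"):
            sweep = sweep.sort_values("time_ms")
            sweeps[float(v)] = sweep["current_pA"].to_numpy()
        first = sub.iloc[0]
        recordings.append(CellRecording(
            cell_id=str(cell_id), group=str(first["group"]),
            zygosity=str(first["zygosity"]), drug=str(first["drug"]),
            condition=str(condition), covariates=cov, protocol=protocol,
            sweeps=sweeps, plate=str(m["plate"])))
    return recordings


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def load_run_config(path: str | Path):
    from .pipeline import RunConfig

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "zygosities" in data:
        data["zygosities"] = tuple(data["zygosities"])
    return RunConfig(**data)


def save_run_config(config, path: str | Path) -> None:
    data = config.to_dict()
    data["zygosities"] = list(data["zygosities"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
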