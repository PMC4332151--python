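"""Tidy TSV input/output for timeseries and expression matrices.

Timeseries tables use the columns (label, genotype, condition, zt, value);
expression matrices use (gene, condition, zt, value).  Parameter sets and
phenotype maps round-trip through YAML (see their classes).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .clustering import ExpressionMatrix
from .observables import Timeseries
from .simulate import SimulationResult

TS_COLUMNS = ("label", "genotype", "condition", "zt", "value")


def write_timeseries(series: dict[str, Timeseries], path,
                     genotype: str = "", condition: str = "") -> None:
    frames = []
    for label, ts in series.items():
        frames.append(pd.DataFrame({
            "label": label, "genotype": genotype, "condition": condition,
            "zt": ts.zt, "value": ts.value,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_timeseries(path) -> dict[str, Timeseries]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = {}
    for label, sub in df.groupby("label", sort=False):
        sub = sub.sort_values("zt")
        out[str(label)] = Timeseries(sub["zt"].to_numpy(float),
                                     sub["value"].to_numpy(float), label=str(label))
    return out


def write_trajectory(r: SimulationResult, path, sidecar: bool = True) -> None:
    """Tidy (species, zt, value) TSV plus a JSON metadata sidecar."""
    r.to_frame().to_csv(path, sep="\t", index=False)
    if sidecar:
        meta = {
            "genotype": r.genotype.label,
            "hours_light": r.environment.light.photoperiod.hours_light,
            "temperature": r.environment.temperature.label,
            "entrained": bool(r.entrained),
            "entrain_cycles": r.solver_report.entrain_cycles,
            "entrain_residual": r.solver_report.entrain_residual,
            "rtol": r.solver_report.rtol,
            "atol": r.solver_report.atol,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> ExpressionMatrix:
    return ExpressionMatrix.from_frame(pd.read_csv(path, sep="\t"))


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")
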