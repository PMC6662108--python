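"""Deterministic tabular and YAML helpers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """BED (0-based half-open) writer; expects chrom/start/end[/name]."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    df = intervals[cols].sort_values(["chrom", "start"], kind="mergesort")
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError("invalid BED intervals")
    df.to_csv(path, sep="\t", header=False, index=False)


def write_truth_yaml(truth, path: str | Path) -> None:
    doc = {
        "scaffold_placements": truth.scaffold_placements.to_dict(orient="records"),
        "centromeres": truth.centromeres.to_dict(orient="records"),
        "genetic_map": truth.genetic_map.to_dict(orient="records"),
        "qtls": truth.qtls.to_dict(orient="records") if truth.qtls is not None else None,
        "h2": dict(truth.h2),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_truth_yaml(path: str | Path):
    from ..simdata.config import SimTruth

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimTruth(
        scaffold_placements=pd.DataFrame(doc["scaffold_placements"]),
        centromeres=pd.DataFrame(doc["centromeres"]),
        genetic_map=pd.DataFrame(doc["genetic_map"]),
        qtls=pd.DataFrame(doc["qtls"]) if doc.get("qtls") else None,
        h2=doc.get("h2", {}),
    )
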