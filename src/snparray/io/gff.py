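"""GFF3 feature I/O (1-based inclusive coordinates)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

_COLUMNS = ["seq", "type", "start", "end", "strand", "feature_id", "parent"]


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into the package's feature-frame layout.

    Malformed lines (wrong column count, non-numeric or inverted
    coordinates) are rejected with their line number.
    """
    import gffutils

    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {ln}: expected 9 columns, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}: line {ln}: invalid interval {start}-{end}")

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.all_features(order_by=("seqid", "start")):
        parent = feat.attributes.get("Parent", [None])[0]
        rows.append(
            (feat.seqid, feat.featuretype, feat.start, feat.end, feat.strand, feat.id, parent)
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Deterministic GFF3 writer for the feature-frame layout."""
    df = features.sort_values(["seq", "start", "feature_id"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples():
            attrs = f"ID={row.feature_id}"
            if row.parent:
                attrs += f";Parent={row.parent}"
            fh.write(
                f"{row.seq}\tsnparray\t{row.type}\t{int(row.start)}\t{int(row.end)}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def gff_to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end
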