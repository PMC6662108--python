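"""AGP v2.1 writing/reading for map-based assembly layouts."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "component_id", "component_beg", "component_end", "orientation",
]
GAP_SIZE = 100


def build_agp(layout: pd.DataFrame, placements) -> pd.DataFrame:
    """AGP rows for chromosomes with placed scaffolds inserted.

    Each scaffold is inserted at the midpoint of its insertion interval with
    a 100 bp U gap on each side; unplaced scaffolds are emitted as their own
    single-component objects.
    """
    lengths = dict(zip(layout["seq"], layout["length_bp"]))
    by_chrom: dict[str, list] = {}
    placed = set()
    for p in placements:
        by_chrom.setdefault(p.chrom, []).append(p)
        placed.add(p.scaffold)
    rows = []
    for row in layout.itertuples():
        if row.kind != "chromosome":
            continue
        chrom, clen = row.seq, int(row.length_bp)
        inserts = sorted(
            by_chrom.get(chrom, []),
            key=lambda p: (sum(p.insertion_interval) / 2, p.scaffold),
        )
        parts = []
        prev = 1
        for p in inserts:
            mid = max(min(int(sum(p.insertion_interval) / 2), clen - 1), prev)
            if mid >= prev:
                parts.append(("W", chrom, prev, mid, "+"))
            parts.append(("N", "gap", None, None, None))
            orient = p.orientation if p.orientation in ("+", "-") else "?"
            parts.append(("W", p.scaffold, 1, int(lengths[p.scaffold]), orient))
            parts.append(("N", "gap", None, None, None))
            prev = mid + 1
        if prev <= clen:
            parts.append(("W", chrom, prev, clen, "+"))
        obj_pos = 1
        for k, part in enumerate(parts, start=1):
            if part[0] == "N":
                rows.append((chrom, obj_pos, obj_pos + GAP_SIZE - 1, k, "U",
                             str(GAP_SIZE), "scaffold", "yes", "map"))
                obj_pos += GAP_SIZE
            else:
                _, cid, cbeg, cend, orient = part
                span = cend - cbeg + 1
                rows.append((chrom, obj_pos, obj_pos + span - 1, k, "W",
                             cid, cbeg, cend, orient))
                obj_pos += span
    for row in layout.itertuples():
        if row.kind == "scaffold" and row.seq not in placed:
            rows.append((row.seq, 1, int(row.length_bp), 1, "W", row.seq, 1,
                         int(row.length_bp), "+"))
    return pd.DataFrame(rows, columns=AGP_COLUMNS)


def write_agp(rows: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows.itertuples(index=False):
            fh.write("\t".join("" if v is None else str(v) for v in r) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    """Parse an AGP file back into the row frame; errors name line numbers."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {ln}: expected 9 columns, got {len(parts)}")
            try:
                ob, oe, pn = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer object coordinates") from exc
            if ob < 1 or oe < ob:
                raise ValueError(f"{path}: line {ln}: invalid object interval")
            ctype = parts[4]
            if ctype in ("N", "U"):
                rows.append((parts[0], ob, oe, pn, ctype, parts[5], parts[6], parts[7], parts[8]))
            else:
                rows.append((parts[0], ob, oe, pn, ctype, parts[5], int(parts[6]),
                             int(parts[7]), parts[8]))
    return pd.DataFrame(rows, columns=AGP_COLUMNS)
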