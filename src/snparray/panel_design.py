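"""Array panel selection from multi-group diversity data.

Implements the per-group MAF/missingness filters, windowed LD pruning,
four-group merging with a Venn accounting, functional site annotation,
minimum-spacing thinning with priority tiers, and spacing summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

SEVERITY_ORDER = [
    "CDS_stop_gain_or_loss",
    "CDS_nonsynonymous",
    "CDS_synonymous",
    "CDS_unresolved",
    "intron",
    "promoter",
    "intergenic",
]

TIERS = {"forced": 3, "trait": 2, "cds": 1, "other": 0}


@dataclass
class PanelDesignParams:
    maf_min: float = 0.1
    missing_max: float = 0.10
    ld_r2_max: float = 0.4
    ld_window_bp: int = 50_000
    min_spacing_bp: int = 200
    promoter_bp: int = 2000
    forced_include: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in (0, 0.5]")
        for name in ("missing_max", "ld_r2_max"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_spacing_bp < 1:
            raise ValueError("min_spacing_bp must be >= 1")


@dataclass
class PanelSelection:
    """Kept variants plus provenance: which groups retained each one, the
    priority tier it entered with and whether it was forced in."""

    kept: list[str]
    provenance: pd.DataFrame  # index variant, columns: groups, tier, forced, anno_class


@dataclass
class VennTable:
    """Counts per non-empty membership pattern over the four groups."""

    counts: dict[frozenset, int]

    def cell(self, *groups: str) -> int:
        return self.counts.get(frozenset(groups), 0)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SiteAnnotation:
    klass: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in SEVERITY_ORDER:
            raise ValueError(f"unknown annotation class {self.klass!r}")


@dataclass
class CodonContext:
    """Reference codon in coding orientation plus the variant's offset."""

    ref_codon: str
    pos_in_codon: int  # 0, 1, 2
    strand: str  # '+' or '-'


# ----------------------------------------------------------------------
def filter_group_variants(g: GenotypeMatrix, params: PanelDesignParams) -> list[str]:
    """Variant ids passing MAF >= maf_min and missing fraction < missing_max.

    MAF is computed by allele counting over non-missing calls only; variants
    with zero non-missing calls are excluded with a warning, order preserved.
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    miss = g.missing_fraction()
    maf = g.maf()
    all_missing = np.isnan(maf)
    if all_missing.any():
        for vid in np.asarray(g.variant_ids)[all_missing]:
            log.warning("variant %s has zero non-missing calls; excluded", vid)
    keep = (~all_missing) & (np.nan_to_num(maf) >= params.maf_min) & (miss < params.missing_max)
    return [v for v, k in zip(g.variant_ids, keep) if k]


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        log.warning("zero-variance variant in r2 computation; r2 defined as 0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_prune(g: GenotypeMatrix, params: PanelDesignParams) -> list[str]:
    """Greedy left-to-right LD pruning within ``ld_window_bp``.

    A variant is dropped if its r2 with any already-kept variant within the
    window (same sequence) is >= ``ld_r2_max``.
    """
    kept: list[str] = []
    kept_pos: dict[str, list[tuple[int, int]]] = {}  # chrom -> [(pos, col)]
    ids = g.variant_ids
    chroms = g.variants["chrom"].to_numpy()
    poss = g.variants["pos"].to_numpy()
    for j, vid in enumerate(ids):
        chrom, pos = chroms[j], int(poss[j])
        window = kept_pos.get(chrom, [])
        drop = False
        for kpos, kcol in reversed(window):
            if pos - kpos > params.ld_window_bp:
                break
            if _pairwise_r2(g.dosage[:, kcol], g.dosage[:, j]) >= params.ld_r2_max:
                drop = True
                break
        if not drop:
            kept.append(vid)
            kept_pos.setdefault(chrom, []).append((pos, j))
    return kept


def merge_group_panels(
    group_kept: dict[str, list[str]], genome_order: list[str]
) -> tuple[list[str], VennTable]:
    """Union of the per-group panels in genome order plus Venn accounting."""
    membership: dict[str, set[str]] = {}
    for group, ids in group_kept.items():
        for vid in ids:
            membership.setdefault(vid, set()).add(group)
    union = [v for v in genome_order if v in membership]
    if len(union) != len(membership):
        missing = set(membership) - set(union)
        raise ValueError(f"kept ids absent from genome order: {sorted(missing)[:5]}")
    counts: dict[frozenset, int] = {}
    for vid in union:
        key = frozenset(membership[vid])
        counts[key] = counts.get(key, 0) + 1
    return union, VennTable(counts)


def pairwise_common_counts(venn: VennTable) -> dict[str, int]:
    """Per-pair shared counts plus the union-of-pairwise-intersections size.

    A SNP in k >= 2 groups contributes to every one of its C(k,2) pairs; the
    ``union_of_pairs`` entry counts each such SNP once.
    """
    from itertools import combinations

    groups = sorted({g for key in venn.counts for g in key})
    out: dict[str, int] = {}
    for a, b in combinations(groups, 2):
        out[f"{a}&{b}"] = sum(n for key, n in venn.counts.items() if a in key and b in key)
    out["union_of_pairs"] = sum(n for key, n in venn.counts.items() if len(key) >= 2)
    return out


# ----------------------------------------------------------------------
def annotate_site(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genes: pd.DataFrame,
    promoter_bp: int = 2000,
    codon_context: CodonContext | None = None,
) -> SiteAnnotation:
    """Classify a variant site against a gene-feature frame.

    ``genes`` uses the layout written by the simulator / GFF3 reader:
    columns ``seq``, ``type``, ``start``, ``end``, ``strand``,
    ``feature_id``, ``parent`` (1-based inclusive coordinates).  The most
    severe class across overlapping transcripts is reported.
    """
    sub = genes[genes["seq"] == chrom]
    best: SiteAnnotation | None = None

    def consider(cand: SiteAnnotation) -> None:
        nonlocal best
        if best is None or SEVERITY_ORDER.index(cand.klass) < SEVERITY_ORDER.index(best.klass):
            best = cand

    genes_here = sub[(sub["type"] == "gene") & (sub["start"] <= pos) & (sub["end"] >= pos)]
    for grow in genes_here.itertuples():
        cds = sub[(sub["type"] == "CDS") & (sub["start"] <= pos) & (sub["end"] >= pos)]
        in_cds = not cds.empty
        if in_cds:
            if codon_context is None:
                consider(SiteAnnotation("CDS_unresolved", grow.feature_id))
            else:
                consider(SiteAnnotation(_cds_class(ref, alt, codon_context), grow.feature_id))
        else:
            consider(SiteAnnotation("intron", grow.feature_id))

    if best is None or SEVERITY_ORDER.index(best.klass) > SEVERITY_ORDER.index("promoter"):
        promoters = sub[sub["type"] == "gene"]
        for grow in promoters.itertuples():
            if grow.strand == "-":
                lo, hi = grow.end + 1, grow.end + promoter_bp
            else:
                lo, hi = grow.start - promoter_bp, grow.start - 1
            if lo <= pos <= hi:
                consider(SiteAnnotation("promoter", grow.feature_id))
                break

    return best if best is not None else SiteAnnotation("intergenic")


def _cds_class(ref: str, alt: str, ctx: CodonContext) -> str:
    codon = ctx.ref_codon.upper()
    if len(codon) != 3 or ctx.pos_in_codon not in (0, 1, 2):
        return "CDS_unresolved"
    ref_c, alt_c = ref.upper(), alt.upper()
    if ctx.strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref_c, alt_c = comp.get(ref_c, "N"), comp.get(alt_c, "N")
    if codon[ctx.pos_in_codon] != ref_c:
        return "CDS_unresolved"
    alt_codon = codon[: ctx.pos_in_codon] + alt_c + codon[ctx.pos_in_codon + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "CDS_synonymous"
    if (aa_ref == "*") != (aa_alt == "*"):
        return "CDS_stop_gain_or_loss"
    return "CDS_nonsynonymous"


# ----------------------------------------------------------------------
def thin_uniform(candidates: pd.DataFrame, params: PanelDesignParams) -> PanelSelection:
    """Minimum-spacing thinning with priority tiers.

    ``candidates`` columns: ``variant``, ``chrom``, ``pos`` and optionally
    ``tier`` (name in :data:`TIERS` or integer) and ``anno_class``.  Higher
    tiers win spacing conflicts; forced variants (tier ``forced`` or listed
    in ``params.forced_include``) are always kept and do not consume spacing.
    Deterministic: ties broken by (tier, position).
    """
    import bisect

    if candidates.empty:
        return PanelSelection(kept=[], provenance=pd.DataFrame(
            columns=["groups", "tier", "forced", "anno_class"]))
    df = candidates.copy()
    if "tier" not in df.columns:
        df["tier"] = "other"
    tier_num = df["tier"].map(lambda t: TIERS.get(t, t if isinstance(t, int) else 0))
    forced_set = set(params.forced_include)
    forced = df["variant"].isin(forced_set) | (df["tier"] == "forced")
    df = df.assign(tiernum=tier_num, forcedflag=forced)

    kept_rows = []
    accepted: dict[str, list[int]] = {}
    order = df.sort_values(["forcedflag", "tiernum", "pos"], ascending=[False, False, True],
                           kind="mergesort")
    for row in order.itertuples():
        if row.forcedflag:
            kept_rows.append(row)
            continue
        positions = accepted.setdefault(row.chrom, [])
        i = bisect.bisect_left(positions, row.pos)
        ok = True
        if i > 0 and row.pos - positions[i - 1] < params.min_spacing_bp:
            ok = False
        if i < len(positions) and positions[i] - row.pos < params.min_spacing_bp:
            ok = False
        if ok:
            bisect.insort(positions, row.pos)
            kept_rows.append(row)

    kept_df = pd.DataFrame(kept_rows).sort_values(["chrom", "pos"], kind="mergesort")
    prov = pd.DataFrame(
        {
            "groups": kept_df.get("groups", pd.Series("", index=kept_df.index)),
            "tier": kept_df["tier"].values,
            "forced": kept_df["forcedflag"].values,
            "anno_class": kept_df.get("anno_class", pd.Series("", index=kept_df.index)).values,
        },
        index=pd.Index(kept_df["variant"], name="variant"),
    )
    return PanelSelection(kept=list(kept_df["variant"]), provenance=prov)


# ----------------------------------------------------------------------
SPACING_BINS = [(0, 2_000), (2_000, 5_000), (5_000, 10_000), (10_000, 100_000), (100_000, None)]


@dataclass
class SpacingStats:
    histogram: dict[str, int]
    n_gaps: int
    fraction_lt_10kb: float
    mean_gap: float
    max_gap: int
    n_gt_100kb: int


def spacing_stats(positions_by_chrom: dict[str, np.ndarray]) -> SpacingStats:
    """Adjacent-gap histogram over chromosomes (single-marker ones skipped)."""
    gaps: list[int] = []
    for chrom, pos in positions_by_chrom.items():
        pos = np.sort(np.asarray(pos))
        if pos.size < 2:
            log.warning("chromosome %s has < 2 markers; contributes no gaps", chrom)
            continue
        gaps.extend(np.diff(pos).astype(int))
    arr = np.asarray(gaps, dtype=float)
    hist: dict[str, int] = {}
    for lo, hi in SPACING_BINS:
        label = f"[{lo},{hi})" if hi is not None else f"[{lo},inf)"
        if arr.size == 0:
            hist[label] = 0
        else:
            hist[label] = int(((arr >= lo) & ((arr < hi) if hi is not None else True)).sum())
    if arr.size == 0:
        return SpacingStats(hist, 0, float("nan"), float("nan"), 0, 0)
    return SpacingStats(
        histogram=hist,
        n_gaps=int(arr.size),
        fraction_lt_10kb=float((arr < 10_000).mean()),
        mean_gap=float(arr.mean()),
        max_gap=int(arr.max()),
        n_gt_100kb=int((arr > 100_000).sum()),
    )
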