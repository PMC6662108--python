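"""Centromere localisation and genetic-map-based scaffold anchoring.

Centromeres are called from two independent signals: a valley in marker
density over sliding windows and a valley in local recombination rate from a
monotone Marey fit (cM vs bp); the consensus is their intersection.
Unanchored scaffolds are assigned to the linkage group holding the majority
of their mapped SNPs and inserted at the physical gap bracketing their
median cM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

log = logging.getLogger(__name__)


@dataclass
class ScanParams:
    window_bp: int = 150_000
    step_bp: int | None = None  # default window_bp // 2
    low_density_quantile: float = 0.25
    smoothing_halfwidth: int = 1  # windows; 0 disables smoothing

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.step_bp is None:
            self.step_bp = self.window_bp // 2
        if self.step_bp <= 0 or self.step_bp > self.window_bp:
            raise ValueError("step_bp must lie in (0, window_bp]")
        if not (0.0 < self.low_density_quantile < 1.0):
            raise ValueError("low_density_quantile must lie in (0, 1)")


@dataclass
class CentromereCall:
    chrom: str
    density_interval: tuple[int, int] | None
    rf_interval: tuple[int, int] | None
    consensus: tuple[int, int] | None
    support: str  # 'density', 'rf' or 'both'


@dataclass
class ScaffoldPlacement:
    scaffold: str
    chrom: str
    insertion_interval: tuple[int, int]
    orientation: str  # '+', '-' or '?'
    n_support_snps: int
    conflict: bool

    def __post_init__(self) -> None:
        if self.n_support_snps < 1:
            raise ValueError("placed scaffolds need >= 1 supporting SNP")


@dataclass
class AssemblyStats:
    total_bp: int
    anchored_bp_before: int
    anchored_bp_after: int

    @property
    def pct_before(self) -> float:
        return round(100.0 * self.anchored_bp_before / self.total_bp, 1)

    @property
    def pct_after(self) -> float:
        return round(100.0 * self.anchored_bp_after / self.total_bp, 1)

    @property
    def improvement_points(self) -> float:
        return round(self.pct_after - self.pct_before, 1)


# ----------------------------------------------------------------------
def window_density(positions: np.ndarray, chrom_length: int, params: ScanParams) -> pd.DataFrame:
    """Marker counts per sliding window ``[start, start + window)``.

    The last partial window is included and flagged.
    """
    positions = np.sort(np.asarray(positions))
    if positions.size and (positions.min() < 1 or positions.max() > chrom_length):
        raise ValueError("positions out of chromosome bounds")
    starts = np.arange(0, max(chrom_length, 1), params.step_bp)
    rows = []
    for s in starts:
        e = s + params.window_bp
        count = int(np.searchsorted(positions, e) - np.searchsorted(positions, s + 1))
        # positions are 1-based; window [s, e) in 0-based bp covers 1-based (s, e]
        rows.append((int(s), int(min(e, chrom_length)), count, e > chrom_length))
        if e >= chrom_length:
            break
    return pd.DataFrame(rows, columns=["start", "end", "count", "partial"])


def _valley_from_values(values: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                        params: ScanParams, mid: float) -> tuple[int, int] | None:
    v = np.asarray(values, dtype=float)
    h = params.smoothing_halfwidth
    if h > 0:
        kernel = np.ones(2 * h + 1)
        sm = np.convolve(v, kernel, mode="same") / np.convolve(np.ones_like(v), kernel, mode="same")
    else:
        sm = v
    thr = np.quantile(sm, params.low_density_quantile)
    below = sm <= thr
    if not below.any():
        return None
    runs = []
    i = 0
    while i < below.size:
        if below[i]:
            j = i
            while j + 1 < below.size and below[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    best = None
    for i, j in runs:
        length = j - i + 1
        center = (starts[i] + ends[j]) / 2.0
        key = (-length, abs(center - mid))
        if best is None or key < best[0]:
            best = (key, (int(starts[i]), int(ends[j])))
    return best[1]


def detect_density_valley(profile: pd.DataFrame, params: ScanParams,
                          chrom_length: int | None = None) -> tuple[int, int] | None:
    """Longest below-quantile run of (smoothed) window counts, ties broken
    by proximity to the chromosome midpoint.  None when no window qualifies
    (uniform counts)."""
    if len(profile) < 10:
        raise ValueError("need >= 10 windows for valley detection")
    counts = profile["count"].to_numpy(dtype=float)
    if np.allclose(counts, counts[0]):
        return None
    mid = (chrom_length if chrom_length is not None else float(profile["end"].iloc[-1])) / 2.0
    return _valley_from_values(
        counts, profile["start"].to_numpy(), profile["end"].to_numpy(), params, mid
    )


def marey_fit(pos_bp: np.ndarray, cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Monotone piecewise-linear Marey curve (bp -> cM) via isotonic
    regression (pool-adjacent-violators); returns (sorted bp, fitted cM)."""
    order = np.argsort(pos_bp)
    x = np.asarray(pos_bp, dtype=float)[order]
    y = np.asarray(cm, dtype=float)[order]
    if np.any(np.diff(y) < 0):
        log.info("non-monotone marker set; applying monotone regression")
    # PAVA
    yhat = y.copy()
    w = np.ones_like(yhat)
    blocks = [[i] for i in range(len(yhat))]
    vals = list(yhat)
    ws = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-12:
            tot = ws[i] + ws[i + 1]
            merged = (vals[i] * ws[i] + vals[i + 1] * ws[i + 1]) / tot
            vals[i : i + 2] = [merged]
            ws[i : i + 2] = [tot]
            blocks[i : i + 2] = [blocks[i] + blocks[i + 1]]
            if i > 0:
                i -= 1
        else:
            i += 1
    for val, blk in zip(vals, blocks):
        for k in blk:
            yhat[k] = val
    return x, yhat


def rf_valley(pos_bp: np.ndarray, cm: np.ndarray, chrom_length: int,
              params: ScanParams) -> tuple[int, int] | None:
    """Low-recombination interval from windowed Marey-curve slopes."""
    pos_bp = np.asarray(pos_bp, dtype=float)
    if pos_bp.size < 10:
        raise ValueError("need >= 10 anchored markers for an rf valley")
    x, yhat = marey_fit(pos_bp, cm)
    starts = np.arange(0, chrom_length, params.step_bp)
    rows = []
    for s in starts:
        e = min(s + params.window_bp, chrom_length)
        c0 = float(np.interp(s, x, yhat))
        c1 = float(np.interp(e, x, yhat))
        rows.append((int(s), int(e), (c1 - c0) / max(e - s, 1)))
        if s + params.window_bp >= chrom_length:
            break
    df = pd.DataFrame(rows, columns=["start", "end", "slope"])
    slopes = df["slope"].to_numpy()
    if np.allclose(slopes, slopes[0]):
        return None
    return _valley_from_values(slopes, df["start"].to_numpy(), df["end"].to_numpy(),
                               params, chrom_length / 2.0)


def consensus_centromere(
    chrom: str,
    density_interval: tuple[int, int] | None,
    rf_interval: tuple[int, int] | None,
) -> CentromereCall | None:
    """Intersection of the two signals when they overlap, else the density
    interval alone; None when both signals are absent."""
    if density_interval is None and rf_interval is None:
        return None
    if density_interval is not None and rf_interval is not None:
        lo = max(density_interval[0], rf_interval[0])
        hi = min(density_interval[1], rf_interval[1])
        if lo <= hi:
            return CentromereCall(chrom, density_interval, rf_interval, (lo, hi), "both")
        log.warning("%s: density and rf centromere signals are disjoint", chrom)
        return CentromereCall(chrom, density_interval, rf_interval, density_interval, "density")
    if density_interval is not None:
        return CentromereCall(chrom, density_interval, None, density_interval, "density")
    return CentromereCall(chrom, None, rf_interval, rf_interval, "rf")


# ----------------------------------------------------------------------
def anchor_scaffolds(
    scaffold_snps: pd.DataFrame,
    anchored: pd.DataFrame,
    lg_chrom: dict[str, str],
) -> tuple[list[ScaffoldPlacement], list[str]]:
    """Place scaffolds on chromosomes via their mapped SNPs.

    Parameters
    ----------
    scaffold_snps:
        One row per mapped scaffold-borne SNP: ``scaffold``, ``local_bp``,
        ``lg``, ``cm``.
    anchored:
        Chromosome-anchored mapped markers: ``chrom``, ``pos``, ``cm``.
    lg_chrom:
        Linkage group -> chromosome labels.

    Returns (placements, unplaced scaffold ids).
    """
    placements: list[ScaffoldPlacement] = []
    unplaced: list[str] = []
    for scaffold, sub in scaffold_snps.groupby("scaffold", sort=True):
        counts = sub["lg"].value_counts()
        top = counts.index[sorted(
            range(len(counts)), key=lambda i: (-counts.iloc[i], str(counts.index[i]))
        )[0]]
        if (counts == counts.max()).sum() > 1:
            log.warning("scaffold %s ties between linkage groups; unplaced", scaffold)
            unplaced.append(scaffold)
            continue
        conflict = len(counts) > 1
        chrom = lg_chrom.get(top)
        if chrom is None:
            unplaced.append(scaffold)
            continue
        onlg = sub[sub["lg"] == top]
        med_cm = float(onlg["cm"].median())
        anch = anchored[anchored["chrom"] == chrom].sort_values("cm")
        before = anch[anch["cm"] <= med_cm]
        after = anch[anch["cm"] >= med_cm]
        lo = int(before["pos"].iloc[-1]) if len(before) else 1
        hi = int(after["pos"].iloc[0]) if len(after) else int(anch["pos"].max()) if len(anch) else 1
        if lo > hi:
            lo, hi = hi, lo
        orientation = "?"
        pts = onlg[["local_bp", "cm"]].drop_duplicates()
        if pts["local_bp"].nunique() >= 2 and pts["cm"].nunique() >= 2:
            rho = spearmanr(pts["local_bp"], pts["cm"]).statistic
            if rho > 0:
                orientation = "+"
            elif rho < 0:
                orientation = "-"
        placements.append(
            ScaffoldPlacement(
                scaffold=str(scaffold),
                chrom=chrom,
                insertion_interval=(lo, hi),
                orientation=orientation,
                n_support_snps=int(len(sub)),
                conflict=bool(conflict),
            )
        )
    return placements, unplaced


def anchoring_rate(
    layout: pd.DataFrame,
    placed_before: set[str],
    placed_after: set[str],
) -> AssemblyStats:
    """Anchored-length accounting.

    ``layout`` rows: ``seq``, ``length_bp``, ``kind``; chromosomes always
    count as anchored, scaffolds count when their id is in the placed set
    (their full length counts).
    """
    total = int(layout["length_bp"].sum())
    if total <= 0:
        raise ValueError("zero total assembly length")

    def anchored_bp(placed: set[str]) -> int:
        bp = 0
        for row in layout.itertuples():
            if row.kind == "chromosome" or row.seq in placed:
                bp += int(row.length_bp)
        return bp

    return AssemblyStats(
        total_bp=total,
        anchored_bp_before=anchored_bp(placed_before),
        anchored_bp_after=anchored_bp(placed_after | placed_before),
    )
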