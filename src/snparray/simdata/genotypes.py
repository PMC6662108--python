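"""Diversity-panel and F1-family genotype simulation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import MISSING, GenotypeMatrix
from .config import GROUPS, SimConfig, rng_for

__all__ = ["sim_group_genotypes", "sim_f1_cross", "sim_f1_family", "F1Family"]


def _variants_frame(markers: pd.DataFrame) -> pd.DataFrame:
    """Marker table -> GenotypeMatrix variant frame, sorted (seq, pos)."""
    v = markers.sort_values(["seq", "pos"], kind="mergesort").copy()
    v["chrom"] = v["seq"]
    v["ref"] = "A"
    v["alt"] = "B"
    v = v.set_index("marker")
    return v[["chrom", "pos", "ref", "alt", "true_chrom", "true_pos", "cm"]]


def sim_group_genotypes(
    markers: pd.DataFrame, config: SimConfig
) -> tuple[dict[str, GenotypeMatrix], np.ndarray]:
    """Simulate the four diverged germplasm groups.

    Ancestral allele frequency per marker is uniform on [0.05, 0.95]; each
    group frequency is a Balding-Nichols beta draw with drift parameter
    ``divergence_f`` and genotypes are Hardy-Weinberg binomial draws.

    Returns the group name -> matrix dict and the ancestral frequencies in
    the order of the returned variant frames.
    """
    variants = _variants_frame(markers)
    m = len(variants)
    rng = rng_for(config.seed, 10)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.divergence_f
    a, b = p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f

    out: dict[str, GenotypeMatrix] = {}
    for gi, (group, size) in enumerate(zip(GROUPS, config.group_sizes)):
        grng = rng_for(config.seed, 11, gi)
        p_group = grng.beta(a, b)
        dosage = grng.binomial(2, p_group, size=(size, m)).astype(np.int8)
        if config.missing_rate > 0:
            dosage[grng.random(dosage.shape) < config.missing_rate] = MISSING
        samples = [f"{group}_{i + 1:03d}" for i in range(size)]
        out[group] = GenotypeMatrix(samples, variants.copy(), dosage)
    return out, p_anc


def sim_f1_cross(
    parent1_haps: np.ndarray,
    parent2_haps: np.ndarray,
    genetic_map: pd.DataFrame,
    n_progeny: int,
    seed: int,
) -> np.ndarray:
    """Simulate progeny dosages of a cross between two phased parents.

    ``parent*_haps`` are ``(2, n_markers)`` 0/1 allele arrays on the order of
    ``genetic_map`` (columns ``true_chrom`` or ``chrom``, and ``cm``).  Per
    meiosis the crossover count is Poisson in the chromosome map length
    (Morgans) with positions uniform on the genetic scale (no interference),
    so the map is effectively compressed to near zero inside any suppressed
    interval.

    Returns an ``(n_progeny, n_markers)`` int8 dosage array.
    """
    chrom_col = "true_chrom" if "true_chrom" in genetic_map.columns else "chrom"
    chroms = genetic_map[chrom_col].to_numpy()
    cms = genetic_map["cm"].to_numpy(dtype=float)
    total_len = 0.0
    blocks = []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        lo, hi = cms[idx].min(), cms[idx].max()
        total_len += hi - lo
        blocks.append((idx, lo, hi))
    if total_len <= 0:
        raise ValueError("genetic map has zero total length")

    rng = np.random.default_rng(seed)
    m = len(genetic_map)
    dosage = np.zeros((n_progeny, m), dtype=np.int8)
    for haps in (parent1_haps, parent2_haps):
        haps = np.asarray(haps)
        if haps.shape != (2, m):
            raise ValueError("parent haplotypes must have shape (2, n_markers)")
        gametes = np.empty((n_progeny, m), dtype=np.int8)
        for idx, lo, hi in blocks:
            length_m = (hi - lo) / 100.0
            pos = cms[idx]
            for k in range(n_progeny):
                n_xo = rng.poisson(length_m)
                start = rng.integers(2)
                if n_xo == 0:
                    phase = np.full(idx.size, start)
                else:
                    xo = np.sort(rng.uniform(lo, hi, size=n_xo))
                    phase = (start + np.searchsorted(xo, pos, side="right")) % 2
                gametes[k, idx] = haps[phase, idx]
        dosage += gametes
    return dosage


@dataclass
class F1Family:
    """A simulated outcrossed family: phased parents plus progeny calls."""

    variants: pd.DataFrame
    parent1_haps: np.ndarray
    parent2_haps: np.ndarray
    progeny: GenotypeMatrix

    @property
    def parent1_dosage(self) -> np.ndarray:
        return self.parent1_haps.sum(axis=0).astype(np.int8)

    @property
    def parent2_dosage(self) -> np.ndarray:
        return self.parent2_haps.sum(axis=0).astype(np.int8)


def sim_f1_family(
    markers: pd.DataFrame,
    config: SimConfig,
    n_progeny: int | None = None,
    missing_rate: float | None = None,
) -> F1Family:
    """Build heterozygous parents per configured segregation-type proportions
    and simulate the full-sib family on the true genetic map."""
    variants = _variants_frame(markers)
    m = len(variants)
    rng = rng_for(config.seed, 20)
    types = rng.choice(3, size=m, p=list(config.seg_type_props))  # 0 lmxll, 1 nnxnp, 2 hkxhk
    p1 = np.zeros((2, m), dtype=np.int8)
    p2 = np.zeros((2, m), dtype=np.int8)
    which = rng.integers(2, size=m)  # which haplotype carries the alt allele
    hom = rng.integers(2, size=m)  # homozygous parent's allele
    which2 = rng.integers(2, size=m)
    for j in range(m):
        if types[j] == 0:
            p1[which[j], j] = 1
            p2[:, j] = hom[j]
        elif types[j] == 1:
            p2[which[j], j] = 1
            p1[:, j] = hom[j]
        else:
            p1[which[j], j] = 1
            p2[which2[j], j] = 1

    n = n_progeny if n_progeny is not None else config.n_progeny
    dosage = sim_f1_cross(p1, p2, variants, n, int(rng_for(config.seed, 21).integers(2**31)))
    mr = config.missing_rate if missing_rate is None else missing_rate
    if mr > 0:
        mrng = rng_for(config.seed, 22)
        dosage[mrng.random(dosage.shape) < mr] = MISSING
    samples = [f"F1_{i + 1:03d}" for i in range(n)]
    progeny = GenotypeMatrix(samples, variants.copy(), dosage)
    return F1Family(variants=variants, parent1_haps=p1, parent2_haps=p2, progeny=progeny)
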