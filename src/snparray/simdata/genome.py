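"""Synthetic genome layout: chromosomes, excised scaffolds, genes, markers.

Scaffolds are literal segments excised from a chromosome, so each one has an
unambiguous true placement (chromosome, insertion point, orientation).
Markers falling inside an excised segment are emitted in scaffold-local
coordinates while their true chromosome position and true cM are recorded in
:class:`~snparray.simdata.config.SimTruth`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig, SimTruth, rng_for

__all__ = ["sim_genome", "true_cm"]


def true_cm(pos_bp, chrom_length: int, cen: tuple[int, int], cm_per_mb: float, cen_scale: float):
    """Genetic position of ``pos_bp`` under a two-rate map.

    The background rate ``cm_per_mb`` is scaled by ``cen_scale`` inside the
    centromeric interval ``cen``, producing recombination suppression.
    """
    pos = np.asarray(pos_bp, dtype=float)
    cs, ce = cen
    below = np.minimum(pos, cs)
    inside = np.clip(pos - cs, 0.0, ce - cs)
    above = np.maximum(pos - ce, 0.0)
    return cm_per_mb * (below + cen_scale * inside + above) / 1e6


def _place_scaffolds(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = config.chrom_names()
    lengths = dict(zip(chroms, config.chrom_lengths_bp))
    cen = {
        c: _centromere(lengths[c], config.centromere_fraction) for c in chroms
    }
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for name, slen in zip(config.scaffold_names(), config.scaffold_lengths_bp):
        candidates = [c for c in chroms if slen < lengths[c]]
        if not candidates:
            raise ValueError(f"scaffold {name} ({slen} bp) exceeds every chromosome length")
        placed = False
        for _ in range(200):
            chrom = candidates[int(rng.integers(len(candidates)))]
            start = int(rng.integers(1, lengths[chrom] - slen + 1))
            iv = (start, start + slen - 1)
            cs, ce = cen[chrom]
            if iv[0] <= ce and iv[1] >= cs:
                continue  # keep excisions clear of the suppressed interval
            if any(iv[0] <= b and iv[1] >= a for a, b in taken[chrom]):
                continue
            taken[chrom].append(iv)
            orientation = "+" if rng.random() < 0.5 else "-"
            rows.append((name, chrom, start, orientation, slen))
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place scaffold {name}; reduce scaffold number/length")
    return pd.DataFrame(rows, columns=["scaffold", "chrom", "insert_bp", "orientation", "length_bp"])


def _centromere(length: int, fraction: float) -> tuple[int, int]:
    half = int(length * fraction / 2)
    mid = length // 2
    return mid - half, mid + half


def _sim_genes(seq: str, length: int, density_per_mb: float, rng: np.random.Generator) -> list[tuple]:
    n = int(rng.poisson(density_per_mb * length / 1e6))
    rows = []
    for i in range(n):
        glen = int(rng.integers(1000, 4001))
        if glen >= length:
            continue
        start = int(rng.integers(1, length - glen + 1))
        end = start + glen - 1
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"{seq}.g{i + 1}"
        rows.append((seq, "gene", start, end, strand, gid, None))
        rows.append((seq, "mRNA", start, end, strand, f"{gid}.t1", gid))
        n_exons = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * (n_exons - 1), replace=False)) if n_exons > 1 else np.array([], dtype=int)
        exon_edges = np.concatenate([[start], bounds, [end]])
        for k in range(n_exons):
            es, ee = int(exon_edges[2 * k]), int(exon_edges[2 * k + 1])
            rows.append((seq, "exon", es, ee, strand, f"{gid}.t1.e{k + 1}", f"{gid}.t1"))
            rows.append((seq, "CDS", es, ee, strand, f"{gid}.t1.c{k + 1}", f"{gid}.t1"))
    return rows


def _sim_marker_positions(length: int, cen: tuple[int, int], config: SimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw from a piecewise-uniform density with reduced mass
    inside the centromere; the marker count is deterministic in the config
    so every chromosome carries its designed density."""
    cs, ce = cen
    f = config.centromere_snp_density_factor
    eff_len = (length - (ce - cs)) + f * (ce - cs)
    n = int(round(config.snp_density_per_mb * eff_len / 1e6))
    u = rng.random(n) * eff_len
    pos = np.empty(n)
    before = u < cs
    mid = (u >= cs) & (u < cs + f * (ce - cs))
    after = ~before & ~mid
    pos[before] = u[before]
    pos[mid] = cs + (u[mid] - cs) / f
    pos[after] = ce + (u[after] - cs - f * (ce - cs))
    pos = np.clip(pos.astype(int) + 1, 1, length)
    return np.unique(pos)


def sim_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a genome layout, gene annotation and ground truth.

    Returns
    -------
    layout:
        One row per emitted sequence: ``seq``, ``length_bp``, ``kind``
        (``chromosome`` or ``scaffold``).
    genes:
        GFF3-like feature frame (``seq``, ``type``, ``start``, ``end``,
        ``strand``, ``feature_id``, ``parent``).
    truth:
        :class:`SimTruth` whose ``genetic_map`` frame doubles as the marker
        table (``marker``, emitted ``seq``/``pos``, ``true_chrom``,
        ``true_pos``, ``cm``).
    """
    config.validate()
    rng = rng_for(config.seed, 1)
    chroms = config.chrom_names()
    lengths = dict(zip(chroms, config.chrom_lengths_bp))

    placements = _place_scaffolds(config, rng_for(config.seed, 2))
    cen_rows = []
    for c in chroms:
        cs, ce = _centromere(lengths[c], config.centromere_fraction)
        cen_rows.append((c, cs, ce))
    centromeres = pd.DataFrame(cen_rows, columns=["chrom", "start_bp", "end_bp"])

    layout = pd.DataFrame(
        [(c, lengths[c], "chromosome") for c in chroms]
        + [(r.scaffold, int(r.length_bp), "scaffold") for r in placements.itertuples()],
        columns=["seq", "length_bp", "kind"],
    )

    gene_rows: list[tuple] = []
    grng = rng_for(config.seed, 3)
    for row in layout.itertuples():
        gene_rows.extend(_sim_genes(row.seq, int(row.length_bp), config.gene_density_per_mb, grng))
    genes = pd.DataFrame(gene_rows, columns=["seq", "type", "start", "end", "strand", "feature_id", "parent"])

    # markers: generated on true chromosome coordinates, then re-labelled if
    # they fall inside an excised scaffold segment
    mrng = rng_for(config.seed, 4)
    marker_rows = []
    for c in chroms:
        cen = _centromere(lengths[c], config.centromere_fraction)
        pos = _sim_marker_positions(lengths[c], cen, config, mrng)
        cms = true_cm(pos, lengths[c], cen, config.cm_per_mb, config.centromere_cm_scale)
        sc = placements[placements["chrom"] == c]
        for p, cm in zip(pos, cms):
            seq, emit_pos = c, int(p)
            for r in sc.itertuples():
                s0, s1 = int(r.insert_bp), int(r.insert_bp) + int(r.length_bp) - 1
                if s0 <= p <= s1:
                    seq = r.scaffold
                    local = int(p) - s0 + 1
                    emit_pos = local if r.orientation == "+" else int(r.length_bp) - local + 1
                    break
            marker_rows.append((f"AX-{c}-{int(p)}", seq, emit_pos, c, int(p), float(cm)))
    genetic_map = pd.DataFrame(
        marker_rows, columns=["marker", "seq", "pos", "true_chrom", "true_pos", "cm"]
    )

    truth = SimTruth(
        scaffold_placements=placements[["scaffold", "chrom", "insert_bp", "orientation"]].copy(),
        centromeres=centromeres,
        genetic_map=genetic_map,
    )
    return layout, genes, truth
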