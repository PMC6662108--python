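"""High-level orchestration shared by the CLI, the tests and the
acceptance script: simulate -> map -> integrate -> associate."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .genome_integration import (
    CentromereCall,
    ScanParams,
    ScaffoldPlacement,
    anchor_scaffolds,
    consensus_centromere,
    detect_density_valley,
    rf_valley,
    window_density,
)
from .linkage_map import (
    GeneticMap,
    MarkerCoding,
    assign_group_chromosomes,
    code_markers,
    group_markers,
    order_markers,
    pairwise_tables,
    segregation_test,
)
from .simdata import F1Family, SimConfig, SimTruth, sim_f1_family, sim_genome, sim_group_genotypes

log = logging.getLogger(__name__)


@dataclass
class SimBundle:
    config: SimConfig
    layout: pd.DataFrame
    genes: pd.DataFrame
    truth: SimTruth
    groups: dict[str, GenotypeMatrix]
    anc_freq: np.ndarray
    family: F1Family


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Run the full simulator stack for one configuration."""
    layout, genes, truth = sim_genome(config)
    groups, anc = sim_group_genotypes(truth.genetic_map, config)
    family = sim_f1_family(truth.genetic_map, config)
    return SimBundle(config, layout, genes, truth, groups, anc, family)


# ----------------------------------------------------------------------
@dataclass
class MapResult:
    codings: dict[str, MarkerCoding]
    kept: list[str]
    rf: np.ndarray = field(repr=False)
    lod: np.ndarray = field(repr=False)
    groups: list[list[str]]
    singles: list[str]
    gmap: GeneticMap
    lg_chrom: dict[str, str | None]


def build_linkage_map(
    parent1: np.ndarray,
    parent2: np.ndarray,
    progeny: GenotypeMatrix,
    marker_chrom: dict[str, str] | None = None,
    physical_pos: dict[str, tuple[str, int]] | None = None,
    lod_min: float = 4.0,
    seg_alpha: float = 0.01,
    max_missing: int = 10,
    categories: dict[str, str] | None = None,
    order_groups: bool = True,
) -> MapResult:
    """Code markers, filter, group at the LOD threshold and order each LG.

    ``marker_chrom`` maps chromosome-anchored markers to their chromosome
    (used for plurality labelling); scaffold-borne markers should be absent
    from it.
    """
    codings = code_markers(parent1, parent2, progeny, categories=categories)
    kept = []
    for m, c in codings.items():
        _, _, keep = segregation_test(c, alpha=seg_alpha, max_missing=max_missing)
        if keep:
            kept.append(m)
    if len(kept) < 2:
        raise ValueError("fewer than 2 markers passed the segregation filters")
    clist = [codings[m] for m in kept]
    rf, lod = pairwise_tables(clist)
    groups, singles = group_markers(lod, kept, lod_min=lod_min)
    chrom_of = marker_chrom or {}
    labels = assign_group_chromosomes(groups, chrom_of)

    lgs = []
    if order_groups:
        for gi, (g, chrom) in enumerate(zip(groups, labels)):
            lg = order_markers(
                g, rf, lod, kept,
                physical_pos=physical_pos, lg_id=f"LG{gi + 1}", chrom=chrom,
            )
            lgs.append(lg)
    gmap = GeneticMap(lgs)
    lg_chrom = {lg.lg_id: lg.chrom for lg in gmap.groups}
    return MapResult(codings, kept, rf, lod, groups, singles, gmap, lg_chrom)


def f1_map_from_bundle(bundle: SimBundle, n_progeny: int | None = None,
                       lod_min: float = 4.0, order_groups: bool = True,
                       seg_alpha: float = 0.01, max_missing: int = 10) -> MapResult:
    """Convenience: linkage map from a simulated family using true layout
    metadata only for chromosome labels (not for grouping/ordering)."""
    fam = bundle.family
    if n_progeny is not None and n_progeny != fam.progeny.n_samples:
        fam = sim_f1_family(bundle.truth.genetic_map, bundle.config, n_progeny=n_progeny)
    variants = fam.progeny.variants
    marker_chrom = {
        m: str(variants.loc[m, "chrom"])
        for m in variants.index
        if str(variants.loc[m, "chrom"]).startswith("chr")
    }
    physical = {
        m: (str(variants.loc[m, "chrom"]), int(variants.loc[m, "pos"]))
        for m in marker_chrom
    }
    return build_linkage_map(
        fam.parent1_dosage, fam.parent2_dosage, fam.progeny,
        marker_chrom=marker_chrom, physical_pos=physical,
        lod_min=lod_min, order_groups=order_groups,
        seg_alpha=seg_alpha, max_missing=max_missing,
    )


# ----------------------------------------------------------------------
def centromere_calls(
    positions_by_chrom: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    params: ScanParams | None = None,
    marey_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict[str, CentromereCall | None]:
    """Density (+ optional recombination) centromere calls per chromosome."""
    params = params or ScanParams()
    out: dict[str, CentromereCall | None] = {}
    for chrom, pos in positions_by_chrom.items():
        clen = int(chrom_lengths[chrom])
        profile = window_density(np.asarray(pos), clen, params)
        dens = detect_density_valley(profile, params, chrom_length=clen)
        rfi = None
        if marey_by_chrom and chrom in marey_by_chrom:
            bp, cm = marey_by_chrom[chrom]
            if len(bp) >= 10:
                rfi = rf_valley(np.asarray(bp), np.asarray(cm), clen, params)
        out[chrom] = consensus_centromere(chrom, dens, rfi)
    return out


def anchor_from_map(result: MapResult, variants: pd.DataFrame) -> tuple[list[ScaffoldPlacement], list[str]]:
    """Anchor scaffold-borne mapped markers using the built map.

    ``variants`` must carry ``chrom`` (emitted sequence) and ``pos``;
    scaffold sequences are those not starting with 'chr'.
    """
    frame = result.gmap.to_frame().set_index("marker")
    rows = []
    anchored_rows = []
    for m, rec in frame.iterrows():
        seq = str(variants.loc[m, "chrom"])
        pos = int(variants.loc[m, "pos"])
        if seq.startswith("chr"):
            chrom = result.lg_chrom.get(rec["lg"])
            if chrom is not None:
                anchored_rows.append((chrom, pos, float(rec["cm"])))
        else:
            rows.append((m, seq, pos, rec["lg"], float(rec["cm"])))
    scaffold_snps = pd.DataFrame(rows, columns=["marker", "scaffold", "local_bp", "lg", "cm"])
    anchored = pd.DataFrame(anchored_rows, columns=["chrom", "pos", "cm"])
    if scaffold_snps.empty:
        return [], []
    return anchor_scaffolds(scaffold_snps, anchored, {k: v for k, v in result.lg_chrom.items() if v})
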