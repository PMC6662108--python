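import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snparray.core import MISSING
from snparray.simdata import (
    ClusterSpec,
    SimConfig,
    sim_f1_cross,
    sim_f1_family,
    sim_genome,
    sim_group_genotypes,
    sim_intensities,
    sim_phenotypes,
)

from conftest import make_markers


# ----------------------------------------------------------- config
def test_config_validation_errors():
    with pytest.raises(ValueError, match="divergence_f"):
        SimConfig(divergence_f=0.0)
    with pytest.raises(ValueError, match="group sizes"):
        SimConfig(group_sizes=(1, 5, 5, 5))
    with pytest.raises(ValueError, match="lengths"):
        SimConfig(n_chromosomes=1, chrom_lengths_bp=[0])
    with pytest.raises(ValueError, match="centromere_fraction"):
        SimConfig(centromere_fraction=1.0)


# ----------------------------------------------------------- genome
def test_genome_counts_forced_by_config():
    cfg = SimConfig(seed=1, n_chromosomes=2, chrom_lengths_bp=[5_000_000] * 2,
                    n_scaffolds=3, scaffold_lengths_bp=[200_000] * 3)
    layout, genes, truth = sim_genome(cfg)
    assert len(layout) == 5
    assert len(truth.scaffold_placements) == 3
    assert (layout["kind"] == "chromosome").sum() == 2


def test_genome_determinism_bytewise():
    cfg = SimConfig(seed=7, n_chromosomes=2, chrom_lengths_bp=[2_000_000] * 2,
                    n_scaffolds=2, scaffold_lengths_bp=[150_000] * 2)
    a = sim_genome(cfg)
    b = sim_genome(cfg)
    for x, y in zip(a[:2], b[:2]):
        pd.testing.assert_frame_equal(x, y)
    pd.testing.assert_frame_equal(a[2].genetic_map, b[2].genetic_map)
    assert a[1].to_csv() == b[1].to_csv()


def test_gene_count_within_poisson_band():
    # oracle: Poisson(50/Mb * 5 Mb) = Poisson(250) central 99% band
    cfg = SimConfig(seed=3, n_chromosomes=1, chrom_lengths_bp=[5_000_000],
                    n_scaffolds=0, scaffold_lengths_bp=[], gene_density_per_mb=50.0)
    _, genes, _ = sim_genome(cfg)
    n = (genes["type"] == "gene").sum()
    lo, hi = stats.poisson.ppf([0.005, 0.995], 250)
    assert lo <= n <= hi


def test_scaffold_too_long_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        cfg = SimConfig(seed=1, n_chromosomes=1, chrom_lengths_bp=[100_000],
                        n_scaffolds=1, scaffold_lengths_bp=[200_000])
        sim_genome(cfg)


def test_truth_cm_monotone_with_bp(small_bundle):
    tm = small_bundle.truth.genetic_map
    for _, sub in tm.groupby("true_chrom"):
        s = sub.sort_values("true_pos")
        assert s["cm"].is_monotonic_increasing


# ----------------------------------------------------------- groups
def test_group_frequencies_converge_to_ancestral_at_low_divergence():
    cfg = SimConfig(seed=2, n_chromosomes=1, chrom_lengths_bp=[5_000_000],
                    n_scaffolds=0, scaffold_lengths_bp=[], snp_density_per_mb=100.0,
                    divergence_f=1e-4, group_sizes=(200, 2, 2, 2))
    _, _, truth = sim_genome(cfg)
    groups, anc = sim_group_genotypes(truth.genetic_map, cfg)
    g = groups["AW"]
    order = truth.genetic_map.sort_values(["seq", "pos"])  # variant frame order
    freq = g.alt_allele_freq()
    assert np.nanmean(np.abs(freq - anc)) < 0.05


def test_hudson_fst_recovers_divergence():
    # oracle: Hudson FST estimator on the two simulated groups
    cfg = SimConfig(seed=4, n_chromosomes=1, chrom_lengths_bp=[50_000_000],
                    n_scaffolds=0, scaffold_lengths_bp=[], snp_density_per_mb=100.0,
                    divergence_f=0.1, group_sizes=(60, 60, 2, 2))
    _, _, truth = sim_genome(cfg)
    assert len(truth.genetic_map) >= 4000
    groups, _ = sim_group_genotypes(truth.genetic_map, cfg)
    p1 = groups["AW"].alt_allele_freq()
    p2 = groups["AC"].alt_allele_freq()
    n1 = 2 * groups["AW"].n_samples
    n2 = 2 * groups["AC"].n_samples
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = np.nansum(num) / np.nansum(den)
    # BN with both groups drifted at F gives Hudson FST ~ F/(1-F) barely
    # above F itself; the spec tolerance of +/-0.04 covers both
    assert abs(fst - 0.1) < 0.04


def test_missing_rate_within_binomial_band():
    cfg = SimConfig(seed=5, n_chromosomes=1, chrom_lengths_bp=[10_000_000],
                    n_scaffolds=0, scaffold_lengths_bp=[], snp_density_per_mb=50.0,
                    missing_rate=0.05)
    _, _, truth = sim_genome(cfg)
    groups, _ = sim_group_genotypes(truth.genetic_map, cfg)
    g = groups["AW"]
    n_cells = g.dosage.size
    n_miss = int((g.dosage == MISSING).sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], n_cells, 0.05)
    assert lo <= n_miss <= hi


# ----------------------------------------------------------- F1 cross
def test_zero_distance_markers_never_recombine():
    markers = make_markers([5.0, 5.0 + 1e-12])
    markers["marker"] = ["a", "b"]
    markers["pos"] = [100, 200]
    markers["true_pos"] = [100, 200]
    p1 = np.array([[1, 1], [0, 0]], dtype=np.int8)
    p2 = np.zeros((2, 2), dtype=np.int8)
    dos = sim_f1_cross(p1, p2, markers, 500, seed=1)
    assert (dos[:, 0] == dos[:, 1]).all()


def test_recombination_matches_haldane_inverse():
    # oracle: r = (1 - exp(-2d)) / 2 = 0.1648 at d = 0.2 Morgans
    markers = make_markers([0.0, 20.0])
    p1 = np.array([[1, 1], [0, 0]], dtype=np.int8)
    p2 = np.zeros((2, 2), dtype=np.int8)
    dos = sim_f1_cross(p1, p2, markers, 2000, seed=42)
    rec = (dos[:, 0] != dos[:, 1]).mean()
    assert abs(rec - 0.1648) < 0.02


def test_centromere_flanking_rf_below_chromosome_median(small_bundle):
    tm = small_bundle.truth.genetic_map
    chrom = "chr1"
    sub = tm[tm["true_chrom"] == chrom].sort_values("true_pos")
    cs, ce = small_bundle.truth.centromere_interval(chrom)
    left = sub[sub["true_pos"] < cs].iloc[-1]
    right = sub[sub["true_pos"] > ce].iloc[0]
    span_cm = right["cm"] - left["cm"]
    span_bp = right["true_pos"] - left["true_pos"]
    rates = np.diff(sub["cm"]) / np.maximum(np.diff(sub["true_pos"]), 1)
    assert span_cm / span_bp < np.median(rates)


def test_zero_length_map_rejected():
    markers = make_markers([3.0, 3.0])
    p1 = np.array([[1, 1], [0, 0]], dtype=np.int8)
    with pytest.raises(ValueError, match="zero total length"):
        sim_f1_cross(p1, np.zeros((2, 2), dtype=np.int8), markers, 10, seed=0)


def test_family_progeny_dosages_consistent_with_parents(small_bundle):
    fam = small_bundle.family
    p1 = fam.parent1_dosage
    p2 = fam.parent2_dosage
    lo = np.maximum((p1 // 2) + (p2 // 2) * 0, 0)
    for j in range(fam.progeny.n_variants):
        vals = set(fam.progeny.dosage[:, j].tolist()) - {MISSING}
        # progeny dosage = one allele from each parent
        allowed = {
            a + b
            for a in set(np.unique(fam.parent1_haps[:, j]))
            for b in set(np.unique(fam.parent2_haps[:, j]))
        }
        assert vals <= allowed


# ----------------------------------------------------------- intensities
def _toy_genotypes(n_s=40, n_v=20, seed=0):
    rng = np.random.default_rng(seed)
    from conftest import toy_matrix

    dos = rng.binomial(2, 0.5, size=(n_s, n_v)).astype(np.int8)
    return toy_matrix(dos)


def test_noiseless_intensities_reproduce_truth_exactly():
    from snparray.genotype_qc import qc_panel

    g = _toy_genotypes()
    spec = ClusterSpec(sd_x=1e-3, sd_y=1e-3)
    panel = sim_intensities(g, spec, seed=1)
    _, _, calls = qc_panel(panel)
    assert (calls == g.dosage).all()


def test_duplicate_sample_ids_identical_rows():
    from snparray.core import GenotypeMatrix

    g = _toy_genotypes()
    # duplicated samples share the same id; the per-sample noise stream is
    # keyed on the id, so their intensity rows must be byte-identical
    dup = GenotypeMatrix(["s0", "s0"], g.variants.copy(),
                         np.stack([g.dosage[0], g.dosage[0]]))
    panel = sim_intensities(dup, ClusterSpec(), seed=3)
    assert np.array_equal(panel.a[0], panel.a[1])
    assert np.array_equal(panel.b[0], panel.b[1])


def test_intensity_determinism():
    g = _toy_genotypes()
    p1 = sim_intensities(g, ClusterSpec(), seed=9, otv_fraction=0.2)
    p2 = sim_intensities(g, ClusterSpec(), seed=9, otv_fraction=0.2)
    assert np.array_equal(p1.a, p2.a)
    assert p1.designed_category == p2.designed_category


def test_nonpositive_spread_rejected():
    with pytest.raises(ValueError, match="spreads"):
        ClusterSpec(sd_x=0.0)


def test_otv_snps_labelled_otv_in_most_replicates():
    from snparray.genotype_qc import qc_panel

    g = _toy_genotypes(n_s=100, n_v=10, seed=4)
    hits = 0
    total = 0
    for seed in range(10):
        panel = sim_intensities(g, ClusterSpec(), seed=seed,
                                otv_snps=list(g.variants.index[:5]))
        per_snp, _, _ = qc_panel(panel)
        total += 5
        hits += (per_snp.loc[g.variants.index[:5], "category"] == "OTV").sum()
    assert hits / total >= 0.9


# ----------------------------------------------------------- phenotypes
def test_h2_one_means_identical_replicates():
    g = _toy_genotypes()
    qtls = pd.DataFrame({"trait": ["t"], "marker": ["v0"], "effect": [1.0]})
    ph = sim_phenotypes(g, qtls, {"t": 1.0}, n_reps=3, seed=1)
    wide = ph.pivot_table(index="genotype", columns="replicate", values="value")
    assert np.allclose(wide.std(axis=1), 0.0)


def test_h2_out_of_range_rejected():
    g = _toy_genotypes()
    qtls = pd.DataFrame({"trait": ["t"], "marker": ["v0"], "effect": [1.0]})
    with pytest.raises(ValueError, match="true_h2"):
        sim_phenotypes(g, qtls, {"t": 0.0}, n_reps=2, seed=1)


def test_unknown_qtl_marker_rejected():
    g = _toy_genotypes()
    qtls = pd.DataFrame({"trait": ["t"], "marker": ["nope"], "effect": [1.0]})
    with pytest.raises(KeyError, match="absent"):
        sim_phenotypes(g, qtls, {"t": 0.5}, n_reps=2, seed=1)


def test_zero_effect_qtls_give_uniform_gwas_pvalues():
    from scipy.stats import kstest

    from snparray.assoc_stats import mlm_assoc, vanraden_kinship

    g = _toy_genotypes(n_s=150, n_v=400, seed=12)
    qtls = pd.DataFrame({"trait": ["t"], "marker": ["v0"], "effect": [0.0]})
    ph = sim_phenotypes(g, qtls, {"t": 0.8}, n_reps=3, seed=3)
    means = ph.groupby("genotype")["value"].mean().reindex(g.samples)
    res = mlm_assoc(g, means.to_numpy(), vanraden_kinship(g), maf_min=0.05)
    assert kstest(res["p"], "uniform").pvalue > 0.01


def test_rf_monotone_in_map_distance():
    markers = make_markers([0.0, 5.0, 15.0, 40.0])
    p1 = np.array([[1, 1, 1, 1], [0, 0, 0, 0]], dtype=np.int8)
    p2 = np.zeros((2, 4), dtype=np.int8)
    dos = sim_f1_cross(p1, p2, markers, 3000, seed=11)
    rfs = [(dos[:, 0] != dos[:, j]).mean() for j in (1, 2, 3)]
    assert rfs[0] < rfs[1] < rfs[2]
    assert all(r <= 0.5 + 0.02 for r in rfs)


def test_h2_recovery():
    from snparray.assoc_stats import heritability

    g = _toy_genotypes(n_s=300, n_v=30, seed=6)
    qtls = pd.DataFrame({"trait": ["t"] * 3, "marker": ["v0", "v1", "v2"],
                         "effect": [1.0, 0.8, -0.5]})
    ph = sim_phenotypes(g, qtls, {"t": 0.6}, n_reps=4, seed=2)
    est = heritability(ph, trait="t")
    assert abs(est.h2_plot - 0.6) < 0.05
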