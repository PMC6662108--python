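import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from snparray.core import MISSING
from snparray.datasets import reference_lg_table
from snparray.linkage_map import (
    GeneticMap,
    LinkageGroup,
    MarkerCoding,
    aggregate_lg_table,
    code_markers,
    group_markers,
    haldane_inverse_cm,
    kosambi_cm,
    kosambi_inverse,
    map_stats,
    order_consistency,
    order_markers,
    pairwise_tables,
    segregation_test,
    twopoint_rf,
)
from snparray.simdata import SimConfig, sim_f1_cross, sim_f1_family

from conftest import make_markers, toy_matrix


# ------------------------------------------------------- coding
def test_code_lmxll():
    progeny = toy_matrix([[0], [1], [1], [0]])
    codings = code_markers(np.array([1]), np.array([0]), progeny)
    mc = codings["v0"]
    assert mc.seg_type == "lmxll"
    assert list(mc.codes) == [0, 1, 1, 0]


def test_homxhom_excluded():
    progeny = toy_matrix([[0], [0]])
    assert code_markers(np.array([0]), np.array([0]), progeny) == {}
    assert code_markers(np.array([2]), np.array([2]), progeny) == {}


def test_code_hkxhk_classes():
    progeny = toy_matrix([[0], [1], [2]])
    codings = code_markers(np.array([1]), np.array([1]), progeny)
    mc = codings["v0"]
    assert mc.seg_type == "hkxhk"
    assert list(mc.codes) == [0, 1, 2]


def test_code_nnxnp_and_alt_homozygous_parent():
    # P1 hom alt (2), P2 het: progeny in {1, 2}; code = P2's transmitted allele
    progeny = toy_matrix([[1], [2], [1]])
    codings = code_markers(np.array([2]), np.array([1]), progeny)
    mc = codings["v0"]
    assert mc.seg_type == "nnxnp"
    assert list(mc.codes) == [0, 1, 0]


def test_mendelian_error_flagging():
    # lmxll with P2 = 0: dosage 2 impossible
    d = [[2]] * 10 + [[0]] * 45 + [[1]] * 45
    progeny = toy_matrix(d)
    codings = code_markers(np.array([1]), np.array([0]), progeny)
    mc = codings["v0"]
    assert mc.n_mendel_errors == 10
    assert mc.flagged  # 10% > 2%
    assert mc.codes[0] == MISSING


def test_category_admission_filter():
    progeny = toy_matrix([[0, 0], [1, 1]])
    cats = {"v0": "PolyHighResolution", "v1": "Other"}
    codings = code_markers(np.array([1, 1]), np.array([0, 0]), progeny, categories=cats)
    assert set(codings) == {"v0"}


# ------------------------------------------------------- segregation test
def test_segregation_balanced_kept():
    codes = np.array([0] * 49 + [1] * 49, dtype=np.int8)
    mc = MarkerCoding("m", "lmxll", codes, 0)
    chi2, p, keep = segregation_test(mc)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert keep


def test_segregation_distorted_dropped():
    # 70:30 of 100 -> chi2 = 16, p ~ 6.3e-5
    codes = np.array([0] * 70 + [1] * 30, dtype=np.int8)
    mc = MarkerCoding("m", "lmxll", codes, 0)
    chi2, p, keep = segregation_test(mc)
    assert chi2 == pytest.approx(16.0)
    assert p == pytest.approx(chi2_dist.sf(16.0, 1))
    assert not keep


def test_segregation_missing_threshold():
    codes = np.array([0] * 44 + [1] * 43 + [MISSING] * 11, dtype=np.int8)
    mc = MarkerCoding("m", "lmxll", codes, 11)
    _, _, keep = segregation_test(mc)
    assert not keep  # more than 10 missing
    mc10 = MarkerCoding("m", "lmxll", codes[:-1], 10)
    assert segregation_test(mc10)[2]


def test_segregation_all_missing(caplog):
    codes = np.full(20, MISSING, dtype=np.int8)
    mc = MarkerCoding("m", "lmxll", codes, 20)
    with caplog.at_level("WARNING"):
        chi2, p, keep = segregation_test(mc)
    assert not keep and np.isnan(chi2)


def test_segregation_hk_1_2_1():
    codes = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
    mc = MarkerCoding("m", "hkxhk", codes, 0)
    chi2, p, keep = segregation_test(mc)
    assert chi2 == pytest.approx(0.0) and keep


# ------------------------------------------------------- two-point
def test_identical_markers_full_lod():
    codes = np.zeros(98, dtype=np.int8)
    est = twopoint_rf(MarkerCoding("a", "lmxll", codes, 0),
                      MarkerCoding("b", "lmxll", codes.copy(), 0))
    assert est.rf == pytest.approx(0.0)
    assert est.lod == pytest.approx(98 * np.log10(2), abs=1e-6)


def test_two_recombinants_closed_form():
    # maximise R log10(2r) + NR log10(2(1-r)): r = 2/98, LOD ~ 25.26
    a = np.zeros(98, dtype=np.int8)
    b = a.copy()
    b[:2] = 1
    est = twopoint_rf(MarkerCoding("a", "lmxll", a, 0),
                      MarkerCoding("b", "lmxll", b, 0))
    assert est.rf == pytest.approx(2 / 98, abs=1e-6)
    expect = 2 * np.log10(2 * 2 / 98) + 96 * np.log10(2 * 96 / 98)
    assert est.lod == pytest.approx(expect, abs=1e-6)


def test_uninformative_pair_null():
    codes = np.zeros(98, dtype=np.int8)
    est = twopoint_rf(MarkerCoding("a", "lmxll", codes, 0),
                      MarkerCoding("b", "nnxnp", codes.copy(), 0))
    assert est.rf is None
    assert est.lod == 0.0
    assert est.n_informative == 0


def test_phase_maximisation_repulsion():
    codes = np.zeros(98, dtype=np.int8)
    est = twopoint_rf(MarkerCoding("a", "lmxll", codes, 0),
                      MarkerCoding("b", "lmxll", 1 - codes, 0))
    assert est.rf == pytest.approx(0.0)
    assert "R" in est.phase


def test_unlinked_pair_rf_half_lod_zero():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 2, 400).astype(np.int8)
    b = rng.integers(0, 2, 400).astype(np.int8)
    est = twopoint_rf(MarkerCoding("a", "lmxll", a, 0),
                      MarkerCoding("b", "lmxll", b, 0))
    assert est.lod < 1.0
    if est.rf >= 0.5 - 1e-9:
        assert est.lod == 0.0


def test_hk_pair_recovers_rf():
    markers = make_markers([0.0, 10.0])
    p1 = np.array([[1, 1], [0, 0]], dtype=np.int8)
    p2 = np.array([[1, 1], [0, 0]], dtype=np.int8)
    dos = sim_f1_cross(p1, p2, markers, 3000, seed=3)
    est = twopoint_rf(MarkerCoding("a", "hkxhk", dos[:, 0], 0),
                      MarkerCoding("b", "hkxhk", dos[:, 1], 0))
    true_r = haldane_inverse_cm(10.0)
    assert est.rf == pytest.approx(true_r, abs=0.02)


def test_hk_lm_pair_recovers_rf():
    markers = make_markers([0.0, 15.0])
    p1 = np.array([[1, 1], [0, 0]], dtype=np.int8)  # het at both
    p2 = np.array([[1, 0], [0, 0]], dtype=np.int8)  # het at first only
    dos = sim_f1_cross(p1, p2, markers, 3000, seed=4)
    est = twopoint_rf(MarkerCoding("a", "hkxhk", dos[:, 0], 0),
                      MarkerCoding("b", "lmxll", dos[:, 1], 0))
    true_r = haldane_inverse_cm(15.0)
    assert est.rf == pytest.approx(true_r, abs=0.03)


def test_pairwise_tables_match_single_pair():
    rng = np.random.default_rng(1)
    markers = make_markers([0.0, 5.0, 12.0])
    p1 = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.int8)
    p2 = np.array([[0, 1, 0], [0, 0, 0]], dtype=np.int8)
    dos = sim_f1_cross(p1, p2, markers, 300, seed=5)
    codings = code_markers(p1.sum(0), p2.sum(0), toy_matrix(dos))
    clist = list(codings.values())
    rf, lod = pairwise_tables(clist, grouping_lod=False)
    for i in range(len(clist)):
        for j in range(i + 1, len(clist)):
            est = twopoint_rf(clist[i], clist[j])
            if est.rf is None:
                assert np.isnan(rf[i, j])
            else:
                assert rf[i, j] == pytest.approx(est.rf, abs=0.006)
                assert lod[i, j] == pytest.approx(est.lod, abs=0.15)


def test_rf_estimator_consistency():
    # spec invariant: bias < 0.01 and RMSE < 0.03 at r in {0.05, 0.1, 0.2}
    rng = np.random.default_rng(7)
    for r_true in (0.05, 0.1, 0.2):
        n = 500
        ests = []
        for rep in range(40):
            a = rng.integers(0, 2, n).astype(np.int8)
            flip = rng.random(n) < r_true
            b = np.where(flip, 1 - a, a).astype(np.int8)
            est = twopoint_rf(MarkerCoding("a", "lmxll", a, 0),
                              MarkerCoding("b", "lmxll", b, 0))
            ests.append(est.rf)
        ests = np.array(ests)
        assert abs(ests.mean() - r_true) < 0.01
        assert np.sqrt(((ests - r_true) ** 2).mean()) < 0.03


# ------------------------------------------------------- kosambi
def test_kosambi_zero():
    assert kosambi_cm(0.0) == 0.0


def test_kosambi_values():
    assert kosambi_cm(0.2) == pytest.approx(25 * np.log(1.4 / 0.6), abs=1e-9)
    assert round(kosambi_cm(0.2), 2) == 21.18
    assert round(kosambi_cm(0.25), 2) == 27.47


def test_kosambi_roundtrip_machine_precision():
    for r in np.linspace(0.0, 0.49, 50):
        assert abs(kosambi_inverse(kosambi_cm(r)) - r) <= 1e-12


def test_kosambi_domain_error():
    with pytest.raises(ValueError):
        kosambi_cm(0.5)


# ------------------------------------------------------- grouping
def _block_lod(sizes, hi=20.0):
    n = sum(sizes)
    lod = np.zeros((n, n))
    start = 0
    for s in sizes:
        lod[start : start + s, start : start + s] = hi
        start += s
    np.fill_diagonal(lod, 0.0)
    return lod


def test_two_blocks_two_groups():
    lod = _block_lod([3, 4])
    ids = [f"m{i}" for i in range(7)]
    groups, singles = group_markers(lod, ids, lod_min=4.0)
    assert len(groups) == 2
    assert sorted(map(len, groups)) == [3, 4]
    assert singles == []


def test_singletons_unplaced():
    lod = _block_lod([2, 1])
    ids = ["a", "b", "c"]
    groups, singles = group_markers(lod, ids)
    assert groups == [["a", "b"]]
    assert singles == ["c"]


def test_raising_lod_never_merges():
    rng = np.random.default_rng(2)
    lod = rng.uniform(0, 10, size=(30, 30))
    lod = (lod + lod.T) / 2
    ids = [f"m{i}" for i in range(30)]
    prev = None
    for lmin in (2.0, 4.0, 6.0, 8.0):
        groups, singles = group_markers(lod, ids, lod_min=lmin)
        n_units = len(groups) + len(singles)
        if prev is not None:
            assert n_units >= prev
        prev = n_units


# ------------------------------------------------------- ordering
def test_two_marker_order():
    rf = np.array([[0.0, 0.2], [0.2, 0.0]])
    lod = np.array([[0.0, 10.0], [10.0, 0.0]])
    lg = order_markers(["a", "b"], rf, lod, ["a", "b"])
    assert lg.length_cm == pytest.approx(kosambi_cm(0.2))


def test_clean_twelve_marker_order_recovered():
    cms = np.arange(12) * 1.8
    markers = make_markers(cms)
    cfg = SimConfig(seed=13, n_chromosomes=1, chrom_lengths_bp=[10_000_000],
                    n_scaffolds=0, scaffold_lengths_bp=[],
                    seg_type_props=(1.0, 0.0, 0.0))
    fam = sim_f1_family(markers, cfg, n_progeny=500)
    codings = code_markers(fam.parent1_dosage, fam.parent2_dosage, fam.progeny)
    kept = [m for m in codings if segregation_test(codings[m], max_missing=10)[2]]
    clist = [codings[m] for m in kept]
    rf, lod = pairwise_tables(clist)
    groups, _ = group_markers(lod, kept)
    assert len(groups) == 1
    lg = order_markers(groups[0], rf, lod, kept)
    genome = [m for m in fam.progeny.variant_ids if m in set(kept)]
    assert lg.markers == genome or lg.markers == genome[::-1]


def test_linkage_group_invariants():
    with pytest.raises(ValueError, match="cM must start at 0"):
        LinkageGroup("LG1", ["a", "b"], np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="non-decreasing|cM"):
        LinkageGroup("LG1", ["a", "b"], np.array([0.0, -1.0]))


# ------------------------------------------------------- map stats
def test_reference_aggregates():
    agg = aggregate_lg_table(reference_lg_table())
    total = agg[agg["lg"] == "Total"].iloc[0]
    assert total["n_snps"] == 2388
    assert total["length_cm"] == pytest.approx(1108.0)
    assert total["avg_interval_cm"] == pytest.approx(0.46)
    assert total["max_gap_cm"] == pytest.approx(5.7)
    lg1 = agg[agg["lg"] == "LG1"].iloc[0]
    assert lg1["avg_interval_cm"] == pytest.approx(0.70)


def test_map_stats_single_marker_group():
    gmap = GeneticMap([LinkageGroup("LG1", ["a"], np.array([0.0]))])
    df = map_stats(gmap)
    row = df[df["lg"] == "LG1"].iloc[0]
    assert row["length_cm"] == 0.0
    assert row["max_gap_cm"] == 0.0


# ------------------------------------------------------- consistency
def _gmap_with_physical(ranks):
    markers = [f"m{i}" for i in range(len(ranks))]
    gmap = GeneticMap([LinkageGroup("LG1", markers, np.arange(len(ranks), dtype=float))])
    physical = {m: ("chr1", int(r) * 1000) for m, r in zip(markers, ranks)}
    return gmap, physical


def test_consistency_perfect():
    gmap, phys = _gmap_with_physical([1, 2, 3, 4])
    df = order_consistency(gmap, phys)
    assert df["consistency_pct"].iloc[0] == pytest.approx(100.0)


def test_consistency_lis_example():
    gmap, phys = _gmap_with_physical([1, 3, 2, 4])
    df = order_consistency(gmap, phys)
    assert df["consistency_pct"].iloc[0] == pytest.approx(75.0)


def test_consistency_reversal_allowed():
    gmap, phys = _gmap_with_physical([4, 3, 2, 1])
    df = order_consistency(gmap, phys)
    assert df["consistency_pct"].iloc[0] == pytest.approx(100.0)


def test_consistency_scaffold_class_and_null():
    markers = ["a", "b", "c"]
    gmap = GeneticMap([LinkageGroup("LG1", markers, np.array([0.0, 1.0, 2.0]))])
    phys = {"a": ("chr1", 100)}
    df = order_consistency(gmap, phys, scaffold_markers={"b", "c"})
    assert np.isnan(df["consistency_pct"].iloc[0])
    assert df["n_scaffold"].iloc[0] == 2
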