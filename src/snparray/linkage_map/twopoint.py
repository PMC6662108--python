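"""Two-point recombination estimation for CP marker pairs.

The likelihood is maximised over the recombination fraction and over the
admissible parental phase configurations.  For one-parent types the MLE has
a closed binomial form; the generic path evaluates the exact multinomial
likelihood of the 3x3 joint code table on an r grid and polishes the best
point with Brent's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ..core import MISSING
from .coding import MarkerCoding

LN10 = np.log(10.0)
# non-uniform grid: fine near 0 where tightly linked pairs need resolution
R_GRID = np.unique(np.concatenate([np.linspace(0.0, 0.05, 51), np.linspace(0.05, 0.5, 91)]))

_P1_HET = {"lmxll": True, "nnxnp": False, "hkxhk": True}
_P2_HET = {"lmxll": False, "nnxnp": True, "hkxhk": True}


@dataclass
class TwoPointEstimate:
    rf: float | None
    lod: float
    phase: str | None
    n_informative: int

    def __post_init__(self) -> None:
        if self.rf is not None and self.rf >= 0.5 and self.lod > 1e-9:
            raise ValueError("rf = 0.5 implies lod = 0")


def informative_pair(type_a: str, type_b: str) -> bool:
    """A pair shares meioses iff some parent is heterozygous at both."""
    return (_P1_HET[type_a] and _P1_HET[type_b]) or (_P2_HET[type_a] and _P2_HET[type_b])


def _gamete_probs(r: np.ndarray, phase: int) -> np.ndarray:
    """(g, 2, 2) transmitted-allele pair probabilities for a doubly het
    parent; phase 0 = coupling, 1 = repulsion."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    g = np.empty((r.size, 2, 2))
    same = (1.0 - r) / 2.0
    diff = r / 2.0
    if phase == 1:
        same, diff = diff, same
    g[:, 0, 0] = g[:, 1, 1] = same
    g[:, 0, 1] = g[:, 1, 0] = diff
    return g


def _uninformative_parent() -> np.ndarray:
    """Allele-pair distribution when the parent is het at <= 1 marker: the
    het-marker allele is uniform, the other axis is a constant 0."""
    g = np.zeros((1, 2, 2))
    g[0, 0, 0] = g[0, 1, 0] = 0.5
    return g


def pair_prob_table(type_a: str, type_b: str, phase1: int | None, phase2: int | None,
                    r: np.ndarray) -> np.ndarray:
    """(g, 3, 3) joint code-class probabilities for a marker pair.

    ``phase*`` is None when the corresponding parent is not doubly het.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    both1 = _P1_HET[type_a] and _P1_HET[type_b]
    both2 = _P2_HET[type_a] and _P2_HET[type_b]
    g1 = _gamete_probs(r, phase1) if both1 else np.broadcast_to(_uninformative_parent(), (r.size, 2, 2))
    g2 = _gamete_probs(r, phase2) if both2 else np.broadcast_to(_uninformative_parent(), (r.size, 2, 2))

    # per-parent contributions; when a parent is het at only one marker its
    # transmitted allele at that marker is uniform and 0 at the other
    def contrib(par_het_a: bool, par_het_b: bool, gp: np.ndarray, both: bool) -> np.ndarray:
        if both:
            return gp
        out = np.zeros((r.size, 2, 2))
        if par_het_a and par_het_b:
            return gp
        if par_het_a:
            out[:, 0, 0] = out[:, 1, 0] = 0.5
        elif par_het_b:
            out[:, 0, 0] = out[:, 0, 1] = 0.5
        else:
            out[:, 0, 0] = 1.0
        return out

    c1 = contrib(_P1_HET[type_a], _P1_HET[type_b], g1, both1)
    c2 = contrib(_P2_HET[type_a], _P2_HET[type_b], g2, both2)

    # code at a marker = sum of transmitted alleles of the parents that are
    # het there (dosage class for hkxhk, transmitted allele otherwise)
    p = np.zeros((r.size, 3, 3))
    for a1 in range(2):
        for b1 in range(2):
            for a2 in range(2):
                for b2 in range(2):
                    ca = a1 * _P1_HET[type_a] + a2 * _P2_HET[type_a]
                    cb = b1 * _P1_HET[type_b] + b2 * _P2_HET[type_b]
                    p[:, ca, cb] += c1[:, a1, b1] * c2[:, a2, b2]
    return p


def _phase_configs(type_a: str, type_b: str) -> list[tuple[int | None, int | None]]:
    both1 = _P1_HET[type_a] and _P1_HET[type_b]
    both2 = _P2_HET[type_a] and _P2_HET[type_b]
    p1s = [0, 1] if both1 else [None]
    p2s = [0, 1] if both2 else [None]
    return [(a, b) for a in p1s for b in p2s]


def joint_counts(m1: MarkerCoding, m2: MarkerCoding) -> np.ndarray:
    """3x3 table of joint code counts over progeny non-missing at both."""
    ok = (m1.codes != MISSING) & (m2.codes != MISSING)
    n = np.zeros((3, 3))
    np.add.at(n, (m1.codes[ok], m2.codes[ok]), 1.0)
    return n


def _loglik(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    logp = np.log(np.maximum(p, 1e-300))
    return np.einsum("cd,gcd->g", n, logp)


def twopoint_rf(m1: MarkerCoding, m2: MarkerCoding) -> TwoPointEstimate:
    """Maximum-likelihood recombination fraction and LOD for one pair."""
    if not informative_pair(m1.seg_type, m2.seg_type):
        return TwoPointEstimate(rf=None, lod=0.0, phase=None, n_informative=0)
    n = joint_counts(m1, m2)
    n_inf = int(n.sum())
    if n_inf == 0:
        return TwoPointEstimate(rf=None, lod=0.0, phase=None, n_informative=0)

    best = None
    for ph in _phase_configs(m1.seg_type, m2.seg_type):
        p = pair_prob_table(m1.seg_type, m2.seg_type, ph[0], ph[1], R_GRID)
        ll = _loglik(n, p)
        g = int(np.argmax(ll))
        if best is None or ll[g] > best[0]:
            best = (ll[g], R_GRID[g], ph, ll[-1])
    _, r0, ph, ll_half = best

    def neg_ll(r: float) -> float:
        p = pair_prob_table(m1.seg_type, m2.seg_type, ph[0], ph[1], np.array([r]))
        return -float(_loglik(n, p)[0])

    lo, hi = max(r0 - 0.01, 0.0), min(r0 + 0.01, 0.5)
    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    r_hat, ll_hat = float(res.x), -float(res.fun)
    if neg_ll(r0) < res.fun:  # guard against a polish that moved off the max
        r_hat, ll_hat = float(r0), -neg_ll(r0)
    # snap to the boundary when the optimum sits against it
    if neg_ll(0.0) <= -ll_hat + 1e-12:
        r_hat, ll_hat = 0.0, -neg_ll(0.0)
    lod = max((ll_hat - ll_half) / LN10, 0.0)
    if r_hat >= 0.5 - 1e-9:
        lod = 0.0
    phase_label = f"p1:{'CR'[ph[0]] if ph[0] is not None else '-'}," \
                  f"p2:{'CR'[ph[1]] if ph[1] is not None else '-'}"
    return TwoPointEstimate(rf=r_hat, lod=float(lod), phase=phase_label, n_informative=n_inf)


def _independence_lod(n: np.ndarray) -> np.ndarray:
    """Distortion-robust grouping LOD from the independence G-test.

    The likelihood-ratio LOD assumes undistorted 1:1 (or 1:2:1) margins, so
    two unlinked markers sharing a segregation skew mimic linkage.  The
    G-test of independence conditions on the observed margins instead; its
    p-value is mapped back to an equivalent 1-df LOD so one threshold
    applies across type pairs with different table sizes.

    ``n`` has shape (a, b, 3, 3).
    """
    from scipy.stats import chi2

    tot = n.sum(axis=(2, 3))
    tot_safe = np.maximum(tot, 1.0)
    rowm = n.sum(axis=3)
    colm = n.sum(axis=2)
    expect = rowm[:, :, :, None] * colm[:, :, None, :] / tot_safe[:, :, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(n / np.maximum(expect, 1e-300)), 0.0)
    g2 = 2.0 * term.sum(axis=(2, 3))
    dfs = (np.maximum((rowm > 0).sum(axis=2) - 1, 1)) * (np.maximum((colm > 0).sum(axis=2) - 1, 1))
    p = chi2.sf(np.maximum(g2, 0.0), dfs)
    g1 = chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return g1 / (2.0 * LN10)


# ----------------------------------------------------------------------
def pairwise_tables(
    codings: list[MarkerCoding], grouping_lod: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rf and LOD matrices over all marker pairs.

    rf is the grid-resolution maximum-likelihood estimate (use
    :func:`twopoint_rf` for a single polished value); the returned LOD is
    the distortion-robust independence LOD used for grouping when
    ``grouping_lod`` is true, else the likelihood-ratio LOD at the rf
    estimate.  rf is nan for uninformative pairs.
    """
    m = len(codings)
    rf = np.full((m, m), np.nan)
    lod = np.zeros((m, m))
    types = [c.seg_type for c in codings]
    by_type: dict[str, list[int]] = {}
    for i, t in enumerate(types):
        by_type.setdefault(t, []).append(i)

    onehot: dict[str, np.ndarray] = {}
    for t, idx in by_type.items():
        codes = np.stack([codings[i].codes for i in idx])  # (mt, n_prog)
        oh = np.zeros((codes.shape[0], codes.shape[1], 3))
        for c in range(3):
            oh[:, :, c] = codes == c
        onehot[t] = oh

    seen = set()
    for ta, ia in by_type.items():
        for tb, ib in by_type.items():
            key = tuple(sorted((ta, tb)))
            if (ta, tb) != key or key in seen:
                continue
            seen.add(key)
            if not informative_pair(ta, tb):
                continue
            n = np.einsum("apc,bpd->abcd", onehot[ta], onehot[tb])
            best_ll = np.full(n.shape[:2], -np.inf)
            best_g = np.zeros(n.shape[:2], dtype=int)
            ll_half = None
            for ph in _phase_configs(ta, tb):
                p = pair_prob_table(ta, tb, ph[0], ph[1], R_GRID)
                logp = np.log(np.maximum(p, 1e-300))
                ll = np.einsum("abcd,gcd->abg", n, logp)
                if ll_half is None:
                    ll_half = ll[:, :, -1]
                g = ll.argmax(axis=2)
                mx = np.take_along_axis(ll, g[:, :, None], axis=2)[:, :, 0]
                upd = mx > best_ll
                best_ll[upd] = mx[upd]
                best_g[upd] = g[upd]
            block_rf = R_GRID[best_g]
            if grouping_lod:
                block_lod = _independence_lod(n)
            else:
                block_lod = np.maximum((best_ll - ll_half) / LN10, 0.0)
                block_lod[block_rf >= 0.5 - 1e-9] = 0.0
            ia_arr, ib_arr = np.asarray(ia), np.asarray(ib)
            rf[np.ix_(ia_arr, ib_arr)] = block_rf
            lod[np.ix_(ia_arr, ib_arr)] = block_lod
            rf[np.ix_(ib_arr, ia_arr)] = block_rf.T
            lod[np.ix_(ib_arr, ia_arr)] = block_lod.T
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    return rf, lod
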