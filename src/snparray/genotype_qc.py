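"""Array-intensity QC: cluster space, DQC, genotype calling, SNP metrics
and the six-way conversion classification.

The vendor caller and its exact metric formulas are proprietary; the
implementations here follow the published verbal definitions and are the
reference formulas for this package: contrast ``x = log2(A) - log2(B)`` and
size ``y = (log2(A) + log2(B)) / 2``; DQC as the normal-CDF separation of
control signal vs noise; FLD as between-cluster distance over pooled
within-cluster spread in x; HetSO as the heterozygote's vertical offset from
the homozygote line; HomRO as the signed distance of the homozygote
cluster(s) from zero contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .core import MISSING

log = logging.getLogger(__name__)

CATEGORIES = (
    "PolyHighResolution",
    "NoMinorHom",
    "OTV",
    "MonoHighResolution",
    "CallRateBelowThreshold",
    "Other",
)

# canonical contrast positions used to seed EM components, by dosage 0/1/2
_CANON_X = np.array([1.5, 0.0, -1.5])


@dataclass
class QcThresholds:
    cr_category: float = 95.0  # below this -> CallRateBelowThreshold
    cr_pass: float = 97.0  # conversion criterion
    fld_min: float = 3.6
    hetso_min: float = -0.1
    homro_min: float = 0.3
    posterior_min: float = 0.95
    dqc_min: float = 0.82


@dataclass
class SampleQc:
    dqc: float
    sample_call_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dqc <= 1.0):
            raise ValueError("dqc must lie in [0, 1]")
        if not (0.0 <= self.sample_call_rate <= 100.0):
            raise ValueError("sample call rate must lie in [0, 100]")


@dataclass
class SnpQcMetrics:
    cr: float
    fld: float | None
    hetso: float | None
    homro: float | None
    n_clusters_observed: int
    maf: float | None
    otv_hetso: float | None = None  # y-offset of a detected extra low-size cluster


@dataclass
class SnpCalls:
    """Per-sample dosage calls (0/1/2, -1 no-call) with posteriors."""

    calls: np.ndarray
    posterior: np.ndarray
    converged: bool
    means_x: dict[int, float] = field(default_factory=dict)  # dosage -> fitted x center


# ----------------------------------------------------------------------
def to_cluster_space(a, b):
    """Two-channel intensities -> (contrast x, size y)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    bad = (a <= 0) | (b <= 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValueError(f"non-positive intensity at index {tuple(int(i) for i in idx)}")
    la, lb = np.log2(a), np.log2(b)
    return la - lb, (la + lb) / 2.0


def compute_dqc(signal, noise) -> float:
    """Signal/noise contrast of non-polymorphic control probes.

    dqc = Phi((mu_s - mu_n) / sqrt(var_s + var_n)); 1 at perfect separation,
    0.5 at none.
    """
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if signal.size < 2 or noise.size < 2:
        raise ValueError("need >= 2 signal and >= 2 noise observations")
    var = signal.var(ddof=1) + noise.var(ddof=1)
    diff = signal.mean() - noise.mean()
    if var == 0.0:
        return 1.0 if diff > 0 else 0.5
    return float(norm.cdf(diff / np.sqrt(var)))


# ----------------------------------------------------------------------
def _em_1d(x: np.ndarray, means0: np.ndarray, max_iter: int = 200, tol: float = 1e-8,
           var_floor: float = 1e-4, var_cap: float = np.inf, tied: bool = False):
    """Tiny fixed-k 1-D Gaussian-mixture EM. Deterministic.

    ``var_cap`` bounds component variances; the caller uses it to keep a
    single broad component from absorbing clearly multi-modal data.
    ``tied`` shares one variance across components (used for genotype
    calling so that ambiguity between clusters is symmetric).
    """
    k = len(means0)
    n = x.size
    means = means0.astype(float).copy()
    var = np.full(k, min(max(x.var(), var_floor), var_cap))
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    converged = False
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        denom = p.sum(axis=1, keepdims=True)
        resp = p / denom
        ll = float((m.ravel() + np.log(denom.ravel())).sum())
        nk = resp.sum(axis=0) + 1e-12
        w = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        if tied:
            var[:] = (var * nk).sum() / nk.sum()
        var = np.clip(var, var_floor, var_cap)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    n_params = 3 * k - 1
    bic = -2.0 * ll + n_params * np.log(n)
    return means, var, w, resp, ll, bic, converged


def call_genotypes(x: np.ndarray, thresholds: QcThresholds | None = None,
                   canonical_x: np.ndarray = _CANON_X) -> SnpCalls:
    """EM genotype calling on the contrast dimension.

    Models with 1-3 components seeded at the canonical contrast positions
    are fitted and selected by BIC; each component keeps the dosage label of
    its seed.  A sample is no-call when its maximum posterior falls below
    the threshold (default 0.95).  Deterministic.
    """
    th = thresholds or QcThresholds()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need >= 10 samples to call genotypes")

    seeds = [
        (np.array([x.mean()]), None),  # label decided post hoc
        (canonical_x[[0, 1]], (0, 1)),
        (canonical_x[[1, 2]], (1, 2)),
        (canonical_x[[0, 2]], (0, 2)),
        (canonical_x, (0, 1, 2)),
    ]
    sep = float(abs(canonical_x[0] - canonical_x[1]))
    best = None
    for means0, _ in seeds:
        means, var, w, resp, ll, bic, conv = _em_1d(
            x, np.asarray(means0, dtype=float), var_cap=(sep / 3.0) ** 2, tied=True)
        if len(means0) > 1 and w.min() * n < 2.0:
            continue  # a component must hold at least ~2 samples
        # label each component by the nearest canonical position post fit
        labels = tuple(int(np.argmin(np.abs(canonical_x - mu))) for mu in means)
        if len(set(labels)) < len(labels):
            continue  # two components collapsed onto one genotype
        if best is None or bic < best[0] - 1e-9:
            best = (bic, means, var, w, resp, labels, conv)
    if best is None:  # all multi-component fits degenerate; fall back to k=1
        means, var, w, resp, ll, bic, conv = _em_1d(x, np.array([x.mean()]), tied=True)
        labels = (int(np.argmin(np.abs(canonical_x - means[0]))),)
        best = (bic, means, var, w, resp, labels, conv)
    bic, means, var, w, resp, labels, conv = best
    if not conv:
        log.warning("EM did not converge in 200 iterations; all samples set to no-call")
        return SnpCalls(np.full(n, MISSING, dtype=np.int8), np.zeros(n), False)
    post = resp.max(axis=1)
    comp = resp.argmax(axis=1)
    calls = np.array([labels[c] for c in comp], dtype=np.int8)
    calls[post < th.posterior_min] = MISSING
    means_x = {int(lab): float(mu) for lab, mu in zip(labels, means)}
    return SnpCalls(calls=calls, posterior=post, converged=True, means_x=means_x)


# ----------------------------------------------------------------------
def _cluster_stats(calls: np.ndarray, v: np.ndarray):
    out = {}
    for dos in (0, 1, 2):
        sel = calls == dos
        if sel.sum() > 0:
            out[dos] = (sel.sum(), float(v[sel].mean()), float(v[sel].var(ddof=1)) if sel.sum() > 1 else None)
    return out


def _detect_extra_low_y(calls: np.ndarray, y: np.ndarray, ref_y: float) -> float | None:
    """Offset of a distinct extra low-size cluster among x~0 / no-call
    samples, or None.  Both a normal-size and a low-size subcluster must be
    present for the cluster to count as *extra*."""
    sel = (calls == 1) | (calls == MISSING)
    ys = y[sel]
    if ys.size < 4:
        return None
    m1 = _em_1d(ys, np.array([ys.mean()]))
    lo, hi = np.quantile(ys, [0.1, 0.9])
    m2 = _em_1d(ys, np.array([lo, hi]))
    if m2[5] >= m1[5] - 10.0:  # require a clear BIC preference for 2 clusters
        return None
    means2, _, w2 = m2[0], m2[1], m2[2]
    low, high = (0, 1) if means2[0] < means2[1] else (1, 0)
    if min(w2) < 0.08:
        return None
    off_low = float(means2[low] - ref_y)
    off_high = float(means2[high] - ref_y)
    if off_high < -0.1:  # the whole cluster is shifted, not an extra one
        return None
    return off_low


def compute_snp_metrics(calls: SnpCalls, x: np.ndarray, y: np.ndarray) -> SnpQcMetrics:
    """Per-SNP cluster-quality metrics from calls and cluster coordinates."""
    c = calls.calls
    n = c.size
    cr = 100.0 * float((c != MISSING).sum()) / n

    xstats = _cluster_stats(c, x)
    ystats = _cluster_stats(c, y)
    present = sorted(xstats)

    pooled = [v for (_, _, v) in xstats.values() if v is not None]
    floor = float(np.mean(pooled)) if pooled else 1e-4

    def var_of(dos):
        nv = xstats[dos][2]
        if nv is None:
            log.warning("cluster %d has < 2 samples; variance from pooled floor", dos)
            return floor
        return nv

    fld = None
    if len(present) >= 2:
        flds = []
        for a, b in zip(present[:-1], present[1:]):
            na, nb = xstats[a][0], xstats[b][0]
            va, vb = var_of(a), var_of(b)
            sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
            sp = max(sp, 1e-9)
            flds.append(abs(xstats[a][1] - xstats[b][1]) / sp)
        fld = float(min(flds))

    homs = [d for d in present if d in (0, 2)]
    hetso = None
    if 1 in present and homs:
        if len(homs) == 2:
            x0, y0 = xstats[0][1], ystats[0][1]
            x2, y2 = xstats[2][1], ystats[2][1]
            xh = xstats[1][1]
            if abs(x2 - x0) > 1e-12:
                line_y = y0 + (y2 - y0) * (xh - x0) / (x2 - x0)
            else:
                line_y = (y0 + y2) / 2.0
            hetso = float(ystats[1][1] - line_y)
        else:
            hetso = float(ystats[1][1] - ystats[homs[0]][1])

    homro = None
    if homs:
        vals = []
        for d in homs:
            mu = xstats[d][1]
            vals.append(mu if d == 0 else -mu)  # dosage 0 = AA sits at +x
        homro = float(min(vals))

    called = c[c != MISSING]
    maf = None
    if called.size:
        p = called.mean() / 2.0
        maf = float(min(p, 1 - p))

    hom_y = [ystats[d][1] for d in homs]
    ref_y = float(np.mean(hom_y)) if hom_y else (ystats[1][1] if 1 in ystats else float(np.mean(y)))
    otv = _detect_extra_low_y(c, y, ref_y)
    n_clusters = len(present) + (1 if otv is not None else 0)

    return SnpQcMetrics(
        cr=cr, fld=fld, hetso=hetso, homro=homro,
        n_clusters_observed=min(n_clusters, 4), maf=maf, otv_hetso=otv,
    )


# ----------------------------------------------------------------------
def classify_snp(m: SnpQcMetrics, thresholds: QcThresholds | None = None) -> str:
    """Six-way conversion category; total and deterministic."""
    th = thresholds or QcThresholds()
    if m.cr < th.cr_category:
        return "CallRateBelowThreshold"
    if m.otv_hetso is not None and m.otv_hetso < th.hetso_min:
        return "OTV"
    n_called_clusters = m.n_clusters_observed - (1 if m.otv_hetso is not None else 0)
    if n_called_clusters <= 1:
        if (
            m.cr >= th.cr_pass
            and m.homro is not None
            and m.homro >= th.homro_min
        ):
            return "MonoHighResolution"
        return "Other"
    hetso_ok = m.hetso is None or m.hetso >= th.hetso_min
    fld_ok = m.fld is not None and m.fld >= th.fld_min
    homro_ok = m.homro is not None and m.homro >= th.homro_min
    if m.cr >= th.cr_pass and fld_ok and hetso_ok and homro_ok:
        if m.maf is not None and m.maf > 0 and _both_homs(m):
            return "PolyHighResolution"
        return "NoMinorHom"
    return "Other"


def _both_homs(m: SnpQcMetrics) -> bool:
    # both homozygote clusters present <=> HomRO was a min over two values;
    # we tag it via n_clusters: 3 called clusters, or 2 called without a het
    n_called = m.n_clusters_observed - (1 if m.otv_hetso is not None else 0)
    if n_called >= 3:
        return True
    return m.hetso is None  # two clusters, no het -> both are homs


def duplicate_concordance(calls_a: np.ndarray, calls_b: np.ndarray) -> float | None:
    """Percent matching genotypes over jointly-called SNPs of a duplicate pair."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    joint = (a != MISSING) & (b != MISSING)
    if joint.sum() == 0:
        log.warning("no jointly-called SNPs between duplicates")
        return None
    return 100.0 * float((a[joint] == b[joint]).mean())


# ----------------------------------------------------------------------
def qc_panel(panel, thresholds: QcThresholds | None = None):
    """Run calling + metrics + classification over an IntensityPanel.

    Returns ``(per_snp frame, per_sample frame, calls matrix)`` where the
    calls matrix is samples x snps with -1 for no-calls.
    """
    import pandas as pd

    th = thresholds or QcThresholds()
    x, y = to_cluster_space(panel.a, panel.b)
    n_s, n_v = x.shape
    calls = np.full((n_s, n_v), MISSING, dtype=np.int8)
    rows = []
    for j, snp in enumerate(panel.snp_ids):
        sc = call_genotypes(x[:, j], th)
        calls[:, j] = sc.calls
        m = compute_snp_metrics(sc, x[:, j], y[:, j])
        rows.append(
            (snp, m.cr, m.fld, m.hetso, m.homro, m.maf, m.n_clusters_observed,
             classify_snp(m, th))
        )
    per_snp = pd.DataFrame(
        rows, columns=["snp", "CR", "FLD", "HetSO", "HomRO", "MAF", "n_clusters", "category"]
    ).set_index("snp")

    sample_rows = []
    for i, sid in enumerate(panel.sample_ids):
        dqc = compute_dqc(panel.control_signal[i], panel.control_noise[i])
        scr = 100.0 * float((calls[i] != MISSING).mean())
        sample_rows.append((sid, dqc, scr, dqc >= th.dqc_min and scr >= th.cr_category))
    per_sample = pd.DataFrame(
        sample_rows, columns=["sample", "dqc", "call_rate", "passed"]
    ).set_index("sample")
    return per_snp, per_sample, calls
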