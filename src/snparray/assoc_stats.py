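"""Kinship, PCA, broad-sense heritability and single-marker mixed-model
association with a 1/n significance threshold and flanking-gene scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class HeritabilityEstimate:
    sigma_g2: float
    sigma_e2: float
    n_reps: float
    h2_plot: float
    h2_family: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_reps > 1 and self.h2_family < self.h2_plot - 1e-12:
            raise ValueError("family-mean H2 must be >= plot H2 when reps > 1")


def _imputed_dosage(g: GenotypeMatrix, maf_min: float = 0.0, missing_max: float = 1.0):
    """Filtered, mean-imputed dosage matrix plus the per-marker alt freq."""
    maf = g.maf()
    miss = g.missing_fraction()
    keep = (~np.isnan(maf)) & (miss <= missing_max)
    if maf_min > 0:
        keep &= np.nan_to_num(maf) >= maf_min
    d = g.dosage[:, keep].astype(float)
    n_missing = int((d == MISSING).sum())
    if n_missing:
        log.info("imputing %d missing dosages to 2p", n_missing)
    d[d == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    d = np.where(np.isnan(d), 2.0 * p, d)
    return d, p, keep


def vanraden_kinship(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """Genomic relationship matrix K = ZZ' / (2 * sum p(1-p)).

    Z centres dosages by twice the allele frequency; missing values are
    imputed to 2p.  Frequencies default to the sample estimates (``freqs``
    overrides, e.g. reference panel values).  Monomorphic markers are
    excluded; an all-monomorphic input is an error (zero denominator).
    """
    d, p, keep = _imputed_dosage(g)
    if freqs is not None:
        p = np.asarray(freqs, dtype=float)[keep]
    poly = (p > 0) & (p < 1)
    d, p = d[:, poly], p[poly]
    denom = 2.0 * float(np.sum(p * (1 - p)))
    if denom <= 0 or d.shape[1] == 0:
        raise ValueError("all markers monomorphic: kinship denominator is zero")
    z = d - 2.0 * p
    return z @ z.T / denom


def genotype_pca(g: GenotypeMatrix, k: int = 3, maf_min: float = 0.05,
                 missing_max: float = 0.2) -> np.ndarray:
    """Top-k principal components of the column-standardised dosage matrix.

    Sign convention: each component's largest-magnitude loading is positive.
    """
    d, p, _ = _imputed_dosage(g, maf_min=maf_min, missing_max=missing_max)
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    x = (d - mu) / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-9).sum())
    if k > rank:
        log.warning("requested %d PCs but rank is %d; truncating", k, rank)
        k = rank
    pcs = u[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ----------------------------------------------------------------------
def heritability(phenotypes: pd.DataFrame, trait: str | None = None) -> HeritabilityEstimate:
    """Broad-sense heritability from a one-way random-effects decomposition.

    ``phenotypes`` is a long frame with columns ``genotype``, ``value`` and
    optionally ``trait`` (selected via the ``trait`` argument).  The mean
    replicate count of an unbalanced design is the harmonic mean.  Estimates
    are clipped at zero; H2_family = sg2 / (sg2 + se2 / n_reps).
    """
    df = phenotypes
    if trait is not None:
        df = df[df["trait"] == trait]
    df = df.dropna(subset=["value"])
    sizes = df.groupby("genotype")["value"].count()
    sizes = sizes[sizes >= 1]
    if len(sizes) < 2:
        raise ValueError("need >= 2 genotypes")
    if (sizes < 2).all():
        raise ValueError("error variance inestimable with a single replicate everywhere")
    n_bar = float(len(sizes) / np.sum(1.0 / sizes))  # harmonic mean
    grand = df["value"].mean()
    means = df.groupby("genotype")["value"].mean()
    ss_g = float((sizes * (means - grand) ** 2).sum())
    ms_g = ss_g / (len(sizes) - 1)
    resid = df["value"] - df["genotype"].map(means)
    ss_e = float((resid**2).sum())
    dfe = int(sizes.sum()) - len(sizes)
    ms_e = ss_e / dfe if dfe > 0 else 0.0
    sigma_e2 = ms_e
    sigma_g2 = max((ms_g - ms_e) / n_bar, 0.0)
    denom_plot = sigma_g2 + sigma_e2
    h2_plot = sigma_g2 / denom_plot if denom_plot > 0 else 1.0
    denom_fam = sigma_g2 + sigma_e2 / n_bar
    h2_family = sigma_g2 / denom_fam if denom_fam > 0 else 1.0
    return HeritabilityEstimate(sigma_g2, sigma_e2, n_bar, h2_plot, h2_family)


# ----------------------------------------------------------------------
def _reml_delta(yr: np.ndarray, xr: np.ndarray, lam: np.ndarray) -> float:
    """REML estimate of delta = sigma_e2 / sigma_g2 on the eigenrotated
    model; 1-D log-grid search polished by Brent."""
    n, p = xr.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (lam + delta)
        xtwx = xr.T @ (xr * w[:, None])
        xtwy = xr.T @ (yr * w)
        beta = np.linalg.solve(xtwx, xtwy)
        r = yr - xr @ beta
        rss = float(np.sum(r * r * w))
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(lam + delta))
            + logdet_xtwx
            + (n - p)
        )
        return -ll

    grid = np.linspace(-8, 8, 33)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


def mlm_assoc(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    kinship: np.ndarray,
    pcs: np.ndarray | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Single-marker mixed linear model: y = Xb + u + e, u ~ N(0, sg2 K).

    The variance ratio is estimated once under the null by REML on the
    eigendecomposition of K (single rotation) and reused per marker
    (generalised least squares with a Wald test).  X holds an intercept
    plus any supplied PCs.  Markers below ``maf_min`` or with zero variance
    are skipped.  Adds the 1/n threshold and significance flags.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    if not ok.all():
        log.info("dropping %d samples with missing trait", int((~ok).sum()))
    yv = y[ok]
    k = kinship[np.ix_(ok, ok)]
    evals, evecs = np.linalg.eigh(k)
    if evals.min() < -1e-8:
        log.warning("kinship not PSD; flooring negative eigenvalues at 0")
    evals = np.maximum(evals, 0.0)

    x_cols = [np.ones(ok.sum())]
    if pcs is not None:
        x_cols.extend(np.asarray(pcs)[ok].T)
    x = np.column_stack(x_cols)

    yr = evecs.T @ yv
    xr = evecs.T @ x
    delta = _reml_delta(yr, xr, evals)
    w = 1.0 / (evals + delta)

    d, p, keep = _imputed_dosage(g, maf_min=maf_min)
    ids = np.asarray(g.variant_ids)[keep]
    chroms = g.variants["chrom"].to_numpy()[keep]
    poss = g.variants["pos"].to_numpy()[keep]
    d = d[ok]

    n, p0 = xr.shape
    rows = []
    dr_all = evecs.T @ d
    for j, vid in enumerate(ids):
        dr = dr_all[:, j]
        if dr.std() < 1e-12:
            log.info("zero-variance marker %s skipped", vid)
            continue
        xj = np.column_stack([xr, dr])
        xtwx = xj.T @ (xj * w[:, None])
        xtwy = xj.T @ (yr * w)
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            continue
        beta = xtwx_inv @ xtwy
        r = yr - xj @ beta
        dof = n - xj.shape[1]
        sigma2 = float(np.sum(r * r * w)) / dof
        se = float(np.sqrt(sigma2 * xtwx_inv[-1, -1]))
        t = beta[-1] / se if se > 0 else 0.0
        pval = 2.0 * stats.t.sf(abs(t), dof)
        pval = min(max(pval, np.finfo(float).tiny), 1.0)
        rows.append((vid, chroms[j], int(poss[j]), float(beta[-1]), se, float(pval)))
    out = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "effect", "se", "p"])
    thr = significance_threshold(len(out)) if len(out) else np.nan
    out["threshold"] = thr
    out["significant"] = out["p"] < thr
    return out


def significance_threshold(n_markers: int) -> float:
    """1 / n significance threshold."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return 1.0 / n_markers


# ----------------------------------------------------------------------
@dataclass
class CandidateScanParams:
    flank_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


def candidate_gene_scan(
    markers: pd.DataFrame,
    genes: pd.DataFrame,
    params: CandidateScanParams | None = None,
) -> pd.DataFrame:
    """Genes whose span intersects the strand-agnostic flanking window of
    each significant marker; distance 0 when the marker lies inside.

    ``markers`` columns: ``marker``, ``chrom``, ``pos``; ``genes`` uses the
    feature-frame layout (rows of type ``gene``).
    """
    params = params or CandidateScanParams()
    gsub = genes[genes["type"] == "gene"]
    rows = []
    for m in markers.itertuples():
        here = gsub[gsub["seq"] == m.chrom]
        if here.empty and (gsub["seq"] == m.chrom).sum() == 0:
            log.info("marker %s on sequence absent from the annotation", m.marker)
        lo, hi = m.pos - params.flank_bp, m.pos + params.flank_bp
        hits = here[(here["start"] <= hi) & (here["end"] >= lo)]
        for h in hits.itertuples():
            if h.start <= m.pos <= h.end:
                dist = 0
            else:
                dist = int(min(abs(h.start - m.pos), abs(h.end - m.pos)))
            rows.append((m.marker, m.chrom, int(m.pos), h.feature_id, int(h.start), int(h.end), dist))
    return pd.DataFrame(
        rows, columns=["marker", "chrom", "pos", "gene", "gene_start", "gene_end", "distance"]
    )


def trait_correlations(phenotypes: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of genotype-mean traits."""
    wide = phenotypes.groupby(["genotype", "trait"])["value"].mean().unstack()
    traits = list(wide.columns)
    out = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            b = traits[j]
            sub = wide[[a, b]].dropna()
            if len(sub) < min_pairs or sub[a].std() == 0 or sub[b].std() == 0:
                r = np.nan
                if sub[a].std() == 0 or sub[b].std() == 0:
                    log.warning("constant trait in correlation (%s, %s)", a, b)
            else:
                r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out
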