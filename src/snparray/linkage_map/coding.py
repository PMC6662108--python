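"""Outcrossed (CP) marker coding and segregation filtering.

Markers are recoded against the parental configuration into the three
segregation types: ``lmxll`` (first parent heterozygous), ``nnxnp`` (second
parent heterozygous) and ``hkxhk`` (both heterozygous).  Codes are stored as
small integers: for the one-parent types the code is the heterozygous
parent's transmitted allele (0/1); for ``hkxhk`` the code is the progeny
dosage class (0/1/2).  Missing is -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..core import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

SEG_TYPES = ("lmxll", "nnxnp", "hkxhk")
ADMITTED_CATEGORIES = ("PolyHighResolution", "NoMinorHom")


@dataclass
class MarkerCoding:
    marker: str
    seg_type: str
    codes: np.ndarray  # int8; -1 missing
    n_missing: int
    n_mendel_errors: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.seg_type not in SEG_TYPES:
            raise ValueError(f"unknown segregation type {self.seg_type!r}")
        hi = 2 if self.seg_type == "hkxhk" else 1
        ok = np.isin(self.codes, list(range(hi + 1)) + [MISSING])
        if not ok.all():
            raise ValueError(f"codes outside alphabet for {self.seg_type}")

    @property
    def n_informative(self) -> int:
        return int((self.codes != MISSING).sum())


def _code_one(p1: int, p2: int, progeny: np.ndarray, marker: str,
              mendel_tol: float) -> MarkerCoding | None:
    het1, het2 = p1 == 1, p2 == 1
    if p1 == MISSING or p2 == MISSING or (not het1 and not het2):
        return None
    codes = np.full(progeny.shape, MISSING, dtype=np.int8)
    errors = 0
    if het1 and het2:
        seg = "hkxhk"
        ok = progeny != MISSING
        codes[ok] = progeny[ok]
    else:
        seg = "lmxll" if het1 else "nnxnp"
        hom = p2 if het1 else p1
        base = hom // 2  # allele contributed by the homozygous parent
        ok = progeny != MISSING
        val = progeny[ok] - base
        good = (val >= 0) & (val <= 1)
        errors = int((~good).sum())
        tmp = np.where(good, val, MISSING).astype(np.int8)
        codes[ok] = tmp
    n_missing = int((codes == MISSING).sum())
    n_obs = progeny.size - int((progeny == MISSING).sum())
    flagged = n_obs > 0 and errors / n_obs > mendel_tol
    if flagged:
        log.warning("marker %s has %.1f%% Mendelian errors; flagged", marker, 100 * errors / n_obs)
    return MarkerCoding(marker, seg, codes, n_missing, errors, flagged)


def code_markers(
    parent1: np.ndarray,
    parent2: np.ndarray,
    progeny: GenotypeMatrix,
    categories: dict[str, str] | None = None,
    mendel_tol: float = 0.02,
) -> dict[str, MarkerCoding]:
    """Recode each marker; hom x hom and missing-parent markers are excluded.

    ``categories``, when given, restricts coding to SNPs whose QC conversion
    category is PolyHighResolution or NoMinorHom.
    """
    out: dict[str, MarkerCoding] = {}
    for j, marker in enumerate(progeny.variant_ids):
        if categories is not None and categories.get(marker) not in ADMITTED_CATEGORIES:
            continue
        mc = _code_one(int(parent1[j]), int(parent2[j]), progeny.dosage[:, j], marker, mendel_tol)
        if mc is not None:
            out[marker] = mc
    return out


def segregation_test(
    coding: MarkerCoding, alpha: float = 0.01, max_missing: int = 10
) -> tuple[float, float, bool]:
    """Chi-square goodness-of-fit against 1:1 (or 1:2:1 for hkxhk).

    Returns (chi2, p, keep); the marker is dropped when p < alpha or when
    more than ``max_missing`` genotypes are missing.
    """
    obs_codes = coding.codes[coding.codes != MISSING]
    if obs_codes.size == 0:
        log.warning("marker %s is all-missing; dropped", coding.marker)
        return float("nan"), float("nan"), False
    if coding.seg_type == "hkxhk":
        counts = np.bincount(obs_codes, minlength=3)[:3]
        expected = obs_codes.size * np.array([0.25, 0.5, 0.25])
    else:
        counts = np.bincount(obs_codes, minlength=2)[:2]
        expected = obs_codes.size * np.array([0.5, 0.5])
    chi2, p = stats.chisquare(counts, expected)
    keep = (p >= alpha) and (coding.n_missing <= max_missing) and not coding.flagged
    return float(chi2), float(p), bool(keep)
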