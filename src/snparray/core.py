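"""Core genotype container shared by every pipeline stage.

Dosages are coded as the number of alternate alleles (0, 1, 2) with ``-1``
for a missing call, stored as an ``int8`` samples x variants matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosage matrix with coordinates.

    Parameters
    ----------
    samples:
        Sample identifiers, one per matrix row.
    variants:
        Frame indexed by variant id with columns ``chrom`` (sequence id),
        ``pos`` (1-based), ``ref`` and ``alt``.  Positions must be sorted
        within each sequence.
    dosage:
        ``int8`` array of shape ``(n_samples, n_variants)`` with values in
        ``{0, 1, 2, -1}``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        for col in _VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variants frame missing column {col!r}")
        if not self.variants.index.is_unique:
            raise ValueError("variant ids must be unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, -1}")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("variant positions must be sorted within each sequence")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    # ------------------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return self.missing_mask().mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls.

        Variants with zero non-missing calls yield ``nan``.
        """
        import warnings

        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    # ------------------------------------------------------------------
    def subset_variants(self, ids) -> "GenotypeMatrix":
        """Select variants, preserving genome order regardless of id order."""
        idx = self.variants.index.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        idx = np.sort(idx)
        return GenotypeMatrix(self.samples, self.variants.iloc[idx].copy(), self.dosage[:, idx])

    def subset_samples(self, names) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[n] for n in names]
        return GenotypeMatrix(list(names), self.variants.copy(), self.dosage[idx, :])

    def sample_dosage(self, name: str) -> np.ndarray:
        return self.dosage[self.samples.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Variants x samples frame of dosage codes (missing as -1)."""
        return pd.DataFrame(self.dosage.T, index=self.variants.index, columns=self.samples)
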