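from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snparray.core import GenotypeMatrix
from snparray.simdata import SimConfig
from snparray.pipeline import SimBundle, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_chromosomes=3,
        chrom_lengths_bp=[3_000_000] * 3,
        n_scaffolds=3,
        scaffold_lengths_bp=[250_000] * 3,
        snp_density_per_mb=15.0,
        gene_density_per_mb=40.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> SimBundle:
    return simulate_dataset(small_config)


def toy_matrix(dosage, positions=None, chrom="chr1") -> GenotypeMatrix:
    """Small helper constructing a GenotypeMatrix from a dosage array."""
    d = np.asarray(dosage, dtype=np.int8)
    n_s, n_v = d.shape
    pos = positions if positions is not None else [(j + 1) * 100 for j in range(n_v)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "B"},
        index=[f"v{j}" for j in range(n_v)],
    )
    return GenotypeMatrix([f"s{i}" for i in range(n_s)], variants, d)


def make_markers(cms, chrom="chr1", cm_per_mb=4.0) -> pd.DataFrame:
    """Marker table on one chromosome at given cM positions (uniform rate)."""
    cms = np.asarray(cms, dtype=float)
    pos = (cms / cm_per_mb * 1e6).astype(int) + 1
    return pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(len(cms))],
            "seq": chrom,
            "pos": pos,
            "true_chrom": chrom,
            "true_pos": pos,
            "cm": cms,
        }
    )
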