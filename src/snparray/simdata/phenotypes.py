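"""Replicated quantitative phenotypes with planted QTLs and known H2."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import MISSING, GenotypeMatrix
from .config import rng_for

__all__ = ["sim_phenotypes"]


def sim_phenotypes(
    genotypes: GenotypeMatrix,
    qtls: pd.DataFrame,
    true_h2: dict[str, float],
    n_reps: int,
    seed: int,
    polygenic_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate replicated phenotypes.

    ``qtls`` has columns ``trait``, ``marker``, ``effect``; a trait may have
    an empty QTL list (pure polygenic control).  The genotypic value is the
    sum of effect x dosage plus a polygenic normal term; the replicate noise
    variance is set so the plot-basis heritability equals ``true_h2[trait]``.

    Returns a long frame (genotype, replicate, trait, value).
    """
    for col in ("trait", "marker", "effect"):
        if col not in qtls.columns:
            raise ValueError(f"qtls frame missing column {col!r}")
    unknown = set(qtls["marker"]) - set(genotypes.variants.index)
    if unknown:
        raise KeyError(f"QTL markers absent from genotypes: {sorted(unknown)[:5]}")

    traits = list(true_h2)
    for t, h2 in true_h2.items():
        if not (0.0 < h2 <= 1.0):
            raise ValueError(f"true_h2[{t!r}] must lie in (0, 1]")

    d = genotypes.dosage.astype(float)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)

    rows = []
    n = genotypes.n_samples
    for ti, trait in enumerate(traits):
        rng = rng_for(seed, 30, ti)
        sub = qtls[qtls["trait"] == trait]
        g = np.zeros(n)
        for r in sub.itertuples():
            j = genotypes.variants.index.get_loc(r.marker)
            g += float(r.effect) * d[:, j]
        g += polygenic_sd * rng.standard_normal(n)
        var_g = float(np.var(g))
        if var_g == 0.0:
            raise ValueError(f"trait {trait!r} has zero genotypic variance")
        h2 = true_h2[trait]
        sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
        noise = sd_e * rng.standard_normal((n, n_reps))
        for rep in range(n_reps):
            vals = g + noise[:, rep]
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": genotypes.samples,
                        "replicate": rep + 1,
                        "trait": trait,
                        "value": vals,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
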