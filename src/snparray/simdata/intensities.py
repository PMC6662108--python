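"""Two-channel probe-intensity simulation in contrast/size cluster space.

A clean SNP yields three Gaussian clusters at canonical contrast positions;
off-target-variant (OTV) SNPs gain a fourth low-size cluster and low-call-rate
SNPs get inflated noise.  Non-polymorphic control probes are emitted so the
per-sample DQC statistic can be computed downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import MISSING, GenotypeMatrix
from .config import rng_for

__all__ = ["ClusterSpec", "IntensityPanel", "sim_intensities"]


@dataclass
class ClusterSpec:
    """Cluster geometry in (contrast x, size y) space per genotype class.

    ``center_x``/``center_y`` are indexed by dosage (0=AA, 1=AB, 2=BB).
    """

    center_x: tuple[float, float, float] = (1.5, 0.0, -1.5)
    center_y: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sd_x: float = 0.12
    sd_y: float = 0.08
    otv_center: tuple[float, float] = (0.0, 0.0)
    otv_sample_fraction: float = 0.35
    lowcr_noise_factor: float = 3.5
    lowcr_uniform_fraction: float = 0.65
    n_control_probes: int = 20
    control_signal: tuple[float, float] = (10.0, 1.5)  # mean, sd
    control_noise: tuple[float, float] = (4.0, 1.5)

    def __post_init__(self) -> None:
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ValueError("cluster spreads must be positive")
        if self.control_signal[1] <= 0 or self.control_noise[1] <= 0:
            raise ValueError("control-probe spreads must be positive")


@dataclass
class IntensityPanel:
    """Simulated hybridization signals plus per-SNP design truth."""

    snp_ids: list[str]
    sample_ids: list[str]
    a: np.ndarray = field(repr=False)  # (n_samples, n_snps)
    b: np.ndarray = field(repr=False)
    control_signal: np.ndarray = field(repr=False)  # (n_samples, n_control)
    control_noise: np.ndarray = field(repr=False)
    designed_category: dict[str, str] = field(default_factory=dict)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready frame (snp, sample, channelA, channelB)."""
        n_s, n_v = self.a.shape
        return pd.DataFrame(
            {
                "snp": np.repeat(self.snp_ids, n_s),
                "sample": np.tile(self.sample_ids, n_v),
                "channelA": self.a.T.ravel(),
                "channelB": self.b.T.ravel(),
            }
        )


def _designed_category(dosages: np.ndarray, role: str) -> str:
    if role == "otv":
        return "OTV"
    if role == "lowcr":
        return "CallRateBelowThreshold"
    if role == "hetso_shift":
        return "Other"
    classes = set(int(d) for d in dosages if d != MISSING)
    if len(classes) == 1:
        return "MonoHighResolution"
    if 0 in classes and 2 in classes:
        return "PolyHighResolution"
    return "NoMinorHom"


def sim_intensities(
    genotypes: GenotypeMatrix,
    spec: ClusterSpec,
    seed: int,
    otv_fraction: float = 0.0,
    lowcr_fraction: float = 0.0,
    other_fraction: float = 0.0,
    otv_snps: list[str] | None = None,
    lowcr_snps: list[str] | None = None,
    other_snps: list[str] | None = None,
) -> IntensityPanel:
    """Emit per-(snp, sample) two-channel intensities.

    Noise is drawn from a per-sample substream keyed on the sample id, so two
    samples sharing an id (duplicates) receive byte-identical intensity rows.
    Failure roles may be given explicitly (``*_snps`` id lists) or sampled by
    fraction; fraction-sampled OTV / het-shift roles are restricted to SNPs
    with a heterozygote present so the designed category is attainable.
    ``other_*`` SNPs get their heterozygous cluster shifted down in size, a
    cluster-quality failure that lands in the ``Other`` category; low-CR
    SNPs get wider clusters plus an off-cluster sub-population.
    """
    n_s, n_v = genotypes.dosage.shape
    snp_ids = genotypes.variant_ids

    roles = np.array([""] * n_v, dtype=object)
    if otv_snps is not None or lowcr_snps is not None or other_snps is not None:
        idx_of = {m: j for j, m in enumerate(snp_ids)}
        for ids, role in ((otv_snps, "otv"), (lowcr_snps, "lowcr"), (other_snps, "hetso_shift")):
            for m in ids or ():
                roles[idx_of[m]] = role
    else:
        srng = rng_for(seed, 8)
        has_het = (genotypes.dosage == 1).sum(axis=0) >= 4
        order = srng.permutation(n_v)
        n_otv = int(round(otv_fraction * n_v))
        n_low = int(round(lowcr_fraction * n_v))
        n_other = int(round(other_fraction * n_v))
        het_pool = [j for j in order if has_het[j]]
        roles[het_pool[:n_otv]] = "otv"
        roles[het_pool[n_otv : n_otv + n_other]] = "hetso_shift"
        free = [j for j in order if roles[j] == ""]
        roles[free[:n_low]] = "lowcr"

    cx = np.asarray(spec.center_x)
    cy = np.asarray(spec.center_y)
    a = np.empty((n_s, n_v))
    b = np.empty((n_s, n_v))
    csig = np.empty((n_s, spec.n_control_probes))
    cnoi = np.empty((n_s, spec.n_control_probes))

    for i, sid in enumerate(genotypes.samples):
        rng = rng_for(seed, 9, zlib.crc32(sid.encode()))
        u_otv = rng.random(n_v)
        u_off = rng.random(n_v)
        x_off = rng.uniform(-1.8, 1.8, n_v)
        eps_x = rng.standard_normal(n_v)
        eps_y = rng.standard_normal(n_v)
        dos = genotypes.dosage[i].astype(int)
        safe = np.where(dos == MISSING, 1, dos)
        mu_x, mu_y = cx[safe], cy[safe].copy()
        sd_x = np.full(n_v, spec.sd_x)
        sd_y = np.full(n_v, spec.sd_y)

        is_otv = (roles == "otv") & (u_otv < spec.otv_sample_fraction)
        mu_x = np.where(is_otv, spec.otv_center[0], mu_x)
        mu_y = np.where(is_otv, spec.otv_center[1], mu_y)
        shift = (roles == "hetso_shift") & (safe == 1)
        mu_y = np.where(shift, mu_y - 0.6, mu_y)
        lown = (roles == "lowcr") | (dos == MISSING)
        sd_x = np.where(lown, sd_x * spec.lowcr_noise_factor, sd_x)
        sd_y = np.where(lown, sd_y * spec.lowcr_noise_factor, sd_y)

        x = mu_x + sd_x * eps_x
        y = mu_y + sd_y * eps_y
        off = lown & (u_off < spec.lowcr_uniform_fraction)
        x = np.where(off, x_off, x)
        a[i] = 2.0 ** (y + x / 2.0)
        b[i] = 2.0 ** (y - x / 2.0)
        mu_s, sd_s = spec.control_signal
        mu_n, sd_n = spec.control_noise
        csig[i] = mu_s + sd_s * rng.standard_normal(spec.n_control_probes)
        cnoi[i] = mu_n + sd_n * rng.standard_normal(spec.n_control_probes)

    designed = {
        snp: _designed_category(genotypes.dosage[:, j], roles[j])
        for j, snp in enumerate(snp_ids)
    }
    return IntensityPanel(
        snp_ids=snp_ids,
        sample_ids=list(genotypes.samples),
        a=a,
        b=b,
        control_signal=csig,
        control_noise=cnoi,
        designed_category=designed,
    )
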