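"""Simulation configuration and ground-truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("AW", "AC", "EW", "EC")  # AsianWild, AsianCult, EuroWild, EuroCult


@dataclass
class SimConfig:
    """Parameters of the synthetic study design.

    Defaults mirror a 17-chromosome outcrossing fruit-tree setting: four
    diverged germplasm groups, an F1 family of 98 progeny, unanchored
    scaffolds excised from known locations and a centromeric interval with
    suppressed recombination and reduced marker density.
    """

    seed: int = 0
    n_chromosomes: int = 17
    chrom_lengths_bp: list[int] | None = None
    n_scaffolds: int = 12
    scaffold_lengths_bp: list[int] | None = None
    gene_density_per_mb: float = 40.0
    group_sizes: tuple[int, int, int, int] = (32, 31, 25, 25)
    divergence_f: float = 0.1
    n_progeny: int = 98
    centromere_fraction: float = 0.15
    otv_snp_fraction: float = 0.0
    lowcr_snp_fraction: float = 0.0
    # marker layout / genetic-scale knobs
    snp_density_per_mb: float = 12.0
    centromere_snp_density_factor: float = 0.15
    cm_per_mb: float = 4.0
    centromere_cm_scale: float = 0.02
    missing_rate: float = 0.0
    seg_type_props: tuple[float, float, float] = (0.4, 0.4, 0.2)  # lmxll, nnxnp, hkxhk

    def __post_init__(self) -> None:
        if self.chrom_lengths_bp is None:
            self.chrom_lengths_bp = [5_000_000] * self.n_chromosomes
        if self.scaffold_lengths_bp is None:
            self.scaffold_lengths_bp = [300_000] * self.n_scaffolds
        self.validate()

    def validate(self) -> None:
        if len(self.chrom_lengths_bp) != self.n_chromosomes:
            raise ValueError("chrom_lengths_bp length must equal n_chromosomes")
        if len(self.scaffold_lengths_bp) != self.n_scaffolds:
            raise ValueError("scaffold_lengths_bp length must equal n_scaffolds")
        if any(l <= 0 for l in self.chrom_lengths_bp + self.scaffold_lengths_bp):
            raise ValueError("all sequence lengths must be > 0")
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("group sizes must be >= 2")
        if not (0.0 < self.divergence_f < 1.0):
            raise ValueError("divergence_f must lie strictly inside (0, 1)")
        if not (0.0 < self.centromere_fraction < 1.0):
            raise ValueError("centromere_fraction must lie strictly inside (0, 1)")
        for name in ("otv_snp_fraction", "lowcr_snp_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if abs(sum(self.seg_type_props) - 1.0) > 1e-9:
            raise ValueError("seg_type_props must sum to 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def scaffold_names(self) -> list[str]:
        return [f"scaffold{i + 1}" for i in range(self.n_scaffolds)]


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for downstream recovery tests.

    Attributes
    ----------
    scaffold_placements:
        One row per scaffold: ``scaffold``, ``chrom``, ``insert_bp`` (1-based
        position on the chromosome where the excised segment starts) and
        ``orientation`` (``+``/``-``).
    centromeres:
        Per chromosome ``start_bp``/``end_bp`` of the suppressed interval.
    genetic_map:
        Per marker: emitted sequence/position, true chromosome, true
        chromosome position and true cM.
    qtls / h2:
        Filled in by :func:`snparray.simdata.sim_phenotypes`.
    """

    scaffold_placements: pd.DataFrame
    centromeres: pd.DataFrame
    genetic_map: pd.DataFrame
    qtls: pd.DataFrame | None = None
    h2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scaffold_placements["scaffold"].duplicated().any():
            raise ValueError("every scaffold must have exactly one true placement")
        for chrom, sub in self.genetic_map.groupby("true_chrom", sort=False):
            s = sub.sort_values("true_pos")
            if not s["cm"].is_monotonic_increasing:
                raise ValueError(f"cM must be non-decreasing with bp on {chrom}")

    def centromere_interval(self, chrom: str) -> tuple[int, int]:
        row = self.centromeres.loc[self.centromeres["chrom"] == chrom].iloc[0]
        return int(row["start_bp"]), int(row["end_bp"])


def rng_for(seed: int, *streams: int) -> np.random.Generator:
    """Independent deterministic substream of the master seed."""
    return np.random.default_rng([int(seed)] + [int(s) for s in streams])
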