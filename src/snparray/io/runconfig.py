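"""Unified run configuration with strict key validation.

Stage defaults carry the pipeline's anchored constants: MAF 0.1, missing
0.10, LD r2 0.4, 200 bp spacing, 2 kb promoters, 150 kb windows, LOD 4.0,
chi-square alpha 0.01, 10 missing genotypes, 95/97% call rates, FLD 3.6,
HetSO -0.1, HomRO 0.3, a 1/n association threshold and 50 kb gene flanks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..assoc_stats import CandidateScanParams
from ..genome_integration import ScanParams
from ..genotype_qc import QcThresholds
from ..panel_design import PanelDesignParams
from ..simdata import SimConfig


@dataclass
class MapParams:
    lod_min: float = 4.0
    seg_alpha: float = 0.01
    max_missing: int = 10
    mendel_tol: float = 0.02


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "snparray_out"
    sim: SimConfig = field(default_factory=SimConfig)
    panel: PanelDesignParams = field(default_factory=PanelDesignParams)
    qc: QcThresholds = field(default_factory=QcThresholds)
    map: MapParams = field(default_factory=MapParams)
    scan: ScanParams = field(default_factory=ScanParams)
    candidate: CandidateScanParams = field(default_factory=CandidateScanParams)
    n_pcs: int = 3

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


_SECTIONS = {
    "sim": SimConfig,
    "panel": PanelDesignParams,
    "qc": QcThresholds,
    "map": MapParams,
    "scan": ScanParams,
    "candidate": CandidateScanParams,
}
_SCALARS = {"seed", "log_level", "out_dir", "n_pcs"}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("run configuration must be a mapping")
    cfg = RunConfig()
    for key, value in doc.items():
        if key in _SCALARS:
            setattr(cfg, key, value)
        elif key in _SECTIONS:
            cls = _SECTIONS[key]
            known = set(cls.__dataclass_fields__)
            unknown = set(value) - known
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            setattr(cfg, key, cls(**value))
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return cfg
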