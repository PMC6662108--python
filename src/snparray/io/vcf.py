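"""VCF v4.2 reading/writing for diploid GT dosage matrices."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ..core import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def read_vcf(path: str | Path, multiallelic: str = "skip") -> GenotypeMatrix:
    """Read a VCF (plain or bgzipped) into a GenotypeMatrix.

    Dosage is the alternate-allele count of the GT field; ``./.`` becomes
    missing.  Multi-allelic records are skipped (logged) or split into
    per-alt records depending on ``multiallelic`` ('skip' or 'split').
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        alleles = rec.ALT
        if len(alleles) != 1:
            if multiallelic == "skip":
                log.warning("skipping multi-allelic record %s:%d", rec.CHROM, rec.POS)
                continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        for ai, alt in enumerate(alleles, start=1):
            dos = (gts == ai).sum(axis=1).astype(np.int8)
            dos[(gts < 0).any(axis=1)] = MISSING
            vid = rec.ID if rec.ID and len(alleles) == 1 else f"{rec.CHROM}_{rec.POS}_{alt}"
            ids.append(vid or f"{rec.CHROM}_{rec.POS}")
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(alt)
            rows.append(dos)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="variant"),
    )
    dosage = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, variants, dosage)


_GT_OF = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Deterministic plain-text VCF writer (records ordered chrom, pos)."""
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for chrom in sorted(set(g.variants["chrom"])):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j in order:
            v = g.variants.iloc[j]
            gts = "\t".join(_GT_OF[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{g.variants.index[j]}\t"
                f"{v['ref']}\t{v['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )
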