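# snparray

A toolkit for the computational workflow around large SNP genotyping arrays
in outcrossing plants:

- **`snparray.simdata`** — synthetic genomes (chromosomes + excised
  scaffolds with known placement), four diverged germplasm groups
  (Balding–Nichols), outcrossed F1 families with centromeric recombination
  suppression, two-channel probe intensities (including off-target-variant
  and low-call-rate SNPs, plus control probes), and replicated phenotypes
  with planted QTLs. Every output comes with a ground-truth container so
  downstream stages can be tested by recovery.
- **`snparray.panel_design`** — per-group MAF/missingness filtering,
  windowed LD pruning, four-group merging with Venn accounting, functional
  site annotation (synonymous / nonsynonymous / stop / intron / promoter /
  intergenic), minimum-spacing thinning with priority tiers, and inter-SNP
  spacing summaries.
- **`snparray.genotype_qc`** — contrast/size cluster space, DQC from
  control probes, a deterministic Gaussian-mixture genotype caller, per-SNP
  metrics (CR, FLD, HetSO, HomRO, MAF) and the six-way conversion
  classification (PolyHighResolution, NoMinorHom, OTV, MonoHighResolution,
  CallRateBelowThreshold, Other), plus duplicate-sample concordance.
- **`snparray.linkage_map`** — CP (outcrossed full-sib) marker coding
  (lm×ll / nn×np / hk×hk), segregation chi-square filtering, two-point
  recombination estimation with phase maximisation, distortion-robust
  LOD grouping, marker ordering by spectral seriation with SARF polishing,
  Kosambi map distances, per-group map statistics and map-vs-assembly order
  consistency.
- **`snparray.genome_integration`** — centromere prediction from marker
  density valleys and Marey-curve recombination valleys with consensus
  calls, scaffold anchoring through mapped scaffold-borne SNPs, and
  anchored-fraction accounting (AGP v2.1 / BED output).
- **`snparray.assoc_stats`** — VanRaden kinship, genotype PCA, broad-sense
  heritability (plot and family-mean basis), a single-rotation REML mixed
  linear model for association with a 1/n significance threshold, flanking
  candidate-gene scans and trait correlations.
- **`snparray.io` / `snparray.cli`** — VCF/GFF3/AGP/BED/TSV/YAML readers
  and writers and the `snparray` command-line interface.

## CLI

```bash
snparray simulate --seed 7 --out sim/           # synthetic dataset + truth
snparray design-panel --vcf AW=sim/group_AW.vcf --vcf AC=sim/group_AC.vcf \
    --vcf EW=sim/group_EW.vcf --vcf EC=sim/group_EC.vcf --out panel/
snparray qc --intensities intensities.tsv --out qc/
snparray map --vcf f1.vcf --p1 P1 --p2 P2 --lod 4.0 --out map/
snparray centromere --map map/genetic_map.tsv --vcf f1.vcf \
    --layout sim/layout.tsv --out centromeres.bed
snparray anchor --map map/genetic_map.tsv --vcf f1.vcf \
    --layout sim/layout.tsv --p1 P1 --p2 P2 --out anchor/
snparray gwas --vcf panel.vcf --pheno phenotypes.csv --trait T1 --pcs 3 --out gwas/
snparray report --seed 7 --out report/          # end-to-end on simulated data
```

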