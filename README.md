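# orchard-gblup

Pedigree BLUP vs genomic GBLUP evaluation pipeline for open-pollinated (OP)
seed-orchard progeny trials, with a fully synthetic test bed.

The package implements the complete analysis chain for a two-orchard OP tree
breeding trial:

- **`simulate`** — coalescent founder haplotypes per orchard (effective size
  set by founder culling, LD decay controlled by a physical recombination
  rate), OP families with unknown sires in the documented pedigree, QTL-based
  true breeding values, and trial phenotypes with replicate and
  set-within-replicate effects. Single master seed, named substreams,
  bit-identical replays.
- **`pedigree`** — numerator relationship matrix **A** (tabular method),
  inbreeding coefficients, group coancestry and status-number effective size
  `N_S = 1 / (2 θ)`.
- **`genomics`** — five-rule marker QC (two platform quality scores, MAF,
  call rate, windowed LD pruning at composite r² ≥ 0.9), EM imputation of
  missing dosages, the trace-scaled genomic relationship matrix
  `G = ZZ' / (tr[ZZ'] / n)` (mean diagonal exactly 1), composite-r² LD decay
  curves, and spectral decomposition of a kernel.
- **`mixed_model`** — AI-REML (with EM fallback and boundary handling) for the
  trial model `y = Xβ + Z₁u + Z₂r + Z₃r(s) + e` under an arbitrary kernel
  (A or G — the kernel is the *only* difference between BLUP and GBLUP),
  mixed-model-equation breeding values with PEV, narrow-sense heritability
  `h² = σ²ₐ / (σ²ₐ + σ²ₑ)` with delta-method SE, and theoretical accuracy
  `r = √(1 − PEV / (K_ii σ²ₐ))`.
- **`evaluation`** — k-fold × replicated cross-validation within, between and
  across orchards (predictive accuracy = correlation of cross-validated
  predictions with full-data pedigree EBVs), and top-20% genetic gain
  comparison between BLUP and GBLUP.
- **`io` / `cli`** — CSV/TSV and PLINK-RAW dialect readers/writers, YAML run
  configuration, provenance headers (config hash + seed) and a JSON manifest.

## Command line

```bash
orchard-gblup simulate --config sim.yaml --out data/ --seed 1
orchard-gblup filter --genotypes data/genotypes.tsv --markers data/markers.tsv \
    --maf 0.01 --call-rate 0.6 --out data/filtered.tsv
orchard-gblup impute --genotypes data/filtered.tsv --out data/complete.tsv
orchard-gblup amat  --pedigree data/pedigree.csv --out A.tsv
orchard-gblup grm   --genotypes data/complete.tsv --out G.tsv
orchard-gblup ne    --matrix A.tsv --ids founders.txt
orchard-gblup fit   --phenotypes data/phenotypes.csv --kernel G.tsv --kind G \
    --trait trait --out fitG
orchard-gblup cv    --phenotypes data/phenotypes.csv --kernel G.tsv \
    --reference-kernel A.tsv --scenario W-T --model GBLUP --trait trait --out cv.tsv
orchard-gblup gain  --bvs fitA.bvs.tsv fitG.bvs.tsv --proportion 0.2
orchard-gblup lddecay --genotypes data/complete.tsv --markers data/markers.tsv --out ld.tsv
orchard-gblup pca   --kernel G.tsv --out pca.tsv
orchard-gblup run   --config pipeline.yaml   # full pipeline + manifest
```

A pipeline config (`orchard-gblup run`) needs either a `simulation:` block or
paths to the three input tables, e.g.

```yaml
out_dir: results/run1
seed: 1
simulation:
  n_founders_per_orchard: [60, 40]
  n_families: [45, 25]
  offspring_per_family: [1, 24, 9.6]
  n_markers: 2000
  h2_target: 0.3
cv_scenarios: [W-W, T-T, W-T, T-W, WT-WT]
n_folds: 10
n_replications: 30
```

The pipeline writes heritability/accuracy, genetic-gain and cross-validation
tables (TSV), both kernels, a filter report, PCA scores, the LD decay curve
and a manifest recording the config hash, seed and package versions.

## File dialects

- Pedigree CSV: `id,sire,dam`, `0` = unknown parent.
- Genotypes: TSV with individuals in rows (first column `id`), marker ids in
  the header, dosages 0/1/2, `NA` missing; or PLINK-RAW
  (`FID IID PAT MAT SEX PHENOTYPE` + dosage columns). Marker metadata TSV:
  `marker, chrom, pos, qa, qb`.
- Phenotypes CSV (long): `id, trait, value, seed_source, replicate, set, orchard`.
- Kernels: labelled dense TSV, plus a long `(i, j, value)` exchange format.
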