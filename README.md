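# polycore

Curation analytics for polyploid SNP-dosage genebank panels: quality
filtering of 0–4 dosage genotype matrices, ploidy inference from
simplex/triplex call frequencies, dosage-based diversity statistics
(observed heterozygosity, Modified Rogers distances, Nei-style FST,
distance-based AMOVA with permutation testing), PCA-based group assignment,
genetic-distance-optimized core/mini-core collection selection, and
phenotypic validation with Gower distances.

## Layout

| module | purpose |
| --- | --- |
| `polycore.geno_io` | dosage matrix I/O (TSV/VCF), metadata and phenotype tables, MAF/missingness filtering |
| `polycore.ploidy` | simplex/triplex frequency classifier, threshold calibration, reference-panel concordance, replicate checks |
| `polycore.diversity` | Ho, Modified Rogers distance, pairwise FST, AMOVA with permutation p-values |
| `polycore.structure` | PCA, K selection by clustering indices, k-means labels |
| `polycore.core_select` | core sizing, A-NE/E-NE/E-E objectives, multi-start swap optimizer, mini-core nesting |
| `polycore.pheno_validate` | Gower distances, core evaluation on phenotypes, summary statistics |
| `polycore.synthetic_data` | seeded mixed-ploidy panel simulator with ground truth |
| `polycore.pipeline` / `polycore.cli` | full-run orchestration from a YAML config; `polycore` CLI |

## CLI

Every stage is a subcommand; `run` executes the whole pipeline:

```sh
polycore simulate --seed 17 --out-prefix sim/
polycore filter --in sim/matrix.tsv --out filtered.tsv --report filter.json
polycore ploidy --in filtered.tsv --meta sim/metadata.csv --out ploidy.tsv
polycore structure --in filtered.tsv --kmin 2 --kmax 10 --seed 17 --out-dir out/
polycore diversity --in filtered.tsv --groups out/groups.tsv --out-dir out/
polycore core --dist out/mrd.tsv --fraction 0.10 --seed 17 --out core.json
polycore pheno --pheno sim/phenotypes.csv --cores out/cores.json --out-dir out/
polycore run --config pipeline.yaml
```

A pipeline config is flat YAML; unknown keys are rejected:

```yaml
schema_version: 1
seed: 17
dosage_tsv: sim/matrix.tsv
metadata_csv: sim/metadata.csv
phenotype_csv: sim/phenotypes.csv
output_dir: out
core_fractions: [0.03, 0.10, 0.15, 0.20]
```

## Conventions

- Matrices are samples × markers; calls are integers 0–4, `NA` (TSV) or
  `.` alleles (VCF) for missing, stored internally as -1.
- All calls are on the tetraploid dosage scale regardless of true ploidy;
  diploids therefore show calls in {0, 2, 4} and near-zero simplex/triplex
  frequency.
- Every stochastic routine takes an explicit seed; the pipeline derives
  per-stage seeds from one global seed.
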