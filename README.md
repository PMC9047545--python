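# tmijoint

Joint quantification of the tumor microenvironment from bulk RNA-seq:
tissue-infiltrating **immune-cell fractions** by support vector regression
deconvolution with particle-swarm hyperparameter tuning, and
**infiltrating-microbe abundance** from host-unmapped ("foreign") reads via an
EM read-assignment mixture model — plus the downstream rank-based differential
abundance analysis and elastic-net tumor/normal classification over the joint
feature set.

## What's inside

| Module | Purpose |
| --- | --- |
| `tmijoint.seqio_reads` | SAM-flag extraction of unmapped reads, QC filters (length/N/quality), reverse-complement mate synthesis, FASTQ/FASTA I/O |
| `tmijoint.microbial_abundance` | EM mixture estimation of genome relative abundance from ambiguous mappings; Shannon diversity |
| `tmijoint.deconv_svr` | ε-SVR (linear kernel) deconvolution X = S·f; coefficient→fraction post-processing |
| `tmijoint.pso_opt` | particle swarm over (ε, C, φ) with linear inertia decay; gene-holdout RMSE fitness |
| `tmijoint.stats_diff` | Mann-Whitney U (exact enumeration / tie-corrected normal), BH-FDR, differential tables, RMSE/Pearson/Spearman |
| `tmijoint.joint_classifier` | elastic-net logistic regression (monotone proximal gradient), three-case 75/25 evaluation |
| `tmijoint.synth_fixtures` | seeded generators: signatures, mixtures, toy genomes with ambiguous reads, paired cohorts with planted effects |
| `tmijoint.cli_config` | `tmijoint` CLI, YAML config, pipeline driver with reproducibility manifest |

## CLI

```bash
# full pipeline on synthetic fixtures (writes manifest.json with checksums)
tmijoint run --seed 17 --out-dir out/

# individual stages
tmijoint extract-reads --bam aln.sam --out-prefix foreign
tmijoint qc --fastq foreign.paired.fastq --out clean.fastq --min-len 36 --max-n 5 --phred 15 --max-low-frac 0.4
tmijoint abundance --cands candidates.tsv --lengths genomes.tsv --out abundance.tsv
tmijoint deconv --mixture X.tsv --signature S.tsv --params auto --out F.tsv
tmijoint tune --mixture X.tsv --signature S.tsv --particles 30 --iters 100 --seed 7 --out params.json
tmijoint diff --a normal.tsv --b tumor.tsv --alpha 0.05 --out diff.tsv
tmijoint classify --bacteria B.tsv --cells F.tsv --labels y.tsv --repeats 50 --seed 1 --out report.json
tmijoint simulate mixtures --seed 2 --out-dir sim/
```

Matrices are TSV with a header row of column ids and a first column of row
ids. Exit code 2 signals a validation error.

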