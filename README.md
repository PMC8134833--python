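# bloodbrain

Cross-tissue DNA-methylation episcore pipeline: projects blood-derived CpG
predictor weight tables (smoking, HDL cholesterol, BMI, alcohol) onto
methylation beta matrices from matched blood and post-mortem brain regions
(BA17, BA20/21, BA24, BA35, BA46), with array-level quality control,
lifestyle-phenotype derivation (pack years, status codes) and the full set
of blood–brain / score–trait correlation analyses. A synthetic-cohort
generator with known ground truth makes the whole chain testable without
access to restricted cohort data.

## Modules

| module | what it does |
|---|---|
| `bloodbrain.io` | TSV readers/writers for beta matrices (+ detection-p / beadcount side-matrices), weight tables, sample sheets; strict validation, `NA`/empty = missing |
| `bloodbrain.qc` | brain-style QC (failing samples → beadcount probes → detection-p probes), blood-style QC (low-detection probes → low-call-rate samples, threshold rescaled for fixture-sized matrices), 2-means sex check, probe blacklists |
| `bloodbrain.episcore` | probe-set harmonization across platforms, weighted score projection (`score = intercept + Σ wⱼ·βⱼ`, terms dropped — never rescaled — with per-sample coverage), single-CpG extraction (cg05575921) |
| `bloodbrain.phenotypes` | smoking status coding, pack-years derivation (cigarettes/day × years ÷ 20, never-smokers = 0, group-mean start-age imputation), cohort summary |
| `bloodbrain.concordance` | Pearson/Spearman correlations with pairwise-complete deletion, t-based two-sided p (df = n−2), Fisher-z CIs, blood-vs-region and inter-region matrices, Pearson/Spearman sensitivity comparison, Monte-Carlo power calculator |
| `bloodbrain.simulate` | latent-factor cohort generator (M-value scale, beta output), weight fixtures, plantable QC failures, ground truth |
| `bloodbrain.cli` | `bloodbrain` command with `simulate`, `qc`, `score`, `phenos`, `correlate`, `run`, `report` subcommands |

## CLI

End-to-end on a synthetic cohort (deterministic given the seed):

```bash
bloodbrain run --simulate --seed 1 --out report/
```

writes `qc_report.tsv`, `score_table.tsv`, `phenotype_table.tsv`,
`correlation_report.tsv`, `interregion_matrix.tsv` (plus sensitivity
table, sample sheet and run log). Re-running with the same seed produces a
byte-identical correlation report.

Individual stages:

```bash
bloodbrain simulate --seed 2 --out sim/          # cohort + ground_truth.yaml
bloodbrain qc --beta sim/beta_BA46.tsv --detp sim/detp_BA46.tsv \
              --beadcount sim/beadcount_BA46.tsv --out qc/
bloodbrain score --weights sim/weights_smoking.tsv --trait smoking \
                 --beta sim/beta_blood.tsv --out scores.tsv
```

Real data are configured through a YAML file (see `inputs:` handling in
`bloodbrain/cli.py`): per-tissue beta/detection-p/beadcount paths, a
sample sheet, a phenotype table and one weight table per trait;
`bloodbrain run --config cfg.yaml --out report/`.

## Conventions

- Tab-separated canonical format; one `#`-prefixed provenance header line
  per output file.
- Betas live in [0, 1]; values outside are hard errors naming the cell.
- Missing values are empty cells or `NA` and are never coerced to 0.
- All QC inequalities are strict, exactly as the thresholds are stated
  (>1%, <3, >5%, <95%, <450 000).
- No multiple-testing adjustment; reports carry the number of tests.
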