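# mrpipe

Two-sample Mendelian randomisation (MR) and two-step mediation analysis on
GWAS summary statistics, with a synthetic-data generator so that every stage
is verifiable at desk scale against known ground truth.

## What it does

- **`sumstats_io`** — read/write/validate a 10-column tab-separated
  summary-statistics dialect (`snp_id, chrom, pos, effect_allele,
  other_allele, eaf, beta, se, pval, n`) and harmonise exposure/outcome
  panels to a shared effect-allele orientation (sign flips for swapped
  alleles, strand-complement resolution, frequency-based rescue or drop of
  palindromic SNPs).
- **`synthetic_gwas`** — generate exposure/mediator/binary-outcome panel
  triplets with configurable causal effects, horizontal pleiotropy,
  block-constant LD, allele-coding noise and per-trait sample sizes;
  deterministic given a seed, with the full generative truth recorded.
- **`iv_selection`** — instrument selection: genome-wide significance
  threshold (5e-8) with a fallback (5e-5) when fewer than 5 SNPs survive,
  greedy LD clumping, outcome-association filter (p > 0.05), per-SNP
  F statistic (keep F > 10) and variance explained, Steiger directionality
  filter, and iterated MR-PRESSO outlier pruning — with a complete per-SNP
  audit trail.  Named profiles: `default` (500 kb / r² 0.01), `bloodcell`
  (10,000 kb / r² 0.001), `reverse_mr` (p < 1e-8, 10,000 kb, r² 0.001).
- **`mr_estimators`** — Wald ratio, fixed/multiplicative-random-effects IVW,
  MR-Egger (slope + intercept pleiotropy test), Cochran's Q, whole-set
  Steiger directionality test.  All confidence intervals are log-symmetric:
  OR = geometric mean of the OR CI bounds.
- **`mr_presso`** — MR-PRESSO global RSS test, Bonferroni-adjusted per-SNP
  outlier test and distortion test via parametric resampling, deterministic
  given a seed.
- **`mvmr`** — multivariable IVW (weighted least squares, no intercept) over
  the union of per-exposure instruments, jointly re-clumped and re-oriented;
  supplies the exposure-adjusted mediator effect.
- **`mediation`** — two-step MR decomposition: indirect = β(A)·β(B),
  direct = total − indirect, mediated proportion = indirect/total, with
  first-order delta (Sobel) intervals and a complete/partial/none/
  inconsistent classification; plus a many-pairs mediation scan.
- **`pipeline_cli`** — forward and reverse screening across trait panels,
  Benjamini–Hochberg FDR (significant when q < 0.1), Risk/Protect
  classification, strict YAML-config-driven runs and a `mrpipe` CLI.

## CLI

```bash
mrpipe simulate --out-dir demo --n-snps 30 --theta-direct 0.1 --alpha 0.5 \
    --b-med 0.2 --seed 1
mrpipe select-iv --exposure demo/exposure.tsv --outcome demo/outcome.tsv \
    --ld demo/ld.tsv --out-prefix demo/iv
mrpipe mr --exposure demo/exposure.tsv --outcome demo/outcome.tsv
mrpipe presso --exposure demo/exposure.tsv --outcome demo/outcome.tsv
mrpipe mvmr --exposure demo/exposure.tsv --exposure demo/mediator.tsv \
    --outcome demo/outcome.tsv
mrpipe mediate --total-beta -0.382 --total-se 0.1 --a-beta -0.031 \
    --a-se 0.02 --b-beta 1.0 --b-se 1e-4
mrpipe screen --exposure demo/exposure.tsv --outcome demo/outcome.tsv \
    --ld demo/ld.tsv --out screen.tsv
mrpipe run config.yaml
```

A config for `mrpipe run` looks like:

```yaml
run_dir: demo_run
seed: 5
simulate:
  n_exposures: 3
  n_mediators: 2
  n_snps: 30
  n_samples: 50000
  theta_direct: 0.1
  alpha: 0.5
  b_med: 0.2
  exposure_effect_sd: 0.15
  med_effect_sd: 0.1
screen:
  profile: default
  fdr_threshold: 0.1
  presso: true
  presso_n_sim: 2000
reverse_screen:
  enabled: true
mediation:
  alpha: 0.1
  gate_alpha: 0.05
```

Unknown config keys are rejected (strict mode).  Each run writes the
simulated panels, `screen.tsv`, `reverse_screen.tsv`, `mediation.tsv`,
a log file and a machine-readable `run_summary.json`.

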