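# pairprog

Paired primary-tumor / adjacent-tissue (PT/AT) prognostic-signature pipeline
for censored survival cohorts:

- **Survival-optimal dichotomization** (`pairprog.ddg`) — per gene, scan all
  admissible expression cutoffs, test each split with a proportional-hazards
  Wald test (Efron ties; log-rank variant behind a flag), keep the minimum-p
  cutoff and its risk design (design 1: high expression → low risk; design 2:
  high expression → high risk). A permutation adjustment
  (`permutation_adjust`) corrects the well-known anti-conservativeness of
  minimum-p cutoff selection.
- **Common prognostic genes** (`pairprog.cpg_agreement`) — genes significant
  in both tissues of the same patients with identical design, plus the
  agreement statistics used to report them: continuity-corrected Wilson
  score intervals (`wilson_cc_ci`), Newcombe hybrid difference-of-proportions
  intervals, hypergeometric overlap tests.
- **Weighted-voting classifier** (`pairprog.swvg`) — binary per-gene risk
  votes weighted by `-log10(training p)`, normalized score in [0, 1], panel
  size and score cutoff selected on pooled out-of-fold scores (5-fold CV;
  the literal in-sample scan is available via `selection="insample"`).
  Models freeze to JSON (bit-exact round trip) and apply to new cohorts
  blinded to survival. `combine_pt_at` forms the conjunction stratification
  (low-risk only if low-risk in both tissues).
- **Survival statistics** (`pairprog.survival_stats`) — Kaplan–Meier curves,
  two-group Wald/log-rank tests, multivariate Cox (lifelines), Fisher exact
  (2×2 and Freeman–Halton r×c), Mann–Whitney.
- **Differential expression & co-expression** (`pairprog.deg_corr`) — Welch
  t tests with Benjamini–Hochberg q-values, Kendall-tau correlation profiles
  against size-matched random control sets, and a survival-blind
  co-expression module filter (`coexpression_module`).
- **Synthetic paired cohorts** (`pairprog.synthetic_data`) — seeded generator
  with a latent binary risk class driving a co-expressed signal block in
  both tissues (attenuated in AT), exponential survival with administrative
  censoring and dropout, and a ground-truth record for recovery tests.

A fast vectorized one-parameter Cox solver (`pairprog._cox`) backs all
cutoff scans; it is verified against lifelines and an independent
brute-force oracle in the test suite.

## CLI

All stages are exposed under a single entry point:

```sh
pairprog simulate --seed 7 --out-dir cohort/           # synthetic paired cohort
pairprog ddg --expr cohort/expression_pt.tsv --clin cohort/clinical.tsv \
         --tissue PT --out ddg_pt.tsv                  # per-gene cutoff scan
pairprog cpg --pt-expr ... --at-expr ... --clin ... --out cpg.tsv
pairprog swvg fit   --expr ... --clin ... --out model.json
pairprog swvg apply --model model.json --expr ... [--clin ...] --out strat.tsv
pairprog swvg combine --pt strat_pt.tsv --at strat_at.tsv --out combined.tsv
pairprog deg  --expr ... --groups groups.tsv --out deg.tsv
pairprog corr --expr ... --target MYC --set genes.txt --out taus.tsv
pairprog stats --clin clinical.tsv --terms age,grade --out cox.tsv
pairprog run --config config.json --out-dir results/   # full pipeline + manifest
```

`pairprog run` takes a JSON/YAML config naming the expression and clinical
files (plus optional validation cohort and panel restriction), executes
cutoff scans → cross-tissue gene selection → module filter → classifier fit
→ frozen application/combination → HR-vs-LR differential expression, and
writes every stage table, the frozen model, and a manifest with input
checksums, seed, and timings.

File formats: expression is tab-separated (rows = genes, first column
`gene_id`, columns = samples); clinical tables need
`sample_id, patient_id, tissue (PT/AT), os_years, event` with extra columns
kept as covariates. A 24-gene ribosomal panel (gene symbols + array probe
ids) ships as a package resource (`pairprog.load_ribosomal_panel()`).

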