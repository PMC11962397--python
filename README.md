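# tcatrace

Analysis of intraoperative [U-¹³C]glucose tracing in lung lesions: from
raw GC-MS mass-isotopologue intensities to survival stratification.

Patients infused with [U-¹³C]glucose during tumor resection yield tissue
fragments whose metabolite labeling reports local metabolism: pyruvate
oxidation via pyruvate dehydrogenase puts M+2 into TCA-cycle
intermediates, pyruvate carboxylase puts in M+3, and multiple turns of
the cycle generate M+1. `tcatrace` is for researchers running or
reanalyzing such tracing studies. It provides:

- **`isocorrect`** — natural-abundance correction of TBDMS-fragment
  GC-MS isotopologue envelopes (correction matrix + nonnegative least
  squares), and MID algebra (convolution, labeled fraction).
- **`metrics`** — the per-sample labeling scores: total TCA score
  `[(1 − M+0)_cit + (1 − M+0)_glu + (1 − M+0)_mal] / glucose M+6`, the
  mean M+2/M+6 score, the PC index (M+3 / pyruvate M+3), lesion/lung
  enrichment ratios, and median dichotomization into high/low groups.
- **`cohort_stats`** — Kaplan–Meier, log-rank (Mantel–Cox) and univariate
  Cox (Breslow ties) via lifelines; Wilcoxon signed-rank with exact
  small-sample p; Holm–Šidák and Benjamini–Hochberg control; Spearman
  correlation matrices; Kruskal–Wallis + Dunn; an automatic
  parametric/nonparametric test selector; a metabolite-abundance survival
  screen.
- **`tca_sim`** — a carbon-resolved positional-isotopomer simulator of
  TCA-cycle labeling (PDH entry, PC anaplerosis, unlabeled dilution,
  succinate symmetry), validated against a single-molecule Monte-Carlo
  tracker, plus generators for full synthetic cohorts with
  labeling-linked survival and annotated single-cell expression data.
- **`expression_scores`** — per-cell gene-set mean scores and per-sample
  score heterogeneity (relative SD).
- **`pipeline_io`** + a `tcatrace` CLI — delimited-table schemas, YAML
  study configs, and end-to-end orchestration.

## Worked example

Simulate a 66-patient tracing study with a built-in between-group hazard
ratio of 4, then run the full analysis:

```sh
cat > study.yaml <<EOF
out_dir: demo_out
seed: 11
metric: tca_total_score
simulation:
  n_patients: 66
  group_hr: 4.0
EOF
tcatrace run --config study.yaml
```

prints (abridged):

```json
{
  "seed": 11,
  "metric": "tca_total_score",
  "n_patients": 66,
  "endpoints": {
    "os":  {"n_high": 33, "n_low": 33, "n_events": 29,
            "logrank_chi2": 11.20, "logrank_p": 0.00082,
            "hazard_ratio": 3.57, "hr_ci95": [1.61, 7.88]},
    "rfs": {"n_high": 33, "n_low": 33, "n_events": 37,
            "logrank_chi2": 12.09, "logrank_p": 0.00051,
            "hazard_ratio": 3.18, "hr_ci95": [1.60, 6.28]}
  }
}
```

Reading: the cohort was split at the median total TCA score into 33
high- and 33 low-labeling patients; with 29 observed deaths the
high-labeling group's overall-survival hazard is 3.6× the low group's
(95% CI 1.6–7.9, log-rank p ≈ 8 × 10⁻⁴), and recurrence-free survival
shows the same pattern — the generative effect (HR 4) is recovered with
the expected within-group attenuation. `demo_out/` contains the
isotopologue and clinical tables, fragment- and patient-level score
tables, group assignments, KM curves, and `summary.json` (stamped with
seed, config hash and version; reruns are bit-identical).

Other subcommands: `tcatrace simulate` (write a synthetic study),
`correct` (raw intensities → corrected MIDs), `score` (metrics table),
`survive` (stratified survival from existing tables), `scores-sc`
(single-cell gene-set scoring).

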