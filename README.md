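# hervscape

Biomarker analysis stack for bulk tumour sequencing cohorts, centred on
human endogenous retrovirus (hERV) expression in stage II/III colorectal
cancer. hERVs are transcriptionally reactivatable retroviral sequences
fixed in the genome; their aggregate expression, combined with CD8+
tumour-infiltrating lymphocyte levels, stratifies patient survival. The
package implements the full downstream stack from counts/calls to
survival curves, together with a synthetic cohort generator so every
stage is testable without patient-level data.

## What it computes

- **median.hERV** — per-sample median CPM over a curated hERV transcript
  panel, after a 0.5-CPM noise floor and removal of panel transcripts
  with tumour-median CPM < 0.1; plus hierarchical two-cluster hERV
  subtyping, top-30% dichotomisation and an 80%/100-round panel
  downsampling robustness study.
- **Absolute immune-cell deconvolution** — marker selection against
  explicit background tissues, common-scale signature normalisation, and
  linear-kernel ν-SVR (ν ∈ {0.25, 0.5, 0.75}) returning absolute RNA
  fractions for CD4/CD8/CD19 without sum-to-one renormalisation, with a
  titration-linearity validation harness.
- **MSI score** — per-site read-length-distribution shift calls against a
  paired normal or pooled baseline (mean ± 3 sd "known range"); MSI
  score = unstable/assessed sites; MSI-H at ≥ 0.30 (paired WES) or
  ≥ 0.20 (baseline panel); also the 5-marker PCR ≥ 2-of-5 rule.
- **Genomic features** — six-rule somatic variant filter (VAF_T ≥ 0.05,
  DP_T ≥ 50, DP_N ≥ 20, AD_T ≥ 5, VAF_N/VAF_T < 0.2, both strands), TMB
  per Mb, arm-level copy-number events (> 20% of genes altered), CIN
  tertiles, the MATH heterogeneity score
  `100 · 1.4826 · MAD(VAF) / median(VAF)`, an NCCN-style Lynch-syndrome
  rule with a BRAF-V600E sporadic override, and PPA/NPA concordance with
  exact Clopper–Pearson 95% intervals.
- **Survival stratification** — OS (endpoint − diagnosis) and RFS
  (endpoint − surgery) in months (30.4375 days), the CD8−/hERV+ = WTS−
  subgroup, the clinicopathological CP± split, Kaplan–Meier/log-rank and
  uni/multivariate Cox models (Efron ties), and categorical enrichment
  tests.

## Worked example

```python
from hervscape.synthetic import SimConfig, simulate_bundle, write_bundle
from hervscape.pipeline import RunConfig, run_pipeline

bundle = simulate_bundle(SimConfig(seed=7, n_samples=60))
write_bundle(bundle, "demo_bundle")
run_pipeline(RunConfig(input_dir="demo_bundle", out_dir="demo_out", seed=7))
```

`demo_out/herv_scores.csv` then starts

```
sample_id  median_herv  herv_label  cluster_label
S001       1.87809      low         low
S002       6.32017      low         high
S003       2.32121      low         low
```

(160 of the 200 reference hERVs survive the expression filter — the
other 40 are simulated as silent), `demo_out/msi_results.csv` starts

```
sample_id  n_assessed  n_unstable  msi_score  classification  mode
S001       200         102         0.510      MSI-H           paired_wes
S002       200         3           0.015      MSS             paired_wes
```

and the OS section of `demo_out/survival_report.json` reports the WTS
stratification: 8 WTS− patients with median OS 10.0 months against 52
WTS+ patients with median OS 28.5 months, log-rank χ² = 29.7,
p = 4.9 × 10⁻⁸ — the planted poor-prognosis subgroup (hazard ratio 4.4
in the generator) is recovered.

The same stages are exposed on the command line:

```sh
hervscape simulate --seed 7 --n-samples 60 --out demo_bundle
hervscape run --input-dir demo_bundle --out-dir demo_out --seed 7
hervscape herv --counts demo_bundle/counts.tsv \
    --library-sizes demo_bundle/library_sizes.tsv \
    --panel demo_bundle/herv_panel.txt --out scores.csv
```

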