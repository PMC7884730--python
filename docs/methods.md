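# Methods

This note documents the models, defaults and numerical choices behind
each module, what the synthetic generator does and does not emulate, and
the design decisions taken where the published procedure leaves details
open.

## hERV quantification

Processing order is fixed and order-sensitive: raw counts → CPM
(`1e6 · count / library size`) → noise floor (CPM < 0.5 set to zero,
strict inequality, so 0.5 itself is kept) → expression filter (panel
transcripts with median CPM < 0.1 across tumour samples removed; the
filtering median is computed on *floored* values, matching the stated
order of operations — the alternative, filtering on raw CPM, keeps
transcripts that hover just below the noise floor, and a regression test
pins the difference) → per-sample median over the retained panel
(**median.hERV**). Even panel sizes use the midpoint-average median;
this convention is load-bearing because the statistic is itself a
median.

Two-cluster subtyping uses Ward linkage on Euclidean distance over
per-transcript z-scored log2(CPM + 1) profiles, cut at k = 2; the
cluster with the larger median of median.hERV is labelled *high*. Ward
on z-scores is the standard choice for heatmap-style two-group structure
and is deterministic. Constant-profile inputs are rejected rather than
silently assigned.

Top-fraction dichotomisation (default 30%) thresholds at the
(1 − fraction) linear-interpolation (type-7) quantile and labels every
value ≥ the threshold, so ties at the threshold are all included and the
rule is independent of input order.

The downsampling robustness study redraws ⌈0.8 · panel⌉ transcripts
without replacement for 100 rounds and reports the Spearman correlation
of the downsampled median.hERV with the full-panel score across samples.

## Absolute immune-cell deconvolution

Signature construction selects, per cell type, genes expressed at
≥ `expr_min` (default 50) in that type and ≥ `fold_min` (default 5)-fold
above the maximum over all background tissues *and* all other cell
types; a pseudocount of 1 on the competing maximum keeps folds finite
against silent backgrounds. Each signature column is then rescaled so
its mean over the type's own markers equals a common constant
(default 100): the common scale keeps the regression conditioned evenly
across cell types, and the per-column scale factors are stored so
coefficients can be mapped back to the raw-profile scale.

Deconvolution regresses the mixture on the normalised signature columns
with linear-kernel ν-SVR over ν ∈ {0.25, 0.5, 0.75} (C = 1, tol 1e-6),
keeping the lowest-RMSE solution. Both sides are divided by one joint
constant before fitting — coefficients are invariant to a joint rescale
and the solver converges orders of magnitude faster on O(1) data.
Negative coefficients are clamped to zero and the column scales are
re-applied, yielding **absolute RNA fractions**; no sum-to-one
renormalisation is performed, which is the point of the absolute
contract (fractions answer "what share of this sample's RNA is CD8",
not "what share of its immune RNA"). Quantile-matching the mixture onto
the signature distribution was considered and rejected: on same-platform
data it is a no-op at best and it breaks the exact equivalence between
the SVR solution and a brute-force simplex search that the test suite
uses as an independent oracle.

Residual background RNA projecting onto the signatures leaves a small
positive bias (~1e-3 in fraction units on the synthetic profiles), which
bounds noise-free titration R² at about 1 − 1e-4 rather than exactly 1;
the titration harness under realistic noise (sd 0.1) achieves median
R² ≈ 0.998.

## MSI scoring

Sites are noncoding mononucleotide homopolymers of 10–50 bases
(inclusive); an explicit exclusion list stands in for ethnicity-biased
or low-coverage panel sites. A site is assessable when tumour and
reference each have ≥ 20 reads (the published procedure excludes
"lower coverage" sites without a number; 20 is this package's gate,
exposed in config). The "known range" is the reference read-weighted
mean length ± 3 population standard deviations of the reference length
distribution; the tumour is unstable when its read-weighted mean falls
outside. In baseline mode the baseline samples' *histograms are pooled*
before the range is formed — this makes a baseline set of size one
exactly equal to the paired computation, a consistency the per-sample
means reading cannot provide (the sd of one mean is zero). A degenerate
zero-sd reference makes any shifted tumour mean unstable.

MSI score = unstable/assessed (exact integer ratio); MSI-H at
score ≥ 0.30 for the paired whole-exome pipeline and ≥ 0.20 for the
baseline panel pipeline (both inclusive). The catalog sizes used in
targeted vs exome assays are properties of the input catalog, not
constants. The PCR rule calls MSI-H at ≥ 2 of the 5 mononucleotide
markers; vendor documentation lists BAT-25 twice, and the second entry
is named BAT-26 here. Pentanucleotide identity markers are accepted but
not used for classification.

## Genomic features

The somatic filter retains a record iff all six conditions hold:
tumour VAF ≥ 0.05, tumour depth ≥ 50, normal depth ≥ 20, tumour alt
reads ≥ 5, normal/tumour VAF ratio strictly < 0.2, and both-strand
support. Rejection counts are reported per rule (a record violating
several rules increments each). TMB = retained mutations / exonic Mb.

Arm-level events require the altered-gene proportion to strictly exceed
20%; the CIN burden is the genome-wide arm-event count, categorised by
cohort tertiles by default (explicit cut points accepted). MATH uses the
scaled MAD (× 1.4826) per the original definition of the score.

The Lynch rule is a reconstruction of the NCCN-style flowchart:
LS-positive iff a pathogenic-flagged variant in MLH1/MSH2/MSH6/PMS2
sits at germline-like tumour VAF (default window [0.3, 0.7],
configurable) — unless the only qualifying gene is MLH1 in the presence
of BRAF p.V600E, the signature of sporadic methylation-driven MSI-H,
which is LS-negative. The rule is validated by internal consistency and
by the PPA/NPA machinery, not against an external truth set.

PPA = TP/(TP+FN) and NPA = TN/(TN+FP) carry exact Clopper–Pearson 95%
intervals (beta quantiles; for x = n the lower bound is 0.025^(1/n) and
the upper bound 1); empty denominators give undefined estimates rather
than 0/0.

## Survival

OS = endpoint − diagnosis, RFS = endpoint − surgery, converted at
30.4375 days/month (median-survival figures depend on this constant).
WTS− is CD8-low ∧ hERV-high, both at the cohort top-30% threshold
(per-cohort, not per-stage); CP− is top-30% age ∨ stage III ∨
right-sided. Kaplan–Meier, the multivariate log-rank test and Cox
models come from lifelines; Cox uses Efron tie handling (the default of
the standard R implementation) with Wald 95% intervals, and
non-convergence is reported explicitly instead of returning silent
defaults. Median survival is NA when the curve never crosses 0.5.
Enrichment grids use a continuity-corrected two-proportion chi-square
test, switching to Fisher's exact test when any observed or expected
cell is below 5.

## Synthetic cohort generator

The generator produces every pipeline input with the structure the
methods assume. It is the package's test bed, not a model of any real
cohort.

**Expression.** Samples split into two latent clusters
(default 50/50). Expressed hERV log2-CPM means sit at 1.0 (low cluster)
and 3.0 (high cluster) — a 4-fold separation; 20% of hERVs are silent
(CPM ≈ 0.01). Within a sample, hERVs share a latent factor scaled so
the pairwise latent correlation equals `co_expression_rho`
(default 0.8), emulating strong inter-locus co-expression. The
per-locus log2 sd defaults to 0.3, chosen so the planted two-cluster
structure is identifiable at the default separation (at 0.5 the shared
latent factor makes recovery marginal); the published study does not
state a dispersion, and the default exists to make recovery tests
meaningful. Counts are negative binomial (dispersion 0.2) around the
log-normal means — the standard over-dispersed bulk RNA model. The
reported library size is the column sum plus an unmodelled-
transcriptome constant (40% of the ~1e7 nominal library), so hERV CPMs
are a small fraction of each library as in real whole-transcriptome
data. Background genes carry an immune mixture: purified-cell profiles
(30 planted markers per type at 140–600 CPM, < 3 CPM elsewhere) are
mixed into the first background tissue at per-sample fractions; the CD8
fraction is Beta-distributed with a mean that shifts with the hERV
cluster through `cd8_herv_rho`, so high-hERV samples carry more CD8
signal without hard-coding the association.

**Microsatellites.** Normal histograms are multinomial draws from a
discretised normal (stutter sd 0.7) centred at the reference length;
unstable tumour sites shift the centre 3 bases shorter, stable sites
resample the normal distribution. MSI-H samples flip sites unstable at
rate 0.5, MSS at 0.02; the cohort is half MSI-H, mirroring a
purpose-balanced study design. ~10% of catalog candidates are
deliberately invalid (coding or out of the 10–50 bp window) to exercise
catalog filtering.

**Variants.** Clonal VAFs are Beta-distributed around purity/2
(purity 0.6), subclonal around 0.12; depths sit above the filter gates.
A configurable fraction of records (default 10%) is crafted to violate
exactly one named filter rule, recorded in the truth. Lynch-positive
samples (drawn from MSI-H samples at rate 0.12, near the 13/113 the
rule is meant to produce) receive a pathogenic MMR variant at VAF
0.42–0.58; sporadic MSI-H samples receive BRAF p.V600E, sometimes with
an MLH1 variant on top to exercise the sporadic override.

**Copy number.** Eight CRC-typical arms (17p/18q loss-biased, 1q/8q/
13q/20q gain-biased); each sample draws a latent CIN tier mapping to
0–1, 2–4 or 5–8 arm events; event arms alter ~50% of their genes,
quiet arms 2%, so the > 20% rule separates them cleanly.

**Survival.** Event times are exponential proportional-hazards draws;
the baseline medians are 37.5 (OS) and 32.8 (RFS) months and the WTS−
subgroup carries hazard ratio 4.4 — the conditions the stratification
machinery is validated against. OS adds a uniform 2–8 month
relapse-to-death lag so a single endpoint date stays consistent with
both endpoints (OS − RFS equals the diagnosis-to-surgery interval by
construction). One censoring time C ~ U(0, c_max) applies to both
endpoints, with c_max solved numerically so the expected censoring
fraction matches `censoring_rate` (default 0.3); rate 1 censors
everyone at time ≈ 0.

**What the generator does not emulate:** read-level data (alignment,
quantification and calling engines are upstream and out of scope),
batch effects and platform shift between purified profiles and
mixtures, subclonal copy-number structure, informative censoring,
competing risks, and any correlation structure among clinical
covariates beyond the MSI-linked age/sidedness skews. Passing tests
therefore demonstrate that the implementations recover the structures
they assume, at realistic noise — not clinical performance on real
cohorts.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: cohorts of
24–60 samples, 80–200 hERVs, 600–2000 background genes, 40–200
microsatellite sites at coverage 100, Cox recovery at n = 1000 with 25
replicates per hazard ratio, and power checks over 100 replicates at
n = 500. All randomness flows from explicit seeds through
`numpy.random.SeedSequence`, and identical configurations produce
byte-identical bundles and reports.

## Known limitations

- The SVR's ε-insensitive tube leaves an irreducible ~1e-3 coefficient
  bias, so noise-free linearity is near-exact (R² ≈ 1 − 1e-4) rather
  than exact.
- The Lynch rule consumes pathogenicity flags as given; no ClinVar-style
  curation is performed.
- CIN tertile categories depend on the cohort composition unless
  explicit cut points are supplied.
- The WES "known range" uses summary statistics (mean ± k·sd) of the
  reference length distribution; per-length distribution tests are not
  implemented.
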