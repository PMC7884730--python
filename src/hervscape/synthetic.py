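"""Synthetic cohort generation.

Produces every input the analysis stack consumes — transcript counts with a
two-cluster hERV structure, purified immune-cell and background-tissue
profiles, titration mixtures, microsatellite length histograms, somatic
variant records, arm-level copy-number calls, and clinical tables with
proportional-hazards survival times — with the statistical structure the
downstream methods assume.  All randomness flows from a single seed through
:class:`numpy.random.SeedSequence` children, so a configuration fully
determines the output.

The generator emulates a stage II/III colorectal-cancer style cohort: half
the samples sit in a high hERV-expression cluster whose loci co-express
through a shared per-sample latent factor, CD8+ infiltration is coupled to
that cluster, MSI-H and MSS samples differ in their per-site instability
rate, and survival times follow an exponential proportional-hazards model
keyed to subgroup labels.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

DAYS_PER_MONTH = 30.4375

CELL_TYPES = ("CD4", "CD8", "CD19")
BACKGROUND_TISSUES = ("colon", "kidney", "pancreas", "ovary", "rectum",
                      "uterus", "esophagus", "thyroid", "bladder")
MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

#: chromosome arms tracked by the copy-number simulator; the amp-biased set
#: mirrors recurrently gained arms in CRC, the rest are loss-biased (17p/18q).
CN_ARMS = ("1p", "1q", "8p", "8q", "13q", "17p", "18q", "20q")
AMP_BIASED_ARMS = frozenset({"1q", "8q", "13q", "20q"})

#: total background-transcriptome expression assigned to the simulated gene
#: panel, in CPM units (the remainder of each library is unmodelled).
PROFILE_TOTAL_CPM = 6.0e5


class InvalidConfigError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions the downstream methods are
    validated against: a balanced two-cluster cohort with 4-fold hERV
    log-separation, pairwise hERV co-expression ~0.8, equal MSI-H/MSS split
    with per-site instability rates 0.5 vs 0.02, and a hazard ratio of 4.4
    for the CD8-low/hERV-high (WTS-) subgroup against baseline medians of
    37.5 (OS) and 32.8 (RFS) months.
    """

    seed: int = 0
    n_samples: int = 60

    # -- expression -------------------------------------------------------
    n_herv: int = 200
    n_background_genes: int = 2000
    herv_silent_fraction: float = 0.2
    cluster_fraction_high: float = 0.5
    herv_logmean_low: float = 1.0    #: log2 CPM of expressed hERVs, low cluster
    herv_logmean_high: float = 3.0   #: log2 CPM, high cluster (4-fold above low)
    herv_logsd: float = 0.3
    co_expression_rho: float = 0.8
    cd8_herv_rho: float = 0.5
    nb_dispersion: float = 0.2
    library_size_mean: float = 1.0e7
    library_size_logsd: float = 0.15
    n_background_tissues: int = 3
    n_markers_per_type: int = 30

    # -- microsatellites --------------------------------------------------
    n_msi_sites: int = 200
    msi_coverage: int = 100
    msi_shift_bases: int = 3
    msi_stutter_sd: float = 0.7
    msih_fraction: float = 0.5
    msi_unstable_rate_msih: float = 0.5
    msi_unstable_rate_mss: float = 0.02
    n_msi_baseline: int = 8
    msi_invalid_candidate_rate: float = 0.1

    # -- somatic variants -------------------------------------------------
    exonic_mb: float = 30.0
    mut_per_mb_mss: float = 4.0
    mut_per_mb_msih: float = 25.0
    tumor_purity: float = 0.6
    filter_violation_rate: float = 0.1
    lynch_rate: float = 0.12

    # -- copy number ------------------------------------------------------
    n_genes_per_arm: int = 50

    # -- survival ---------------------------------------------------------
    hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"WTS-": 4.4})
    baseline_median_os: float = 37.5   #: months
    baseline_median_rfs: float = 32.8  #: months
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        proportions = {
            "herv_silent_fraction": self.herv_silent_fraction,
            "cluster_fraction_high": self.cluster_fraction_high,
            "co_expression_rho": self.co_expression_rho,
            "cd8_herv_rho": self.cd8_herv_rho,
            "msih_fraction": self.msih_fraction,
            "msi_unstable_rate_msih": self.msi_unstable_rate_msih,
            "msi_unstable_rate_mss": self.msi_unstable_rate_mss,
            "filter_violation_rate": self.filter_violation_rate,
            "lynch_rate": self.lynch_rate,
            "censoring_rate": self.censoring_rate,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name}={value} outside [0, 1]")
        if self.n_samples < 4:
            raise InvalidConfigError("n_samples must be >= 4")
        if self.n_herv < 2:
            raise InvalidConfigError("n_herv must be >= 2")
        for group, hr in self.hazard_ratios.items():
            if hr <= 0:
                raise InvalidConfigError(
                    f"hazard ratio for {group!r} must be > 0, got {hr}")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    """Counts plus the latent truth behind them."""

    counts: pd.DataFrame            #: transcripts x samples, integer
    library_sizes: pd.Series        #: per-sample total library counts
    herv_ids: list[str]             #: full candidate hERV panel
    purified_profiles: pd.DataFrame  #: background genes x cell types
    background_profiles: pd.DataFrame  #: background genes x tissues
    marker_genes: dict[str, list[str]]
    cluster: pd.Series              #: 'high' / 'low' per sample
    expressed_herv: pd.Series       #: bool per hERV id
    fractions: pd.DataFrame         #: samples x cell types, true RNA fractions


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def simulate_immune_profiles(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Purified-cell and background-tissue profiles with planted markers.

    Each cell type gets ``n_markers_per_type`` marker genes expressed at
    140-600 CPM in its own profile and <3 CPM everywhere else; all other
    genes share a jittered baseline so no spurious marker passes a 5-fold
    selection screen.  Columns are rescaled to a common total so mixtures
    stay on one CPM-like scale.
    """
    genes = [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]
    n_types = len(CELL_TYPES)
    needed = n_types * cfg.n_markers_per_type
    if needed > cfg.n_background_genes:
        raise InvalidConfigError("not enough background genes for markers")
    marker_idx = rng.choice(cfg.n_background_genes, size=needed, replace=False)
    marker_genes = {
        ct: [genes[j] for j in marker_idx[k * cfg.n_markers_per_type:
                                          (k + 1) * cfg.n_markers_per_type]]
        for k, ct in enumerate(CELL_TYPES)
    }
    base = rng.lognormal(np.log(250.0), 1.0, cfg.n_background_genes)

    tissues = list(BACKGROUND_TISSUES[:cfg.n_background_tissues])
    purified = pd.DataFrame(index=genes, columns=list(CELL_TYPES), dtype=float)
    background = pd.DataFrame(index=genes, columns=tissues, dtype=float)
    for col, frame in [(ct, purified) for ct in CELL_TYPES] + [
            (ts, background) for ts in tissues]:
        frame[col] = base * rng.uniform(0.8, 1.25, cfg.n_background_genes)
    for k, ct in enumerate(CELL_TYPES):
        rows = marker_genes[ct]
        purified.loc[rows, ct] = rng.uniform(200.0, 600.0, len(rows))
        others = [c for c in CELL_TYPES if c != ct]
        purified.loc[rows, others] = rng.uniform(0.0, 2.0, (len(rows),
                                                            len(others)))
        background.loc[rows, :] = rng.uniform(0.0, 2.0, (len(rows),
                                                         len(tissues)))
    purified *= PROFILE_TOTAL_CPM / purified.sum(axis=0)
    background *= PROFILE_TOTAL_CPM / background.sum(axis=0)
    return purified, background, marker_genes


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = m + disp*m^2)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def simulate_expression(cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> ExpressionSim:
    """Simulate the cohort count matrix with two latent hERV clusters.

    Expressed hERV log2-CPM values share a per-sample latent factor scaled
    so the pairwise latent correlation within a cluster equals
    ``co_expression_rho``; a fraction of hERVs is silent (CPM ~0.01) and is
    recorded in the truth.  Background genes carry an immune-fraction
    mixture of the purified profiles into the first background tissue, so
    deconvolution is exercisable on the same matrix.  Counts are negative
    binomial around the log-normal means and the reported library size is
    the column total plus an unmodelled-transcriptome constant, so hERV
    CPMs remain a small fraction of the library.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    samples = _sample_ids(cfg.n_samples)
    herv_ids = [f"hERV_{i + 1:04d}" for i in range(cfg.n_herv)]

    n_high = int(round(cfg.n_samples * cfg.cluster_fraction_high))
    cluster_arr = np.array(["high"] * n_high
                           + ["low"] * (cfg.n_samples - n_high))
    rng.shuffle(cluster_arr)
    cluster = pd.Series(cluster_arr, index=samples, name="cluster")

    n_silent = int(round(cfg.n_herv * cfg.herv_silent_fraction))
    silent_mask = np.zeros(cfg.n_herv, dtype=bool)
    silent_mask[rng.choice(cfg.n_herv, size=n_silent, replace=False)] = True
    expressed = pd.Series(~silent_mask, index=herv_ids, name="expressed")

    mu = np.where(cluster_arr == "high", cfg.herv_logmean_high,
                  cfg.herv_logmean_low)
    delta = rng.normal(0.0, 0.3, cfg.n_herv)               # per-locus offset
    z = rng.normal(0.0, 1.0, cfg.n_samples)                # shared latent
    eps = rng.normal(0.0, 1.0, (cfg.n_herv, cfg.n_samples))
    rho = cfg.co_expression_rho
    log2cpm = (mu[None, :] + delta[:, None]
               + cfg.herv_logsd * (np.sqrt(rho) * z[None, :]
                                   + np.sqrt(1.0 - rho) * eps))
    silent_noise = rng.normal(0.0, 0.3, (n_silent, cfg.n_samples))
    log2cpm[silent_mask, :] = np.log2(0.01) + silent_noise
    herv_cpm = 2.0 ** log2cpm

    purified, background, markers = simulate_immune_profiles(cfg, rng)

    # CD8 infiltration coupled to the hERV cluster through the Beta mean.
    concentration = 60.0
    cd8_mean = np.where(cluster_arr == "high",
                        0.04 + 0.12 * cfg.cd8_herv_rho, 0.04)
    means = {"CD4": np.full(cfg.n_samples, 0.06),
             "CD8": cd8_mean,
             "CD19": np.full(cfg.n_samples, 0.03)}
    fractions = pd.DataFrame(index=samples, columns=list(CELL_TYPES),
                             dtype=float)
    for ct in CELL_TYPES:
        m = means[ct]
        fractions[ct] = rng.beta(m * concentration,
                                 (1.0 - m) * concentration)

    frac = fractions.to_numpy()
    total = frac.sum(axis=1)
    bg_tissue = background.iloc[:, 0].to_numpy()
    mixture_cpm = ((1.0 - total)[None, :] * bg_tissue[:, None]
                   + purified.to_numpy() @ frac.T)

    nominal = rng.lognormal(np.log(cfg.library_size_mean),
                            cfg.library_size_logsd, cfg.n_samples)
    cpm = np.vstack([herv_cpm, mixture_cpm])
    mean_counts = cpm * nominal[None, :] / 1.0e6
    counts = _negative_binomial(rng, mean_counts, cfg.nb_dispersion)
    counts = pd.DataFrame(counts, index=herv_ids + list(purified.index),
                          columns=samples)
    library = counts.sum(axis=0) + np.round(0.4 * nominal).astype(np.int64)
    library = library.astype(np.int64).rename("library_size")

    return ExpressionSim(counts=counts, library_sizes=library,
                         herv_ids=herv_ids, purified_profiles=purified,
                         background_profiles=background,
                         marker_genes=markers, cluster=cluster,
                         expressed_herv=expressed, fractions=fractions)


# ---------------------------------------------------------------------------
# titration mixtures
# ---------------------------------------------------------------------------

def simulate_mixtures(purified_profiles: pd.DataFrame,
                      background_profile: pd.Series,
                      fractions: pd.DataFrame,
                      noise_sd: float = 0.0,
                      seed: int | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear in-silico titration of purified cells into a background.

    ``mixture_g = (sum_c f_c S_gc + (1 - sum_c f_c) B_g) * eps_g`` with
    ``eps`` log-normal(0, noise_sd).  Returns the mixture matrix
    (genes x mixtures) and a copy of the truth table.
    """
    if not purified_profiles.index.equals(
            background_profile.index if isinstance(background_profile,
                                                   pd.Series)
            else background_profile.index):
        raise ValueError("purified and background profiles must share a "
                         "gene index")
    missing = [c for c in fractions.columns
               if c not in purified_profiles.columns]
    if missing:
        raise ValueError(f"fractions reference unknown cell types: {missing}")
    totals = fractions.sum(axis=1)
    if (totals > 1.0 + 1e-9).any():
        bad = totals[totals > 1.0 + 1e-9].index.tolist()
        raise ValueError(f"fraction rows sum to more than 1: {bad}")

    rng = np.random.default_rng(seed)
    S = purified_profiles[fractions.columns].to_numpy()
    B = np.asarray(background_profile, dtype=float)
    F = fractions.to_numpy()
    clean = S @ F.T + B[:, None] * (1.0 - F.sum(axis=1))[None, :]
    if noise_sd > 0:
        clean = clean * rng.lognormal(0.0, noise_sd, clean.shape)
    mixtures = pd.DataFrame(clean, index=purified_profiles.index,
                            columns=fractions.index)
    return mixtures, fractions.copy()


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------

@dataclass
class MsiSim:
    sites: pd.DataFrame        #: candidate catalog incl. invalid entries
    histograms: pd.DataFrame   #: long: site_id, sample_id, length, count
    msi_truth: pd.Series       #: 'MSI-H' / 'MSS' per tumor sample
    unstable_sites: pd.DataFrame  #: bool, valid sites x tumor samples


def _length_probs(ref_len: int, shift: int, sd: float,
                  offsets: np.ndarray) -> np.ndarray:
    """Discretised normal over repeat lengths, centred at ref - shift."""
    centers = ref_len - shift + 0.0
    p = norm.pdf(offsets + ref_len, loc=centers, scale=sd)
    return p / p.sum()


def simulate_msi_data(cfg: SimConfig,
                      rng: np.random.Generator | None = None,
                      sample_ids: list[str] | None = None,
                      msi_labels: pd.Series | None = None) -> MsiSim:
    """Microsatellite site catalog plus tumor/normal/baseline histograms.

    Normal read-length histograms are multinomial draws from a discretised
    normal (stutter) centred at the reference repeat length; unstable tumor
    sites shift the centre ``msi_shift_bases`` shorter while stable sites
    resample the normal distribution.  Paired normals are named
    ``<sample>.N`` and pooled-baseline normals ``BASE<k>``.  A fraction of
    catalog candidates is deliberately invalid (coding or out of the 10-50
    bp range) to exercise catalog filtering.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    if cfg.n_msi_sites < 1:
        raise InvalidConfigError("n_msi_sites must be >= 1")
    if sample_ids is None:
        sample_ids = _sample_ids(cfg.n_samples)
    if msi_labels is None:
        n_h = int(round(len(sample_ids) * cfg.msih_fraction))
        lab = np.array(["MSI-H"] * n_h + ["MSS"] * (len(sample_ids) - n_h))
        rng.shuffle(lab)
        msi_labels = pd.Series(lab, index=sample_ids, name="msi")

    n_invalid = int(round(cfg.n_msi_sites * cfg.msi_invalid_candidate_rate))
    n_valid = cfg.n_msi_sites
    rows = []
    for i in range(n_valid + n_invalid):
        invalid = i >= n_valid
        if invalid and rng.random() < 0.5:
            ref_len = int(rng.integers(5, 10))      # too short
            noncoding = True
        elif invalid:
            ref_len = int(rng.integers(10, 31))
            noncoding = False                       # coding site
        else:
            ref_len = int(rng.integers(10, 31))
            noncoding = True
        chrom = str(rng.integers(1, 23))
        start = int(rng.integers(1_000, 50_000_000))
        rows.append({"site_id": f"MS{i + 1:04d}", "chrom": chrom,
                     "start": start, "end": start + ref_len,
                     "repeat_unit": str(rng.choice(["A", "T"])),
                     "ref_repeat_length": ref_len, "noncoding": noncoding})
    sites = pd.DataFrame(rows)

    valid = sites[(sites.noncoding) & (sites.ref_repeat_length >= 10)
                  & (sites.ref_repeat_length <= 50)]
    offsets = np.arange(-cfg.msi_shift_bases - 3, 4)
    rate = {"MSI-H": cfg.msi_unstable_rate_msih,
            "MSS": cfg.msi_unstable_rate_mss}

    hist_rows: list[tuple[str, str, int, int]] = []
    unstable = pd.DataFrame(False, index=valid.site_id,
                            columns=list(sample_ids))

    def _emit(site_id: str, ref_len: int, sample: str, shift: int) -> None:
        cov = rng.poisson(cfg.msi_coverage)
        if cov == 0:
            return
        probs = _length_probs(ref_len, shift, cfg.msi_stutter_sd, offsets)
        draws = rng.multinomial(cov, probs)
        for off, count in zip(offsets, draws):
            if count > 0:
                hist_rows.append((site_id, sample, ref_len + int(off),
                                  int(count)))

    baselines = [f"BASE{k + 1:02d}" for k in range(cfg.n_msi_baseline)]
    for _, site in valid.iterrows():
        sid, ref_len = site.site_id, int(site.ref_repeat_length)
        for b in baselines:
            _emit(sid, ref_len, b, shift=0)
        for s in sample_ids:
            _emit(sid, ref_len, f"{s}.N", shift=0)
            hit = rng.random() < rate[str(msi_labels[s])]
            unstable.loc[sid, s] = hit
            _emit(sid, ref_len, s, shift=cfg.msi_shift_bases if hit else 0)

    histograms = pd.DataFrame(hist_rows, columns=["site_id", "sample_id",
                                                  "length", "count"])
    return MsiSim(sites=sites, histograms=histograms, msi_truth=msi_labels,
                  unstable_sites=unstable)


# ---------------------------------------------------------------------------
# somatic variants
# ---------------------------------------------------------------------------

FILTER_RULES = ("vaf_tumor", "dp_tumor", "dp_normal", "ad_tumor",
                "vaf_ratio", "strands")

_BASES = np.array(list("ACGT"))


@dataclass
class VariantSim:
    records: pd.DataFrame      #: one row per variant call
    lynch_truth: pd.Series     #: bool per tumor sample
    braf_v600e: pd.Series      #: bool per tumor sample


def simulate_variants(cfg: SimConfig,
                      rng: np.random.Generator | None = None,
                      sample_ids: list[str] | None = None,
                      msi_labels: pd.Series | None = None) -> VariantSim:
    """Somatic variant records with controllable filter violations.

    Passing records draw clonal/subclonal VAFs from Beta mixtures around
    purity/2, Poisson-like depths above the filter gates and clean normal
    VAFs.  A ``filter_violation_rate`` fraction of records is crafted to
    break exactly one named quality rule and carries that rule in the
    ``violated_rule`` column, so filter behaviour is testable per rule.
    Lynch-positive samples receive a pathogenic mismatch-repair variant at
    germline-like VAF; sporadic MSI-H samples receive BRAF p.V600E (and
    sometimes an MLH1 variant on top, exercising the sporadic override).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    if sample_ids is None:
        sample_ids = _sample_ids(cfg.n_samples)
    if msi_labels is None:
        msi_labels = pd.Series("MSS", index=sample_ids)

    msih = [s for s in sample_ids if msi_labels[s] == "MSI-H"]
    n_lynch = min(len(msih), int(round(cfg.lynch_rate * len(sample_ids))))
    lynch_set = set(rng.choice(msih, size=n_lynch, replace=False)) \
        if n_lynch else set()
    lynch_truth = pd.Series([s in lynch_set for s in sample_ids],
                            index=sample_ids, name="lynch")
    braf = pd.Series(False, index=sample_ids, name="braf_v600e")

    rows: list[dict] = []

    def _passing_record(sample: str, clonal: bool) -> dict:
        mean = cfg.tumor_purity / 2.0 if clonal else 0.12
        k = 30.0 if clonal else 40.0
        vaf = float(np.clip(rng.beta(mean * k, (1 - mean) * k), 0.07, 0.9))
        dp_t = int(55 + rng.poisson(80))
        dp_n = int(25 + rng.poisson(40))
        ad = int(max(5, round(vaf * dp_t)))
        return {"sample_id": sample,
                "chrom": str(rng.integers(1, 23)),
                "pos": int(rng.integers(10_000, 50_000_000)),
                "vaf_tumor": round(vaf, 4),
                "vaf_normal": round(float(rng.uniform(0.0, 0.15) * vaf), 4),
                "dp_tumor": dp_t, "dp_normal": dp_n, "ad_tumor": ad,
                "both_strands": True, "gene": "", "aa_change": "",
                "pathogenic": False, "truth_pass": True, "violated_rule": ""}

    def _violate(rec: dict, rule: str) -> dict:
        rec = dict(rec)
        if rule == "vaf_tumor":
            rec["vaf_tumor"] = round(float(rng.uniform(0.005, 0.045)), 4)
            rec["ad_tumor"] = max(5, int(round(rec["vaf_tumor"]
                                               * rec["dp_tumor"])) or 5)
        elif rule == "dp_tumor":
            rec["dp_tumor"] = int(rng.integers(10, 50))
            rec["ad_tumor"] = max(5, int(round(rec["vaf_tumor"]
                                               * rec["dp_tumor"])))
        elif rule == "dp_normal":
            rec["dp_normal"] = int(rng.integers(1, 20))
        elif rule == "ad_tumor":
            rec["dp_tumor"] = 55
            rec["vaf_tumor"] = 0.06
            rec["ad_tumor"] = int(rng.integers(1, 5))
        elif rule == "vaf_ratio":
            rec["vaf_normal"] = round(rec["vaf_tumor"]
                                      * float(rng.uniform(0.25, 0.6)), 4)
        elif rule == "strands":
            rec["both_strands"] = False
        rec["truth_pass"] = False
        rec["violated_rule"] = rule
        return rec

    for sample in sample_ids:
        per_mb = (cfg.mut_per_mb_msih if msi_labels[sample] == "MSI-H"
                  else cfg.mut_per_mb_mss)
        n = int(rng.poisson(per_mb * cfg.exonic_mb))
        for _ in range(n):
            rec = _passing_record(sample, clonal=rng.random() < 0.7)
            if rng.random() < cfg.filter_violation_rate:
                rec = _violate(rec, str(rng.choice(FILTER_RULES)))
            rows.append(rec)
        if sample in lynch_set:
            rec = _passing_record(sample, clonal=True)
            rec.update(gene=str(rng.choice(MMR_GENES)),
                       vaf_tumor=round(float(rng.uniform(0.42, 0.58)), 4),
                       pathogenic=True)
            rec["ad_tumor"] = int(round(rec["vaf_tumor"] * rec["dp_tumor"]))
            rows.append(rec)
        elif msi_labels[sample] == "MSI-H":
            if rng.random() < 0.7:
                braf[sample] = True
                rec = _passing_record(sample, clonal=True)
                rec.update(gene="BRAF", aa_change="p.V600E", pathogenic=True)
                rows.append(rec)
                if rng.random() < 0.5:
                    # sporadic MLH1 hit that must NOT be read as Lynch
                    rec = _passing_record(sample, clonal=True)
                    rec.update(gene="MLH1", pathogenic=True,
                               vaf_tumor=round(float(rng.uniform(0.42, 0.58)),
                                               4))
                    rec["ad_tumor"] = int(round(rec["vaf_tumor"]
                                                * rec["dp_tumor"]))
                    rows.append(rec)

    columns = ["sample_id", "chrom", "pos", "vaf_tumor", "vaf_normal",
               "dp_tumor", "dp_normal", "ad_tumor", "both_strands", "gene",
               "aa_change", "pathogenic", "truth_pass", "violated_rule"]
    records = pd.DataFrame(rows, columns=columns)
    if len(records):
        records["ref"] = _BASES[rng.integers(0, 4, len(records))]
        alt_shift = rng.integers(1, 4, len(records))
        records["alt"] = _BASES[(np.searchsorted(_BASES, records["ref"])
                                 + alt_shift) % 4]
        records = records.sort_values(
            ["sample_id", "chrom", "pos"],
            key=lambda c: c.astype(int) if c.name == "chrom" else c,
        ).reset_index(drop=True)
    else:
        records["ref"] = pd.Series(dtype=str)
        records["alt"] = pd.Series(dtype=str)
    return VariantSim(records=records, lynch_truth=lynch_truth,
                      braf_v600e=braf)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@dataclass
class CnSim:
    calls: pd.DataFrame          #: genes x samples in {del, neutral, amp}
    gene_arms: pd.Series         #: arm per gene
    arm_event_truth: pd.DataFrame  #: arms x samples in {del, amp, none}


def simulate_cn(cfg: SimConfig, rng: np.random.Generator | None = None,
                sample_ids: list[str] | None = None) -> CnSim:
    """Arm-level copy-number events over per-gene calls.

    Each sample draws a latent CIN tier (stable/medium/high -> 0-1 / 2-4 /
    5-8 arm events); event arms alter ~50% of their genes in the biased
    direction while quiet arms carry a 2% background alteration rate, so
    the >20% arm-event rule separates them cleanly.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    if sample_ids is None:
        sample_ids = _sample_ids(cfg.n_samples)
    genes = [f"{arm}_G{i + 1:03d}" for arm in CN_ARMS
             for i in range(cfg.n_genes_per_arm)]
    gene_arms = pd.Series([g.split("_")[0] for g in genes], index=genes,
                          name="arm")

    calls = pd.DataFrame("neutral", index=genes, columns=list(sample_ids))
    truth = pd.DataFrame("none", index=list(CN_ARMS), columns=list(sample_ids))
    tiers = rng.choice(["stable", "medium", "high"], size=len(sample_ids),
                       p=[0.4, 0.35, 0.25])
    for sample, tier in zip(sample_ids, tiers):
        if tier == "stable":
            n_events = int(rng.integers(0, 2))
        elif tier == "medium":
            n_events = int(rng.integers(2, 5))
        else:
            n_events = int(rng.integers(5, len(CN_ARMS) + 1))
        event_arms = rng.choice(CN_ARMS, size=n_events, replace=False)
        for arm in CN_ARMS:
            arm_genes = gene_arms[gene_arms == arm].index
            if arm in event_arms:
                kind = "amp" if arm in AMP_BIASED_ARMS else "del"
                if rng.random() < 0.1:
                    kind = "del" if kind == "amp" else "amp"
                hit = rng.random(len(arm_genes)) < 0.5
                calls.loc[arm_genes[hit], sample] = kind
                truth.loc[arm, sample] = kind
            else:
                u = rng.random(len(arm_genes))
                calls.loc[arm_genes[u < 0.02], sample] = "del"
                calls.loc[arm_genes[(u >= 0.02) & (u < 0.04)], sample] = "amp"
    return CnSim(calls=calls, gene_arms=gene_arms, arm_event_truth=truth)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _uniform_censor_max(mean_time: float, censoring_rate: float) -> float:
    """Upper bound c of U(0, c) censoring achieving a target censor rate.

    For exponential event times with mean theta and C ~ U(0, c), the
    probability of censoring is (theta/c)(1 - exp(-c/theta)); invert it.
    """
    if censoring_rate <= 0:
        return np.inf
    if censoring_rate >= 1:
        return 1e-9

    def f(c: float) -> float:
        return (mean_time / c) * (1.0 - np.exp(-c / mean_time)) \
            - censoring_rate

    return float(brentq(f, 1e-9, 1e9))


def simulate_survival(cohort_labels: pd.Series,
                      hazard_ratios: Mapping[str, float],
                      baseline_scale: float = 37.5,
                      censoring_rate: float = 0.3,
                      seed: int | None = None,
                      rfs_fraction: float = 32.8 / 37.5) -> pd.DataFrame:
    """Exponential proportional-hazards event times with uniform censoring.

    ``baseline_scale`` is the baseline median OS in months; groups named in
    ``hazard_ratios`` multiply the hazard (labels absent from the map get
    HR 1).  RFS times are exponential with median ``rfs_fraction *
    baseline_scale``; OS adds a uniform 2-8 month relapse-to-death lag so
    date arithmetic stays consistent.  One censoring time C ~ U(0, c_max)
    applies to both endpoints; c_max is solved so the expected censoring
    fraction matches ``censoring_rate``.
    """
    for group, hr in hazard_ratios.items():
        if hr <= 0:
            raise ValueError(f"hazard ratio for {group!r} must be > 0")
    rng = np.random.default_rng(seed)
    labels = pd.Series(cohort_labels)
    hr = labels.map(lambda g: float(hazard_ratios.get(g, 1.0))).to_numpy()
    n = len(labels)

    median_rfs = baseline_scale * rfs_fraction
    scale_rfs = median_rfs / np.log(2.0) / hr
    t_rfs = rng.exponential(scale_rfs)
    t_os = t_rfs + rng.uniform(2.0, 8.0, n)

    mean_time = float(np.mean(scale_rfs))
    c_max = _uniform_censor_max(mean_time, censoring_rate)
    censor = rng.uniform(0.0, c_max, n) if np.isfinite(c_max) \
        else np.full(n, np.inf)

    rfs_event = t_rfs <= censor
    os_event = t_os <= censor
    out = pd.DataFrame({
        "os_months": np.where(os_event, t_os, censor),
        "os_event": os_event.astype(int),
        "rfs_months": np.where(rfs_event, t_rfs, censor),
        "rfs_event": rfs_event.astype(int),
    }, index=labels.index)
    return out


# ---------------------------------------------------------------------------
# clinical covariates and bundle assembly
# ---------------------------------------------------------------------------

def simulate_clinical(cfg: SimConfig, rng: np.random.Generator,
                      sample_ids: list[str],
                      msi_labels: pd.Series) -> pd.DataFrame:
    """Clinical covariates with MSI-linked age and sidedness skews."""
    n = len(sample_ids)
    msih = (msi_labels.loc[sample_ids] == "MSI-H").to_numpy()
    age = np.clip(np.round(rng.normal(66.0, 8.0, n) + 8.0 * msih), 40, 92)
    stage = rng.choice(["II", "III"], size=n, p=[0.6, 0.4])
    p_right = np.where(msih, 0.8, 0.3)
    sidedness = np.where(rng.random(n) < p_right, "right", "left")
    adjuvant = np.where(stage == "III", rng.random(n) < 0.63,
                        rng.random(n) < 0.2)
    return pd.DataFrame({
        "patient_id": sample_ids,
        "age": age.astype(int),
        "sex": rng.choice(["F", "M"], size=n, p=[0.6, 0.4]),
        "stage": stage,
        "sidedness": sidedness,
        "adjuvant": adjuvant.astype(int),
    }).set_index("patient_id")


@dataclass
class SyntheticCohortBundle:
    """Every pipeline input for one simulated cohort, plus the truth."""

    config: SimConfig
    counts: pd.DataFrame
    library_sizes: pd.Series
    herv_ids: list[str]
    purified_profiles: pd.DataFrame
    background_profiles: pd.DataFrame
    msi_sites: pd.DataFrame
    msi_histograms: pd.DataFrame
    variants: pd.DataFrame
    cn_calls: pd.DataFrame
    gene_arms: pd.Series
    clinical: pd.DataFrame
    truth: dict


def simulate_bundle(cfg: SimConfig) -> SyntheticCohortBundle:
    """Run every simulator off one seed and assemble a coherent cohort."""
    ss = np.random.SeedSequence(cfg.seed)
    (ss_expr, ss_msi, ss_var, ss_cn, ss_clin,
     ss_surv, ss_dates) = ss.spawn(7)

    expr = simulate_expression(cfg, np.random.default_rng(ss_expr))
    samples = list(expr.counts.columns)

    msi = simulate_msi_data(cfg, np.random.default_rng(ss_msi),
                            sample_ids=samples)
    var = simulate_variants(cfg, np.random.default_rng(ss_var),
                            sample_ids=samples, msi_labels=msi.msi_truth)
    cn = simulate_cn(cfg, np.random.default_rng(ss_cn), sample_ids=samples)
    clinical = simulate_clinical(cfg, np.random.default_rng(ss_clin),
                                 samples, msi.msi_truth)

    # truth-level WTS grouping: hERV-high cluster with sub-top-30% CD8
    cd8 = expr.fractions["CD8"]
    cd8_high = cd8 >= cd8.quantile(0.70)
    wts = pd.Series(np.where((expr.cluster == "high") & ~cd8_high,
                             "WTS-", "WTS+"), index=samples, name="wts")
    surv = simulate_survival(wts, cfg.hazard_ratios,
                             baseline_scale=cfg.baseline_median_os,
                             censoring_rate=cfg.censoring_rate,
                             seed=ss_surv,
                             rfs_fraction=(cfg.baseline_median_rfs
                                           / cfg.baseline_median_os))

    rng_dates = np.random.default_rng(ss_dates)
    diag = rng_dates.integers(0, 365, len(samples))
    surgery = diag + rng_dates.integers(14, 61, len(samples))
    rfs_days = np.round(surv["rfs_months"].to_numpy() * DAYS_PER_MONTH)
    os_days = np.round(surv["os_months"].to_numpy() * DAYS_PER_MONTH)
    endpoint = surgery + np.maximum(rfs_days, 0).astype(int)
    # keep A - C consistent with the OS draw: shift diagnosis back
    diag = endpoint - np.maximum(os_days, surgery - diag).astype(int)

    clinical = clinical.copy()
    clinical["date_diagnosis"] = diag
    clinical["date_surgery"] = surgery
    clinical["date_endpoint"] = endpoint
    clinical["death_event"] = surv["os_event"].to_numpy()
    clinical["relapse_event"] = surv["rfs_event"].to_numpy()

    truth = {
        "cluster": expr.cluster.to_dict(),
        "expressed_herv": {k: bool(v)
                           for k, v in expr.expressed_herv.items()},
        "marker_genes": expr.marker_genes,
        "fractions": {s: {c: float(expr.fractions.loc[s, c])
                          for c in expr.fractions.columns}
                      for s in samples},
        "msi": msi.msi_truth.to_dict(),
        "lynch": {k: bool(v) for k, v in var.lynch_truth.items()},
        "braf_v600e": {k: bool(v) for k, v in var.braf_v600e.items()},
        "wts": wts.to_dict(),
        "arm_events": {s: {a: str(cn.arm_event_truth.loc[a, s])
                           for a in cn.arm_event_truth.index
                           if cn.arm_event_truth.loc[a, s] != "none"}
                       for s in samples},
        "variant_pass_counts": var.records.groupby("sample_id")
                                  ["truth_pass"].sum().astype(int).to_dict()
                               if len(var.records) else {},
    }

    return SyntheticCohortBundle(
        config=cfg, counts=expr.counts, library_sizes=expr.library_sizes,
        herv_ids=expr.herv_ids, purified_profiles=expr.purified_profiles,
        background_profiles=expr.background_profiles, msi_sites=msi.sites,
        msi_histograms=msi.histograms, variants=var.records,
        cn_calls=cn.calls, gene_arms=cn.gene_arms, clinical=clinical,
        truth=truth)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_VCF_HEADER = ("##fileformat=VCFv4.2\n"
               + "".join(f"##contig=<ID={c}>\n" for c in range(1, 23))
               + """\
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumor sample id">
##INFO=<ID=DP_T,Number=1,Type=Integer,Description="Tumor depth">
##INFO=<ID=DP_N,Number=1,Type=Integer,Description="Normal depth">
##INFO=<ID=AD_T,Number=1,Type=Integer,Description="Tumor alt reads">
##INFO=<ID=VAF_T,Number=1,Type=Float,Description="Tumor VAF">
##INFO=<ID=VAF_N,Number=1,Type=Float,Description="Normal VAF">
##INFO=<ID=STRANDS,Number=1,Type=Integer,Description="Strands supporting">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=AA,Number=1,Type=String,Description="Amino acid change">
##INFO=<ID=PATH,Number=0,Type=Flag,Description="Pathogenic flag">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
""")


def write_variants_vcf(records: pd.DataFrame, path: Path | str) -> None:
    """Serialise variant records as a sorted single-file VCFv4.2."""
    path = Path(path)
    if len(records):
        records = records.sort_values(
            ["chrom", "pos", "sample_id"],
            key=lambda c: c.astype(int) if c.name in ("chrom", "pos") else c)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for _, r in records.iterrows():
            info = (f"SAMPLE={r.sample_id};DP_T={int(r.dp_tumor)};"
                    f"DP_N={int(r.dp_normal)};AD_T={int(r.ad_tumor)};"
                    f"VAF_T={r.vaf_tumor:.4f};VAF_N={r.vaf_normal:.4f};"
                    f"STRANDS={2 if r.both_strands else 1}")
            if r.gene:
                info += f";GENE={r.gene}"
            if r.aa_change:
                info += f";AA={r.aa_change}"
            if r.pathogenic:
                info += ";PATH"
            fh.write(f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\t"
                     f"PASS\t{info}\n")


def write_bundle(bundle: SyntheticCohortBundle, out_dir: Path | str) -> Path:
    """Write the bundle as plain-text files readable by the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"

    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="id")
    bundle.library_sizes.rename("library_size").to_csv(
        out / "library_sizes.tsv", sep="\t", index_label="sample_id")
    (out / "herv_panel.txt").write_text("\n".join(bundle.herv_ids) + "\n")
    bundle.purified_profiles.to_csv(out / "purified.tsv", sep="\t",
                                    index_label="gene_id", float_format=ff)
    bundle.background_profiles.to_csv(out / "background.tsv", sep="\t",
                                      index_label="gene_id", float_format=ff)
    sites = bundle.msi_sites
    bed = sites[["chrom", "start", "end", "site_id"]].copy()
    bed["score"] = sites["ref_repeat_length"]
    bed["strand"] = "+"
    bed["annotation"] = np.where(sites["noncoding"], "noncoding", "coding")
    bed["repeat_unit"] = sites["repeat_unit"]
    bed.to_csv(out / "msi_sites.bed", sep="\t", header=False, index=False)
    bundle.msi_histograms.to_csv(out / "msi_hist.tsv", sep="\t", index=False)
    write_variants_vcf(bundle.variants, out / "variants.vcf")
    cn = bundle.cn_calls.copy()
    cn.insert(0, "arm", bundle.gene_arms)
    cn.to_csv(out / "cn_calls.tsv", sep="\t", index_label="gene_id")
    bundle.clinical.to_csv(out / "clinical.csv", index_label="patient_id")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(bundle.truth, fh, sort_keys=True)
    manifest = {"seed": bundle.config.seed,
                "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                           for k, v in
                           dataclasses.asdict(bundle.config).items()}}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
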