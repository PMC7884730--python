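"""Somatic-variant, copy-number and heterogeneity feature extraction.

Covers the six-rule somatic variant quality filter, tumor mutational
burden per megabase, arm-level copy-number event calls and the
chromosomal-instability (CIN) burden, the MATH intra-tumoral heterogeneity
score, an NCCN-style Lynch-syndrome classification rule, and positive /
negative percent agreement with exact Clopper-Pearson intervals.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

#: filter thresholds: tumor VAF >= 0.05, tumor depth >= 50, normal depth
#: >= 20, tumor alt reads >= 5, normal/tumor VAF ratio strictly < 0.2, and
#: support on both strands.
VAF_TUMOR_MIN = 0.05
DP_TUMOR_MIN = 50
DP_NORMAL_MIN = 20
AD_TUMOR_MIN = 5
VAF_RATIO_MAX = 0.2

FILTER_RULES = ("vaf_tumor", "dp_tumor", "dp_normal", "ad_tumor",
                "vaf_ratio", "strands")

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")

REQUIRED_VARIANT_COLUMNS = ("vaf_tumor", "vaf_normal", "dp_tumor",
                            "dp_normal", "ad_tumor", "both_strands")


def filter_somatic(variants: pd.DataFrame
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the six-rule somatic quality filter.

    Returns the retained records and per-rule rejection counts; a record
    violating several rules increments each of them.  Records with tumor
    VAF 0 fail the VAF rule (the ratio rule is skipped for them so no
    division by zero occurs).
    """
    missing = [c for c in REQUIRED_VARIANT_COLUMNS
               if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table is missing columns: {missing}")
    for col in ("vaf_tumor", "vaf_normal"):
        bad = variants.index[(variants[col] < 0) | (variants[col] > 1)]
        if len(bad):
            raise ValueError(
                f"malformed record(s) at row(s) {list(bad[:5])}: "
                f"{col} outside [0, 1]")

    vt = variants["vaf_tumor"].to_numpy(dtype=float)
    vn = variants["vaf_normal"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vt > 0, vn / np.where(vt > 0, vt, 1.0), np.inf)

    passes = {
        "vaf_tumor": vt >= VAF_TUMOR_MIN,
        "dp_tumor": variants["dp_tumor"].to_numpy() >= DP_TUMOR_MIN,
        "dp_normal": variants["dp_normal"].to_numpy() >= DP_NORMAL_MIN,
        "ad_tumor": variants["ad_tumor"].to_numpy() >= AD_TUMOR_MIN,
        "vaf_ratio": np.where(vt > 0, ratio < VAF_RATIO_MAX, True),
        "strands": variants["both_strands"].to_numpy(dtype=bool),
    }
    rejections = {rule: int((~ok).sum()) for rule, ok in passes.items()}
    keep = np.logical_and.reduce(list(passes.values()))
    return variants[keep].copy(), rejections


def compute_tmb(n_retained_somatic: int, exonic_mb: float) -> float:
    """Tumor mutational burden: retained somatic mutations per megabase."""
    if exonic_mb <= 0:
        raise ValueError("exonic_mb must be positive")
    return n_retained_somatic / exonic_mb


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@dataclass
class ArmCNProfile:
    """Per-arm gene-level alteration tallies."""

    arm_id: str
    n_genes: int
    n_deleted: int
    n_amplified: int

    @property
    def p_del(self) -> float:
        return self.n_deleted / self.n_genes

    @property
    def p_amp(self) -> float:
        return self.n_amplified / self.n_genes


def arm_events(profile: ArmCNProfile, event_fraction: float = 0.20
               ) -> dict[str, bool]:
    """Arm-level event calls: deleted / amplified when the proportion of
    altered genes strictly exceeds ``event_fraction``."""
    if profile.n_genes == 0:
        raise ValueError(f"arm {profile.arm_id!r} has no genes")
    return {"deleted": profile.p_del > event_fraction,
            "amplified": profile.p_amp > event_fraction}


def arm_profiles_from_calls(calls: pd.Series, gene_arms: pd.Series
                            ) -> list[ArmCNProfile]:
    """Aggregate one sample's {del, neutral, amp} gene calls by arm."""
    profiles = []
    for arm, genes in gene_arms.groupby(gene_arms):
        sub = calls.loc[genes.index]
        profiles.append(ArmCNProfile(
            arm_id=str(arm), n_genes=len(sub),
            n_deleted=int((sub == "del").sum()),
            n_amplified=int((sub == "amp").sum())))
    return profiles


def count_arm_events(calls: pd.Series, gene_arms: pd.Series,
                     event_fraction: float = 0.20) -> int:
    """Number of arm-level deletion/amplification events for one sample."""
    total = 0
    for profile in arm_profiles_from_calls(calls, gene_arms):
        ev = arm_events(profile, event_fraction)
        total += int(ev["deleted"]) + int(ev["amplified"])
    return total


def cin_burden(event_counts: pd.Series,
               cut_points: tuple[float, float] | None = None) -> pd.Series:
    """CIN category per sample from arm-event counts.

    Categories are stable / medium / high split at ``cut_points``; by
    default the cohort's tertiles (counts <= q33 stable, > q67 high).
    """
    counts = event_counts.astype(float)
    if cut_points is None:
        q1, q2 = np.quantile(counts.to_numpy(), [1 / 3, 2 / 3])
    else:
        q1, q2 = cut_points
        if q2 < q1:
            raise ValueError("cut points must be non-decreasing")
    cats = np.where(counts <= q1, "stable",
                    np.where(counts <= q2, "medium", "high"))
    return pd.Series(cats, index=event_counts.index, name="cin_class")


# ---------------------------------------------------------------------------
# intra-tumoral heterogeneity
# ---------------------------------------------------------------------------

MAD_SCALE = 1.4826  # consistency constant making the MAD estimate sigma


def math_score(vafs: Iterable[float]) -> float:
    """Mutant-Allele Tumor Heterogeneity score.

    ``MATH = 100 * (1.4826 * median(|VAF - median(VAF)|)) / median(VAF)``
    over the tumor VAFs of retained somatic variants.
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size < 3:
        raise ValueError("MATH needs at least 3 variants")
    med = float(np.median(v))
    if med <= 0:
        raise ValueError("median VAF is zero; MATH undefined")
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * MAD_SCALE * mad / med


# ---------------------------------------------------------------------------
# Lynch syndrome
# ---------------------------------------------------------------------------

def classify_lynch(variants: pd.DataFrame,
                   vaf_window: tuple[float, float] = (0.3, 0.7),
                   mmr_genes: Iterable[str] = MMR_GENES) -> str:
    """NCCN-flowchart-style Lynch call from one patient's variant table.

    LS-positive iff a pathogenic-flagged variant in a mismatch-repair gene
    sits at germline-like tumor VAF (inside ``vaf_window``), unless the
    only such evidence is MLH1 in the presence of BRAF p.V600E — the
    signature of sporadic (methylation-driven) MSI-H, which is called
    LS-negative.

    Needs columns ``gene``, ``pathogenic``, ``vaf_tumor`` and
    ``aa_change``.
    """
    needed = ["gene", "pathogenic", "vaf_tumor", "aa_change"]
    missing = [c for c in needed if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table lacks annotations: {missing}")
    lo, hi = vaf_window
    braf_v600e = bool(((variants["gene"] == "BRAF")
                       & (variants["aa_change"] == "p.V600E")).any())
    germline_like = variants[
        variants["gene"].isin(list(mmr_genes))
        & variants["pathogenic"].astype(bool)
        & variants["vaf_tumor"].between(lo, hi)]
    qualifying = set(germline_like["gene"])
    if braf_v600e:
        qualifying.discard("MLH1")
    return "LS-positive" if qualifying else "LS-negative"


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceTable:
    """PPA/NPA between a test call set and a reference call set."""

    tp: int
    fp: int
    fn: int
    tn: int
    ppa: float | None
    npa: float | None
    ppa_ci: tuple[float, float] | None
    npa_ci: tuple[float, float] | None


def _exact_ci(successes: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="beta")
    return float(lo), float(hi)


def concordance(calls_test: Iterable[bool],
                calls_reference: Iterable[bool]) -> ConcordanceTable:
    """Positive/negative percent agreement with exact binomial 95% CIs.

    ``PPA = TP / (TP + FN)`` and ``NPA = TN / (TN + FP)`` against the
    reference; intervals are Clopper-Pearson (for x = n the lower bound is
    0.025**(1/n) and the upper bound 1).  An estimate with an empty
    denominator is returned as ``None``.
    """
    test = np.asarray(list(calls_test), dtype=bool)
    ref = np.asarray(list(calls_reference), dtype=bool)
    if test.shape != ref.shape:
        raise ValueError("call vectors must be aligned and equal length")
    tp = int((test & ref).sum())
    fn = int((~test & ref).sum())
    fp = int((test & ~ref).sum())
    tn = int((~test & ~ref).sum())

    ppa = npa = None
    ppa_ci = npa_ci = None
    if tp + fn > 0:
        ppa = tp / (tp + fn)
        ppa_ci = _exact_ci(tp, tp + fn)
    if tn + fp > 0:
        npa = tn / (tn + fp)
        npa_ci = _exact_ci(tn, tn + fp)
    return ConcordanceTable(tp=tp, fp=fp, fn=fn, tn=tn, ppa=ppa, npa=npa,
                            ppa_ci=ppa_ci, npa_ci=npa_ci)


# ---------------------------------------------------------------------------
# per-sample feature extraction driver
# ---------------------------------------------------------------------------

def extract_features(variants: pd.DataFrame, cn_calls: pd.DataFrame,
                     gene_arms: pd.Series, exonic_mb: float = 30.0,
                     event_fraction: float = 0.20,
                     cin_cut_points: tuple[float, float] | None = None,
                     vaf_window: tuple[float, float] = (0.3, 0.7),
                     ) -> pd.DataFrame:
    """TMB, MATH, CIN and Lynch status per sample.

    ``variants`` is a multi-sample table with a ``sample_id`` column;
    ``cn_calls`` is genes x samples.  Samples present in either input are
    reported; MATH is NaN where fewer than 3 variants survive the filter.
    """
    samples = sorted(set(cn_calls.columns)
                     | set(variants.get("sample_id", pd.Series(dtype=str))))
    rows = {}
    for s in samples:
        sub = variants[variants["sample_id"] == s] if len(variants) else \
            variants
        retained, _ = filter_somatic(sub) if len(sub) else (sub, {})
        tmb = compute_tmb(len(retained), exonic_mb)
        try:
            math = math_score(retained["vaf_tumor"]) if len(retained) >= 3 \
                else float("nan")
        except ValueError:
            math = float("nan")
        ls = classify_lynch(retained, vaf_window=vaf_window) \
            if len(retained) else "LS-negative"
        cin_count = count_arm_events(cn_calls[s], gene_arms,
                                     event_fraction) \
            if s in cn_calls.columns else 0
        rows[s] = {"tmb": tmb, "math": math, "cin_count": cin_count,
                   "ls_status": ls}
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    out["cin_count"] = out["cin_count"].astype(int)
    out["cin_class"] = cin_burden(out["cin_count"],
                                  cut_points=cin_cut_points)
    return out
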