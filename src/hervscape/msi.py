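"""Sequencing-based microsatellite-instability scoring.

Sites are noncoding mononucleotide homopolymers of 10-50 bases.  A site is
called unstable when the read-weighted mean repeat length in the tumor
falls outside the reference "known range" (reference mean +/- k standard
deviations of the reference length distribution); the reference is either
the paired normal or a pooled baseline of normal samples.  The MSI score
is the fraction of assessed sites that are unstable, and a sample is
MSI-H when the score reaches the pipeline threshold (>= 0.30 for paired
whole-exome, >= 0.20 for the baseline panel pipeline).  The orthogonal
5-marker PCR rule (two or more altered mononucleotide markers -> MSI-H)
is also provided.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_READS = 20
DEFAULT_K_SD = 3.0
#: MSI-H score thresholds per pipeline mode (inclusive)
MODE_THRESHOLDS = {"paired_wes": 0.30, "baseline_panel": 0.20}
#: the five mononucleotide markers of the PCR panel.  Vendor documentation
#: lists BAT-25 twice; the second entry is named BAT-26 here.
PCR_MARKERS = ("BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27")
MIN_REPEAT, MAX_REPEAT = 10, 50


@dataclass
class MsiResult:
    sample_id: str
    n_assessed: int
    n_unstable: int
    msi_score: float
    classification: str     #: 'MSI-H' or 'MSS'
    pipeline_mode: str


def filter_site_catalog(candidates: pd.DataFrame,
                        exclusion_list: Iterable[str] = (),
                        ) -> pd.DataFrame:
    """Keep noncoding mononucleotide homopolymers of 10-50 bases.

    ``candidates`` needs columns ``site_id``, ``ref_repeat_length``,
    ``noncoding`` and ``repeat_unit``.  ``exclusion_list`` removes named
    sites (standing in for ethnicity-biased or low-coverage panel sites).
    """
    excluded = set(exclusion_list)
    keep = (candidates["noncoding"]
            & candidates["repeat_unit"].str.len().eq(1)
            & candidates["ref_repeat_length"].between(MIN_REPEAT, MAX_REPEAT)
            & ~candidates["site_id"].isin(excluded))
    return candidates[keep].reset_index(drop=True)


def _weighted_stats(histogram: Mapping[int, int]
                    ) -> tuple[float, float, int]:
    """(read-weighted mean, population sd, total reads) of a histogram."""
    if not histogram:
        return np.nan, np.nan, 0
    lengths = np.array(list(histogram.keys()), dtype=float)
    counts = np.array(list(histogram.values()), dtype=float)
    total = counts.sum()
    if total <= 0:
        return np.nan, np.nan, 0
    mean = float((lengths * counts).sum() / total)
    var = float((counts * (lengths - mean) ** 2).sum() / total)
    return mean, float(np.sqrt(var)), int(total)


def assess_site(tumor: Mapping[int, int],
                reference: Mapping[int, int] | Iterable[Mapping[int, int]],
                min_reads: int = DEFAULT_MIN_READS,
                k_sd: float = DEFAULT_K_SD) -> str:
    """Verdict for one site: 'stable', 'unstable' or 'not_assessed'.

    ``reference`` is a single paired-normal histogram or an iterable of
    baseline histograms; baselines are pooled into one combined histogram
    before the known range is formed, so a baseline set of size one is
    exactly the paired computation.  The site is unstable when the tumor
    read-weighted mean length lies outside reference mean +/- k_sd *
    reference sd.  A degenerate zero-sd reference makes any shifted mean
    unstable.
    """
    if isinstance(reference, Mapping):
        reference = [reference]
    pooled: dict[int, int] = {}
    for hist in reference:
        for length, count in hist.items():
            pooled[length] = pooled.get(length, 0) + int(count)

    t_mean, _, t_total = _weighted_stats(tumor)
    r_mean, r_sd, r_total = _weighted_stats(pooled)
    if t_total < min_reads or r_total < min_reads:
        return "not_assessed"
    return "unstable" if abs(t_mean - r_mean) > k_sd * r_sd else "stable"


def msi_score_and_classify(site_verdicts: Iterable[str],
                           pipeline_mode: str = "paired_wes",
                           sample_id: str = "",
                           threshold: float | None = None) -> MsiResult:
    """Roll site verdicts up into the MSI score and MSI-H/MSS call.

    score = unstable / assessed; the classification is MSI-H when the
    score is greater than or equal to the mode's threshold.
    """
    if pipeline_mode not in MODE_THRESHOLDS:
        raise ValueError(f"unknown pipeline mode {pipeline_mode!r}")
    verdicts = list(site_verdicts)
    n_assessed = sum(v != "not_assessed" for v in verdicts)
    n_unstable = sum(v == "unstable" for v in verdicts)
    if n_assessed == 0:
        raise ValueError("MSI score undefined: zero assessed sites")
    if threshold is None:
        threshold = MODE_THRESHOLDS[pipeline_mode]
    score = n_unstable / n_assessed
    return MsiResult(sample_id=sample_id, n_assessed=n_assessed,
                     n_unstable=n_unstable, msi_score=score,
                     classification="MSI-H" if score >= threshold else "MSS",
                     pipeline_mode=pipeline_mode)


def msi_pcr_classify(marker_altered: Mapping[str, bool] | Iterable[bool],
                     ) -> str:
    """PCR five-marker rule: MSI-H when two or more markers are altered.

    Pentanucleotide identity markers (Penta C/D), if present in a mapping,
    are ignored for classification.
    """
    if isinstance(marker_altered, Mapping):
        calls = {k: v for k, v in marker_altered.items()
                 if not k.startswith("Penta")}
        if set(calls) != set(PCR_MARKERS):
            raise ValueError(
                f"expected the 5 mononucleotide markers {PCR_MARKERS}, "
                f"got {sorted(calls)}")
        values = list(calls.values())
    else:
        values = list(marker_altered)
        if len(values) != 5:
            raise ValueError("expected exactly 5 marker calls, got "
                             f"{len(values)}")
    return "MSI-H" if sum(bool(v) for v in values) >= 2 else "not MSI-H"


# ---------------------------------------------------------------------------
# cohort driver over long-format histogram tables
# ---------------------------------------------------------------------------

def _histograms_by_site(hist_df: pd.DataFrame, sample_id: str
                        ) -> dict[str, dict[int, int]]:
    sub = hist_df[hist_df["sample_id"] == sample_id]
    out: dict[str, dict[int, int]] = {}
    for site_id, grp in sub.groupby("site_id"):
        out[str(site_id)] = dict(zip(grp["length"].astype(int),
                                     grp["count"].astype(int)))
    return out


def score_sample(sites: pd.DataFrame, hist_df: pd.DataFrame,
                 sample_id: str, pipeline_mode: str = "paired_wes",
                 baseline_samples: Iterable[str] = (),
                 min_reads: int = DEFAULT_MIN_READS,
                 k_sd: float = DEFAULT_K_SD,
                 threshold: float | None = None) -> MsiResult:
    """Score one tumor sample over a filtered site catalog.

    Paired mode reads the ``<sample_id>.N`` histograms as reference;
    baseline mode pools the named baseline samples.
    """
    tumor = _histograms_by_site(hist_df, sample_id)
    if pipeline_mode == "paired_wes":
        refs = {sid: [h] for sid, h in
                _histograms_by_site(hist_df, f"{sample_id}.N").items()}
    else:
        refs = {}
        for b in baseline_samples:
            for sid, h in _histograms_by_site(hist_df, b).items():
                refs.setdefault(sid, []).append(h)
    verdicts = []
    for site_id in sites["site_id"]:
        t = tumor.get(site_id, {})
        r = refs.get(site_id, [])
        verdicts.append(assess_site(t, r, min_reads=min_reads, k_sd=k_sd)
                        if r else "not_assessed")
    return msi_score_and_classify(verdicts, pipeline_mode=pipeline_mode,
                                  sample_id=sample_id, threshold=threshold)
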