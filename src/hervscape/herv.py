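"""hERV expression quantification and the median.hERV biomarker.

The processing order is fixed: raw counts -> CPM -> noise floor (CPM < 0.5
set to zero) -> expression filter (drop panel transcripts whose median CPM
over tumor samples is below 0.1) -> per-sample median over the retained
panel (``median.hERV``).  The module also provides the 80%/100-round
downsampling robustness study, hierarchical two-cluster subtyping, and
top-fraction dichotomisation used to derive hERV-high labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

DEFAULT_NOISE_FLOOR = 0.5     #: CPM below which a measurement is noise
DEFAULT_MEDIAN_FLOOR = 0.1    #: tumor-median CPM below which a locus is silent
DEFAULT_TOP_FRACTION = 0.30


@dataclass
class ExpressionMatrix:
    """CPM values with per-sample library sizes and tumor flags.

    ``values`` is transcripts x samples.  ``is_tumor`` defaults to all-True
    (whole-transcriptome cohorts here sequence tumor tissue only).
    """

    values: pd.DataFrame
    library_sizes: pd.Series
    is_tumor: pd.Series

    def __post_init__(self) -> None:
        self.library_sizes = self.library_sizes.reindex(self.values.columns)
        self.is_tumor = self.is_tumor.reindex(self.values.columns)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass
class HervPanel:
    """Transcripts retained by the expression filter."""

    transcript_ids: list[str]
    n_reference: int

    @property
    def n_retained(self) -> int:
        return len(self.transcript_ids)


def compute_cpm(counts: pd.DataFrame, library_sizes: pd.Series,
                is_tumor: pd.Series | None = None) -> ExpressionMatrix:
    """Counts-per-million: 1e6 * count / library size, per sample."""
    libs = library_sizes.reindex(counts.columns)
    bad = libs[(libs.isna()) | (libs <= 0)]
    if len(bad):
        raise ValueError(
            "non-positive or missing library size for sample(s): "
            + ", ".join(map(str, bad.index)))
    cpm = counts.div(libs, axis=1) * 1.0e6
    if is_tumor is None:
        is_tumor = pd.Series(True, index=counts.columns)
    return ExpressionMatrix(values=cpm, library_sizes=libs,
                            is_tumor=is_tumor)


def apply_noise_floor(m: ExpressionMatrix,
                      floor: float = DEFAULT_NOISE_FLOOR) -> ExpressionMatrix:
    """Zero out CPM values strictly below ``floor``; values >= floor kept."""
    if floor < 0:
        raise ValueError("noise floor must be >= 0")
    values = m.values.where(m.values >= floor, 0.0)
    return ExpressionMatrix(values=values, library_sizes=m.library_sizes,
                            is_tumor=m.is_tumor)


def filter_expressed(m: ExpressionMatrix, reference_panel: list[str],
                     median_floor: float = DEFAULT_MEDIAN_FLOOR) -> HervPanel:
    """Drop panel transcripts not expressed across tumor samples.

    A transcript is kept when its median CPM over tumor samples only is at
    least ``median_floor`` (strictly-below medians are removed).  Panel ids
    absent from the matrix are ignored.
    """
    tumor_cols = m.is_tumor[m.is_tumor.fillna(False)].index
    if len(tumor_cols) == 0:
        raise ValueError("expression filter needs at least one tumor sample")
    present = [t for t in reference_panel if t in m.values.index]
    medians = m.values.loc[present, tumor_cols].median(axis=1)
    retained = medians[medians >= median_floor].index.tolist()
    return HervPanel(transcript_ids=retained,
                     n_reference=len(reference_panel))


def median_herv(m: ExpressionMatrix, panel: HervPanel) -> pd.Series:
    """Per-sample median CPM over the retained panel (``median.hERV``).

    Even panel sizes use the midpoint-average median.
    """
    if panel.n_retained == 0:
        raise ValueError("cannot compute median.hERV over an empty panel")
    return m.values.loc[panel.transcript_ids].median(axis=0) \
        .rename("median_herv")


def downsampling_robustness(m: ExpressionMatrix, panel: HervPanel,
                            fraction: float = 0.8, rounds: int = 100,
                            seed: int | None = None,
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Panel-downsampling robustness of median.hERV.

    Each round draws ``ceil(fraction * panel size)`` transcripts without
    replacement, recomputes median.hERV and reports the Spearman rank
    correlation with the full-panel score across samples.  Returns the
    per-round score matrix (rounds x samples) and the correlation series.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if panel.n_retained < 2:
        raise ValueError("panel too small to downsample")
    rng = np.random.default_rng(seed)
    full = median_herv(m, panel)
    k = ceil(fraction * panel.n_retained)
    ids = np.asarray(panel.transcript_ids)
    scores = {}
    rhos = {}
    for r in range(rounds):
        sub = ids[rng.choice(panel.n_retained, size=k, replace=False)]
        sub_panel = HervPanel(transcript_ids=list(sub),
                              n_reference=panel.n_reference)
        s = median_herv(m, sub_panel)
        scores[r] = s
        if fraction == 1.0:
            rhos[r] = 1.0
        else:
            rhos[r] = float(spearmanr(full.to_numpy(), s.to_numpy())
                            .statistic)
    return (pd.DataFrame(scores).T,
            pd.Series(rhos, name="spearman_rho"))


def cluster_two(m: ExpressionMatrix, panel: HervPanel) -> pd.Series:
    """Two-group hierarchical subtyping on hERV expression profiles.

    Ward linkage on Euclidean distances over per-transcript z-scored
    log2(CPM + 1) profiles, cut at k = 2.  The cluster with the larger
    median of per-sample median.hERV is labelled ``high``.
    """
    if m.values.shape[1] < 4:
        raise ValueError("clustering needs at least 4 samples")
    logged = np.log2(m.values.loc[panel.transcript_ids] + 1.0)
    sd = logged.std(axis=1, ddof=0)
    variable = logged.loc[sd > 0]
    if variable.empty:
        raise ValueError("all hERV profiles are identical; no two-cluster "
                         "structure exists")
    z = variable.sub(variable.mean(axis=1), axis=0) \
                .div(variable.std(axis=1, ddof=0), axis=0)
    Z = linkage(z.T.to_numpy(), method="ward")
    assignment = fcluster(Z, t=2, criterion="maxclust")
    if len(set(assignment)) < 2:
        raise ValueError("hierarchical clustering collapsed to one cluster")
    score = median_herv(m, panel)
    labels = pd.Series(assignment, index=m.values.columns)
    medians = score.groupby(labels).median()
    high_cluster = medians.idxmax()
    return labels.map(lambda c: "high" if c == high_cluster else "low") \
        .rename("cluster")


def dichotomize_top_fraction(values: pd.Series | np.ndarray,
                             fraction: float = DEFAULT_TOP_FRACTION
                             ) -> np.ndarray | pd.Series:
    """Flag the top ``fraction`` of a distribution.

    The threshold is the (1 - fraction) linear-interpolation quantile and
    every value >= the threshold is flagged, so ties at the threshold are
    all included and the rule is order-independent.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to dichotomize")
    if np.all(finite == finite[0]):
        warnings.warn("all values identical; every sample labelled high",
                      stacklevel=2)
        labels = np.ones_like(arr, dtype=bool)
    else:
        threshold = np.quantile(finite, 1.0 - fraction)  # type-7 / linear
        labels = arr >= threshold
    if isinstance(values, pd.Series):
        return pd.Series(labels, index=values.index)
    return labels
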