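"""Survival stratification: endpoints, subgroups, KM/log-rank and Cox.

Overall survival runs from diagnosis to the endpoint date, relapse-free
survival from surgery; both are expressed in months (30.4375 days).  The
prognostic subgroups are CD8-low/hERV-high (``WTS-``, every other
CD8/hERV combination is ``WTS+``) and the clinicopathological split
(``CP-`` = top-30% age, stage III or right-sided).  Kaplan-Meier and
log-rank statistics and Cox proportional-hazards fits (Efron ties) come
from lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from hervscape.herv import dichotomize_top_fraction

DAYS_PER_MONTH = 30.4375


@dataclass
class GroupSurvival:
    name: str
    n: int
    events: int
    median_months: float | None   #: None when the curve never crosses 0.5


@dataclass
class SurvivalFit:
    groups: list[GroupSurvival] = field(default_factory=list)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    hazard_ratios: pd.DataFrame | None = None  #: per covariate: hr, ci, p
    converged: bool = True


def compute_survival_times(frame: pd.DataFrame) -> pd.DataFrame:
    """OS and RFS durations in months plus event flags from date offsets.

    Expects numeric day offsets (or datetimes) in ``date_diagnosis``,
    ``date_surgery`` and ``date_endpoint`` plus ``death_event`` /
    ``relapse_event`` flags.  OS = endpoint - diagnosis, RFS = endpoint -
    surgery, divided by 30.4375 days per month.  Negative durations are a
    data error, reported with the patient id.
    """
    out = pd.DataFrame(index=frame.index)
    a = _as_days(frame["date_endpoint"])
    for endpoint, start_col, event_col in [
            ("os", "date_diagnosis", "death_event"),
            ("rfs", "date_surgery", "relapse_event")]:
        if start_col not in frame.columns:
            raise ValueError(f"missing {start_col} required for "
                             f"{endpoint.upper()}")
        start = _as_days(frame[start_col])
        days = a - start
        bad = days[days < 0]
        if len(bad):
            raise ValueError(
                f"negative {endpoint.upper()} duration for patient(s): "
                + ", ".join(map(str, bad.index[:5])))
        out[f"{endpoint}_months"] = days / DAYS_PER_MONTH
        out[f"{endpoint}_event"] = frame[event_col].astype(int)
    return out


def _as_days(col: pd.Series) -> pd.Series:
    if np.issubdtype(col.dtype, np.datetime64):
        return (col - col.min()).dt.days.astype(float)
    return col.astype(float)


def assign_wts_group(cd8_fraction: pd.Series, median_herv: pd.Series,
                     fraction: float = 0.30) -> pd.DataFrame:
    """CD8/hERV subgrouping: WTS- iff CD8-low and hERV-high.

    Both markers are dichotomised at the cohort top-``fraction``; the
    poor-prognosis ``WTS-`` cell is low CD8 with high hERV, the other
    three cells are ``WTS+``.
    """
    if len(cd8_fraction) != len(median_herv):
        raise ValueError("cd8 and median.hERV vectors must be aligned")
    cd8_high = dichotomize_top_fraction(cd8_fraction, fraction)
    herv_high = dichotomize_top_fraction(median_herv, fraction)
    wts = np.where(~cd8_high & herv_high, "WTS-", "WTS+")
    return pd.DataFrame({"cd8_high": cd8_high,
                         "herv_high": herv_high,
                         "wts_group": wts}, index=cd8_fraction.index)


def assign_cp_group(age: pd.Series, stage: pd.Series, sidedness: pd.Series,
                    fraction: float = 0.30) -> pd.Series:
    """Clinicopathological split: CP- on unfavourable age, stage or side.

    CP- iff age in the cohort top ``fraction``, stage III, or right-sided;
    otherwise CP+.  Patients with a missing covariate get NA with a
    warning.
    """
    missing = age.isna() | stage.isna() | sidedness.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} patient(s) with missing "
                      "covariates labelled NA", stacklevel=2)
    age_filled = age.fillna(age.median())
    age_high = dichotomize_top_fraction(age_filled, fraction)
    unfavourable = age_high | (stage == "III") | (sidedness == "right")
    labels = pd.Series(np.where(unfavourable, "CP-", "CP+"),
                       index=age.index, name="cp_group")
    labels[missing] = pd.NA
    return labels


def km_logrank(times: pd.Series, events: pd.Series,
               groups: pd.Series) -> SurvivalFit:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    times = pd.Series(times).astype(float)
    events = pd.Series(events).astype(int)
    groups = pd.Series(groups)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    levels = [g for g in groups.dropna().unique()]
    if len(levels) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")

    fit = SurvivalFit()
    for g in sorted(map(str, levels)):
        mask = groups.astype(str) == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        med = kmf.median_survival_time_
        fit.groups.append(GroupSurvival(
            name=g, n=int(mask.sum()), events=int(events[mask].sum()),
            median_months=None if np.isinf(med) else float(med)))
    res = multivariate_logrank_test(times, groups.astype(str), events)
    fit.logrank_stat = float(res.test_statistic)
    fit.logrank_p = float(res.p_value)
    return fit


def cox_fit(times: pd.Series, events: pd.Series,
            covariates: pd.DataFrame,
            mode: str = "multivariate") -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald 95% CIs).

    ``mode='univariate'`` fits one single-covariate model per column;
    ``mode='multivariate'`` fits them jointly.  Non-convergence is
    reported through ``converged=False`` rather than silent defaults.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    base = pd.DataFrame({"_time": pd.Series(times).astype(float),
                         "_event": pd.Series(events).astype(int)})
    cov = covariates.apply(pd.to_numeric, errors="raise")
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")

    column_sets = [[c] for c in cov.columns] if mode == "univariate" \
        else [list(cov.columns)]
    rows = []
    converged = True
    for cols in column_sets:
        df = pd.concat([base, cov[cols]], axis=1)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError:
            converged = False
            for c in cols:
                rows.append({"covariate": c, "coef": np.nan, "hr": np.nan,
                             "hr_ci_low": np.nan, "hr_ci_high": np.nan,
                             "p": np.nan})
            continue
        summary = cph.summary
        for c in cols:
            rows.append({
                "covariate": c,
                "coef": float(summary.loc[c, "coef"]),
                "hr": float(summary.loc[c, "exp(coef)"]),
                "hr_ci_low": float(summary.loc[c, "exp(coef) lower 95%"]),
                "hr_ci_high": float(summary.loc[c, "exp(coef) upper 95%"]),
                "p": float(summary.loc[c, "p"]),
            })
    table = pd.DataFrame(rows).set_index("covariate")
    return SurvivalFit(hazard_ratios=table, converged=converged)


def two_by_two_test(table: np.ndarray) -> tuple[float, str]:
    """Two-sided test on a 2x2 count table.

    Continuity-corrected chi-square two-proportion test, falling back to
    Fisher's exact test when any expected cell is below 5.  Returns (p,
    method); a table with an empty margin returns (nan, 'NA').
    """
    from scipy.stats import chi2_contingency, fisher_exact

    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if table.sum() == 0 or table.sum(axis=1).min() == 0:
        return float("nan"), "NA"
    expected = (table.sum(axis=1)[:, None]
                * table.sum(axis=0)[None, :]) / table.sum()
    if (expected < 5).any() or table.min() < 5:
        return float(fisher_exact(table)[1]), "fisher"
    return float(chi2_contingency(table, correction=True)[1]), "chi2_cc"


def enrichment_test(label_a: pd.Series, label_b: pd.Series
                    ) -> pd.DataFrame:
    """Two-sided enrichment p-values for every category pair.

    For each (category of a, category of b) the 2x2 membership table is
    tested with :func:`two_by_two_test`.  Empty categories yield NA.
    """
    a = pd.Series(label_a).astype(str)
    b = pd.Series(label_b).astype(str)
    rows = []
    for ca in sorted(a.dropna().unique()):
        for cb in sorted(b.dropna().unique()):
            in_a, in_b = (a == ca), (b == cb)
            table = np.array([
                [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
                [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())]])
            p, method = two_by_two_test(table)
            rows.append({"category_a": ca, "category_b": cb, "p": p,
                         "method": method})
    return pd.DataFrame(rows)
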