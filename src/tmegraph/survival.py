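"""Survival and clinical-association statistics for patient subgroups.

Thin, validated wrappers around lifelines: Kaplan-Meier curves per
subgroup, the G-sample (multivariate) log-rank test, and per-subgroup Cox
proportional-hazards fits of a single in/out indicator (patients outside
the subgroup are the baseline; Efron tie handling; p-value from the
log-likelihood-ratio test).  Association helpers use Spearman rank
correlation and the Mann-Whitney U test.  All p-values are two-sided and
reported without multiple-testing correction; apply your own if you screen
many patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


def km_estimate(
    times: np.ndarray, events: np.ndarray, grouping: pd.Series | np.ndarray | None = None
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a frame with columns ``time``, ``survival`` and
    ``at_risk``; with ``grouping=None`` a single ``all`` curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if grouping is None:
        grouping = np.repeat("all", times.size)
    grouping = np.asarray(grouping)
    out = {}
    for g in pd.unique(grouping):
        mask = grouping == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(),
             "survival": sf.iloc[:, 0].to_numpy(),
             "at_risk": at_risk.to_numpy()}
        )
    return out


def multivariate_logrank(
    times: np.ndarray, events: np.ndarray, grouping: np.ndarray
) -> tuple[float, int, float]:
    """G-sample log-rank test; returns (chi2 statistic, df = G-1, p)."""
    grouping = np.asarray(grouping)
    groups = pd.unique(grouping)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), grouping, np.asarray(events, dtype=int)
    )
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def pairwise_logrank(
    times: np.ndarray, events: np.ndarray, mask_a: np.ndarray
) -> tuple[float, float]:
    """Two-sample log-rank between ``mask_a`` and its complement: (chi2, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    mask_a = np.asarray(mask_a, dtype=bool)
    if mask_a.all() or (~mask_a).all():
        raise ValueError("both groups must be nonempty")
    res = logrank_test(times[mask_a], times[~mask_a], events[mask_a], events[~mask_a])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float  # log-likelihood-ratio test
    n_in: int
    n_out: int
    estimable: bool = True
    message: str = ""


def cox_subgroup_hr(
    times: np.ndarray, events: np.ndarray, indicator: np.ndarray
) -> CoxResult:
    """Hazard ratio of a binary subgroup indicator vs the rest of the cohort.

    Univariate Cox PH fit (Efron ties); 95 % CI from the coefficient's
    normal approximation; p from the log-likelihood-ratio test.  Degenerate
    inputs (a level without events, or perfect separation) are reported as
    non-estimable rather than raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ind = np.asarray(indicator, dtype=int)
    n_in, n_out = int(ind.sum()), int((1 - ind).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("indicator must have both levels")
    for level in (0, 1):
        if events[ind == level].sum() == 0:
            msg = f"no events at indicator level {level}; hazard ratio non-estimable"
            logger.warning(msg)
            return CoxResult(np.nan, np.nan, np.nan, np.nan, n_in, n_out, False, msg)
    df = pd.DataFrame({"time": times, "event": events, "in_group": ind})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        msg = f"Cox fit failed: {exc}"
        logger.warning(msg)
        return CoxResult(np.nan, np.nan, np.nan, np.nan, n_in, n_out, False, msg)
    ci = cph.confidence_intervals_.loc["in_group"]
    llr = cph.log_likelihood_ratio_test()
    with np.errstate(over="ignore"):  # wide CIs on tiny subgroups may hit inf
        hr = float(np.exp(cph.params_["in_group"]))
        ci_low, ci_high = float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))
    return CoxResult(
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(llr.p_value),
        n_in=n_in,
        n_out=n_out,
    )


def subgroup_survival_report(
    times: np.ndarray, events: np.ndarray, subgroups: pd.Series
) -> tuple[pd.DataFrame, tuple[float, int, float]]:
    """Per-subgroup Cox hazard ratios (subgroup vs rest) plus the overall log-rank.

    Subgroups of size 1 or without both indicator levels are reported with
    NaN estimates.  Returns (report frame indexed by subgroup, (chi2, df, p)).
    """
    labels = np.asarray(subgroups)
    rows = {}
    for g in sorted(pd.unique(labels)):
        ind = (labels == g).astype(int)
        try:
            res = cox_subgroup_hr(times, events, ind)
        except ValueError as exc:
            res = CoxResult(np.nan, np.nan, np.nan, np.nan, int(ind.sum()),
                            int(len(ind) - ind.sum()), False, str(exc))
        rows[str(g)] = {
            "n": res.n_in, "hr": res.hr, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p, "estimable": res.estimable,
        }
    overall = multivariate_logrank(times, events, labels)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subgroup"), overall


# ---------------------------------------------------------------------------
# clinical associations


def spearman_association(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p; NaN pairs dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        return float("nan"), float("nan")  # constant vector: undefined
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two independent samples."""
    res = stats.mannwhitneyu(np.asarray(a, float), np.asarray(b, float),
                             alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def associate_with_clinical(
    subgroups: pd.Series, clinical: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Spearman correlations between subgroup membership and clinical one-hots.

    Each (subgroup indicator, clinical-category indicator or numeric column)
    pair yields a row with rho and two-sided p; missing clinical values are
    dropped pairwise.
    """
    common = subgroups.index.intersection(clinical.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping patients")
    sub = subgroups.loc[common]
    clin = clinical.loc[common]
    columns = columns or list(clin.columns)
    rows = []
    for g in sorted(sub.unique()):
        ind = (sub == g).astype(float).to_numpy()
        for col in columns:
            series = clin[col]
            if series.dtype.kind in "ifu":
                variables = {col: series.astype(float).to_numpy()}
            else:
                variables = {
                    f"{col}={val}": (series == val).astype(float).where(series.notna()).to_numpy()
                    for val in sorted(series.dropna().unique())
                }
            for name, vec in variables.items():
                try:
                    rho, p = spearman_association(ind, vec)
                except ValueError:
                    rho, p = float("nan"), float("nan")
                rows.append({"subgroup": str(g), "clinical": name, "rho": rho, "p": p})
    return pd.DataFrame(rows)
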