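"""Statistical procedures for simulated cohorts.

Rank-sum comparison (Wilcoxon–Mann–Whitney), rank-based ROC/AUC,
a complete/near-complete separation diagnostic, Kaplan–Meier product-limit
curves, the log-rank test, and tertile stratification of the cohort's
time-to-peak delay feature.

The separation diagnostic exists because a predictor that (nearly)
perfectly splits the outcome classes makes logistic-regression likelihoods
diverge; rather than fitting a divergent model, the overlap between classes
is measured and flagged explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .cohort import CohortResult

__all__ = [
    "GroupComparison",
    "SurvivalCurve",
    "SeparationDiagnostic",
    "mann_whitney_u",
    "roc_auc",
    "detect_complete_separation",
    "kaplan_meier",
    "log_rank",
    "tertile_split",
    "km_by_delay_tertiles",
]


@dataclass(frozen=True)
class GroupComparison:
    """Test statistic, two-sided p-value and group sizes for a comparison."""

    statistic: float
    p_value: float
    group_sizes: tuple
    method: str


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit step function with at-risk and event counts."""

    times: np.ndarray      # distinct observed times, ascending
    survival: np.ndarray   # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        """S(t): product over event times <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "events": self.events,
            "group": self.label,
        })


@dataclass(frozen=True)
class SeparationDiagnostic:
    """Flag plus overlap fraction for (near-)complete class separation."""

    separated: bool
    overlap_fraction: float
    n_overlap: int


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum comparison.

    Midranks handle ties; the p-value uses exact enumeration when the
    combined sample is small (n <= 10) and tie-free, and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(a.size, b.size),
        method=f"mann-whitney-{method}",
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the rank statistic."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("AUC is undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def detect_complete_separation(
    scores: Sequence[float],
    labels: Sequence[int],
    near_fraction: float = 0.05,
) -> SeparationDiagnostic:
    """Flag complete or near-complete stratification of classes by a score.

    Complete: the score ranges of the two classes are disjoint. Near-complete:
    the overlap interval [min positive score, max negative score] contains
    fewer than ``near_fraction`` of all subjects.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if pos.min() > neg.max() or neg.min() > pos.max():
        return SeparationDiagnostic(True, 0.0, 0)  # disjoint score ranges
    lo = max(pos.min(), neg.min())
    hi = min(pos.max(), neg.max())
    inside = int(np.sum((scores >= lo) & (scores <= hi)))
    frac = inside / scores.size
    return SeparationDiagnostic(frac < near_fraction, float(frac), inside)


def kaplan_meier(
    event_times: Sequence[float],
    event_observed: Sequence[int],
    label: str = "",
) -> SurvivalCurve:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    times = np.asarray(event_times, dtype=float)
    observed = np.asarray(event_observed, dtype=int)
    if np.any(times < 0):
        raise ValueError("event times must be nonnegative")
    if times.shape != observed.shape:
        raise ValueError("event_times and event_observed must align")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 else kmf.event_table
    tt = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(tt).to_numpy(dtype=float)
    return SurvivalCurve(
        times=tt,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        label=label,
    )


def log_rank(groups: Sequence[tuple]) -> GroupComparison:
    """Log-rank chi-square across k groups of (event_times, observed flags)."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    times, observed, membership, sizes = [], [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        times.append(t)
        observed.append(e)
        membership.append(np.full(t.size, g))
        sizes.append(int(t.size))
    observed_all = np.concatenate(observed)
    if observed_all.sum() == 0:
        raise ValueError("log-rank is degenerate with no events in any group")
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(membership), observed_all
    )
    return GroupComparison(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=tuple(sizes),
        method=f"log-rank-{len(groups)}-group",
    )


def tertile_split(values: Sequence[float]) -> np.ndarray:
    """Assign tertile 1/2/3 by the empirical 1/3 and 2/3 quantiles.

    Values equal to a boundary fall in the lower tertile; a degenerate
    (all-identical) input collapses into tertile 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot split empty values")
    b1, b2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    if b1 == b2 and np.all(values == values[0]):
        warnings.warn("all values identical; every subject assigned to tertile 1")
    out = np.full(values.size, 3, dtype=int)
    out[values <= b2] = 2
    out[values <= b1] = 1
    return out


def km_by_delay_tertiles(cohort: CohortResult):
    """Survival curves by tertile of time-to-peak Y, plus their log-rank test.

    Event-positive subjects "fail" at the simulated time their output Y
    peaks; event-free subjects are censored at the end of the simulation
    window. Returns ``(curves, comparison, tertiles)``.
    """
    tpk = np.array([m.time_to_peak_y for m in cohort.metrics])
    if np.unique(tpk).size < 3:
        raise ValueError("need at least 3 distinct time-to-peak values to stratify")
    ev = np.array([m.event_cv for m in cohort.metrics])
    t_end = cohort.trajectories[0].grid.t_end
    times = np.where(ev == 1, tpk, t_end)
    tert = tertile_split(tpk)
    curves = []
    groups = []
    for g in (1, 2, 3):
        mask = tert == g
        curves.append(kaplan_meier(times[mask], ev[mask], label=f"T{g}"))
        groups.append((times[mask], ev[mask]))
    comparison = log_rank(groups) if ev.sum() > 0 else None
    return curves, comparison, tert
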