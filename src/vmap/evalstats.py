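"""Discrimination, survival curves, risk dichotomization, impact analysis.

Time-dependent discrimination follows the cumulative/dynamic convention
on the discrete bin grid: at horizon bin m the positives are maps known
to need (more) ablation by m — Category 1, plus Category 2 with event
bin <= m — and the negatives are maps known event-free through m —
Category 3, Category 2 with a later event bin, and maps censored at or
after m.  Maps censored before m are excluded.  The AUC is the exact
pairwise probability P(score_pos > score_neg) + 0.5 P(tie).

Kaplan-Meier curves and log-rank tests are delegated to lifelines behind
this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import rankdata

from .errors import InputError, ThresholdError, UndefinedMetricError
from .network import ModelOutput

PRE, EVENT, EVENT_FREE, CENSORED = 1, 2, 3, 0


@dataclass
class EvalResult:
    """Container for pooled evaluation outputs."""

    auc_by_bin: dict = field(default_factory=dict)  # task -> list[(m, auc or None)]
    c_stat: dict = field(default_factory=dict)  # task -> 1-year AUC
    c_stat_post_only: dict = field(default_factory=dict)
    per_fold: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def risk_score(output, m: int, mode: str = "prognosis"):
    """Completeness risk of output vector(s) at horizon bin m.

    Prognosis mode scores Categories 1 and 2 against 3: p_pre + F(m).
    Practice mode scores Category 1 against 2 and 3: p_pre.
    Accepts a single (K+2,) vector or a (B, K+2) batch.
    """
    p = np.asarray(output, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    K = p.shape[1] - 2
    if not 1 <= m <= K:
        raise InputError(f"horizon bin {m} out of range 1..{K}")
    if mode == "prognosis":
        score = p[:, 0] + p[:, 1 : m + 1].sum(axis=1)
    elif mode == "practice":
        score = p[:, 0]
    else:
        raise InputError(f"unknown decision mode {mode!r}")
    return float(score[0]) if single else score


def auc_masks(status: np.ndarray, bins: np.ndarray, m: int) -> tuple:
    """(positive, negative) membership masks at horizon bin m."""
    status = np.asarray(status)
    bins = np.asarray(bins)
    pos = (status == PRE) | ((status == EVENT) & (bins <= m))
    neg = (
        (status == EVENT_FREE)
        | ((status == EVENT) & (bins > m))
        | ((status == CENSORED) & (bins >= m))
    )
    return pos, neg


def time_dependent_auc(scores, status, bins, m: int) -> float:
    """Exact pairwise AUC at horizon bin m (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = auc_masks(status, bins, m)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined at bin {m}: {n_pos} positives, {n_neg} negatives"
        )
    # midrank formulation: identical to exhaustive pair counting with ties
    pooled = np.concatenate([scores[pos], scores[neg]])
    ranks = rankdata(pooled)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_curve(scores, status, bins, n_bins: int) -> list:
    """AUC at every horizon bin; None where a class is empty."""
    out = []
    for m in range(1, n_bins + 1):
        try:
            out.append((m, time_dependent_auc(scores, status, bins, m)))
        except UndefinedMetricError:
            out.append((m, None))
    return out


def km_curve(times, events) -> tuple:
    """Product-limit estimate; returns (event times, S(t) at those times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise InputError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()


def km_at(times, events, t: float) -> float:
    """S(t) from the product-limit step function."""
    grid, surv = km_curve(times, events)
    idx = np.searchsorted(grid, t, side="right") - 1
    return float(surv[idx]) if idx >= 0 else 1.0


def logrank_test(times_a, events_a, times_b, events_b) -> tuple:
    """Two-group log-rank (chi-square, p); chi-square from chi2(1)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise UndefinedMetricError("log-rank requires two non-empty groups")
    if events_a.sum() + events_b.sum() == 0:
        raise UndefinedMetricError("log-rank undefined without any events")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def dichotomize(scores, status, bins, m: int) -> float:
    """Training-set threshold maximizing the Youden index at bin m.

    Candidate thresholds are midpoints between consecutive distinct
    sorted scores; classification is score > theta -> Incomplete.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = auc_masks(status, bins, m)
    if pos.sum() == 0 or neg.sum() == 0:
        raise ThresholdError("dichotomization needs at least one positive and one negative")
    used = pos | neg
    s, p = scores[used], pos[used]
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ThresholdError("all scores identical; no threshold separates the groups")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_theta, best_j = candidates[0], -np.inf
    n_pos, n_neg = p.sum(), (~p).sum()
    for theta in candidates:
        called = s > theta
        sens = np.sum(called & p) / n_pos
        spec = np.sum(~called & ~p) / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_theta = j, theta
    return float(best_theta)


def classify(score, theta: float):
    """'Incomplete' if the risk score exceeds the threshold, else 'Complete'."""
    score = np.asarray(score, dtype=float)
    labels = np.where(score > theta, "Incomplete", "Complete")
    return labels.item() if labels.ndim == 0 else labels


def task_time_event(df: pd.DataFrame, task: str) -> tuple:
    if task == "union":
        event_day = df["recurrence_day"]
    else:
        col = "pvi_event_day" if task == "PVI" else "bepvi_event_day"
        event_day = df[col]
    has_event = event_day.notna().to_numpy()
    times = np.where(
        has_event, event_day.to_numpy(dtype=float, na_value=0.0), df["followup_end_day"]
    ).astype(float)
    return times, has_event


def ablation_impact_analysis(
    table: pd.DataFrame, incomplete: dict, horizon_days: float = 365.0
) -> dict:
    """Compare additional vs no-additional ablation within risk strata.

    ``table`` needs the manifest outcome columns plus ``additional_after``;
    ``incomplete`` maps task -> boolean array (model-called Incomplete) of
    the same length.  For PVI and beyond-PVI the event is a same-target
    redo; for the 'union' contrast any recurrence counts and a map is
    Incomplete if either task calls it Incomplete.  Empty strata or
    eventless contrasts are reported, not raised.
    """
    results: dict = {}
    inc_union = np.asarray(incomplete["PVI"]) | np.asarray(incomplete["bePVI"])
    for task in ("PVI", "bePVI", "union"):
        inc = inc_union if task == "union" else np.asarray(incomplete[task])
        times, events = task_time_event(table, task)
        additional = table["additional_after"].to_numpy(dtype=bool)
        per_task: dict = {}
        for stratum, mask in (("Incomplete", inc), ("Complete", ~inc)):
            g_add = mask & additional
            g_no = mask & ~additional
            entry: dict = {
                "n_additional": int(g_add.sum()),
                "n_no_additional": int(g_no.sum()),
            }
            try:
                chi2, p = logrank_test(times[g_add], events[g_add], times[g_no], events[g_no])
                entry["logrank_chi2"], entry["logrank_p"] = chi2, p
                entry["km_1y_additional"] = km_at(times[g_add], events[g_add], horizon_days)
                entry["km_1y_no_additional"] = km_at(times[g_no], events[g_no], horizon_days)
            except UndefinedMetricError as err:
                entry["logrank_chi2"] = entry["logrank_p"] = None
                entry["reason"] = str(err)
            per_task[stratum] = entry
        results[task] = per_task
    return results
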