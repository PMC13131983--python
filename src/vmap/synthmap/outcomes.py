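"""Discrete-time outcome simulation with administrative right censoring.

Each task (redo-PVI, redo-beyond-PVI) has a piecewise-constant discrete
hazard over bins of the 1-year horizon:

    h = logistic(beta0 + beta1 * feature)

where the feature is the mean PV gap fraction for PVI and the
low-voltage burden for beyond-PVI.  Event bins are geometric draws with
that per-bin hazard (events may fall beyond the horizon); the event day
is uniform within its bin.  Follow-up ends at an administrative
censoring day drawn uniformly from a configured window, and an event is
recorded only if it precedes the end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ..errors import ConfigurationError
from .phantom import Phantom

TASKS = ("PVI", "bePVI")


@dataclass(frozen=True)
class HazardConfig:
    """Per-task logistic hazards and the censoring window (days)."""

    beta0_pvi: float = -5.0
    beta1_pvi: float = 6.0
    beta0_bepvi: float = -5.0
    beta1_bepvi: float = 12.0
    n_bins: int = 12
    horizon_days: float = 365.0
    censor_min_days: float = 180.0
    censor_max_days: float = 730.0

    def __post_init__(self):
        if self.n_bins < 1:
            raise ConfigurationError("need at least one hazard bin")
        if not (0.0 < self.censor_min_days <= self.censor_max_days <= 2.0 * self.horizon_days):
            raise ConfigurationError("censoring window must lie within (0, 2*horizon]")

    def hazard(self, task: str, feature: float) -> float:
        """Per-bin event probability for a task given its driving feature."""
        if task == "PVI":
            eta = self.beta0_pvi + self.beta1_pvi * feature
        elif task == "bePVI":
            eta = self.beta0_bepvi + self.beta1_bepvi * feature
        else:
            raise ConfigurationError(f"unknown task {task!r}")
        return float(np.clip(expit(eta), 1e-12, 1.0 - 1e-12))

    def one_year_event_probability(self, task: str, feature: float) -> float:
        """Closed-form P(event within the horizon) ignoring censoring."""
        h = self.hazard(task, feature)
        return 1.0 - (1.0 - h) ** self.n_bins


@dataclass
class OutcomeRecord:
    """Simulated follow-up of one patient after one ablation session.

    Days count from the end of the session.  ``target_known=False``
    means a recurrence happened but the redo target was not identified,
    so both task-specific event days are withheld (the labeling stage
    censors such maps just before the recurrence).
    """

    pvi_event_day: float | None
    bepvi_event_day: float | None
    recurrence_day: float | None
    followup_end_day: float
    target_known: bool = True
    censor_reason: str = "none"

    def event_day(self, task: str) -> float | None:
        return self.pvi_event_day if task == "PVI" else self.bepvi_event_day

    def validate(self) -> None:
        for day in (self.pvi_event_day, self.bepvi_event_day, self.recurrence_day):
            if day is not None and not (0.0 <= day <= self.followup_end_day):
                raise ConfigurationError("event days must lie within follow-up")


def _draw_event_day(rng: np.random.Generator, hazard: float, bin_width: float) -> float:
    """Geometric bin draw, day uniform within the bin (in (e_{k-1}, e_k])."""
    k = int(rng.geometric(hazard))
    return (k - rng.uniform()) * bin_width


def simulate_outcomes(
    phantom: Phantom, hz: HazardConfig, seed: int | np.random.Generator
) -> OutcomeRecord:
    """Draw one follow-up trajectory from the phantom's current state."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return simulate_outcomes_from_features(phantom.gap_mean, phantom.lv_burden, hz, rng)


def simulate_outcomes_from_features(
    gap_mean: float, lv_burden: float, hz: HazardConfig, seed: int | np.random.Generator
) -> OutcomeRecord:
    """Outcome draw given the driving features directly.

    With both slopes at zero this yields outcomes independent of the
    substrate — the null-control configuration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bin_width = hz.horizon_days / hz.n_bins
    raw_pvi = _draw_event_day(rng, hz.hazard("PVI", gap_mean), bin_width)
    raw_bep = _draw_event_day(rng, hz.hazard("bePVI", lv_burden), bin_width)
    censor = rng.uniform(hz.censor_min_days, hz.censor_max_days)

    pvi = raw_pvi if raw_pvi <= censor else None
    bep = raw_bep if raw_bep <= censor else None
    earliest = min(raw_pvi, raw_bep)
    recurrence = earliest if earliest <= censor else None
    reason = "none"
    if recurrence is None and censor < hz.horizon_days:
        reason = "follow-up ended"
    return OutcomeRecord(
        pvi_event_day=pvi,
        bepvi_event_day=bep,
        recurrence_day=recurrence,
        followup_end_day=float(censor),
        target_known=True,
        censor_reason=reason,
    )
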