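"""Censored three-category labels per task and follow-up discretization.

Every map gets one label per task (PVI, beyond-PVI), assigned
independently:

* Category 1 (pre-intervention): that task's ablation happened after the
  map within the same session.
* Category 2 (event): a same-target redo occurred within the 1-year
  horizon; carries the discrete event bin.
* Category 3 (event-free): followed at least one year without a
  same-target redo.
* Censored: follow-up ended before one year, or a recurrence occurred
  whose redo target is unknown; carries the last fully survived bin.

The horizon is discretized into K equal bins (monthly by default); all
downstream metrics accept an arbitrary bin scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InputError, LabelingError
from .synthmap.cohort import Dataset
from .synthmap.outcomes import TASKS, OutcomeRecord

#: sentinel returned by bin_index for days beyond the horizon
BEYOND_HORIZON = None


class Category(Enum):
    """Ablation-completeness status of a map for one task."""

    PRE = 1  # Category 1: acquired before the task's ablation
    EVENT = 2  # Category 2: same-target redo within the horizon
    EVENT_FREE = 3  # Category 3: no same-target redo for >= 1 year
    CENSORED = 0


@dataclass(frozen=True)
class BinScheme:
    """K bins partitioning (0, H] days; bin k covers (edge_{k-1}, edge_k]."""

    edges: tuple

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 1 or np.any(np.diff(e) <= 0) or e[0] <= 0:
            raise InputError("bin edges must be strictly increasing and positive")

    @classmethod
    def equal(cls, n_bins: int = 12, horizon_days: float = 365.0) -> "BinScheme":
        return cls(edges=tuple(horizon_days * (k + 1) / n_bins for k in range(n_bins)))

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def horizon_days(self) -> float:
        return float(self.edges[-1])


@dataclass(frozen=True)
class TaskLabel:
    task: str
    status: Category
    event_bin: int | None = None  # 1..K, present iff status == EVENT
    censor_bin: int | None = None  # 0..K, present iff status == CENSORED

    def __post_init__(self):
        if (self.event_bin is not None) != (self.status is Category.EVENT):
            raise InputError("event_bin present iff status is EVENT")
        if (self.censor_bin is not None) != (self.status is Category.CENSORED):
            raise InputError("censor_bin present iff status is CENSORED")


def bin_index(day: float, scheme: BinScheme):
    """1-based bin of a day; BEYOND_HORIZON for days past the last edge."""
    if day <= 0:
        raise InputError("day must be positive")
    if day > scheme.horizon_days:
        return BEYOND_HORIZON
    edges = np.asarray(scheme.edges)
    return int(np.searchsorted(edges, day, side="left")) + 1


def survived_bins(day: float, scheme: BinScheme, inclusive: bool = True) -> int:
    """Number of bins fully survived by a subject observed up to `day`.

    ``inclusive`` counts a bin whose right edge equals the observation
    day as survived (administrative end of follow-up); an event AT the
    edge day belongs to that bin, so unknown-target recurrences use
    ``inclusive=False``.
    """
    edges = np.asarray(scheme.edges)
    side = "right" if inclusive else "left"
    return int(np.searchsorted(edges, day, side=side))


def assign_category(
    pvi_after: bool, bepvi_after: bool, outcome: OutcomeRecord, scheme: BinScheme
) -> dict:
    """Label one map for both tasks from its timing flags and outcome."""
    flags = {"PVI": pvi_after, "bePVI": bepvi_after}
    horizon = scheme.horizon_days
    labels = {}
    for task in TASKS:
        if flags[task]:
            labels[task] = TaskLabel(task=task, status=Category.PRE)
            continue
        if outcome is None or outcome.followup_end_day is None:
            raise LabelingError(f"post-intervention map for {task} lacks follow-up")
        event = outcome.event_day(task)
        if event is not None and event <= horizon:
            labels[task] = TaskLabel(
                task=task, status=Category.EVENT, event_bin=bin_index(event, scheme)
            )
            continue
        unknown = (
            outcome.recurrence_day
            if (not outcome.target_known and outcome.recurrence_day is not None)
            else None
        )
        if unknown is not None and unknown <= horizon:
            labels[task] = TaskLabel(
                task=task,
                status=Category.CENSORED,
                censor_bin=survived_bins(unknown, scheme, inclusive=False),
            )
            continue
        if outcome.followup_end_day >= horizon:
            labels[task] = TaskLabel(task=task, status=Category.EVENT_FREE)
            continue
        labels[task] = TaskLabel(
            task=task,
            status=Category.CENSORED,
            censor_bin=survived_bins(outcome.followup_end_day, scheme, inclusive=True),
        )
    return labels


def build_label_table(dataset: Dataset, scheme: BinScheme | None = None) -> pd.DataFrame:
    """One row per map with both task labels flattened into columns."""
    scheme = scheme or BinScheme.equal()
    rows = []
    for s in dataset.samples:
        try:
            labels = assign_category(s.pvi_after, s.bepvi_after, s.outcome, scheme)
        except LabelingError as err:
            raise LabelingError(f"map {s.map_id}: {err}") from err
        row = {"map_id": s.map_id, "patient_id": s.patient_id}
        for task, prefix in (("PVI", "pvi"), ("bePVI", "bepvi")):
            lab = labels[task]
            row[f"{prefix}_status"] = lab.status.value
            row[f"{prefix}_bin"] = (
                lab.event_bin if lab.status is Category.EVENT else lab.censor_bin
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("pvi_bin", "bepvi_bin"):
        df[col] = df[col].astype(float).fillna(0).astype(int)
    return df
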