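"""Three-category labeling rules, bin arithmetic, and an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmap.errors import InputError, LabelingError
from vmap.labeling import (
    BEYOND_HORIZON,
    BinScheme,
    Category,
    assign_category,
    bin_index,
    build_label_table,
)
from vmap.synthmap import OutcomeRecord
from vmap.synthmap.cohort import Dataset, MapSample


def record(pvi=None, bepvi=None, recurrence=None, followup=400.0, known=True):
    if recurrence is None and (pvi is not None or bepvi is not None):
        recurrence = min(d for d in (pvi, bepvi) if d is not None)
    return OutcomeRecord(
        pvi_event_day=pvi,
        bepvi_event_day=bepvi,
        recurrence_day=recurrence,
        followup_end_day=followup,
        target_known=known,
    )


class TestBinIndex:
    def test_edges(self, bin_scheme):
        assert bin_index(1.0, bin_scheme) == 1
        assert bin_index(365.0, bin_scheme) == 12  # closed right edge
        assert bin_index(365.0 / 12, bin_scheme) == 1
        assert bin_index(366.0, bin_scheme) is BEYOND_HORIZON

    def test_nonpositive_day_rejected(self, bin_scheme):
        with pytest.raises(InputError):
            bin_index(0.0, bin_scheme)

    def test_custom_edges_must_increase(self):
        with pytest.raises(InputError):
            BinScheme(edges=(100.0, 50.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        day=st.floats(min_value=1e-6, max_value=365.0, exclude_min=True),
        n_bins=st.integers(min_value=1, max_value=24),
    )
    def test_day_lies_inside_its_bin(self, day, n_bins):
        scheme = BinScheme.equal(n_bins=n_bins)
        k = bin_index(day, scheme)
        edges = (0.0,) + scheme.edges
        assert edges[k - 1] < day <= edges[k]
        # a bin that may contain an event at `day` is never counted survived
        from vmap.labeling import survived_bins

        assert survived_bins(day, scheme, inclusive=False) == k - 1
        assert survived_bins(day, scheme, inclusive=True) == (k if day == edges[k] else k - 1)


class TestAssignCategory:
    def test_pre_intervention_wins_regardless_of_outcome(self, bin_scheme):
        labels = assign_category(True, False, record(pvi=10.0, bepvi=20.0), bin_scheme)
        assert labels["PVI"].status is Category.PRE
        assert labels["bePVI"].status is Category.EVENT

    def test_full_followup_without_redo_is_event_free(self, bin_scheme):
        labels = assign_category(False, False, record(followup=400.0), bin_scheme)
        assert labels["PVI"].status is Category.EVENT_FREE
        assert labels["bePVI"].status is Category.EVENT_FREE

    def test_event_bin_and_censor_bin_arithmetic(self, bin_scheme):
        # redo-PVI at day 200 falls in bin 7 of the monthly grid
        labels = assign_category(False, False, record(pvi=200.0), bin_scheme)
        assert labels["PVI"].status is Category.EVENT
        assert labels["PVI"].event_bin == 7
        # follow-up ending at day 100 fully survives bins 1..3
        labels = assign_category(False, False, record(followup=100.0), bin_scheme)
        assert labels["PVI"].status is Category.CENSORED
        assert labels["PVI"].censor_bin == 3

    def test_unknown_redo_target_censors_before_recurrence(self, bin_scheme):
        out = record(recurrence=91.25, followup=400.0, known=False)
        labels = assign_category(False, False, out, bin_scheme)
        # an event AT an edge day belongs to that bin: only 2 bins survived
        assert labels["PVI"].status is Category.CENSORED
        assert labels["PVI"].censor_bin == 2
        assert labels["bePVI"].censor_bin == 2

    def test_event_beyond_horizon_is_event_free(self, bin_scheme):
        labels = assign_category(False, False, record(pvi=400.0, followup=500.0), bin_scheme)
        assert labels["PVI"].status is Category.EVENT_FREE

    def test_missing_followup_raises(self, bin_scheme):
        out = OutcomeRecord(None, None, None, followup_end_day=None)
        with pytest.raises(LabelingError):
            assign_category(False, False, out, bin_scheme)

    def test_pvi_outcome_never_changes_bepvi_label(self, bin_scheme):
        base = record(pvi=50.0, bepvi=200.0, followup=400.0)
        permuted = record(pvi=300.0, bepvi=200.0, followup=400.0)
        for flags in ((False, False), (True, False), (False, True)):
            a = assign_category(*flags, base, bin_scheme)["bePVI"]
            b = assign_category(*flags, permuted, bin_scheme)["bePVI"]
            assert a == b


def _oracle_label(after: bool, out: OutcomeRecord, edges, task: str):
    """Straight-line re-statement of the rules using explicit loops."""
    H = edges[-1]
    if after:
        return ("PRE", None)
    event = out.pvi_event_day if task == "PVI" else out.bepvi_event_day
    if event is not None and event <= H:
        k = 1
        while event > edges[k - 1]:
            k += 1
        return ("EVENT", k)
    if not out.target_known and out.recurrence_day is not None and out.recurrence_day <= H:
        c = 0
        for e in edges:
            if e < out.recurrence_day:
                c += 1
        return ("CENSORED", c)
    if out.followup_end_day >= H:
        return ("FREE", None)
    c = 0
    for e in edges:
        if e <= out.followup_end_day:
            c += 1
    return ("CENSORED", c)


def test_labeling_agrees_with_independent_oracle(bin_scheme):
    """10^4 randomized (flags, outcome) tuples, all censoring branches."""
    rng = np.random.default_rng(123)
    edges = list(bin_scheme.edges)
    name_of = {Category.PRE: "PRE", Category.EVENT: "EVENT",
               Category.EVENT_FREE: "FREE", Category.CENSORED: "CENSORED"}
    for _ in range(10_000):
        followup = float(rng.uniform(1.0, 730.0))
        if rng.uniform() < 0.2:  # hit bin boundaries exactly
            followup = float(rng.choice(edges))
        def day():
            if rng.uniform() < 0.5:
                return None
            d = float(rng.uniform(0.5, followup))
            if rng.uniform() < 0.2:
                d = float(min(rng.choice(edges), followup))
            return d
        pvi, bep = day(), day()
        known = bool(rng.uniform() < 0.8) if (pvi or bep) else True
        rec_day = min(d for d in (pvi, bep) if d is not None) if (pvi or bep) else None
        out = OutcomeRecord(
            pvi_event_day=None if not known else pvi,
            bepvi_event_day=None if not known else bep,
            recurrence_day=rec_day,
            followup_end_day=followup,
            target_known=known,
        )
        flags = (bool(rng.uniform() < 0.3), bool(rng.uniform() < 0.3))
        labels = assign_category(flags[0], flags[1], out, bin_scheme)
        for task, after in zip(("PVI", "bePVI"), flags):
            got = labels[task]
            want_status, want_bin = _oracle_label(after, out, edges, task)
            assert name_of[got.status] == want_status, (out, flags, task)
            got_bin = got.event_bin if got.status is Category.EVENT else got.censor_bin
            assert got_bin == want_bin, (out, flags, task)


def _fake_dataset(outcomes, flags):
    samples = [
        MapSample(
            patient_id=f"P{i:03d}", session_id="S1", acq_index=j, role="pre" if f[0] else "post",
            images=np.zeros((4, 8, 8, 3), dtype=np.uint8),
            pvi_after=f[0], bepvi_after=f[1], additional_after=False,
            gap_mean=0.0, lv_burden=0.0, final_gap_mean=0.0, final_lv_burden=0.0,
            outcome=out,
        )
        for i, (out, fs) in enumerate(zip(outcomes, flags))
        for j, f in enumerate(fs)
    ]
    return Dataset(samples=samples)


def test_label_table_on_pre_post_pairs(bin_scheme):
    outcomes = [record(followup=400.0)] * 10
    flags = [[(True, True), (False, False)]] * 10
    table = build_label_table(_fake_dataset(outcomes, flags), bin_scheme)
    assert len(table) == 20
    assert (table.pvi_status == Category.PRE.value).sum() == 10
    assert (table.pvi_status == Category.EVENT_FREE.value).sum() == 10


def test_label_table_early_censoring(bin_scheme):
    outcomes = [record(followup=30.0)] * 5
    flags = [[(True, True), (False, False)]] * 5
    table = build_label_table(_fake_dataset(outcomes, flags), bin_scheme)
    post = table[table.pvi_status == Category.CENSORED.value]
    assert len(post) == 5
    assert (post.pvi_bin == 0).all()
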