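"""End-to-end study workflows on simulated cohorts.

These functions bundle the full pipeline — simulate a cohort, train under
patient-grouped cross-validation, pool predictions, and run the survival
analyses — for the two standard experiment designs:

* the planted-effect study, where lesion gaps and residual low-voltage
  burden drive the redo hazards, and
* the null-control study, where outcomes are re-simulated independently
  of the substrate, so no image feature carries outcome information.

The default desk-scale study uses 400 patients rendered at side 64 with
the generator's planted hazard slopes; training runs 30 epochs per fold
(early-stopped on a held-in validation split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evalstats
from .crossval import CrossvalResult, TrainConfig, run_crossval
from .labeling import BinScheme
from .losses import LossConfig
from .network import ArchConfig
from .synthmap import (
    CohortConfig,
    Dataset,
    HazardConfig,
    OperatorConfig,
    randomize_outcomes,
    simulate_cohort,
)

#: intercept-only hazards for the null control, matched to a realistic
#: ~20% 1-year event rate per task
NULL_HAZARD = HazardConfig(beta0_pvi=-4.0, beta1_pvi=0.0, beta0_bepvi=-4.0, beta1_bepvi=0.0)

DEFAULT_TRAIN = TrainConfig(epochs=30, patience=8, learning_rate=2e-3, batch_size=32)


@dataclass
class StudyResult:
    dataset: Dataset
    cv: CrossvalResult
    table: pd.DataFrame  # pooled predictions joined with the manifest


def run_study(
    n_patients: int = 400,
    image_size: int = 64,
    seed: int = 7,
    train_cfg: TrainConfig | None = None,
    k: int = 5,
    null_outcomes: bool = False,
) -> StudyResult:
    """Simulate, cross-validate, and join predictions with ground truth."""
    dataset = simulate_cohort(CohortConfig(n_patients=n_patients, image_size=image_size), seed)
    if null_outcomes:
        dataset = randomize_outcomes(dataset, NULL_HAZARD, seed=seed + 1)
    scheme = BinScheme.equal()
    cv = run_crossval(
        dataset,
        scheme=scheme,
        arch=ArchConfig(side=image_size, n_bins=scheme.n_bins),
        loss_cfg=LossConfig(),
        train_cfg=train_cfg or DEFAULT_TRAIN,
        k=k,
        seed=seed,
    )
    table = cv.pooled.merge(dataset.manifest(), on=["map_id", "patient_id"], validate="1:1")
    return StudyResult(dataset=dataset, cv=cv, table=table)


def end_of_session_maps(table: pd.DataFrame) -> pd.DataFrame:
    """Maps acquired at the end of a session (no further lesion delivery)."""
    return table[~table.additional_after].reset_index(drop=True)


def prognosis_stratification(table: pd.DataFrame) -> dict:
    """Incomplete- vs Complete-called end-of-session maps, any recurrence."""
    end = end_of_session_maps(table)
    inc = (end.pvi_incomplete | end.bepvi_incomplete).to_numpy()
    times, events = evalstats.task_time_event(end, "union")
    chi2, p = evalstats.logrank_test(times[inc], events[inc], times[~inc], events[~inc])
    return {
        "chi2": chi2,
        "p": p,
        "n_incomplete": int(inc.sum()),
        "n_complete": int((~inc).sum()),
        "km_1y_incomplete": evalstats.km_at(times[inc], events[inc], 365.0),
        "km_1y_complete": evalstats.km_at(times[~inc], events[~inc], 365.0),
    }


def additional_ablation_impact(table: pd.DataFrame) -> dict:
    """The additional-ablation contrast on intra-procedural (post) maps."""
    post = table[table.role == "post"].reset_index(drop=True)
    incomplete = {
        "PVI": post.pvi_incomplete.to_numpy(),
        "bePVI": post.bepvi_incomplete.to_numpy(),
    }
    return evalstats.ablation_impact_analysis(post, incomplete)


def one_year_recurrence_rate(dataset: Dataset) -> float:
    """Kaplan-Meier 1-year any-recurrence probability at the patient level."""
    mf = dataset.manifest()
    per_patient = mf.groupby("patient_id").first()
    has_event = per_patient.recurrence_day.notna().to_numpy()
    times = np.where(
        has_event,
        per_patient.recurrence_day.to_numpy(dtype=float, na_value=0.0),
        per_patient.followup_end_day.to_numpy(dtype=float),
    )
    return 1.0 - evalstats.km_at(times, has_event, 365.0)


def saliency_pv_ring_ratio(study: StudyResult, n_maps: int = 8) -> float:
    """How much the PVI saliency concentrates on the PV encircling rings.

    Runs SmoothGrad for the PVI prognosis target on post-ablation maps
    from fold 0's held-out set (predicted by fold 0's model), then
    compares mean saliency over pixels that render the PV ring bands
    against mean saliency over all anatomy pixels, averaged across the
    four views.  A ratio above 1 means the model looks where the lesion
    gaps live; the quantity is reported, not asserted, because saliency
    concentration is qualitative.
    """
    from .network import preprocess
    from .saliency import SmoothGradConfig, smoothgrad
    from .synthmap import PhantomConfig, get_mesh, pv_sites
    from .synthmap.mesh import VIEWS

    model = study.cv.models[0]
    scheme_k = model.arch.n_bins
    fold0 = set(study.cv.pooled[study.cv.pooled.fold == 0].map_id)
    samples = [
        s for s in study.dataset.samples if s.map_id in fold0 and s.role == "post"
    ][:n_maps]

    pcfg = PhantomConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in study.dataset.config_echo["config"]["phantom"].items()
    })
    mesh = get_mesh(pcfg.semi_axes, pcfg.subdivisions)
    ring = np.zeros(mesh.n_vertices, dtype=bool)
    for site in pv_sites(mesh, pcfg.radii_by_pv()):
        dist = np.linalg.norm(mesh.vertices - site.center, axis=1)
        ring |= (dist > site.radius) & (dist <= site.radius + pcfg.ring_width)

    cfg = SmoothGradConfig(task="PVI", mode="prognosis", horizon_bin=scheme_k, seed=0)
    ratios = []
    for s in samples:
        heat = smoothgrad(model, preprocess(s.images), cfg)
        size = s.images.shape[1]
        for vi, view in enumerate(VIEWS):
            mask, vidx = mesh.pixel_map(view, size)
            ring_px = mask & ring[vidx]
            if ring_px.sum() == 0:
                continue
            anatomy_mean = heat[vi][mask].mean()
            if anatomy_mean > 0:
                ratios.append(heat[vi][ring_px].mean() / anatomy_mean)
    return float(np.mean(ratios))


def noeffect_additional_sign(seed: int, n_patients: int = 120) -> float:
    """One null draw of the additional-ablation contrast.

    Simulates a cohort whose additional ablation changes nothing
    (closure and substrate effect both zero), stratifies post maps as
    Incomplete by the TRUE substrate features, and returns the 1-year KM
    survival difference (additional minus none) in the Incomplete
    stratum.  Under this null the sign of the difference is a coin flip.
    """
    op = OperatorConfig(additional_gap_closure=0.0, additional_bepvi_effect=0.0)
    cfg = CohortConfig(n_patients=n_patients, image_size=64, operator=op)
    ds = simulate_cohort(cfg, seed)
    mf = ds.manifest()
    post = mf[mf.role == "post"].reset_index(drop=True)
    inc = (
        (post.gap_mean > op.gap_tolerance) | (post.lv_burden > op.burden_tolerance)
    ).to_numpy()
    add = post.additional_after.to_numpy(dtype=bool)
    times, events = evalstats.task_time_event(post, "union")
    s_add = evalstats.km_at(times[inc & add], events[inc & add], 365.0)
    s_no = evalstats.km_at(times[inc & ~add], events[inc & ~add], 365.0)
    return s_add - s_no
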