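"""Cohort simulation and on-disk dataset format.

One simulated patient is one ablation session: a pre-ablation map, a
post-ablation map after the initial lesion set, and — when the operator
reacts to an incomplete-looking map — a final map after additional
ablation.  Outcomes are simulated from the phantom state at the end of
the session, so additional ablation that truly closes gaps lowers the
redo hazard: the planted effect behind the additional-ablation impact
analysis.

On disk a dataset is plain text + PNG: one RGB image per view named
``{patient}_{session}_{index}_{view}.png``, a ``manifest.csv`` with one
row per map, and a ``config.json`` provenance echo.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ..errors import ConfigurationError, DatasetError
from .mesh import VIEWS
from .outcomes import HazardConfig, OutcomeRecord, simulate_outcomes
from .phantom import BePviEffect, PhantomConfig, PviEffect, apply_ablation, generate_phantom
from .render import ColorScale, render_views


@dataclass(frozen=True)
class OperatorConfig:
    """Stochastic model of the ablating operator.

    The initial PVI leaves each PV fully encircled with probability
    ``1 - p_pv_gap``, otherwise a residual gap with fraction drawn from
    ``gap_range``.  Beyond-PVI is attempted when the pre-ablation
    low-voltage burden exceeds ``bepvi_indication`` and then performed
    with probability ``p_bepvi``.  After seeing the post map, an
    incomplete result (mean gap or residual burden above tolerance)
    triggers additional ablation with probability ``p_additional``;
    additional ablation closes ``additional_gap_closure`` of each
    remaining gap and treats ``additional_bepvi_effect`` of the residual
    burden.  A recurrence loses its redo-target identity with
    probability ``p_unknown_target`` (those cases are censored by the
    labeling rules).
    """

    p_pv_gap: float = 0.4
    gap_range: tuple = (0.1, 0.6)
    bepvi_indication: float = 0.05
    p_bepvi: float = 0.7
    bepvi_effect_range: tuple = (0.5, 0.9)
    p_additional: float = 0.5
    gap_tolerance: float = 0.02
    burden_tolerance: float = 0.10
    additional_gap_closure: float = 1.0
    additional_bepvi_effect: float = 0.8
    p_unknown_target: float = 0.05


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    hazard: HazardConfig = field(default_factory=HazardConfig)
    operator: OperatorConfig = field(default_factory=OperatorConfig)
    color_scale: ColorScale = field(default_factory=ColorScale)
    image_size: int = 256

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("need at least one patient")


@dataclass
class MapSample:
    """Four co-registered view images plus their place in the session.

    ``pvi_after`` / ``bepvi_after`` flag whether that task's ablation
    occurred after this map within the same session (the Category 1
    condition).  ``additional_after`` flags whether any further lesion
    delivery followed this map — the contrast of the additional-ablation
    impact analysis.  Ground-truth phantom features at acquisition and at
    session end are carried along for oracle checks and diagnostics.
    """

    patient_id: str
    session_id: str
    acq_index: int
    role: str  # pre | post | final
    images: np.ndarray  # (4, S, S, 3) uint8 in AP, PA, INF, SUP order
    pvi_after: bool
    bepvi_after: bool
    additional_after: bool
    gap_mean: float
    lv_burden: float
    final_gap_mean: float
    final_lv_burden: float
    outcome: OutcomeRecord

    @property
    def map_id(self) -> str:
        return f"{self.patient_id}_{self.session_id}_{self.acq_index}"


# a map sample IS the four-view image set; keep both names
MapImageSet = MapSample


@dataclass
class Dataset:
    samples: list
    config_echo: dict = field(default_factory=dict)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            o = s.outcome
            rows.append(
                {
                    "map_id": s.map_id,
                    "patient_id": s.patient_id,
                    "session_id": s.session_id,
                    "acq_index": s.acq_index,
                    "role": s.role,
                    "pvi_after": s.pvi_after,
                    "bepvi_after": s.bepvi_after,
                    "additional_after": s.additional_after,
                    "gap_mean": s.gap_mean,
                    "lv_burden": s.lv_burden,
                    "final_gap_mean": s.final_gap_mean,
                    "final_lv_burden": s.final_lv_burden,
                    "pvi_event_day": o.pvi_event_day,
                    "bepvi_event_day": o.bepvi_event_day,
                    "recurrence_day": o.recurrence_day,
                    "followup_end_day": o.followup_end_day,
                    "target_known": o.target_known,
                    "censor_reason": o.censor_reason,
                }
            )
        return pd.DataFrame(rows)


def _config_echo(config: CohortConfig, seed: int) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {"seed": seed, "config": encode(config)}


def simulate_cohort(config: CohortConfig, seed: int) -> Dataset:
    """Simulate a full cohort of sessions; deterministic in (config, seed)."""
    op = config.operator
    hz = config.hazard
    root = np.random.SeedSequence(seed)
    samples: list[MapSample] = []

    for p_idx, child in enumerate(root.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        pid = f"P{p_idx:04d}"
        sid = "S1"
        phantom_pre = generate_phantom(config.phantom, rng)

        # initial lesion set decided up front so the pre map's flags are known
        gaps = tuple(
            float(rng.uniform(*op.gap_range)) if rng.uniform() < op.p_pv_gap else 0.0
            for _ in range(4)
        )
        gap_centers = tuple(float(rng.uniform(-np.pi, np.pi)) for _ in range(4))
        bepvi_indicated = phantom_pre.lv_burden > op.bepvi_indication
        do_bepvi = bool(bepvi_indicated and rng.uniform() < op.p_bepvi)
        bepvi_effect = float(rng.uniform(*op.bepvi_effect_range))

        phantom_post = apply_ablation(
            phantom_pre, "PVI", PviEffect(gaps=gaps, gap_centers=gap_centers)
        )
        if do_bepvi:
            phantom_post = apply_ablation(phantom_post, "bePVI", BePviEffect(bepvi_effect))

        incomplete = (
            phantom_post.gap_mean > op.gap_tolerance
            or phantom_post.lv_burden > op.burden_tolerance
        )
        do_additional = bool(incomplete and rng.uniform() < op.p_additional)
        add_pvi = bool(do_additional and phantom_post.gap_mean > op.gap_tolerance)
        add_bepvi = bool(do_additional and phantom_post.lv_burden > op.burden_tolerance)

        phantom_final = phantom_post
        if add_pvi:
            closed = tuple(
                g * (1.0 - op.additional_gap_closure) for g in
                (phantom_post.gaps[name] for name in ("LSPV", "LIPV", "RSPV", "RIPV"))
            )
            phantom_final = apply_ablation(
                phantom_final, "PVI", PviEffect(gaps=closed, gap_centers=gap_centers)
            )
        if add_bepvi:
            phantom_final = apply_ablation(
                phantom_final, "bePVI", BePviEffect(op.additional_bepvi_effect)
            )

        outcome = simulate_outcomes(phantom_final, hz, rng)
        if (
            outcome.recurrence_day is not None
            and rng.uniform() < op.p_unknown_target
        ):
            outcome.pvi_event_day = None
            outcome.bepvi_event_day = None
            outcome.target_known = False
            outcome.censor_reason = "redo-target unknown"

        def emit(idx, role, phantom, pvi_after, bepvi_after, additional_after):
            samples.append(
                MapSample(
                    patient_id=pid,
                    session_id=sid,
                    acq_index=idx,
                    role=role,
                    images=render_views(phantom, config.color_scale, config.image_size),
                    pvi_after=pvi_after,
                    bepvi_after=bepvi_after,
                    additional_after=additional_after,
                    gap_mean=phantom.gap_mean,
                    lv_burden=phantom.lv_burden,
                    final_gap_mean=phantom_final.gap_mean,
                    final_lv_burden=phantom_final.lv_burden,
                    outcome=outcome,
                )
            )

        emit(0, "pre", phantom_pre, True, do_bepvi or add_bepvi, True)
        emit(1, "post", phantom_post, add_pvi, add_bepvi, do_additional)
        if do_additional:
            emit(2, "final", phantom_final, False, False, False)

    return Dataset(samples=samples, config_echo=_config_echo(config, seed))


def randomize_outcomes(dataset: Dataset, hz: HazardConfig, seed: int) -> Dataset:
    """Re-simulate every session's outcome independently of the phantom.

    Hazards are evaluated at zero features, so with any slopes the event
    process reduces to the intercept-only hazard — the null-control
    counterpart of a planted-effect cohort.  Images and flags are shared
    with the input dataset; only the outcome records are replaced.
    """
    from .outcomes import simulate_outcomes_from_features

    sessions: dict = {}
    root = np.random.SeedSequence(seed)
    keys = sorted({(s.patient_id, s.session_id) for s in dataset.samples})
    for key, child in zip(keys, root.spawn(len(keys))):
        rng = np.random.default_rng(child)
        sessions[key] = simulate_outcomes_from_features(0.0, 0.0, hz, rng)
    samples = [
        dataclasses.replace(s, outcome=sessions[(s.patient_id, s.session_id)])
        for s in dataset.samples
    ]
    echo = dict(dataset.config_echo)
    echo["outcomes_randomized"] = {"seed": seed, "hazard": _config_echo_value(hz)}
    return Dataset(samples=samples, config_echo=echo)


def _config_echo_value(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_echo_value(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return obj


# ----------------------------------------------------------------------
# on-disk format

_BOOL_COLS = ("pvi_after", "bepvi_after", "additional_after", "target_known")
_OPTIONAL_DAY_COLS = ("pvi_event_day", "bepvi_event_day", "recurrence_day")


def write_dataset(dataset: Dataset, directory) -> Path:
    """Write PNGs + manifest.csv + config.json; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in dataset.samples:
        for vi, view in enumerate(VIEWS):
            Image.fromarray(s.images[vi]).save(directory / f"{s.map_id}_{view}.png")
    manifest_path = directory / "manifest.csv"
    # %.17g round-trips IEEE doubles exactly through text
    dataset.manifest().to_csv(manifest_path, index=False, float_format="%.17g")
    (directory / "config.json").write_text(json.dumps(dataset.config_echo, indent=2))
    return manifest_path


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_dataset(directory) -> Dataset:
    """Read a dataset back; inverse of write_dataset on every field and pixel."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise DatasetError(f"no manifest.csv under {directory}")
    df = pd.read_csv(manifest_path, float_precision="round_trip")
    n_png = len(list(directory.glob("*.png")))
    if n_png != 4 * len(df):
        raise DatasetError(
            f"manifest lists {len(df)} maps but found {n_png} view images (expected {4 * len(df)})"
        )
    config_echo = {}
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        config_echo = json.loads(cfg_path.read_text())

    samples = []
    for row in df.itertuples(index=False):
        images = []
        for view in VIEWS:
            path = directory / f"{row.map_id}_{view}.png"
            if not path.exists():
                raise DatasetError(f"missing {view} view image for map {row.map_id}")
            images.append(np.asarray(Image.open(path).convert("RGB")))
        outcome = OutcomeRecord(
            pvi_event_day=_opt_float(row.pvi_event_day),
            bepvi_event_day=_opt_float(row.bepvi_event_day),
            recurrence_day=_opt_float(row.recurrence_day),
            followup_end_day=float(row.followup_end_day),
            target_known=bool(row.target_known),
            censor_reason=str(row.censor_reason),
        )
        samples.append(
            MapSample(
                patient_id=str(row.patient_id),
                session_id=str(row.session_id),
                acq_index=int(row.acq_index),
                role=str(row.role),
                images=np.stack(images),
                pvi_after=bool(row.pvi_after),
                bepvi_after=bool(row.bepvi_after),
                additional_after=bool(row.additional_after),
                gap_mean=float(row.gap_mean),
                lv_burden=float(row.lv_burden),
                final_gap_mean=float(row.final_gap_mean),
                final_lv_burden=float(row.final_lv_burden),
                outcome=outcome,
            )
        )
    return Dataset(samples=samples, config_echo=config_echo)
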