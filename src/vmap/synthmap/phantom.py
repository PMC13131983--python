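"""Parametric left-atrial phantoms: voltage substrate and ablation lesions.

A phantom is the simulator's ground truth.  It carries a per-vertex
bipolar voltage field on the ellipsoid shell, an explicit lesion mask,
and the two summary features that drive simulated outcomes:

* per-PV encircling-lesion gap fraction ``g`` (1 = no lesion at all,
  0 = fully encircled) whose mean drives redo-PVI hazard, and
* low-voltage burden ``b``: the area fraction of the non-PV surface
  that is below the low-voltage threshold and NOT yet ablated, which
  drives redo-beyond-PVI hazard.

Lesioned tissue is rendered at the (very low) lesion voltage but is
excluded from ``b`` because ablated scar is treated, not arrhythmogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import ConfigurationError, InputError
from .mesh import PV_NAMES, ShellMesh, get_mesh, pv_sites, ring_angles

TASKS = ("PVI", "bePVI")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and substrate parameters of the synthetic left atrium.

    Voltages are in mV, lengths in mm.  The healthy baseline field is
    log-normal: spatially smooth noise enters the log so that low-voltage
    regions form contiguous patches rather than salt-and-pepper speckle.
    """

    semi_axes: tuple = (35.0, 30.0, 28.0)
    pv_radius: float = 6.0  # scalar or per-PV via pv_radii
    pv_radii: dict | None = None
    ring_width: float = 4.0
    baseline_median_mv: float = 1.5
    baseline_sigma: float = 0.7  # dispersion of log-voltage
    lesion_voltage_mv: float = 0.05
    low_voltage_threshold_mv: float = 0.5
    lv_patch_count: tuple = (0, 3)  # inclusive range
    lv_patch_radius: tuple = (5.0, 15.0)
    lv_patch_severity: tuple = (0.6, 1.0)  # fractional voltage reduction
    smooth_iterations: int = 12
    subdivisions: int = 5
    seed: int = 0

    def __post_init__(self):
        axes = np.asarray(self.semi_axes, dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise ConfigurationError("semi_axes must be three positive lengths")
        radii = self.radii_by_pv()
        if max(radii.values()) >= axes.min():
            raise ConfigurationError("PV radii must be smaller than the smallest semi-axis")
        lo, hi = self.lv_patch_severity
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("severity range must lie within [0, 1]")
        if self.lv_patch_count[0] > self.lv_patch_count[1] or self.lv_patch_count[0] < 0:
            raise ConfigurationError("invalid low-voltage patch count range")
        if self.baseline_median_mv <= 0 or self.lesion_voltage_mv < 0:
            raise ConfigurationError("voltages must be non-negative (median positive)")

    def radii_by_pv(self) -> dict:
        if self.pv_radii is not None:
            return {name: float(self.pv_radii[name]) for name in PV_NAMES}
        return {name: float(self.pv_radius) for name in PV_NAMES}


@dataclass(frozen=True)
class PviEffect:
    """Encircling lesions around each PV with per-PV gap fractions.

    ``gaps`` are fractions of the ring circumference left unablated, in
    LSPV/LIPV/RSPV/RIPV order; ``gap_centers`` are angles (rad) of the
    gap midpoints around each PV axis (0 = posterior-facing side).
    """

    gaps: tuple = (0.0, 0.0, 0.0, 0.0)
    gap_centers: tuple = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.gaps) != 4 or any(not 0.0 <= g <= 1.0 for g in self.gaps):
            raise InputError("gap fractions must be four values in [0, 1]")


@dataclass(frozen=True)
class BePviEffect:
    """Substrate ablation: fraction of low-voltage burden to lesion."""

    fraction: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise InputError("be-PVI effect fraction must lie in [0, 1]")


@dataclass
class Phantom:
    """Ground-truth state of one left atrium at one moment in time."""

    config: PhantomConfig
    voltage: np.ndarray  # (n_vertices,) mV, >= 0
    lesion: np.ndarray  # (n_vertices,) bool
    gaps: dict = field(default_factory=lambda: {name: 1.0 for name in PV_NAMES})

    @property
    def mesh(self) -> ShellMesh:
        return get_mesh(self.config.semi_axes, self.config.subdivisions)

    @property
    def pv_sites(self):
        return pv_sites(self.mesh, self.config.radii_by_pv())

    @property
    def gap_mean(self) -> float:
        """Mean PV gap fraction; 1.0 before any PVI, 0.0 when fully encircled."""
        return float(np.mean([self.gaps[name] for name in PV_NAMES]))

    def _non_pv_mask(self) -> np.ndarray:
        """Vertices outside every PV ostium disk and encircling-ring band."""
        mesh = self.mesh
        keep = np.ones(mesh.n_vertices, dtype=bool)
        for site in self.pv_sites:
            dist = np.linalg.norm(mesh.vertices - site.center, axis=1)
            keep &= dist > site.radius + self.config.ring_width
        return keep

    @property
    def lv_burden(self) -> float:
        """Area fraction of untreated low voltage on the non-PV surface."""
        mesh = self.mesh
        eligible = self._non_pv_mask()
        low = (self.voltage < self.config.low_voltage_threshold_mv) & ~self.lesion
        areas = mesh.vertex_areas
        return float(areas[eligible & low].sum() / areas[eligible].sum())

    def copy(self) -> "Phantom":
        return Phantom(
            config=self.config,
            voltage=self.voltage.copy(),
            lesion=self.lesion.copy(),
            gaps=dict(self.gaps),
        )


def _check_geometry(config: PhantomConfig) -> None:
    mesh = get_mesh(config.semi_axes, config.subdivisions)
    sites = pv_sites(mesh, config.radii_by_pv())
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            min_sep = a.radius + b.radius
            if np.linalg.norm(a.center - b.center) <= min_sep:
                raise ConfigurationError(
                    f"PV ostia {a.name} and {b.name} overlap for this geometry"
                )


def generate_phantom(config: PhantomConfig, seed: int | np.random.Generator | None = None) -> Phantom:
    """Sample a pre-ablation phantom: healthy baseline plus diseased patches.

    Deterministic in (config, seed).  The returned phantom has no lesions
    and all PV gap fractions equal to 1 (nothing encircled yet).
    """
    _check_geometry(config)
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mesh = get_mesh(config.semi_axes, config.subdivisions)

    noise = mesh.correlated_noise(rng, config.smooth_iterations)
    voltage = np.exp(np.log(config.baseline_median_mv) + config.baseline_sigma * noise)

    lo, hi = config.lv_patch_count
    n_patches = int(rng.integers(lo, hi + 1))
    for _ in range(n_patches):
        direction = rng.standard_normal(3)
        center = mesh.surface_point(direction)
        radius = rng.uniform(*config.lv_patch_radius)
        severity = rng.uniform(*config.lv_patch_severity)
        dist = np.linalg.norm(mesh.vertices - center, axis=1)
        # full severity inside the patch, linear falloff in a 30% halo
        # (a border zone, as around clinical low-voltage areas)
        core = dist <= radius
        halo = (dist > radius) & (dist <= 1.3 * radius)
        voltage[core] *= 1.0 - severity
        t = (dist[halo] - radius) / (0.3 * max(radius, 1e-9))
        voltage[halo] *= 1.0 - severity * (1.0 - t)

    return Phantom(
        config=config,
        voltage=voltage,
        lesion=np.zeros(mesh.n_vertices, dtype=bool),
    )


def apply_ablation(phantom: Phantom, task: str, effect) -> Phantom:
    """Return a new phantom with lesions applied; the input is unmodified.

    ``task='PVI'`` places an encircling lesion ring around each PV with
    the stated gap fraction (gap fraction 1 leaves the ring untouched).
    ``task='bePVI'`` lesions the stated fraction of the current
    low-voltage burden, lowest-voltage tissue first (the densest
    substrate is the natural first target).
    """
    if task not in TASKS:
        raise InputError(f"unknown task {task!r}; expected one of {TASKS}")
    out = phantom.copy()
    cfg = phantom.config
    mesh = phantom.mesh

    if task == "PVI":
        if not isinstance(effect, PviEffect):
            raise InputError("PVI ablation requires a PviEffect")
        for site, g, center_angle in zip(out.pv_sites, effect.gaps, effect.gap_centers):
            dist = np.linalg.norm(mesh.vertices - site.center, axis=1)
            ring = (dist > site.radius) & (dist <= site.radius + cfg.ring_width)
            if g < 1.0:
                idx = np.where(ring)[0]
                ang = ring_angles(mesh, site, idx)
                rel = np.angle(np.exp(1j * (ang - center_angle)))
                in_gap = np.abs(rel) < np.pi * g
                target = idx[~in_gap]
                out.lesion[target] = True
                out.voltage[target] = cfg.lesion_voltage_mv
            out.gaps[site.name] = float(g)
        return out

    if not isinstance(effect, BePviEffect):
        raise InputError("be-PVI ablation requires a BePviEffect")
    eligible = out._non_pv_mask()
    low = eligible & (out.voltage < cfg.low_voltage_threshold_mv) & ~out.lesion
    idx = np.where(low)[0]
    if len(idx) == 0 or effect.fraction == 0.0:
        return out
    areas = mesh.vertex_areas[idx]
    order = np.argsort(out.voltage[idx], kind="stable")
    cum = np.cumsum(areas[order])
    target_area = effect.fraction * areas.sum()
    n_take = int(np.searchsorted(cum, target_area, side="left") + 1)
    chosen = idx[order[:n_take]]
    out.lesion[chosen] = True
    out.voltage[chosen] = cfg.lesion_voltage_mv
    return out
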