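"""Triangulated ellipsoid shell and orthographic view geometry.

The left atrium is idealized as an ellipsoid whose surface carries the
bipolar voltage field.  The surface is discretized as a subdivided
icosphere (>= 10^4 faces at the default subdivision) so that area
integrals (low-voltage burden, lesion coverage) are accurate well below
the pixel scale of a 256x256 rendering.

Rendering uses analytic orthographic ray casting against the ellipsoid:
for every pixel the front-facing surface point is computed in closed
form and mapped to its nearest mesh vertex, whose voltage supplies the
pixel colour.  Pixel -> vertex lookup tables are cached per (geometry,
view, image size), which makes rendering a whole cohort cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh
from scipy import sparse
from scipy.spatial import cKDTree

# Patient-based coordinate frame:
#   +x: patient left, +y: posterior, +z: superior (units: mm).
# Each view is (name, view direction d pointing INTO the scene from the
# camera, image-right axis u, image-up axis v).
VIEWS = ("AP", "PA", "INF", "SUP")

_VIEW_FRAMES = {
    # camera anterior, looking posterior; patient left on image right
    "AP": (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    # camera posterior, looking anterior; mirror of AP
    "PA": (np.array([0.0, -1.0, 0.0]), np.array([-1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    # camera below, looking superior
    "INF": (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])),
    # camera above, looking inferior
    "SUP": (np.array([0.0, 0.0, -1.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0])),
}

# Canonical unit directions of the four pulmonary vein ostia on the
# posterior aspect of the shell (LSPV, LIPV, RSPV, RIPV).
PV_NAMES = ("LSPV", "LIPV", "RSPV", "RIPV")
_PV_DIRECTIONS = {
    "LSPV": np.array([0.75, 0.55, 0.45]),
    "LIPV": np.array([0.75, 0.60, -0.40]),
    "RSPV": np.array([-0.75, 0.55, 0.45]),
    "RIPV": np.array([-0.75, 0.60, -0.40]),
}


@lru_cache(maxsize=4)
def _unit_icosphere(subdivisions: int) -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=subdivisions)


def ellipsoid_point(direction: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """Surface point of the ellipsoid along a (not necessarily unit) direction."""
    d = np.asarray(direction, dtype=float)
    scale = 1.0 / np.sqrt(np.sum((d / semi_axes) ** 2))
    return d * scale


class ShellMesh:
    """Discretized ellipsoid shell shared by all phantoms of one geometry.

    Holds the scaled vertices, per-vertex areas (one third of incident
    face areas), outward normals, a neighbourhood-smoothing operator for
    generating spatially correlated voltage fields, and a KD-tree on the
    unit-sphere vertex directions used by the renderer.
    """

    def __init__(self, semi_axes, subdivisions: int = 5):
        self.semi_axes = np.asarray(semi_axes, dtype=float)
        self.subdivisions = int(subdivisions)
        base = _unit_icosphere(self.subdivisions)
        self.unit_vertices = np.asarray(base.vertices, dtype=float)
        self.faces = np.asarray(base.faces)
        self.vertices = self.unit_vertices * self.semi_axes  # (n, 3) mm
        self.n_vertices = len(self.vertices)

        # per-vertex area from scaled face areas
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        face_area = 0.5 * np.linalg.norm(cross, axis=1)
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.ravel(), np.repeat(face_area / 3.0, 3))
        self.vertex_areas = va
        self.total_area = va.sum()

        # outward normal of the ellipsoid at each vertex
        grad = self.vertices / self.semi_axes**2
        self.normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)

        # row-normalized vertex adjacency (with self) for field smoothing
        edges = base.edges_unique
        i = np.concatenate([edges[:, 0], edges[:, 1], np.arange(self.n_vertices)])
        j = np.concatenate([edges[:, 1], edges[:, 0], np.arange(self.n_vertices)])
        adj = sparse.csr_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self._smooth_op = sparse.diags(1.0 / deg) @ adj

        self._tree = cKDTree(self.unit_vertices)
        self._pixel_maps: dict = {}

    # -- fields ---------------------------------------------------------
    def smooth_field(self, values: np.ndarray, iterations: int) -> np.ndarray:
        """Neighbour-average a per-vertex field `iterations` times."""
        out = np.asarray(values, dtype=float)
        for _ in range(iterations):
            out = self._smooth_op @ out
        return out

    def correlated_noise(self, rng: np.random.Generator, iterations: int) -> np.ndarray:
        """Zero-mean, unit-variance spatially smooth random field."""
        field = self.smooth_field(rng.standard_normal(self.n_vertices), iterations)
        sd = field.std()
        if sd == 0:  # pragma: no cover - degenerate smoothing
            return field
        return (field - field.mean()) / sd

    def surface_point(self, direction) -> np.ndarray:
        return ellipsoid_point(direction, self.semi_axes)

    # -- rendering geometry ----------------------------------------------
    @property
    def render_extent(self) -> float:
        """Half-width (mm) of the square image plane, common to all views."""
        return 1.1 * float(self.semi_axes.max())

    def pixel_map(self, view: str, size: int):
        """(mask, vertex index) lookup for one view at one image size.

        mask is a (size, size) bool array of anatomy pixels; vidx holds,
        for masked pixels, the nearest mesh vertex of the front-facing
        surface point under orthographic projection.
        """
        key = (view, int(size))
        if key in self._pixel_maps:
            return self._pixel_maps[key]
        d, u, v = _VIEW_FRAMES[view]
        ext = self.render_extent
        # pixel centers; row 0 = top of image
        coords = (np.arange(size) + 0.5) / size
        uu = ext * (2.0 * coords - 1.0)
        vv = ext * (1.0 - 2.0 * coords)
        U, V = np.meshgrid(uu, vv)  # (size, size), V varies along rows

        # ray p(t) = U*u + V*v + t*d against (x/a)^2+(y/b)^2+(z/c)^2 = 1
        o = U[..., None] * u + V[..., None] * v  # (s, s, 3)
        a = self.semi_axes
        A = np.sum((d / a) ** 2)
        B = 2.0 * np.sum(o * (d / a**2), axis=-1)
        C = np.sum((o / a) ** 2, axis=-1) - 1.0
        disc = B**2 - 4.0 * A * C
        mask = disc >= 0.0
        t = np.zeros_like(disc)
        t[mask] = (-B[mask] - np.sqrt(disc[mask])) / (2.0 * A)  # front hit
        pts = o[mask] + t[mask, None] * d
        dirs = pts / a
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        _, vidx = self._tree.query(dirs)
        full_idx = np.zeros(mask.shape, dtype=np.int64)
        full_idx[mask] = vidx
        self._pixel_maps[key] = (mask, full_idx)
        return self._pixel_maps[key]

    def front_facing(self, view: str, vertex_idx) -> np.ndarray:
        """Whether vertices face the camera of a view (normal opposes ray)."""
        d, _, _ = _VIEW_FRAMES[view]
        return self.normals[vertex_idx] @ d < 0.0

    def project(self, view: str, points: np.ndarray) -> np.ndarray:
        """Project 3D points (mm) to pixel-unit (row, col) floats for a size-S image."""
        d, u, v = _VIEW_FRAMES[view]
        return np.stack([points @ u, points @ v], axis=-1)


_MESH_CACHE: dict = {}


def get_mesh(semi_axes, subdivisions: int = 5) -> ShellMesh:
    """Shared ShellMesh instance per (semi-axes, subdivision)."""
    key = (tuple(np.round(np.asarray(semi_axes, dtype=float), 6)), int(subdivisions))
    if key not in _MESH_CACHE:
        _MESH_CACHE[key] = ShellMesh(semi_axes, subdivisions)
    return _MESH_CACHE[key]


@dataclass(frozen=True)
class PvSite:
    """One pulmonary vein ostium on the shell."""

    name: str
    center: np.ndarray  # surface point, mm
    axis: np.ndarray  # outward unit direction at the center
    radius: float  # ostium radius, mm


def pv_sites(mesh: ShellMesh, radii) -> list[PvSite]:
    """The four canonical PV ostia projected onto a given geometry.

    `radii` is a scalar or a mapping PV name -> radius (mm).
    """
    sites = []
    for name in PV_NAMES:
        r = radii[name] if isinstance(radii, dict) else float(radii)
        direction = _PV_DIRECTIONS[name]
        center = mesh.surface_point(direction)
        axis = direction / np.linalg.norm(direction)
        sites.append(PvSite(name=name, center=center, axis=axis, radius=r))
    return sites


def ring_angles(mesh: ShellMesh, site: PvSite, vertex_idx: np.ndarray) -> np.ndarray:
    """Angle of vertices around a PV axis, measured in the tangent plane.

    Angle 0 points toward the posterior (+y) direction so that a gap
    placed at angle 0 sits on the posterior-facing side of the ring.
    """
    n = site.axis
    ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = mesh.vertices[vertex_idx] - site.center
    return np.arctan2(rel @ e2, rel @ e1)
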