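"""Synthetic head phantoms: nested-sphere heads and a gyrus variant.

The sphere phantom is five nested icosphere shells (skin, skull, CSF, GM,
WM) with a GM-WM gap of ~2.5 mm, i.e. a cortical thickness on the mm
scale of adult segmentations. The gyrus phantom carves two smooth
Gaussian-profile trenches into the GM and WM shells, leaving a ridge (the
gyral crown, the analog of the precentral hand-knob crown) flanked by two
sulcal walls; the trench profile is analytic, so sulcal-wall normals have
a closed form usable as an oracle for placement tests.

The seed drives a small "inter-subject" jitter (global scale, crown
azimuth, sulcus depth/width); generation is otherwise deterministic, and
``sulcus_depth=0`` with the same seed reproduces the sphere head exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .meshkit import HeadModel, ObservationSurface, SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "TargetSet",
    "GyrusPhantom",
    "make_sphere_head",
    "make_gyrus_head",
    "place_targets",
]

DEFAULT_RADII = (92.0, 86.0, 82.0, 80.0, 77.5)
#: standard head-modelling compartment conductivities in S/m (config
#: defaults, not ground truth; measured values vary widely).
DEFAULT_CONDUCTIVITIES = {
    "skin": 0.465,
    "skull": 0.010,
    "csf": 1.654,
    "gm": 0.276,
    "wm": 0.126,
}
SHELL_ORDER = ("skin", "skull", "csf", "gm", "wm")


@dataclass
class PhantomSpec:
    kind: str = "sphere"                       # "sphere" | "gyrus"
    shell_radii: tuple = DEFAULT_RADII         # mm, outer to inner
    conductivities: dict = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES))
    mesh_density: float = 12.0                 # target edge length, mm
    subdivisions: tuple | None = None          # per-shell override of icosphere level
    crown_axis: tuple = (1.0, 0.0, 0.0)        # ridge direction (unit, not parallel z)
    sulcus_depth: float = 7.0                  # mm
    sulcus_width: float = 10.0                 # mm (2 sigma of the Gaussian trench)
    ridge_length: float = 90.0                 # mm, trench extent along the crown
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.shell_radii, float)
        if not np.all(np.diff(r) < 0):
            raise ValueError("shell_radii must be strictly decreasing (outer to inner)")

    def shell_subdivisions(self) -> list[int]:
        if self.subdivisions is not None:
            return list(self.subdivisions)
        subs = []
        for r in self.shell_radii:
            # icosahedron edge ~1.05 R; each subdivision halves the edge
            lvl = int(np.floor(np.log2(1.05 * r / self.mesh_density) + 0.5))
            subs.append(int(np.clip(lvl, 1, 6)))
        return subs


@dataclass
class TargetSet:
    """Targets on the gyral crown with neighbour links and field-averaging nodes."""

    targets: np.ndarray            # (n, 3) mm, on the GM surface
    neighbors: list                # per target, list of neighbour target indices
    nearest_obs_nodes: np.ndarray | None  # (n, k) obs-point indices or None
    spacing_mean: float
    spacing_std: float

    def __len__(self) -> int:
        return len(self.targets)

    def attach_observation_nodes(self, obs: ObservationSurface, n_nodes: int = 4) -> None:
        """Assign the ``n_nodes`` observation points nearest each target."""
        tree = cKDTree(obs.points)
        d, idx = tree.query(self.targets, k=n_nodes)
        span = d.max(axis=1) if n_nodes > 1 else d
        if np.any(span > 6.0):
            log.warning("field-averaging domain exceeds 6 mm for some targets")
        self.nearest_obs_nodes = np.atleast_2d(idx)


def _jitter(spec: PhantomSpec):
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(-1.0, 1.0, size=4)
    scale = 1.0 + 0.02 * u[0]
    azimuth = np.pi * u[1]
    depth = spec.sulcus_depth * (1.0 + 0.10 * u[2])
    width = spec.sulcus_width * (1.0 + 0.10 * u[3])
    return scale, azimuth, depth, width


def _crown_frame(spec: PhantomSpec, azimuth: float):
    """Orthonormal frame (u: along ridge, v: 'up' in crown plane, w: transverse)."""
    u = np.asarray(spec.crown_axis, float)
    u = u / np.linalg.norm(u)
    z = np.array([0.0, 0.0, 1.0])
    if abs(u @ z) > 0.95:
        raise ValueError("crown_axis must not be parallel to z")
    Rz = np.array(
        [[np.cos(azimuth), -np.sin(azimuth), 0.0],
         [np.sin(azimuth), np.cos(azimuth), 0.0],
         [0.0, 0.0, 1.0]]
    )
    u = Rz @ u
    v = z - (z @ u) * u
    v = v / np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


def _nested_spheres(spec: PhantomSpec, scale: float) -> list[SurfaceMesh]:
    meshes = []
    for r, lvl in zip(spec.shell_radii, spec.shell_subdivisions()):
        ico = trimesh.creation.icosphere(subdivisions=lvl, radius=1.0)
        meshes.append(
            SurfaceMesh(np.asarray(ico.vertices) * (r * scale),
                        np.asarray(ico.faces, np.int64))
        )
    return meshes


def _as_head(spec: PhantomSpec, meshes) -> HeadModel:
    sig = spec.conductivities
    shells = []
    outer = 0.0
    for name, mesh in zip(SHELL_ORDER, meshes):
        shells.append((name, mesh, sig[name], outer))
        outer = sig[name]
    return HeadModel(shells)


def make_sphere_head(spec: PhantomSpec) -> HeadModel:
    """Five nested icosphere shells at ``spec.shell_radii`` (times seed jitter)."""
    if spec.kind != "sphere":
        raise ValueError("spec.kind must be 'sphere'")
    scale, _, _, _ = _jitter(spec)
    return _as_head(spec, _nested_spheres(spec, scale))


@dataclass
class GyrusPhantom:
    """Gyrus head plus the analytic crown/wall description.

    ``crown`` is the ridge-apex polyline on the deformed GM surface;
    ``wall_normal(p)`` returns the outward GM-surface normal at the
    sulcal-wall point nearest to ``p`` (closed form via the implicit
    trench profile).
    """

    head: HeadModel
    crown: np.ndarray              # (k, 3) polyline on GM
    frame: tuple                   # (u, v, w) crown frame
    gm_radius: float               # scaled undeformed GM radius
    depth: float
    sigma: float                   # Gaussian trench sigma, mm
    trench_offset: float           # |s| of the trench centerlines, mm
    ridge_length: float

    # -- analytic trench profile -------------------------------------------
    def _st(self, p: np.ndarray):
        u, v, w = self.frame
        p = np.atleast_2d(p)
        r = np.linalg.norm(p, axis=1)
        ph = p / r[:, None]
        s = self.gm_radius * np.arcsin(np.clip(ph @ w, -1, 1))
        t = self.gm_radius * np.arctan2(ph @ u, ph @ v)
        return s, t

    def trench_depth(self, s, t):
        g = np.exp(-((s - self.trench_offset) ** 2) / (2 * self.sigma**2)) + np.exp(
            -((s + self.trench_offset) ** 2) / (2 * self.sigma**2)
        )
        taper = np.exp(-((2 * t / self.ridge_length) ** 4))
        return self.depth * taper * g

    def surface_value(self, p: np.ndarray, radius: float | None = None) -> np.ndarray:
        """Implicit function |p| - (R - D(s,t)); zero on the deformed surface."""
        radius = self.gm_radius if radius is None else radius
        p = np.atleast_2d(p)
        s, t = self._st(p)
        return np.linalg.norm(p, axis=1) - (radius - self.trench_depth(s, t))

    def wall_normal(self, point: np.ndarray) -> np.ndarray:
        """Outward surface normal at the nearest sulcal-wall point.

        The wall is taken at the inner inflection line of the nearer
        trench (|s| = trench_offset - sigma); ambiguity at s = 0 is
        resolved toward +s with a warning.
        """
        p = np.asarray(point, float)
        s, t = self._st(p)
        s, t = float(s[0]), float(t[0])
        if abs(s) < 0.05 * self.sigma:
            warnings.warn("target equidistant from both sulcal walls; using +s wall",
                          stacklevel=2)
            sign = 1.0
        else:
            sign = np.sign(s)
        s_wall = sign * max(self.trench_offset - self.sigma, 0.5 * self.sigma)
        pw = self.point_at(s_wall, t)
        return self._gradient(pw)

    def point_at(self, s: float, t: float) -> np.ndarray:
        u, v, w = self.frame
        R = self.gm_radius
        a, b = s / R, t / R
        direction = (
            np.sin(a) * w + np.cos(a) * (np.sin(b) * u + np.cos(b) * v)
        )
        r = R - float(self.trench_depth(np.array([s]), np.array([t]))[0])
        return r * direction

    def _gradient(self, p: np.ndarray, h: float = 1e-4) -> np.ndarray:
        g = np.zeros(3)
        for i in range(3):
            dp = np.zeros(3)
            dp[i] = h
            g[i] = float(
                self.surface_value(p + dp)[0] - self.surface_value(p - dp)[0]
            ) / (2 * h)
        return g / np.linalg.norm(g)


def make_gyrus_head(spec: PhantomSpec) -> GyrusPhantom:
    """Sphere head whose GM and WM shells carry a crown flanked by two trenches."""
    if spec.kind != "gyrus":
        raise ValueError("spec.kind must be 'gyrus'")
    scale, azimuth, depth, width = _jitter(spec)
    frame = _crown_frame(spec, azimuth)
    meshes = _nested_spheres(spec, scale)
    gm_index = SHELL_ORDER.index("gm")
    gm_radius = spec.shell_radii[gm_index] * scale
    sigma = 0.5 * width
    trench_offset = width

    ph = GyrusPhantom(
        head=None,  # filled below
        crown=None,
        frame=frame,
        gm_radius=gm_radius,
        depth=depth,
        sigma=sigma,
        trench_offset=trench_offset,
        ridge_length=spec.ridge_length,
    )
    # slope bound for a Gaussian trench: max |dD/ds| = depth/(sigma sqrt(e));
    # > 1 means folding (self-intersecting walls)
    if depth > 0 and depth / (sigma * np.sqrt(np.e)) >= 1.0:
        raise ValueError(
            f"sulcus_depth={depth:.1f} with sulcus_width={width:.1f} folds the "
            "trench walls (reduce depth or widen the sulcus)"
        )

    deformed = []
    for name, mesh in zip(SHELL_ORDER, meshes):
        if name not in ("gm", "wm") or depth == 0.0:
            deformed.append(mesh)
            continue
        verts = mesh.vertices
        r = np.linalg.norm(verts, axis=1)
        s, t = ph._st(verts)
        d = ph.trench_depth(s, t)
        new_verts = verts * ((r - d) / r)[:, None]
        new_mesh = SurfaceMesh(new_verts, mesh.triangles)
        if new_mesh.signed_volume() <= 0 or not new_mesh.is_closed():
            raise ValueError(f"trench deformation broke the {name} shell")
        deformed.append(new_mesh)

    ph.head = _as_head(spec, deformed)

    # ridge-apex polyline at s=0, sampled finely along t
    t_max = 0.75 * spec.ridge_length
    ts = np.linspace(-t_max, t_max, 301)
    ph.crown = np.array([ph.point_at(0.0, t) for t in ts])
    return ph


# ---------------------------------------------------------------------------
# Target placement along the crown
# ---------------------------------------------------------------------------

def place_targets(
    head: HeadModel,
    crown: np.ndarray,
    n_targets: int = 3,
    spacing: float = 10.0,
    obs: ObservationSurface | None = None,
    n_avg_nodes: int = 4,
) -> TargetSet:
    """Place ``n_targets`` points on the crown polyline.

    Consecutive targets are chord-marched so that straight-line distances
    equal ``spacing`` (mm) to numerical precision; the set is centred on
    the crown midpoint. With an observation surface supplied, the
    ``n_avg_nodes`` nearest field-sampling nodes are attached per target.
    """
    crown = np.asarray(crown, float)
    seg = np.linalg.norm(np.diff(crown, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    need = (n_targets - 1) * spacing
    if total < need:
        raise ValueError(f"crown length {total:.1f} mm < required {need:.1f} mm")

    def point_at_arc(a):
        i = np.searchsorted(arc, a, side="right") - 1
        i = min(max(i, 0), len(seg) - 1)
        f = (a - arc[i]) / seg[i]
        return crown[i] + f * (crown[i + 1] - crown[i])

    start_arc = 0.5 * total - 0.5 * need
    pts = [point_at_arc(start_arc)]
    a = start_arc
    for _ in range(n_targets - 1):
        prev = pts[-1]
        lo, hi = a, total
        # chord distance grows monotonically with arc length on a gentle crown
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(point_at_arc(mid) - prev) < spacing:
                lo = mid
            else:
                hi = mid
        a = 0.5 * (lo + hi)
        pts.append(point_at_arc(a))
    targets = np.array(pts)

    d = np.linalg.norm(np.diff(targets, axis=0), axis=1)
    neighbors = [
        [j for j in (i - 1, i + 1) if 0 <= j < n_targets] for i in range(n_targets)
    ]
    ts = TargetSet(
        targets=targets,
        neighbors=neighbors,
        nearest_obs_nodes=None,
        spacing_mean=float(d.mean()) if len(d) else 0.0,
        spacing_std=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
    )
    if obs is not None:
        ts.attach_observation_nodes(obs, n_avg_nodes)
    return ts
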