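"""Coil models as magnetic-dipole clouds, pose transforms, primary E-field.

A coil is a cloud of magnetic dipoles (position + moment per unit coil
current). A planar current loop is electromagnetically equivalent, outside
the windings, to a uniformly magnetized disc spanning it, so a spiral wing
of a figure-8 coil is discretized as a polar grid of surface patches whose
dipole moments are proportional to the number of turns enclosing each
patch. Positions are stored in mm (head-frame convention of the rest of
the package); moments in A*m^2 per ampere. The CCD text format stores
positions in metres.

Local coil frame: the winding plane is z=0 with the normal (centerline)
along +z pointing away from the head; the two wings are stacked along
+/-y, so the dominant induced E-field under the coil center -- the coil
"handle" direction used by the sulcus-aligned placement -- is along +x.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

MU0_OVER_4PI = 1e-7  # T*m/A

__all__ = [
    "Coil",
    "CoilPose",
    "make_figure8_coil",
    "make_loop_coil",
    "coil_preset",
    "load_ccd",
    "save_ccd",
    "rotation_matrix",
    "pose_from_frame",
    "transform_coil",
    "primary_field",
    "coil_scalp_clearance",
]


@dataclass
class Coil:
    """Magnetic-dipole cloud representing a TMS coil.

    positions : (k, 3) mm, dipole locations.
    moments : (k, 3) A*m^2 per unit current.
    handle_axis : unit vector, direction of the dominant induced E.
    normal_axis : unit vector, coil centerline.
    bounding_points : (b, 3) mm, subset of positions used for the
        coil-scalp clearance constraint (the lowest winding layer).
    """

    positions: np.ndarray
    moments: np.ndarray
    handle_axis: np.ndarray
    normal_axis: np.ndarray
    bounding_points: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.moments = np.atleast_2d(np.asarray(self.moments, float))
        self.handle_axis = np.asarray(self.handle_axis, float)
        self.normal_axis = np.asarray(self.normal_axis, float)
        self.bounding_points = np.atleast_2d(np.asarray(self.bounding_points, float))
        if len(self.positions) < 1:
            raise ValueError("coil needs at least one dipole")
        if not np.all(np.isfinite(self.moments)):
            raise ValueError("non-finite dipole moment")
        if abs(float(self.handle_axis @ self.normal_axis)) > 1e-8:
            raise ValueError("handle_axis must be perpendicular to normal_axis")

    @property
    def total_moment(self) -> np.ndarray:
        return self.moments.sum(axis=0)


@dataclass(frozen=True)
class CoilPose:
    """6-parameter rigid coil pose in the head frame.

    center in mm; pitch (about local x), roll (about local y) and yaw
    (about the coil normal, local z) in radians, stored unwrapped.
    Rotation convention (fixed, documented): yaw is applied first in the
    local frame, then pitch, then roll:  R = R_y(roll) R_x(pitch) R_z(yaw).
    """

    center: tuple
    pitch: float = 0.0
    roll: float = 0.0
    yaw: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def as_array(self) -> np.ndarray:
        return np.array([*self.center, self.pitch, self.roll, self.yaw])

    @classmethod
    def from_array(cls, a) -> "CoilPose":
        a = np.asarray(a, float)
        return cls(center=tuple(a[:3]), pitch=float(a[3]), roll=float(a[4]), yaw=float(a[5]))

    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.pitch, self.roll, self.yaw)


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(pitch: float, roll: float, yaw: float) -> np.ndarray:
    """R = R_y(roll) R_x(pitch) R_z(yaw): yaw about the coil normal first."""
    return _ry(roll) @ _rx(pitch) @ _rz(yaw)


def pose_from_frame(center, normal_dir, handle_dir) -> CoilPose:
    """Pose whose rotation maps local +z to ``normal_dir`` and +x to ``handle_dir``.

    ``handle_dir`` is orthogonalized against ``normal_dir`` before the yaw
    angle is extracted, so an approximately-perpendicular handle request is
    accepted.
    """
    z = np.asarray(normal_dir, float)
    z = z / np.linalg.norm(z)
    h = np.asarray(handle_dir, float)
    h = h - (h @ z) * z
    nh = np.linalg.norm(h)
    if nh < 1e-12:
        raise ValueError("handle_dir is parallel to normal_dir")
    h = h / nh
    pitch = -np.arcsin(np.clip(z[1], -1.0, 1.0))
    roll = np.arctan2(z[0], z[2])
    # remove pitch/roll, solve yaw from where +x must land
    h_local = _rx(pitch).T @ _ry(roll).T @ h
    yaw = np.arctan2(h_local[1], h_local[0])
    return CoilPose(center=tuple(np.asarray(center, float)), pitch=float(pitch),
                    roll=float(roll), yaw=float(yaw))


# ---------------------------------------------------------------------------
# Coil construction
# ---------------------------------------------------------------------------

def _disc_dipoles(radius_outer, radius_inner, turns, elements_per_turn, n_rings):
    """Dipole patches for one spiral wing centred at the origin, normal +z.

    The enclosed-turns density is ``turns`` inside the innermost winding
    and tapers linearly to zero at the outer winding, matching a uniform
    spiral. Returns positions (mm), scalar moments (A*m^2 per A).
    """
    edges = np.linspace(0.0, radius_outer, n_rings + 1)
    pos = []
    mom = []
    for r0, r1 in zip(edges[:-1], edges[1:]):
        rc = 0.5 * (r0 + r1)
        n_phi = max(int(np.ceil(elements_per_turn * rc / radius_outer)), 6)
        phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
        dA = 0.5 * (r1**2 - r0**2) * (2 * np.pi / n_phi)  # mm^2
        if rc <= radius_inner:
            density = float(turns)
        else:
            density = turns * (radius_outer - rc) / (radius_outer - radius_inner)
        pos.append(np.column_stack([rc * np.cos(phi), rc * np.sin(phi), np.zeros(n_phi)]))
        mom.append(np.full(n_phi, density * dA * 1e-6))  # mm^2 -> m^2
    return np.concatenate(pos), np.concatenate(mom)


def make_figure8_coil(
    outer_radius: float = 17.5,
    inner_radius: float = 5.0,
    turns: int = 9,
    elements_per_turn: int = 36,
    wing_gap: float = 2.0,
    n_rings: int | None = None,
) -> Coil:
    """Parametric figure-8 coil (two counter-wound spiral wings).

    Wings of outer radius ``outer_radius`` mm are centred at
    ``y = +/-(outer_radius + wing_gap/2)`` in the winding plane z=0; their
    dipole moments point along -/+z so the induced currents add under the
    coil center and the dominant induced E there is along +x (the handle).
    """
    if inner_radius >= outer_radius:
        raise ValueError("inner_radius must be < outer_radius")
    if elements_per_turn < 8:
        raise ValueError("elements_per_turn must be >= 8")
    if n_rings is None:
        n_rings = max(turns, 6)
    pos, mom = _disc_dipoles(outer_radius, inner_radius, turns, elements_per_turn, n_rings)
    d = outer_radius + 0.5 * wing_gap
    up = pos + np.array([0.0, d, 0.0])
    dn = pos + np.array([0.0, -d, 0.0])
    positions = np.concatenate([up, dn])
    z = np.array([0.0, 0.0, 1.0])
    # counter-wound: +y wing carries -z moment so the induced E of both
    # wings adds along +x under the coil center (for a point on the -z side)
    moments = np.concatenate([np.outer(mom, -z), np.outer(mom, z)])
    # clearance check uses the outer winding ring of each wing plus the center
    ring_phi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ring = np.column_stack(
        [outer_radius * np.cos(ring_phi), outer_radius * np.sin(ring_phi), np.zeros(24)]
    )
    bounding = np.concatenate([ring + [0, d, 0], ring + [0, -d, 0], [[0.0, 0.0, 0.0]]])
    return Coil(
        positions=positions,
        moments=moments,
        handle_axis=np.array([1.0, 0.0, 0.0]),
        normal_axis=z,
        bounding_points=bounding,
    )


def make_loop_coil(radius: float = 20.0, turns: int = 1,
                   elements_per_turn: int = 36, n_rings: int = 12) -> Coil:
    """Single circular loop (validation geometry; total moment = pi r^2 turns)."""
    pos, mom = _disc_dipoles(radius, radius * 0.999, turns, elements_per_turn, n_rings)
    z = np.array([0.0, 0.0, 1.0])
    ring_phi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ring = np.column_stack([radius * np.cos(ring_phi), radius * np.sin(ring_phi), np.zeros(24)])
    return Coil(pos, np.outer(mom, z), np.array([1.0, 0.0, 0.0]), z,
                np.concatenate([ring, [[0.0, 0.0, 0.0]]]))


#: characteristic handle-direction dimensions of the two shipped presets
#: differ by a factor of ~2 (a large elliptical-class coil vs a small one).
_PRESETS = {
    "large": dict(outer_radius=35.0, inner_radius=10.0, turns=9,
                  elements_per_turn=36, wing_gap=2.0),
    "small": dict(outer_radius=17.5, inner_radius=5.0, turns=9,
                  elements_per_turn=36, wing_gap=2.0),
}


def coil_preset(name: str, **overrides) -> Coil:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return make_figure8_coil(**params)


# ---------------------------------------------------------------------------
# CCD I/O (comment line, count line, rows "x y z mx my mz"; metres, A*m^2)
# ---------------------------------------------------------------------------

def save_ccd(coil: Coil, path) -> None:
    with open(path, "w") as f:
        f.write("# magnetic dipole cloud; x y z [m], mx my mz [A*m^2 per A]\n")
        f.write(f"{len(coil.positions)}\n")
        for p, m in zip(coil.positions * 1e-3, coil.moments):
            f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {m[0]:.17g} {m[1]:.17g} {m[2]:.17g}\n")


def load_ccd(path) -> Coil:
    with open(path) as f:
        lines = [ln for ln in (l.strip() for l in f) if ln]
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: expected a leading comment line")
    count = int(lines[1])
    rows = lines[2:]
    if len(rows) != count:
        raise ValueError(f"{path}: count line says {count} dipoles, found {len(rows)} rows")
    arr = np.array([r.split() for r in rows], dtype=float)
    positions = arr[:, :3] * 1e3  # m -> mm
    moments = arr[:, 3:6]
    # axes are not stored in CCD; reconstruct canonical local axes
    return Coil(
        positions=positions,
        moments=moments,
        handle_axis=np.array([1.0, 0.0, 0.0]),
        normal_axis=np.array([0.0, 0.0, 1.0]),
        bounding_points=positions,
    )


# ---------------------------------------------------------------------------
# Pose transform, primary field, clearance
# ---------------------------------------------------------------------------

def transform_coil(coil: Coil, pose: CoilPose) -> Coil:
    """Rigid map of the coil from its local frame to the head frame."""
    R = pose.rotation()
    c = np.asarray(pose.center, float)
    return replace(
        coil,
        positions=coil.positions @ R.T + c,
        moments=coil.moments @ R.T,
        handle_axis=R @ coil.handle_axis,
        normal_axis=R @ coil.normal_axis,
        bounding_points=coil.bounding_points @ R.T + c,
    )


def primary_field(coil: Coil, points: np.ndarray, dIdt: float = 9.4e7,
                  block: int = 2_000_000) -> np.ndarray:
    """Incident (primary) E-field of the coil at ``points`` (mm), in V/m.

    E_p(r) = -(mu0 / 4 pi) dI/dt sum_k m_k x (r - p_k) / |r - p_k|^3,
    the time derivative of the magnetic-dipole vector potential; exactly
    linear in dI/dt and in the moments.
    """
    pts = np.atleast_2d(np.asarray(points, float)) * 1e-3
    pos = coil.positions * 1e-3
    mom = coil.moments
    n, k = len(pts), len(pos)
    out = np.zeros((n, 3))
    rows = max(int(block // max(k, 1)), 1)
    for i0 in range(0, n, rows):
        sl = slice(i0, min(i0 + rows, n))
        d = pts[sl, None, :] - pos[None, :, :]          # (b, k, 3) metres
        r2 = np.einsum("bkx,bkx->bk", d, d)
        if np.any(r2 < 1e-20):
            raise ValueError("observation point coincides with a coil dipole")
        w = r2 ** -1.5
        out[sl] = -MU0_OVER_4PI * dIdt * np.einsum(
            "bk,bkx->bx", w, np.cross(mom[None, :, :], d)
        )
    return out


def coil_scalp_clearance(coil: Coil, skin) -> float:
    """Minimum distance (mm) from the coil bounding points to the skin surface.

    Exact point-to-triangle distances over KD-tree candidate facets.
    Negative values signal penetration (bounding point inside the skin
    shell); the optimizer rejects poses below the 10 mm hard constraint.
    """
    pts = coil.bounding_points
    tree = cKDTree(skin.centroids)
    k = min(24, skin.n_triangles)
    _, idx = tree.query(pts, k=k)
    idx = np.atleast_2d(idx)
    best = np.full(len(pts), np.inf)
    best_face = np.zeros(len(pts), dtype=np.int64)
    tri = skin.vertices[skin.triangles]
    for j in range(idx.shape[1]):
        faces = idx[:, j]
        d = _point_triangle_distance(pts, tri[faces])
        closer = d < best
        best = np.where(closer, d, best)
        best_face = np.where(closer, faces, best_face)
    # sign: outside if the point lies on the outward side of its closest facet
    n = skin.normals[best_face]
    c = skin.centroids[best_face]
    outside = np.einsum("ij,ij->i", pts - c, n) >= 0
    signed = np.where(outside, best, -best)
    return float(signed.min())


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from points p[i] to triangles tri[i] (vectorized Eberly scheme)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    closest = np.empty_like(p)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom_full = va + vb + vc

    # region masks evaluated in priority order
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        nonlocal done
        m = mask & ~done
        closest[m] = value[m]
        done |= m

    assign(m_a, a)
    assign(m_b, b)
    assign(m_c, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        assign(m_ab, a + t_ab[:, None] * ab)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        assign(m_ac, a + t_ac[:, None] * ac)
        denom_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        assign(m_bc, b + t_bc[:, None] * (c - b))
        denom = np.where(denom_full != 0, denom_full, 1.0)
        v = vb / denom
        w = vc / denom
        assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(p - closest, axis=1)
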