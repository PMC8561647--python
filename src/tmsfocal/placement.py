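"""Sulcus-aligned initial coil placement (the inverse search's initial guess).

Three-step construction: (1) the coil centerline passes through the
cortical target; (2) the centerline is perpendicular to the skin at the
skin-centerline intersection with the lowest winding point a fixed
standoff above the skin; (3) the coil handle (dominant induced-E
direction) is rotated about the centerline to be perpendicular to the
nearest sulcal wall, i.e. the induced current crosses the sulcus at 90
degrees.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .coilkit import Coil, CoilPose, coil_scalp_clearance, pose_from_frame, transform_coil
from .meshkit import HeadModel, SurfaceMesh

log = logging.getLogger(__name__)

__all__ = ["sulcus_aligned_pose", "find_wall_normal_from_mesh"]


def _gm_outward_normal(gm: SurfaceMesh, target: np.ndarray) -> np.ndarray:
    tree = cKDTree(gm.centroids)
    _, idx = tree.query(target, k=4)
    n = gm.normals[np.atleast_1d(idx)].mean(axis=0)
    return n / np.linalg.norm(n)


def _ray_mesh_intersection(origin, direction, mesh: SurfaceMesh):
    """First Moller-Trumbore hit along the ray, or None."""
    v = mesh.vertices[mesh.triangles]
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origin - v[:, 0]
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    vv = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", e2, q)
    hit = ok & (u >= -1e-9) & (vv >= -1e-9) & (u + vv <= 1 + 1e-9) & (t > 1e-6)
    if not hit.any():
        return None
    i = np.flatnonzero(hit)[np.argmin(t[hit])]
    return origin + t[i] * np.asarray(direction), i


def find_wall_normal_from_mesh(gm: SurfaceMesh, target: np.ndarray,
                               radial_tolerance_deg: float = 30.0) -> np.ndarray:
    """Nearest trench-wall facet normal on a gyrus phantom.

    Wall facets are those whose outward normal deviates from the local
    radial direction by more than ``radial_tolerance_deg``; the facet with
    the centroid closest to the target wins. Two walls within 5% distance
    of each other trigger a warning (nearer wall kept).
    """
    c = gm.centroids
    radial = c / np.linalg.norm(c, axis=1)[:, None]
    cosang = np.einsum("ij,ij->i", gm.normals, radial)
    walls = cosang < np.cos(np.deg2rad(radial_tolerance_deg))
    if not walls.any():
        # coarse meshes flatten the trench below the angular cutoff: fall
        # back to the most-tilted decile of facets
        cut = np.quantile(cosang, 0.10)
        walls = cosang <= cut
        if cosang[walls].min() > np.cos(np.deg2rad(10.0)):
            raise ValueError("no sulcal-wall facets found (is this a gyrus phantom?)")
        warnings.warn("sulcal walls barely resolved by this mesh; using the "
                      "most-tilted facets", stacklevel=2)
    wc = c[walls]
    d = np.linalg.norm(wc - target, axis=1)
    order = np.argsort(d)
    nearest = order[0]
    # a second wall candidate with an opposing normal within 5% distance
    n0 = gm.normals[walls][nearest]
    for j in order[1:]:
        if d[j] > 1.05 * d[nearest]:
            break
        if gm.normals[walls][j] @ n0 < 0:
            warnings.warn("two sulcal walls nearly equidistant from the target; "
                          "using the nearer one", stacklevel=2)
            break
    return gm.normals[walls][nearest]


def sulcus_aligned_pose(
    head: HeadModel,
    target,
    coil: Coil,
    wall_normal="auto",
    standoff: float = 10.0,
    standoff_tol: float = 0.25,
) -> CoilPose:
    """Construct the sulcus-aligned pose for ``target`` on the GM surface.

    ``wall_normal`` may be a 3-vector, ``"auto"`` (nearest wall facet of a
    gyrus phantom), or ``None``: then the handle angle is rotationally
    degenerate (e.g. a pure sphere head); an arbitrary in-plane handle is
    chosen and a warning is emitted rather than resolving it silently.
    """
    target = np.asarray(target, float)
    gm = head.shell("gm")
    skin = head.shell("skin")
    out_n = _gm_outward_normal(gm, target)

    hit = _ray_mesh_intersection(target, out_n, skin)
    if hit is None:
        tree = cKDTree(skin.centroids)
        _, fi = tree.query(target, k=1)
        skin_point = skin.centroids[fi]
        skin_face = fi
        log.info("outward-normal ray missed the skin; using nearest skin point")
    else:
        skin_point, skin_face = hit
    centerline = skin.normals[skin_face]            # outward skin normal
    if centerline @ out_n < 0:
        centerline = -centerline

    # lowest winding point sits in the coil plane z=0 -> the coil center is
    # standoff above the skin along the centerline
    center = skin_point + standoff * centerline

    if wall_normal is None:
        warnings.warn("no sulcal wall supplied: handle angle is degenerate; "
                      "an arbitrary in-plane direction was chosen", stacklevel=2)
        handle = _any_perpendicular(centerline)
    else:
        if isinstance(wall_normal, str) and wall_normal == "auto":
            wn = find_wall_normal_from_mesh(gm, target)
        else:
            wn = np.asarray(wall_normal, float)
        handle = wn - (wn @ centerline) * centerline
        nh = np.linalg.norm(handle)
        if nh < 1e-8:
            warnings.warn("wall normal parallel to centerline; handle degenerate",
                          stacklevel=2)
            handle = _any_perpendicular(centerline)
        else:
            handle /= nh

    pose = pose_from_frame(center, centerline, handle)
    clearance = coil_scalp_clearance(transform_coil(coil, pose), skin)
    if abs(clearance - standoff) > standoff_tol:
        log.info("standoff re-measured at %.2f mm (target %.2f +- %.2f)",
                 clearance, standoff, standoff_tol)
    return pose


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)
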