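"""Surface-mesh data model, I/O, subdivision and inter-shell geometry.

All geometry is in millimetres. A head model is an ordered set of closed,
outward-oriented triangulated tissue boundaries (skin, skull, CSF, gray
matter, white matter, optionally ventricles), each carrying the electrical
conductivity just inside and just outside of it. Intracortical observation
surfaces -- where the induced E-field is sampled and the focality cost is
evaluated -- are built between the gray- and white-matter shells from
shortest GM-centroid-to-refined-WM-centroid vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "HeadModel",
    "ObservationSurface",
    "read_mesh",
    "write_mesh",
    "read_head_msh",
    "write_head_msh",
    "barycentric_subdivide",
    "shell_distance",
    "build_observation_surface",
]


class MeshFormatError(ValueError):
    """Raised for malformed mesh files (message names the offending record)."""


@dataclass
class SurfaceMesh:
    """A triangulated tissue boundary.

    Parameters
    ----------
    vertices : (n, 3) float array, mm.
    triangles : (m, 3) int array of vertex indices; consistent outward
        orientation is assumed (``signed_volume() > 0`` for closed shells).

    Zero-area triangles are dropped at construction with a logged warning.
    Per-triangle normals, centroids and areas are computed lazily and
    cached.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        cross = self._raw_cross()
        area2 = np.linalg.norm(cross, axis=1)
        bad = area2 < 1e-14
        if bad.any():
            log.warning("dropping %d zero-area facet(s)", int(bad.sum()))
            self.triangles = self.triangles[~bad]
            self._cache.clear()

    def _raw_cross(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def normals(self) -> np.ndarray:
        """Per-triangle outward unit normals."""
        if "normals" not in self._cache:
            cross = self._raw_cross()
            self._cache["normals"] = cross / np.linalg.norm(cross, axis=1)[:, None]
        return self._cache["normals"]

    @property
    def centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.vertices[self.triangles].mean(axis=1)
        return self._cache["centroids"]

    @property
    def areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            self._cache["areas"] = 0.5 * np.linalg.norm(self._raw_cross(), axis=1)
        return self._cache["areas"]

    @property
    def mean_edge_length(self) -> float:
        if "edge" not in self._cache:
            v = self.vertices[self.triangles]
            e = np.concatenate(
                [v[:, 1] - v[:, 0], v[:, 2] - v[:, 1], v[:, 0] - v[:, 2]]
            )
            self._cache["edge"] = float(np.linalg.norm(e, axis=1).mean())
        return self._cache["edge"]

    def signed_volume(self) -> float:
        """Signed volume in mm^3 (positive for closed, outward-oriented shells)."""
        v = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)

    def is_closed(self) -> bool:
        tm = self.to_trimesh()
        return bool(tm.is_watertight)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(),
            faces=self.triangles.copy(),
            process=False,
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


@dataclass
class HeadModel:
    """Ordered nested tissue shells, outermost first.

    ``shells`` is a list of ``(name, mesh, sigma_in, sigma_out)`` with
    conductivities in S/m. Nesting consistency requires each shell's
    ``sigma_out`` to equal the ``sigma_in`` of the shell that encloses it
    and the outermost ``sigma_out`` to be 0 (air).
    """

    shells: list  # [(name, SurfaceMesh, sigma_in, sigma_out), ...]

    KNOWN_NAMES = ("skin", "skull", "csf", "gm", "wm", "ventricles")

    def __post_init__(self):
        if not self.shells:
            raise ValueError("HeadModel needs at least one shell")
        if abs(self.shells[0][3]) > 0:
            raise ValueError("outermost shell must have sigma_out = 0 (air)")
        for (n0, _, s_in, _), (n1, _, _, s_out1) in zip(self.shells, self.shells[1:]):
            if not np.isclose(s_out1, s_in):
                raise ValueError(
                    f"shell {n1!r}: sigma_out={s_out1} != enclosing {n0!r} sigma_in={s_in}"
                )

    def shell(self, name: str) -> SurfaceMesh:
        for n, mesh, _, _ in self.shells:
            if n == name:
                return mesh
        raise KeyError(name)

    def conductivities(self, name: str) -> tuple[float, float]:
        for n, _, s_in, s_out in self.shells:
            if n == name:
                return s_in, s_out
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n for n, _, _, _ in self.shells]


@dataclass
class ObservationSurface:
    """Intracortical field-sampling points between the GM and WM shells.

    ``points[i]`` lies on the segment from the i-th retained GM facet
    centroid toward its nearest refined-WM centroid, at fraction ``fraction``
    of the GM->WM vector (0.5 for the 1:1 mid-surface, 0.8 for the 4:1
    deep surface). ``gm_wm_vector[i]`` is that full vector.
    """

    points: np.ndarray            # (n, 3) mm
    source_facet: np.ndarray      # (n,) indices into the GM mesh
    ratio: str                    # "1:1" or "4:1"
    gm_wm_vector: np.ndarray      # (n, 3) mm
    fraction: float

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read a single surface mesh from STL, PLY, or Gmsh MSH v2 ASCII.

    For multi-group MSH files all surface triangles are merged; use
    :func:`read_head_msh` to recover the individual shells.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("stl", "ply"):
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
        if fmt == "stl":
            tm.merge_vertices()  # STL stores vertices per facet
        mesh = SurfaceMesh.from_trimesh(tm)
    elif fmt == "msh":
        groups = _parse_msh(path)
        verts = groups["vertices"]
        tris = np.concatenate([t for _, t in groups["groups"]], axis=0)
        mesh = SurfaceMesh(verts, tris)
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    if not mesh.is_closed():
        warnings.warn(f"{path.name}: mesh is not watertight", stacklevel=2)
    return mesh


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    """Write a surface mesh as STL (binary), PLY (ASCII) or MSH v2 ASCII."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "stl":
        mesh.to_trimesh().export(str(path), file_type="stl")
    elif fmt == "ply":
        path.write_bytes(mesh.to_trimesh().export(file_type="ply", encoding="ascii"))
    elif fmt == "msh":
        _write_msh(path, mesh.vertices, [("surface", mesh.triangles)])
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")


def write_head_msh(head: HeadModel, path) -> None:
    """Write a multi-shell head model as Gmsh MSH v2 ASCII.

    One surface physical group per shell; physical names encode the shell
    name and conductivities as ``name:sigma_in:sigma_out`` so the model
    round-trips without a sidecar file.
    """
    offset = 0
    verts = []
    groups = []
    for name, mesh, s_in, s_out in head.shells:
        verts.append(mesh.vertices)
        groups.append((f"{name}:{float(s_in)!r}:{float(s_out)!r}",
                       mesh.triangles + offset))
        offset += len(mesh.vertices)
    _write_msh(Path(path), np.concatenate(verts, axis=0), groups)


def read_head_msh(path) -> HeadModel:
    """Read a multi-shell head model written by :func:`write_head_msh`."""
    parsed = _parse_msh(Path(path))
    verts = parsed["vertices"]
    shells = []
    for name, tris in parsed["groups"]:
        parts = name.split(":")
        if len(parts) == 3:
            shell_name, s_in, s_out = parts[0], float(parts[1]), float(parts[2])
        else:
            raise MeshFormatError(
                f"physical name {name!r} does not encode conductivities"
            )
        used = np.unique(tris)
        remap = np.full(len(verts), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        shells.append((shell_name, SurfaceMesh(verts[used], remap[tris]), s_in, s_out))
    return HeadModel(shells)


def _write_msh(path: Path, vertices: np.ndarray, groups) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(groups))]
    for gid, (name, _) in enumerate(groups, start=1):
        lines.append(f'2 {gid} "{name}"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(len(vertices))]
    for i, (x, y, z) in enumerate(vertices, start=1):
        lines.append(f"{i} {x:.17g} {y:.17g} {z:.17g}")
    lines.append("$EndNodes")
    n_elem = sum(len(t) for _, t in groups)
    lines += ["$Elements", str(n_elem)]
    eid = 1
    for gid, (_, tris) in enumerate(groups, start=1):
        for a, b, c in tris + 1:
            lines.append(f"{eid} 2 2 {gid} {gid} {a} {b} {c}")
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _parse_msh(path: Path) -> dict:
    text = path.read_text().splitlines()
    i = 0
    names: dict[int, str] = {}
    vertices = None
    node_ids = None
    elements: list[tuple[int, tuple[int, int, int]]] = []

    def fail(msg, ln):
        raise MeshFormatError(f"{path.name}: line {ln + 1}: {msg}")

    while i < len(text):
        tok = text[i].strip()
        if tok == "$PhysicalNames":
            n = int(text[i + 1])
            for j in range(n):
                parts = text[i + 2 + j].split(maxsplit=2)
                names[int(parts[1])] = parts[2].strip().strip('"')
            i += n + 3
        elif tok == "$Nodes":
            n = int(text[i + 1])
            rows = text[i + 2 : i + 2 + n]
            try:
                arr = np.array([r.split() for r in rows], dtype=float)
            except ValueError:
                fail("malformed node record", i + 2)
            node_ids = arr[:, 0].astype(np.int64)
            vertices = arr[:, 1:4]
            i += n + 3
        elif tok == "$Elements":
            n = int(text[i + 1])
            for j in range(n):
                parts = text[i + 2 + j].split()
                if len(parts) < 5:
                    fail("malformed element record", i + 2 + j)
                etype = int(parts[1])
                if etype != 2:  # only 3-node triangles carry the surfaces
                    continue
                ntags = int(parts[2])
                phys = int(parts[3]) if ntags >= 1 else 0
                conn = tuple(int(p) for p in parts[3 + ntags : 6 + ntags])
                if len(conn) != 3:
                    fail("triangle with wrong connectivity", i + 2 + j)
                elements.append((phys, conn))
            i += n + 3
        else:
            i += 1
    if vertices is None:
        raise MeshFormatError(f"{path.name}: no $Nodes section")
    id_map = np.full(node_ids.max() + 1, -1, dtype=np.int64)
    id_map[node_ids] = np.arange(len(node_ids))
    by_group: dict[int, list] = {}
    for phys, conn in elements:
        by_group.setdefault(phys, []).append(conn)
    groups = []
    for phys in sorted(by_group):
        tris = id_map[np.array(by_group[phys], dtype=np.int64)]
        groups.append((names.get(phys, f"group{phys}"), tris))
    return {"vertices": vertices, "groups": groups}


# ---------------------------------------------------------------------------
# Subdivision and inter-shell distances
# ---------------------------------------------------------------------------

def barycentric_subdivide(mesh: SurfaceMesh, levels: int = 1) -> SurfaceMesh:
    """Barycentric (1:6) subdivision applied ``levels`` times.

    Each triangle is split into 6 subtriangles through its centroid and
    edge midpoints, so ``levels=2`` yields the 1:36 refinement used for
    inter-shell distance and observation-surface construction. Total area
    is conserved and subtriangle centroids stay in the parent plane.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    verts = mesh.vertices
    tris = mesh.triangles
    for _ in range(levels):
        verts, tris = _barycentric_once(verts, tris)
    return SurfaceMesh(verts, tris)


def _barycentric_once(verts: np.ndarray, tris: np.ndarray):
    n_v = len(verts)
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])
    cen = verts[tris].mean(axis=1)
    n_t = len(tris)
    mid_idx = n_v + inverse.reshape(3, n_t)      # midpoint vertex ids per edge slot
    cen_idx = n_v + len(uniq) + np.arange(n_t)
    m01, m12, m20 = mid_idx
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    c = cen_idx
    new_tris = np.stack(
        [
            np.column_stack([v0, m01, c]),
            np.column_stack([m01, v1, c]),
            np.column_stack([v1, m12, c]),
            np.column_stack([m12, v2, c]),
            np.column_stack([v2, m20, c]),
            np.column_stack([m20, v0, c]),
        ],
        axis=1,
    ).reshape(-1, 3)
    new_verts = np.concatenate([verts, mid, cen], axis=0)
    return new_verts, new_tris


def shell_distance(
    a: SurfaceMesh, b: SurfaceMesh, refine_levels: int = 2, symmetric: bool = False
) -> float:
    """Mean shortest centroid-to-centroid distance from shell ``a`` to ``b``.

    ``b`` is barycentrically refined ``refine_levels`` times (default 1:36)
    before the nearest-neighbour search. The measure is one-directional by
    default; ``symmetric=True`` averages both directions.
    """
    if a.n_triangles == 0 or b.n_triangles == 0:
        raise ValueError("shell_distance requires non-empty meshes")
    d_ab = _directed_shell_distance(a, b, refine_levels)
    if not symmetric:
        return d_ab
    return 0.5 * (d_ab + _directed_shell_distance(b, a, refine_levels))


def _directed_shell_distance(a, b, refine_levels):
    refined = barycentric_subdivide(b, refine_levels) if refine_levels >= 1 else b
    tree = cKDTree(refined.centroids)
    d, _ = tree.query(a.centroids, k=1)
    return float(d.mean())


def build_observation_surface(
    gm: SurfaceMesh,
    wm: SurfaceMesh,
    ratio: str = "1:1",
    refine_levels: int = 2,
    thickness_cap: float = 6.0,
) -> ObservationSurface:
    """Build the intracortical observation surface between GM and WM.

    For each GM facet centroid ``c`` the shortest vector ``v`` to the
    refined-WM centroid cloud is found and the sampling point placed at
    ``c + f * v`` with ``f = 0.5`` ("1:1" mid-surface, ~layer 2/3) or
    ``f = 0.8`` ("4:1", GM-side : WM-side distance 4:1, ~bottom of layer
    5). Points whose GM-WM vector exceeds ``thickness_cap`` (mm) are
    excluded as unpaired (e.g. across a ventricle or a mesh defect).
    """
    if wm.n_triangles == 0:
        raise ValueError("WM mesh is empty")
    fractions = {"1:1": 0.5, "4:1": 0.8}
    if ratio not in fractions:
        raise ValueError(f"ratio must be one of {sorted(fractions)}, got {ratio!r}")
    f = fractions[ratio]
    refined = barycentric_subdivide(wm, refine_levels) if refine_levels >= 1 else wm
    tree = cKDTree(refined.centroids)
    c = gm.centroids
    dist, idx = tree.query(c, k=1)
    v = refined.centroids[idx] - c
    keep = dist <= thickness_cap
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning(
            "observation surface: %d point(s) exceed the %.1f mm cortical-thickness cap",
            n_drop, thickness_cap,
        )
    return ObservationSurface(
        points=c[keep] + f * v[keep],
        source_facet=np.flatnonzero(keep),
        ratio=ratio,
        gm_wm_vector=v[keep],
        fraction=f,
    )


def export_observation_csv(obs: ObservationSurface, path) -> None:
    """Export observation points as CSV: point_id,x,y,z,source_facet,ratio."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "point_id": np.arange(len(obs)),
            "x": obs.points[:, 0],
            "y": obs.points[:, 1],
            "z": obs.points[:, 2],
            "source_facet": obs.source_facet,
            "ratio": obs.ratio,
        }
    )
    df.to_csv(path, index=False)
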