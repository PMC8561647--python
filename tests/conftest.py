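"""Shared fixtures: analytic micro-geometries and desk-scale phantom cases."""

import numpy as np
import pytest
import trimesh

from tmsfocal import SurfaceMesh, HeadModel
from tmsfocal.pipeline import build_case, run_batch


def make_plate(nx: int = 20, ny: int = 20, size: float = 60.0, z: float = 0.0,
               flip: bool = False) -> SurfaceMesh:
    """Flat square plate mesh in the z-plane (open; used as an analytic oracle)."""
    xs = np.linspace(-size / 2, size / 2, nx + 1)
    ys = np.linspace(-size / 2, size / 2, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    tris = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            b = (i + 1) * (ny + 1) + j
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    tris = np.array(tris, dtype=np.int64)
    if flip:
        tris = tris[:, ::-1]
    return SurfaceMesh(verts, tris)


def make_icosphere(radius: float, subdivisions: int = 2) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces, np.int64))


@pytest.fixture
def unit_tetra() -> SurfaceMesh:
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    tris = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(verts, tris)


@pytest.fixture(scope="session")
def homogeneous_sphere_system():
    """Single conducting sphere + factorized operator (forward-solver tests)."""
    from tmsfocal import assemble_system

    mesh = make_icosphere(80.0, 3)
    head = HeadModel([("skin", mesh, 0.3, 0.0)])
    return head, assemble_system(head)


@pytest.fixture(scope="session")
def small_case():
    """Coarse gyrus-phantom case for inverse-engine tests (N ~ 3k facets)."""
    return build_case(seed=3, n_targets=3, subdivisions=(1, 1, 2, 3, 3))


@pytest.fixture(scope="session")
def batch():
    """The seeded 10-run gyrus-phantom batch (acceptance criteria 2-4)."""
    reports, cases = run_batch(seed=7)
    return reports, cases
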