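"""BEM forward solver: contracts, physics invariants, sphere oracle."""

import numpy as np
import pytest

from tmsfocal import (
    CoilPose,
    HeadModel,
    assemble_system,
    coil_preset,
    primary_field,
    solve_charges,
    sphere_analytic_field,
    total_field,
    transform_coil,
)
from tmsfocal.forward import sphere_analytic_field_coil

from conftest import make_icosphere


@pytest.fixture(scope="module")
def placed_coil():
    return transform_coil(coil_preset("small"), CoilPose(center=(0.0, 0.0, 95.0)))


def interior_points(rmax, n=300, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return pts * rng.uniform(10.0, rmax, n)[:, None]


def test_no_contrast_head_gives_primary_field_only(placed_coil):
    mesh = make_icosphere(60.0, 1)
    head = HeadModel([("skin", mesh, 0.3, 0.0), ("skull", make_icosphere(40.0, 1),
                                                 0.3, 0.3)])
    system = assemble_system(head)
    # the no-contrast inner shell contributes no equations
    assert system.n_facets == mesh.n_triangles
    uniform = HeadModel([("skin", mesh, 0.0, 0.0)])  # no contrast anywhere
    empty = assemble_system(uniform)
    assert empty.n_facets == 0
    ch = solve_charges(empty, placed_coil)
    pts = interior_points(30.0, n=20)
    fm = total_field(empty, ch, placed_coil, None, pts)
    assert np.array_equal(fm.E, primary_field(placed_coil, pts))


def test_factorize_once_solve_many(homogeneous_sphere_system, placed_coil):
    _, system = homogeneous_sphere_system
    n0 = system.n_solves
    for _ in range(5):
        solve_charges(system, placed_coil)
    assert system.n_factorizations == 1
    assert system.n_solves == n0 + 5


def test_operator_matches_brute_force_double_loop():
    """Far-field operator entries equal an independent double loop over the
    row-averaged collocation rule (6 subtriangle centroids per row)."""
    from tmsfocal.forward import _bary_weights

    mesh = make_icosphere(50.0, 1)  # 80 facets
    head = HeadModel([("skin", mesh, 0.3, 0.0)])
    system = assemble_system(head)
    A = system.matrix
    w = _bary_weights(1)
    tri = mesh.vertices[mesh.triangles]
    c, nrm, ar = mesh.centroids, mesh.normals, mesh.areas
    edge = mesh.mean_edge_length
    checked = 0
    for m in range(0, mesh.n_triangles, 7):
        colloc = w @ tri[m]
        for k in range(mesh.n_triangles):
            if k == m or np.linalg.norm(c[m] - c[k]) <= 3.0 * edge:
                continue  # near entries use refined quadrature
            val = 0.0
            for p in colloc:
                d = p - c[k]
                val += ar[k] * (nrm[m] @ d) / (4 * np.pi * np.linalg.norm(d) ** 3)
            val /= len(colloc)
            assert abs(A[m, k] + val) < 1e-10
            checked += 1
    assert checked > 100


def test_charge_linearity(homogeneous_sphere_system, placed_coil):
    _, system = homogeneous_sphere_system
    zero = solve_charges(system, placed_coil, dIdt=0.0)
    assert np.all(zero.scaled_charge == 0.0)
    g1 = solve_charges(system, placed_coil, dIdt=1e7).scaled_charge
    g2 = solve_charges(system, placed_coil, dIdt=2e7).scaled_charge
    assert np.allclose(g2, 2 * g1, rtol=1e-10)


def test_charge_mirror_symmetry(homogeneous_sphere_system, placed_coil):
    """Coil above the pole: the figure-8 charge pattern is mirror-symmetric
    across the inter-wing plane (|g| at mirrored facets agrees within 1%)."""
    _, system = homogeneous_sphere_system
    g = solve_charges(system, placed_coil).scaled_charge
    c = system.centroids
    mirrored = c * np.array([1.0, -1.0, 1.0])
    from scipy.spatial import cKDTree

    d, idx = cKDTree(c).query(mirrored)
    exact = d < 1e-9  # icosphere tessellation is y-mirror symmetric
    assert exact.mean() > 0.9
    gm = g[idx[exact]]
    scale = np.abs(g).max()
    assert np.abs(np.abs(gm) - np.abs(g[exact])).max() < 0.01 * scale


def test_total_field_tangential_inside_sphere(homogeneous_sphere_system, placed_coil):
    _, system = homogeneous_sphere_system
    ch = solve_charges(system, placed_coil)
    pts = interior_points(70.0)
    fm = total_field(system, ch, placed_coil, None, pts)
    rad = np.einsum("ij,ij->i", fm.E, pts / np.linalg.norm(pts, axis=1)[:, None])
    assert np.linalg.norm(rad) / np.linalg.norm(fm.E) < 0.02


def test_superposition_of_two_coils(homogeneous_sphere_system):
    _, system = homogeneous_sphere_system
    c1 = transform_coil(coil_preset("small"), CoilPose(center=(0, 0, 95.0)))
    c2 = transform_coil(coil_preset("small"), CoilPose(center=(30.0, 0, 92.0),
                                                       pitch=0.3))
    pts = interior_points(60.0, n=50)
    f1 = total_field(system, solve_charges(system, c1), c1, None, pts)
    f2 = total_field(system, solve_charges(system, c2), c2, None, pts)
    both = np.concatenate  # combined cloud acts as one coil
    from tmsfocal.coilkit import Coil

    c12 = Coil(positions=both([c1.positions, c2.positions]),
               moments=both([c1.moments, c2.moments]),
               handle_axis=c1.handle_axis, normal_axis=c1.normal_axis,
               bounding_points=both([c1.bounding_points, c2.bounding_points]))
    f12 = total_field(system, solve_charges(system, c12), c12, None, pts)
    assert np.linalg.norm(f12.E - (f1.E + f2.E)) / np.linalg.norm(f12.E) < 1e-10


def test_corotation_invariance():
    """Rotating head and coil together leaves ||E|| at co-rotated points."""
    from scipy.spatial.transform import Rotation

    mesh = make_icosphere(70.0, 2)
    coil = coil_preset("small")
    pose = CoilPose(center=(5.0, -3.0, 84.0), pitch=0.1, yaw=0.5)
    placed = transform_coil(coil, pose)
    pts = interior_points(55.0, n=60, seed=3)

    head = HeadModel([("skin", mesh, 0.3, 0.0)])
    system = assemble_system(head)
    f0 = total_field(system, solve_charges(system, placed), placed, None, pts)

    R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
    from dataclasses import replace
    from tmsfocal import SurfaceMesh

    rot_mesh = SurfaceMesh(mesh.vertices @ R.T, mesh.triangles)
    rot_coil = replace(placed,
                       positions=placed.positions @ R.T,
                       moments=placed.moments @ R.T,
                       handle_axis=R @ placed.handle_axis,
                       normal_axis=R @ placed.normal_axis,
                       bounding_points=placed.bounding_points @ R.T)
    rot_head = HeadModel([("skin", rot_mesh, 0.3, 0.0)])
    system_r = assemble_system(rot_head)
    f1 = total_field(system_r, solve_charges(system_r, rot_coil), rot_coil, None,
                     pts @ R.T)
    assert np.abs(f1.magnitude - f0.magnitude).max() / f0.magnitude.max() < 1e-8


def test_sphere_analytic_center_and_linearity():
    m = np.array([0.0, 0.0, 2e-4])
    pos = np.array([0.0, 0.0, 95.0])
    fm = sphere_analytic_field(pos, m, 9.4e7, [0, 0, 0], [[0.0, 0.0, 0.0]],
                               sphere_radius=80.0)
    assert np.allclose(fm.E, 0.0)  # dipole at center sees no external B
    pts = interior_points(70.0, n=40)
    e1 = sphere_analytic_field(pos, m, 1e7, [0, 0, 0], pts).E
    e2 = sphere_analytic_field(pos, 2 * m, 2e7, [0, 0, 0], pts).E
    assert np.allclose(e2, 4 * e1, rtol=1e-12)
    rad = np.einsum("ij,ij->i", e1, pts / np.linalg.norm(pts, axis=1)[:, None])
    assert np.abs(rad).max() < 1e-12 * np.abs(e1).max()


def test_sphere_analytic_preconditions():
    m = [0.0, 0.0, 1e-4]
    with pytest.raises(ValueError, match="outside"):
        sphere_analytic_field([0, 0, 50.0], m, 1e7, [0, 0, 0], [[0, 0, 0]],
                              sphere_radius=80.0)
    with pytest.raises(ValueError, match="inside"):
        sphere_analytic_field([0, 0, 95.0], m, 1e7, [0, 0, 0], [[0, 0, 90.0]],
                              sphere_radius=80.0)


def test_bem_vs_analytic_coarse_sanity(placed_coil):
    """Coarse (320-facet) sphere already lands within ~10% of the closed
    form; the default-density check lives in the acceptance suite."""
    mesh = make_icosphere(80.0, 2)
    head = HeadModel([("skin", mesh, 0.3, 0.0)])
    system = assemble_system(head)
    ch = solve_charges(system, placed_coil)
    pts = interior_points(70.0, n=200)
    fm = total_field(system, ch, placed_coil, None, pts)
    an = sphere_analytic_field_coil(placed_coil, [0, 0, 0], pts, sphere_radius=80.0)
    assert np.linalg.norm(fm.E - an.E) / np.linalg.norm(an.E) < 0.10
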