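"""Habit construction, vertex enumeration, canonical morphology, metrics."""
import numpy as np
import pytest
from scipy.spatial import ConvexHull, HalfspaceIntersection
from scipy.spatial.distance import cdist

from facetfit._geometry import rotation_matrix, rotvec_from_matrix
from facetfit.errors import DegenerateShapeError, HabitMismatchError, UnboundedShapeError
from facetfit.habit import (
    CrystalConfiguration,
    CrystalHabit,
    build_polyhedron,
    canonicalize,
    config_metrics,
    normals_from_miller,
    vertex_distance,
)

from conftest import random_bounded_habit, random_config


# -- miller normals ---------------------------------------------------------

@pytest.mark.parametrize(
    "cell,hkl,expected",
    [
        ((1, 1, 1, 90, 90, 90), (1, 0, 0), (1, 0, 0)),
        ((1, 1, 1, 90, 90, 90), (1, 1, 0), (1 / np.sqrt(2), 1 / np.sqrt(2), 0)),
        # orthorhombic a=2: a* = (1/2,0,0), b* = (0,1,0) => (1,2,0)/sqrt(5)
        ((2, 1, 1, 90, 90, 90), (1, 1, 0), (1 / np.sqrt(5), 2 / np.sqrt(5), 0)),
    ],
)
def test_miller_normal_directions(cell, hkl, expected):
    n = normals_from_miller(cell, [hkl])[0]
    assert np.allclose(n, expected, atol=1e-12)


def test_miller_normals_match_crystallographic_d_spacings():
    """The reciprocal metric implied by the unnormalized reciprocal vectors
    must reproduce gemmi's interplanar d-spacings on a triclinic cell."""
    gemmi = pytest.importorskip("gemmi")
    from facetfit._geometry import reciprocal_lattice_vectors

    cell_t = (7.068, 10.277, 8.755, 83.2, 99.1, 101.5)
    B = reciprocal_lattice_vectors(cell_t)
    cell = gemmi.UnitCell(*cell_t)
    rng = np.random.default_rng(0)
    for _ in range(20):
        hkl = rng.integers(-3, 4, 3)
        if not hkl.any():
            continue
        d_ours = 1.0 / np.linalg.norm(hkl @ B)
        assert d_ours == pytest.approx(cell.calculate_d([int(x) for x in hkl]), rel=1e-12)


try:
    from hypothesis import given, settings as hyp_settings, strategies as st

    _miller = st.tuples(
        st.integers(-3, 3), st.integers(-3, 3), st.integers(-3, 3)
    ).filter(lambda t: any(t))
    _length = st.floats(0.5, 20.0, allow_nan=False)
    _angle = st.floats(60.0, 120.0, allow_nan=False)

    @hyp_settings(deadline=None, max_examples=40, derandomize=True)
    @given(_length, _length, _length, _angle, _angle, _angle, _miller)
    def test_miller_normals_are_unit_and_scale_invariant(a, b, c, al, be, ga, hkl):
        """Property: normals are unit vectors, and uniformly scaling the
        cell leaves the plane-normal direction unchanged."""
        from facetfit.errors import InvalidCellError

        cell = (a, b, c, al, be, ga)
        try:
            n1 = normals_from_miller(cell, [hkl])[0]
        except (InvalidCellError, ValueError):
            return  # angle triple does not define a 3D lattice
        assert np.linalg.norm(n1) == pytest.approx(1.0, abs=1e-9)
        n2 = normals_from_miller((3 * a, 3 * b, 3 * c, al, be, ga), [hkl])[0]
        assert np.allclose(n1, n2, atol=1e-9)

except ImportError:  # pragma: no cover - hypothesis is part of the test extra
    pass


def test_miller_rejects_degenerate_cells():
    from facetfit.errors import InvalidCellError

    # angle triple violating the triangle-like inequality: no 3D lattice
    with pytest.raises((InvalidCellError, ValueError)):
        normals_from_miller((1, 1, 1, 30, 150, 90), [(1, 0, 0)])
    with pytest.raises(ValueError):
        normals_from_miller((1, 1, 1, 90, 90, 90), [(0, 0, 0)])


# -- polyhedron construction ------------------------------------------------

def test_unit_cube(cube_habit):
    cfg = CrystalConfiguration(cube_habit, np.ones(6))
    mesh = build_polyhedron(cube_habit, cfg)
    corners = np.array(sorted(map(tuple, np.round(mesh.vertices, 9))))
    expected = np.array(sorted({(x, y, z) for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)}))
    assert np.allclose(corners, expected)
    assert np.allclose(mesh.face_areas, 4.0)
    assert mesh.volume == pytest.approx(8.0)
    assert mesh.euler_characteristic() == 2


def test_octahedron_against_halfspace_oracle(octa_habit):
    cfg = CrystalConfiguration(octa_habit, np.ones(8))
    mesh = build_polyhedron(octa_habit, cfg)
    s3 = np.sqrt(3)
    expected = np.array(
        [[s3, 0, 0], [-s3, 0, 0], [0, s3, 0], [0, -s3, 0], [0, 0, s3], [0, 0, -s3]]
    )
    assert len(mesh.vertices) == 6
    assert cdist(mesh.vertices_crystal, expected).min(axis=0).max() < 1e-9
    assert mesh.volume == pytest.approx(4.0 / 3.0 * 3 ** 1.5, rel=1e-9)


def test_corner_touching_plane_has_zero_area(cube_habit):
    normals = np.vstack([cube_habit.normals, [[1, 1, 1] / np.sqrt(3)]])
    habit = CrystalHabit.from_normals("cube+corner", normals)
    d = np.concatenate([np.ones(6), [np.sqrt(3)]])
    mesh = build_polyhedron(habit, CrystalConfiguration(habit, d))
    assert len(mesh.vertices) == 8
    assert 6 in mesh.zero_area_faces
    assert mesh.face_areas[6] == 0.0
    assert mesh.volume == pytest.approx(8.0)


def test_unbounded_habit_raises():
    # all normals in the upper half-space: open in the -z direction
    normals = np.array([[1, 0, 0.5], [-1, 0, 0.5], [0, 1, 0.5], [0, -1, 0.5], [0, 0, 1]])
    habit = CrystalHabit.from_normals("open", normals)
    with pytest.raises(UnboundedShapeError):
        build_polyhedron(habit, CrystalConfiguration(habit, np.ones(5)))


def test_halfspace_intersection_oracle_random_shapes():
    """Vertices, total area and volume agree with scipy's half-space
    intersection (dual convex hull) on 200 random bounded systems."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        habit = random_bounded_habit(rng)
        cfg = random_config(habit, rng, rotate=False)
        try:
            mesh = build_polyhedron(habit, cfg)
        except DegenerateShapeError:
            continue
        halfspaces = np.column_stack([habit.normals, -cfg.distances])
        # interior point: the Chebyshev-ish centroid (origin works: d > 0)
        hs = HalfspaceIntersection(halfspaces, np.zeros(3))
        oracle = ConvexHull(hs.intersections)
        ours = mesh.vertices_crystal
        lam = cdist(ours, hs.intersections[oracle.vertices])
        assert lam.min(axis=1).max() < 1e-6, "extra vertex not in oracle"
        assert lam.min(axis=0).max() < 1e-6, "oracle vertex missed"
        assert mesh.volume == pytest.approx(oracle.volume, rel=1e-6)
        assert mesh.face_areas.sum() == pytest.approx(oracle.area, rel=1e-6)


def test_vertex_filter_soundness():
    """Every returned vertex satisfies all half-space constraints."""
    rng = np.random.default_rng(11)
    for _ in range(25):
        habit = random_bounded_habit(rng)
        cfg = random_config(habit, rng)
        try:
            mesh = build_polyhedron(habit, cfg)
        except DegenerateShapeError:
            continue
        slack = mesh.vertices_crystal @ habit.normals.T - cfg.distances
        assert slack.max() < 1e-6 * np.abs(cfg.distances).max()


def test_watertightness_euler_characteristic():
    rng = np.random.default_rng(13)
    checked = 0
    for _ in range(40):
        habit = random_bounded_habit(rng)
        cfg = random_config(habit, rng)
        try:
            mesh = build_polyhedron(habit, cfg)
        except DegenerateShapeError:
            continue
        assert mesh.euler_characteristic() == 2
        for fids in mesh.edges.values():
            assert len(fids) == 2
        checked += 1
    assert checked > 20


def test_monotone_envelope_volume():
    """Increasing any single distance never decreases the volume."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        habit = random_bounded_habit(rng)
        cfg = random_config(habit, rng, rotate=False)
        try:
            v0 = build_polyhedron(habit, cfg).volume
        except DegenerateShapeError:
            continue
        i = rng.integers(habit.n_faces)
        cfg2 = cfg.copy()
        cfg2.distances[i] *= 1.3
        assert build_polyhedron(habit, cfg2).volume >= v0 - 1e-12


# -- canonical morphology ---------------------------------------------------

def test_canonicalize_clamps_grown_out_faces(cube_habit):
    normals = np.vstack([cube_habit.normals, [[1, 1, 1] / np.sqrt(3)]])
    habit = CrystalHabit.from_normals("cube+corner", normals)
    d = np.concatenate([np.ones(6), [2 * np.sqrt(3)]])
    canon = canonicalize(CrystalConfiguration(habit, d))
    # the clamp takes the corner plane to the envelope max N.v = sqrt(3);
    # the least-squares origin of the clamped 7-plane system is (1,1,1)/3
    # (solve (2I + n n^T) o = (1,1,1) with n = (1,1,1)/sqrt(3)), which
    # shifts the canonical corner distance to sqrt(3) - n.o = 2/sqrt(3)
    assert canon.distances[6] == pytest.approx(2 / np.sqrt(3), abs=1e-9)
    assert canon.origin == pytest.approx(np.full(3, 1 / 3), abs=1e-9)
    # the envelope itself sits exactly at the threshold of appearance
    mesh = build_polyhedron(habit, canon)
    env = np.max(mesh.vertices_crystal @ habit.normals.T, axis=0)
    assert env[6] == pytest.approx(canon.distances[6], abs=1e-9)


def test_canonicalize_is_idempotent(cube_habit, lga_habit):
    rng = np.random.default_rng(19)
    for habit in (cube_habit, lga_habit):
        for _ in range(10):
            cfg = random_config(habit, rng)
            c1 = canonicalize(cfg)
            c2 = canonicalize(c1)
            assert np.allclose(c1.distances, c2.distances, atol=1e-8)
            assert np.allclose(c1.origin, c2.origin, atol=1e-8)
            assert np.allclose(
                rotation_matrix(c1.rotation), rotation_matrix(c2.rotation), atol=1e-8
            )


def test_canonicalize_recenters_origin(cube_habit):
    """Distances encoding an off-center origin are recentred; the posed
    shape is unchanged."""
    d = np.array([1.3, 0.7, 1.0, 1.0, 1.0, 1.0])  # origin displaced 0.3 in +x
    cfg = CrystalConfiguration(cube_habit, d)
    canon = canonicalize(cfg)
    assert np.allclose(canon.distances, 1.0, atol=1e-9)
    assert np.allclose(canon.origin, [0.3, 0, 0], atol=1e-9)
    v0 = np.sort(build_polyhedron(cube_habit, cfg).vertices, axis=0)
    v1 = np.sort(build_polyhedron(cube_habit, canon).vertices, axis=0)
    assert np.allclose(v0, v1, atol=1e-9)


def test_symmetry_op_invariance(cube_habit, lga_habit):
    """Applying any habit symmetry op before canonicalization changes
    nothing: same canonical distances and zero vertex distance."""
    rng = np.random.default_rng(23)
    for habit in (cube_habit, lga_habit):
        cfg = random_config(habit, rng)
        canon = canonicalize(cfg)
        for Q, perm in habit.symmetry_ops[:8]:
            inv = np.empty_like(perm)
            inv[perm] = np.arange(len(perm))
            alt = cfg.copy()
            alt.distances = cfg.distances[inv]
            alt.rotation = rotvec_from_matrix(rotation_matrix(cfg.rotation) @ Q.T)
            canon_alt = canonicalize(alt)
            assert np.allclose(canon_alt.distances, canon.distances, atol=1e-8)
            m = config_metrics(canon_alt, canon)
            assert m.E_v < 1e-8


# -- metrics ---------------------------------------------------------------

def test_metrics_identical_configs_are_zero(lga_habit):
    cfg = canonicalize(random_config(lga_habit, np.random.default_rng(3)))
    m = config_metrics(cfg, cfg)
    for v in (m.E_d, m.E_v, m.L_d, m.L_P, m.L_R, m.L_m, m.L_l):
        assert v == pytest.approx(0.0, abs=1e-12)


def test_metrics_distance_offset(cube_habit):
    a = CrystalConfiguration(cube_habit, np.ones(6))
    b = CrystalConfiguration(cube_habit, np.full(6, 1.1))
    m = config_metrics(a, b)
    assert m.E_d == pytest.approx(0.1)
    assert m.L_d == pytest.approx(6 * 0.1**2)


def test_vertex_distance_matches_hand_computed_table():
    """Bidirectional nearest-neighbor mean on tiny explicit sets."""
    A = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    B = np.array([[0.0, 0, 0], [0.0, 2.0, 0], [4.0, 0, 0]])
    # row mins: 0, min(1, sqrt(5), 3)=1 ; col mins: 0, 2, 3
    expected = (0 + 1 + 0 + 2 + 3) / 5
    assert vertex_distance(A, B) == pytest.approx(expected)
    assert vertex_distance(B, A) == pytest.approx(expected)


def test_metrics_rejects_habit_mismatch(cube_habit, octa_habit):
    a = CrystalConfiguration(cube_habit, np.ones(6))
    b = CrystalConfiguration(octa_habit, np.ones(8))
    with pytest.raises(HabitMismatchError):
        config_metrics(a, b)


def test_rotation_metric_is_geodesic(cube_habit):
    a = CrystalConfiguration(cube_habit, np.ones(6))
    b = CrystalConfiguration(cube_habit, np.ones(6), rotation=np.array([0.0, 0.0, 0.4]))
    assert config_metrics(a, b).L_R == pytest.approx(0.4, abs=1e-9)
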