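"""Polyhedral crystal shapes: habits, configurations, meshes.

A crystal *habit* fixes the set of bounding lattice planes (unit normals
``N_i`` derived from Miller indices and the unit cell), their grouping into
crystallographically equivalent *forms*, and the point-group rotations that
map the face set onto itself.  A *configuration* adds the per-face
center-to-plane distances ``d_i`` (mm), a pose (axis-angle rotation applied
first, then a translation of the internal origin into the cell frame) and
the material scalars used by downstream losses.

The polyhedron itself is recovered by enumerating the intersection points of
all linearly independent plane triples and keeping the points inside every
half-space — the classical vertex-enumeration route for convex
habit morphologies.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from ._geometry import (
    geodesic_angle,
    reciprocal_lattice_vectors,
    rotation_matrix,
    rotvec_from_matrix,
)
from .errors import (
    DegenerateShapeError,
    HabitMismatchError,
    InvalidCellError,
    UnboundedShapeError,
)

# Relative tolerances (scaled by max |d_i|): vertex dedup and half-space
# membership.  Plane triples with condition number above COND_MAX are treated
# as linearly dependent and skipped.
DEDUP_RTOL = 1e-8
INSIDE_RTOL = 1e-8
COND_MAX = 1e8


def normals_from_miller(unit_cell, miller_faces) -> np.ndarray:
    """Unit face normals for Miller indices ``(h, k, l)``.

    The normal of the lattice plane family (h, k, l) is the reciprocal
    lattice vector ``h a* + k b* + l c*``; only its direction matters here.
    """
    miller = np.atleast_2d(np.asarray(miller_faces, dtype=float))
    if miller.shape[1] != 3:
        raise ValueError("miller_faces must be (m, 3)")
    if np.any(np.abs(miller).sum(axis=1) == 0):
        raise ValueError("each face needs a nonzero (h, k, l)")
    try:
        B = reciprocal_lattice_vectors(unit_cell)
    except ValueError as exc:
        raise InvalidCellError(str(exc)) from exc
    raw = miller @ B
    norms = np.linalg.norm(raw, axis=1)
    return raw / norms[:, None]


@dataclass(frozen=True)
class CrystalHabit:
    """Immutable habit definition.

    ``symmetry_ops`` is a list of ``(Q, perm)`` pairs with ``Q`` a proper
    rotation in the crystal Cartesian frame and ``perm`` the induced face
    permutation, ``Q @ N[i] == N[perm[i]]``.  The identity must be present.
    """

    name: str
    normals: np.ndarray  # (m, 3) unit vectors, crystal frame
    face_groups: tuple  # tuple of tuples of face indices
    symmetry_ops: tuple  # tuple of (Q (3,3), perm (m,)) pairs
    unit_cell: tuple | None = None
    miller_faces: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "normals", np.asarray(self.normals, dtype=float))
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_miller(cls, name, unit_cell, miller_faces, face_groups, symmetry_ops):
        normals = normals_from_miller(unit_cell, miller_faces)
        return cls(
            name=name,
            normals=normals,
            face_groups=tuple(tuple(g) for g in face_groups),
            symmetry_ops=tuple((np.asarray(Q, float), np.asarray(p, int)) for Q, p in symmetry_ops),
            unit_cell=tuple(float(x) for x in unit_cell),
            miller_faces=tuple(tuple(int(v) for v in f) for f in miller_faces),
        )

    @classmethod
    def from_normals(cls, name, normals, face_groups=None, symmetry_ops=None):
        """Habit from explicit normals (e.g. test shapes without a lattice)."""
        normals = np.asarray(normals, dtype=float)
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
        m = len(normals)
        if face_groups is None:
            face_groups = [(i,) for i in range(m)]
        if symmetry_ops is None:
            symmetry_ops = [(np.eye(3), np.arange(m))]
        return cls(
            name=name,
            normals=normals,
            face_groups=tuple(tuple(g) for g in face_groups),
            symmetry_ops=tuple((np.asarray(Q, float), np.asarray(p, int)) for Q, p in symmetry_ops),
        )

    # -- invariants -------------------------------------------------------
    def _validate(self):
        N = self.normals
        m = self.n_faces
        if not np.allclose(np.linalg.norm(N, axis=1), 1.0, atol=1e-9):
            raise ValueError("habit normals must be unit length")
        flat = sorted(i for g in self.face_groups for i in g)
        if flat != list(range(m)):
            raise ValueError("face_groups must partition the face indices")
        has_identity = False
        group_of = self.group_index
        for Q, perm in self.symmetry_ops:
            if sorted(perm.tolist()) != list(range(m)):
                raise ValueError("symmetry permutation is not a bijection")
            if not np.allclose(Q @ Q.T, np.eye(3), atol=1e-8) or np.linalg.det(Q) < 0:
                raise ValueError("symmetry op is not a proper rotation")
            if not np.allclose(N[perm], N @ Q.T, atol=1e-6):
                raise ValueError("symmetry permutation inconsistent with rotation")
            if np.any(group_of[perm] != group_of):
                raise ValueError("symmetry permutation crosses face groups")
            if np.allclose(Q, np.eye(3), atol=1e-12):
                has_identity = True
        if not has_identity:
            raise ValueError("identity symmetry op must be present")

    @property
    def n_faces(self) -> int:
        return len(self.normals)

    @property
    def group_index(self) -> np.ndarray:
        """Per-face index of the containing form."""
        out = np.empty(self.n_faces, dtype=int)
        for k, g in enumerate(self.face_groups):
            out[list(g)] = k
        return out

    def is_bounded(self) -> bool:
        """Whether the half-space system is bounded for *any* positive distances.

        True iff the normals positively span R^3, i.e. 0 is an interior point
        of their convex hull (checked by a small LP, cached per habit —
        boundedness depends only on the normals).
        """
        cached = getattr(self, "_bounded_cache", None)
        if cached is not None:
            return cached
        m = self.n_faces
        if m < 4:
            return False
        A_eq = np.vstack([self.normals.T, np.ones(m)])
        b_eq = np.array([0.0, 0.0, 0.0, 1.0])
        res = linprog(
            c=np.zeros(m),
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=[(1e-9, None)] * m,
            method="highs",
        )
        object.__setattr__(self, "_bounded_cache", bool(res.success))
        return bool(res.success)


@dataclass
class CrystalConfiguration:
    """Fit state: shape distances plus pose and material scalars."""

    habit: CrystalHabit
    distances: np.ndarray  # (m,) mm, positive
    origin: np.ndarray = None  # (3,) mm, cell frame; z up toward camera
    rotation: np.ndarray = None  # (3,) axis-angle, radians
    refractive_index: float = 1.0
    roughness: float = 0.0
    light: np.ndarray = None  # (3,) RGB radiance, metric parity only

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).copy()
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, float).copy()
        )
        self.rotation = (
            np.zeros(3) if self.rotation is None else np.asarray(self.rotation, float).copy()
        )
        self.light = (
            np.ones(3) if self.light is None else np.asarray(self.light, float).copy()
        )
        if len(self.distances) != self.habit.n_faces:
            raise ValueError("need one distance per habit face")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")
        if self.refractive_index <= 0:
            raise ValueError("refractive index must be positive")

    def copy(self) -> "CrystalConfiguration":
        return CrystalConfiguration(
            habit=self.habit,
            distances=self.distances.copy(),
            origin=self.origin.copy(),
            rotation=self.rotation.copy(),
            refractive_index=self.refractive_index,
            roughness=self.roughness,
            light=self.light.copy(),
        )

    @property
    def size(self) -> float:
        """Crystal size used for normalization: mean center-to-plane distance."""
        return float(np.mean(self.distances))


@dataclass
class PolyhedronMesh:
    """Posed convex polyhedron with per-face vertex cycles.

    ``vertices`` are in the cell frame (rotation applied, then translation);
    ``vertices_crystal`` keeps the unposed coordinates used by the canonical
    morphology.  ``faces[i]`` is the counter-clockwise cycle (viewed from
    outside along ``+N_i``) of indices into ``vertices``; grown-out faces have
    cycles with fewer than three distinct vertices and zero area.
    """

    vertices: np.ndarray  # (n, 3) mm, posed
    vertices_crystal: np.ndarray  # (n, 3) mm, crystal frame
    faces: list  # per-face vertex cycles
    face_areas: np.ndarray  # (m,)
    volume: float
    zero_area_faces: set
    normals_crystal: np.ndarray  # (m, 3) habit normals N_i
    normals_world: np.ndarray  # (m, 3) R @ N_i
    plane_offsets_world: np.ndarray  # (m,) x . n_world = offset
    vertex_faces: list  # per-vertex sorted incident face indices
    vertex_triples: np.ndarray  # (n, 3) defining plane triple per vertex

    @property
    def edges(self) -> dict:
        """Map (vi, vj) with vi < vj -> sorted list of incident face ids."""
        out: dict = {}
        for fid, cycle in enumerate(self.faces):
            if fid in self.zero_area_faces or len(cycle) < 3:
                continue
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                key = (a, b) if a < b else (b, a)
                out.setdefault(key, []).append(fid)
        return {k: sorted(v) for k, v in out.items()}

    def triangles(self) -> np.ndarray:
        """Fan triangulation around each face centroid, (T, 3, 3) posed coords."""
        tris = []
        for fid, cycle in enumerate(self.faces):
            if len(set(cycle)) < 3:
                continue
            pts = self.vertices[list(cycle)]
            centroid = pts.mean(axis=0)
            for a, b in zip(pts, np.roll(pts, -1, axis=0)):
                tris.append([centroid, a, b])
        return np.asarray(tris)

    def euler_characteristic(self) -> int:
        n_f = sum(1 for i, c in enumerate(self.faces) if i not in self.zero_area_faces and len(c) >= 3)
        return len(self.vertices) - len(self.edges) + n_f


def build_polyhedron(habit: CrystalHabit, config: CrystalConfiguration) -> PolyhedronMesh:
    """Construct the posed polyhedral mesh of a configuration.

    Candidate vertices are the intersections of all linearly independent
    plane triples; those inside every half-space (within a scale-relative
    tolerance) survive, coincident candidates are merged, and each surviving
    vertex keeps the full set of incident faces (4-fold and higher vertices
    are common in symmetric habits).
    """
    N = habit.normals
    d = np.asarray(config.distances, dtype=float)
    m = habit.n_faces
    if m < 4:
        raise DegenerateShapeError("need at least four faces")
    if not habit.is_bounded():
        raise UnboundedShapeError(f"habit {habit.name!r} normals do not positively span R^3")

    scale = float(np.max(np.abs(d)))
    tol_in = INSIDE_RTOL * scale
    tol_dedup = DEDUP_RTOL * scale

    triples = np.array(list(itertools.combinations(range(m), 3)))
    A = N[triples]  # (T, 3, 3)
    dets = np.linalg.det(A)
    # condition-number screen for (near) linearly dependent triples
    svals = np.linalg.svd(A, compute_uv=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = svals[:, 0] / svals[:, 2]
    ok = (np.abs(dets) > 1e-300) & np.isfinite(cond) & (cond < COND_MAX)
    if not np.any(ok):
        raise DegenerateShapeError("no linearly independent plane triples")
    cand = np.linalg.solve(A[ok], d[triples[ok]][..., None])[..., 0]
    cand_triples = triples[ok]

    inside = np.all(cand @ N.T <= d[None, :] + tol_in, axis=1)
    cand = cand[inside]
    cand_triples = cand_triples[inside]
    if len(cand) < 4:
        raise DegenerateShapeError("fewer than four polyhedral vertices")

    # dedup coincident candidates, keeping the best-conditioned defining triple
    verts, vert_triples = [], []
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    for idx in order:
        v = cand[idx]
        for j, u in enumerate(verts):
            if np.max(np.abs(v - u)) <= tol_dedup:
                break
        else:
            verts.append(v)
            vert_triples.append(cand_triples[idx])
    V = np.asarray(verts)
    n = len(V)
    if n < 4:
        raise DegenerateShapeError("fewer than four distinct vertices")

    # face incidence (within tolerance of each plane)
    on_plane = np.abs(V @ N.T - d[None, :]) <= 10 * tol_in
    vertex_faces = [sorted(np.nonzero(on_plane[i])[0].tolist()) for i in range(n)]

    # per-face CCW cycles about the outward normal
    faces, zero_area = [], set()
    for i in range(m):
        vids = np.nonzero(on_plane[:, i])[0]
        if len(vids) < 3:
            faces.append(list(vids))
            zero_area.add(i)
            continue
        ni = N[i]
        e1 = np.cross(ni, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(ni, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ni, e1)
        pts = V[vids]
        rel = pts - pts.mean(axis=0)
        ang = np.arctan2(rel @ e2, rel @ e1)
        cyc = vids[np.argsort(ang)].tolist()
        # (e1, e2, ni) is right-handed, so ascending angle is CCW about +ni
        faces.append(cyc)

    # pose
    R = rotation_matrix(config.rotation)
    V_world = V @ R.T + config.origin
    normals_world = N @ R.T
    offsets_world = d + normals_world @ config.origin

    # areas as sums of centroid-fan triangle areas; volume as signed
    # tetrahedra (apex at the crystal-frame origin) over the same fans
    areas = np.zeros(m)
    volume = 0.0
    for i, cyc in enumerate(faces):
        if len(set(cyc)) < 3:
            zero_area.add(i)
            continue
        pts = V[cyc]
        cen = pts.mean(axis=0)
        a = pts - cen
        b = np.roll(pts, -1, axis=0) - cen
        cross = np.cross(a, b)
        areas[i] = 0.5 * np.linalg.norm(cross, axis=1).sum()
        for pa, pb in zip(pts, np.roll(pts, -1, axis=0)):
            volume += np.dot(cen, np.cross(pa, pb)) / 6.0

    return PolyhedronMesh(
        vertices=V_world,
        vertices_crystal=V,
        faces=faces,
        face_areas=areas,
        volume=float(volume),
        zero_area_faces=zero_area,
        normals_crystal=N.copy(),
        normals_world=normals_world,
        plane_offsets_world=offsets_world,
        vertex_faces=vertex_faces,
        vertex_triples=np.asarray(vert_triples, dtype=int),
    )


def canonicalize(config: CrystalConfiguration) -> CrystalConfiguration:
    """Resolve the three representational ambiguities of a configuration.

    (i) grown-out plane distances are clamped to the threshold of appearance
    ``d_i <- max_v N_i . v``; (ii) among the habit's symmetry rotations the
    one whose composition with the pose has the smallest geodesic angle to
    the identity is applied (distances permuted accordingly; ties prefer the
    identity, then the lowest op index, for determinism and idempotence);
    (iii) the internal origin is moved to the least-squares point of the
    plane system, compensating the pose translation so the posed shape is
    unchanged.  Idempotent.
    """
    habit = config.habit
    mesh = build_polyhedron(habit, config)
    V = mesh.vertices_crystal
    d = np.max(V @ habit.normals.T, axis=0)

    R = rotation_matrix(config.rotation)
    angles = []
    for Q, _ in habit.symmetry_ops:
        angles.append(geodesic_angle(R @ Q.T, np.eye(3)))
    angles = np.asarray(angles)
    best = float(np.min(angles))
    tied = np.nonzero(angles <= best + 1e-9)[0]
    chosen = None
    for idx in tied:
        Q, _ = habit.symmetry_ops[idx]
        if np.allclose(Q, np.eye(3), atol=1e-12):
            chosen = idx
            break
    if chosen is None:
        chosen = int(tied[0])
    Q, perm = habit.symmetry_ops[chosen]
    inv_perm = np.empty_like(perm)
    inv_perm[perm] = np.arange(len(perm))
    d = d[inv_perm]
    R_new = R @ Q.T

    # least-squares origin of the plane system
    N = habit.normals
    o, *_ = np.linalg.lstsq(N, d, rcond=None)
    d = d - N @ o
    P_new = config.origin + R_new @ o

    out = config.copy()
    out.distances = d
    out.rotation = rotvec_from_matrix(R_new)
    out.origin = P_new
    return out


@dataclass
class ConfigMetrics:
    """Agreement metrics between two configurations on the same habit."""

    E_d: float  # mean |d_i - d^_i|, mm
    E_v: float  # bidirectional nearest-neighbor mean vertex distance, mm
    L_d: float  # squared distance-vector norm
    L_P: float  # squared origin offset
    L_R: float  # geodesic rotation angle, rad
    L_m: float  # (d eta)^2 + (d r)^2
    L_l: float  # squared light radiance offset


def vertex_distance(Va: np.ndarray, Vb: np.ndarray) -> float:
    """Bidirectional nearest-neighbor mean distance between 3D vertex sets."""
    lam = cdist(Va, Vb)
    return float(np.mean(np.concatenate([lam.min(axis=1), lam.min(axis=0)])))


def config_metrics(pred: CrystalConfiguration, target: CrystalConfiguration) -> ConfigMetrics:
    """Error metrics between a predicted and a target configuration.

    Both configurations should be canonical; vertices are compared posed in
    the cell frame.
    """
    if pred.habit.name != target.habit.name or pred.habit.n_faces != target.habit.n_faces:
        raise HabitMismatchError("configurations are on different habits")
    dd = pred.distances - target.distances
    mesh_p = build_polyhedron(pred.habit, pred)
    mesh_t = build_polyhedron(target.habit, target)
    Rp = rotation_matrix(pred.rotation)
    Rt = rotation_matrix(target.rotation)
    return ConfigMetrics(
        E_d=float(np.mean(np.abs(dd))),
        E_v=vertex_distance(mesh_p.vertices, mesh_t.vertices),
        L_d=float(np.dot(dd, dd)),
        L_P=float(np.sum((pred.origin - target.origin) ** 2)),
        L_R=geodesic_angle(Rp, Rt),
        L_m=float((pred.refractive_index - target.refractive_index) ** 2 + (pred.roughness - target.roughness) ** 2),
        L_l=float(np.sum((pred.light - target.light) ** 2)),
    )
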