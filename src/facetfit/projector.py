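"""Orthographic wireframe projection with refraction of back edges.

The crystal is viewed from above along ``-z`` with an orthographic camera.
Front faces (posed outward normal with positive z-component) are projected
directly; every front face also acts as a refraction *window* through which
the hidden back edges appear, displaced according to the vector form of
Snell's law.  Because the refracted ray direction inside the crystal is the
same for every ray entering a given planar window, the refracted image of a
straight edge is itself a straight segment, so projecting the two endpoints
suffices.  Refracted segments are clipped to the projected window polygon;
clip points on the window boundary are first-class keypoints alongside the
projected (direct and refracted) vertices.

``project_wireframe`` additionally records a :class:`ProjectionTrace` — the
discrete combinatorics of the projection (defining plane triples, window
assignments, clip edges, keypoint merge groups).  With the combinatorics
frozen, the map from configuration parameters to keypoint positions is
smooth, and :func:`smooth_keypoints` re-evaluates it for whole batches of
parameter vectors at once; the fitting losses differentiate through this
path.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import rotation_matrices
from .habit import PolyhedronMesh

#: reference detector resolution at which the keypoint merge radius of 20 px
#: is defined; defaults scale with the configured image width.
FULL_RESOLUTION_PX = 2160
MERGE_RADIUS_FULL_RES = 20.0


@dataclass(frozen=True)
class ImageGeometry:
    """Orthographic image raster: origin top-left, x right, y down,
    pixel centers at integer coordinates."""

    width: int = 400
    height: int = 400
    scale: float = 100.0  # px per mm
    center: tuple | None = None  # px offset of the cell-frame origin

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.center is None:
            object.__setattr__(self, "center", ((self.width - 1) / 2.0, (self.height - 1) / 2.0))

    def to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        """Map cell-frame (x, y) mm to pixel coordinates (y axis flips)."""
        xy = np.asarray(xy_mm, dtype=float)
        out = np.empty_like(xy)
        out[..., 0] = self.center[0] + self.scale * xy[..., 0]
        out[..., 1] = self.center[1] - self.scale * xy[..., 1]
        return out

    def to_mm(self, xy_px: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy_px, dtype=float)
        out = np.empty_like(xy)
        out[..., 0] = (xy[..., 0] - self.center[0]) / self.scale
        out[..., 1] = (self.center[1] - xy[..., 1]) / self.scale
        return out

    @property
    def area_px(self) -> float:
        return float(self.width * self.height)

    @property
    def merge_tol_default(self) -> float:
        return MERGE_RADIUS_FULL_RES * self.width / FULL_RESOLUTION_PX


@dataclass
class Segment2D:
    p0: np.ndarray
    p1: np.ndarray
    provenance: tuple  # ("front", (face ids)) | ("refracted", edge vids, window fid)


@dataclass
class Wireframe2D:
    segments: list
    keypoints: np.ndarray  # (K, 2) px, merged
    keypoint_tags: list  # "vertex" | "window-boundary"
    trace: "ProjectionTrace"


@dataclass
class ProjectionTrace:
    """Frozen projection combinatorics for the smooth re-evaluation path."""

    normals: np.ndarray  # (m, 3) habit normals, crystal frame
    A_inv: np.ndarray  # (n, 3, 3) inverse plane-triple matrices
    triple_faces: np.ndarray  # (n, 3) face ids defining each vertex
    front_pairs: np.ndarray  # (F, 2) vids of directly projected edges
    refr_win: np.ndarray  # (S,) window face id per refracted segment
    refr_edge: np.ndarray  # (S, 2) back-edge vids
    refr_clip_vids: np.ndarray  # (S, 2, 2) window-edge vids per endpoint, -1 unclipped
    merge_matrix: np.ndarray  # (K, E) row-stochastic keypoint averaging matrix
    keypoint_tags: list
    argmin_z_vid: int
    env_argmax_vid: np.ndarray  # (m,) vid achieving max N_i . v
    n_dropped: int = 0

    @property
    def n_keypoints(self) -> int:
        return self.merge_matrix.shape[0]


def classify_faces(mesh: PolyhedronMesh):
    """Partition non-degenerate faces into front (window) and back sets.

    A face is front iff its posed outward normal has a positive z-component;
    profile faces (normal perpendicular to the view) are classed back and
    contribute only silhouette edges.
    """
    front, back = [], []
    for i in range(len(mesh.normals_world)):
        if i in mesh.zero_area_faces:
            continue
        (front if mesh.normals_world[i, 2] > 1e-12 else back).append(i)
    return front, back


def refracted_direction(n: np.ndarray, eta) -> np.ndarray:
    """In-crystal unit ray direction for a view ray (0, 0, -1) entering
    through a planar interface with outward unit normal ``n`` (vector Snell
    law with relative index 1/eta).  Broadcasts over leading dimensions."""
    n = np.asarray(n, dtype=float)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), n.shape[:-1])
    i = np.array([0.0, 0.0, -1.0])
    r = 1.0 / eta
    cos_i = n[..., 2]  # = -i . n
    rad = 1.0 - r**2 * (1.0 - cos_i**2)
    if np.any(rad < 0):
        raise ValueError("total internal reflection entering the crystal (eta < 1)")
    cos_t = np.sqrt(rad)
    return r[..., None] * i + (r * cos_i - cos_t)[..., None] * n


def refract_point(v, window_normal, window_offset, eta, geometry: ImageGeometry):
    """Apparent pixel position of a point seen through a planar window.

    Solves for the entry point ``q`` on the window plane such that
    ``q + s t = v`` with the refracted direction ``t``; returns ``None``
    when the point lies in front of the window plane (s < 0).
    """
    v = np.asarray(v, dtype=float)
    n = np.asarray(window_normal, dtype=float)
    t = refracted_direction(n, eta)
    s = (v @ n - window_offset) / (t @ n)
    if s < -1e-12:
        return None
    q = v - s * t
    return geometry.to_px(q[:2])


def _clip_segment_to_polygon(p0, p1, poly):
    """Liang-Barsky clip of segment [p0, p1] to a convex polygon (k, 2).

    Returns (t0, t1, e0, e1) with parameter range and the polygon edge index
    that produced each bound (-1 = original endpoint), or None if the
    segment misses the polygon.
    """
    # orient so that the interior is on the positive side of each edge normal
    area2 = 0.0
    k = len(poly)
    for i in range(k):
        a, b = poly[i], poly[(i + 1) % k]
        area2 += a[0] * b[1] - b[0] * a[1]
    sign = 1.0 if area2 > 0 else -1.0
    t0, t1 = 0.0, 1.0
    e0, e1 = -1, -1
    dvec = p1 - p0
    for i in range(k):
        a, b = poly[i], poly[(i + 1) % k]
        edge = b - a
        n = sign * np.array([-edge[1], edge[0]])
        denom = n @ dvec
        f0 = n @ (p0 - a)
        if abs(denom) < 1e-300:
            if f0 < 0:
                return None
            continue
        tc = -f0 / denom
        if denom > 0:
            if tc > t0:
                t0, e0 = tc, i
        else:
            if tc < t1:
                t1, e1 = tc, i
    if t0 > t1 - 1e-12:
        return None
    return t0, t1, e0, e1


def project_wireframe(
    mesh: PolyhedronMesh,
    eta: float,
    geometry: ImageGeometry,
    merge_tol: float | None = None,
) -> Wireframe2D:
    """Project a posed mesh to a refracted 2D wireframe with keypoints.

    Keypoints are the merged endpoints of all emitted segments: projected
    vertices (direct or refracted) and intersections of refracted back edges
    with their window boundary.  Endpoints closer than ``merge_tol`` px are
    merged to their centroid (default: the detector merge radius of 20 px at
    full 2160 px resolution, scaled to this image width).
    """
    if merge_tol is None:
        merge_tol = geometry.merge_tol_default
    front, back = classify_faces(mesh)
    edges = mesh.edges
    front_set = set(front)

    front_pairs, refr_records = [], []
    back_edges = []
    for (va, vb), fids in edges.items():
        if any(f in front_set for f in fids):
            front_pairs.append((va, vb, tuple(fids)))
        else:
            back_edges.append((va, vb))

    V = mesh.vertices
    segments = []
    endpoint_pos = []  # flattened endpoint pixel positions
    endpoint_tags = []

    for va, vb, fids in front_pairs:
        p0 = geometry.to_px(V[va, :2])
        p1 = geometry.to_px(V[vb, :2])
        segments.append(Segment2D(p0, p1, ("front", fids)))
        endpoint_pos += [p0, p1]
        endpoint_tags += ["vertex", "vertex"]

    n_dropped = 0
    for f in front:
        nf = mesh.normals_world[f]
        off = mesh.plane_offsets_world[f]
        poly_vids = mesh.faces[f]
        poly = geometry.to_px(V[poly_vids, :2])
        for va, vb in back_edges:
            qa = refract_point(V[va], nf, off, eta, geometry)
            qb = refract_point(V[vb], nf, off, eta, geometry)
            if qa is None or qb is None:
                n_dropped += 1
                continue
            clip = _clip_segment_to_polygon(qa, qb, poly)
            if clip is None:
                continue
            t0, t1, e0, e1 = clip
            p0 = qa + t0 * (qb - qa)
            p1 = qa + t1 * (qb - qa)
            k = len(poly_vids)
            cv0 = (poly_vids[e0], poly_vids[(e0 + 1) % k]) if e0 >= 0 else (-1, -1)
            cv1 = (poly_vids[e1], poly_vids[(e1 + 1) % k]) if e1 >= 0 else (-1, -1)
            segments.append(Segment2D(p0, p1, ("refracted", (va, vb), f)))
            refr_records.append((f, (va, vb), (cv0, cv1)))
            endpoint_pos += [p0, p1]
            endpoint_tags += [
                "vertex" if e0 < 0 else "window-boundary",
                "vertex" if e1 < 0 else "window-boundary",
            ]

    endpoint_pos = np.asarray(endpoint_pos).reshape(-1, 2)
    groups = _merge_groups(endpoint_pos, merge_tol)
    E = len(endpoint_pos)
    M = np.zeros((len(groups), E))
    tags = []
    for gi, g in enumerate(groups):
        M[gi, g] = 1.0 / len(g)
        tags.append("vertex" if any(endpoint_tags[i] == "vertex" for i in g) else "window-boundary")
    keypoints = M @ endpoint_pos

    Nc = mesh.vertices_crystal
    normals = mesh.normals_crystal
    trace = ProjectionTrace(
        normals=normals,
        A_inv=np.linalg.inv(normals[mesh.vertex_triples]),
        triple_faces=mesh.vertex_triples,
        front_pairs=np.asarray([(a, b) for a, b, _ in front_pairs], dtype=int).reshape(-1, 2),
        refr_win=np.asarray([r[0] for r in refr_records], dtype=int),
        refr_edge=np.asarray([r[1] for r in refr_records], dtype=int).reshape(-1, 2),
        refr_clip_vids=np.asarray([r[2] for r in refr_records], dtype=int).reshape(-1, 2, 2),
        merge_matrix=M,
        keypoint_tags=tags,
        argmin_z_vid=int(np.argmin(mesh.vertices[:, 2])),
        env_argmax_vid=np.argmax(Nc @ normals.T, axis=0),
        n_dropped=n_dropped,
    )
    return Wireframe2D(segments=segments, keypoints=keypoints, keypoint_tags=tags, trace=trace)


def _merge_groups(points: np.ndarray, tol: float):
    """Connected components of the 'closer than tol' graph (deterministic)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if tol > 0 and n > 1:
        d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
        close = d2 <= tol * tol
        for i in range(n):
            for j in range(i + 1, n):
                if close[i, j]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.asarray(groups[k], dtype=int) for k in sorted(groups)]


# ---------------------------------------------------------------------------
# smooth batched re-evaluation with frozen combinatorics
# ---------------------------------------------------------------------------

def smooth_keypoints(
    trace: ProjectionTrace,
    D: np.ndarray,
    P: np.ndarray,
    rotvec: np.ndarray,
    eta: np.ndarray,
    geometry: ImageGeometry,
):
    """Re-evaluate keypoints and auxiliary quantities for a parameter batch.

    All combinatoric choices (plane triples, windows, clip edges, merge
    groups) come frozen from ``trace``; the remaining arithmetic is smooth,
    making this path suitable for finite-difference Jacobians.  Shapes:
    ``D (B, m)``, ``P (B, 3)``, ``rotvec (B, 3)``, ``eta (B,)``.

    Returns ``(K, aux)`` with ``K (B, n_kp, 2)`` px and ``aux`` a dict with
    ``min_z (B,)`` mm and ``envelope (B, m)`` mm (per-face max of N_i . v).
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    rotvec = np.atleast_2d(np.asarray(rotvec, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    B = D.shape[0]
    N = trace.normals

    d_tr = D[:, trace.triple_faces]  # (B, n, 3)
    Vc = np.einsum("nij,bnj->bni", trace.A_inv, d_tr)
    R = rotation_matrices(rotvec)  # (B, 3, 3)
    Vw = np.einsum("bij,bnj->bni", R, Vc) + P[:, None, :]
    nw = np.einsum("bij,mj->bmi", R, N)  # (B, m, 3)
    offw = D + np.einsum("bmi,bi->bm", nw, P)

    parts = []
    if len(trace.front_pairs):
        fp = Vw[:, trace.front_pairs.reshape(-1), :2]  # (B, 2F, 2)
        parts.append(geometry.to_px(fp))
    if len(trace.refr_win):
        ns = nw[:, trace.refr_win]  # (B, S, 3)
        offs = offw[:, trace.refr_win]  # (B, S)
        r = (1.0 / eta)[:, None]
        cos_i = ns[..., 2]
        cos_t = np.sqrt(np.clip(1.0 - r**2 * (1.0 - cos_i**2), 0.0, None))
        i_vec = np.array([0.0, 0.0, -1.0])
        t_dir = r[..., None] * i_vec + (r * cos_i - cos_t)[..., None] * ns  # (B, S, 3)
        v_ends = Vw[:, trace.refr_edge]  # (B, S, 2, 3)
        s = (np.einsum("bsei,bsi->bse", v_ends, ns) - offs[..., None]) / np.einsum(
            "bsi,bsi->bs", t_dir, ns
        )[..., None]
        q = v_ends - s[..., None] * t_dir[:, :, None, :]  # (B, S, 2, 3)
        q_px = geometry.to_px(q[..., :2])  # (B, S, 2, 2)
        clip_mask = trace.refr_clip_vids[..., 0] >= 0  # (S, 2)
        if np.any(clip_mask):
            safe_vids = np.where(trace.refr_clip_vids >= 0, trace.refr_clip_vids, 0)
            wa = geometry.to_px(Vw[:, safe_vids[..., 0], :2])  # (B, S, 2, 2)
            wb = geometry.to_px(Vw[:, safe_vids[..., 1], :2])
            q0 = q_px[:, :, 0:1, :]  # (B, S, 1, 2)
            q1 = q_px[:, :, 1:2, :]
            dq = q1 - q0
            e = wb - wa

            def cross2(u, v):
                return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

            denom = cross2(e, np.broadcast_to(dq, e.shape))
            tpar = cross2(e, wa - q0) / np.where(np.abs(denom) < 1e-300, 1.0, denom)
            p_clip = q0 + tpar[..., None] * dq  # (B, S, 2, 2)
            q_px = np.where(clip_mask[None, :, :, None], p_clip, q_px)
        parts.append(q_px.reshape(B, -1, 2))
    endpoints = np.concatenate(parts, axis=1) if parts else np.zeros((B, 0, 2))
    K = np.einsum("ke,bed->bkd", trace.merge_matrix, endpoints)

    aux = {
        "min_z": Vw[:, trace.argmin_z_vid, 2],
        "envelope": np.einsum("bmi,mi->bm", Vc[:, trace.env_argmax_vid], N),
    }
    return K, aux


def render_heatmap(keypoints: np.ndarray, geometry: ImageGeometry, variance: float = 5.0) -> np.ndarray:
    """Keypoint heatmap: Gaussian blobs of height 1 and the given variance
    (px^2), combined with the max operation so values never exceed 1."""
    H, W = geometry.height, geometry.width
    out = np.zeros((H, W))
    if len(keypoints) == 0:
        return out
    ys = np.arange(H)[:, None]
    xs = np.arange(W)[None, :]
    for kx, ky in np.asarray(keypoints, dtype=float):
        d2 = (xs - kx) ** 2 + (ys - ky) ** 2
        np.maximum(out, np.exp(-d2 / (2.0 * variance)), out=out)
    return out
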