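"""Randomized, realism-constrained crystal configurations.

Mirrors the synthetic-dataset recipe: per-form mean distances are drawn from
independent normals and rejection-sampled against a preferred ordering of
the forms and Zingg shape bounds; per-face asymmetry within each form is
then added; pose is a uniform random rotation with the crystal scaled so
its orthographic silhouette covers a target fraction of the image, placed
fully inside the frame and touching the glass at z = 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from ._geometry import random_rotvec
from .errors import InfeasiblePriorError
from .habit import CrystalConfiguration, CrystalHabit, build_polyhedron, canonicalize
from .projector import ImageGeometry


@dataclass
class MorphologyPrior:
    """Distribution over configurations of one habit.

    ``mu``/``sigma`` are per-form mean/SD of the center-to-plane distance in
    mm.  ``ordering`` is a partial order: pairs (k_small, k_large) meaning
    the drawn mean of form ``k_small`` must not exceed that of ``k_large``.
    ``zingg_bounds`` constrains the two oriented-bounding-box axis ratios
    (elongation = intermediate/long, flatness = short/intermediate).
    """

    mu: np.ndarray  # (n_groups,) mm
    sigma: np.ndarray  # (n_groups,) mm
    ordering: tuple = ()  # pairs of group indices (smaller, larger)
    zingg_bounds: tuple = ((0.2, 1.0), (0.2, 1.0))
    intra_group_spread: float = 0.1  # relative SD of per-face asymmetry
    area_range: tuple = (0.05, 0.25)  # silhouette area, fraction of image
    eta_range: tuple = (1.5, 1.8)
    roughness_range: tuple = (0.0, 0.5)
    light_range: tuple = (0.5, 1.0)
    rejection_budget: int = 1000

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if not (0 < self.area_range[0] <= self.area_range[1]):
            raise ValueError("area_range must be ordered and positive")


def zingg_ratios(mesh) -> tuple:
    """(elongation, flatness) from the PCA-oriented bounding box of the
    vertices — intermediate/long and short/intermediate axis ratios."""
    V = mesh.vertices_crystal
    C = V - V.mean(axis=0)
    _, _, W = np.linalg.svd(C, full_matrices=False)
    ext = np.sort((C @ W.T).max(axis=0) - (C @ W.T).min(axis=0))[::-1]
    long, inter, short = ext
    return float(inter / long), float(short / inter)


def sample_distances(
    habit: CrystalHabit, prior: MorphologyPrior, rng: np.random.Generator
) -> np.ndarray:
    """Draw one canonicalized distance vector honoring the prior constraints.

    Group means are redrawn until the preferred ordering and Zingg bounds
    hold for the resulting shape; per-face asymmetry d_i ~ N(dbar_k,
    spread * dbar_k) is then applied and the distances canonicalized so
    grown-out faces sit at the threshold of appearance.
    """
    groups = habit.face_groups
    if len(prior.mu) != len(groups):
        raise ValueError("prior must cover every face group")
    (e_lo, e_hi), (f_lo, f_hi) = prior.zingg_bounds
    for _ in range(prior.rejection_budget):
        means = rng.normal(prior.mu, prior.sigma)
        if np.any(means <= 0):
            continue
        if any(means[a] > means[b] for a, b in prior.ordering):
            continue
        d = np.empty(habit.n_faces)
        for k, g in enumerate(groups):
            spread = prior.intra_group_spread * means[k]
            for i in g:
                di = rng.normal(means[k], spread)
                while di <= 0:
                    di = rng.normal(means[k], spread)
                d[i] = di
        cfg = CrystalConfiguration(habit, d)
        try:
            mesh = build_polyhedron(habit, cfg)
        except Exception:
            continue
        elong, flat = zingg_ratios(mesh)
        if not (e_lo <= elong <= e_hi and f_lo <= flat <= f_hi):
            continue
        canon = canonicalize(cfg)
        if np.any(canon.distances <= 0):
            continue
        return canon.distances
    raise InfeasiblePriorError(
        f"no feasible draw in {prior.rejection_budget} attempts"
    )


def silhouette_area_mm2(mesh) -> float:
    """Orthographic silhouette area: 2D convex hull of the projected
    vertices (exact for convex shapes)."""
    pts = mesh.vertices[:, :2]
    return float(ConvexHull(pts).volume)  # 2D "volume" is the area


def sample_pose_and_scale(
    config: CrystalConfiguration,
    prior: MorphologyPrior,
    geometry: ImageGeometry,
    rng: np.random.Generator,
    pose_budget: int = 50,
) -> CrystalConfiguration:
    """Random pose with silhouette-area scaling and substrate contact.

    Applies a uniform random rotation, rescales the distances so the
    silhouette covers ``a_target ~ U(area_range) * image area`` (the
    silhouette is homogeneous of degree 2 in scale, so one correction is
    exact), places the crystal uniformly such that the silhouette stays
    inside the frame, and sets min_z = 0.  Material/light scalars are drawn
    from their prior ranges.
    """
    area_img_mm2 = geometry.area_px / geometry.scale**2
    for _ in range(pose_budget):
        out = config.copy()
        out.rotation = random_rotvec(rng)
        a_target = rng.uniform(*prior.area_range) * area_img_mm2
        mesh = build_polyhedron(out.habit, out)
        s = np.sqrt(a_target / silhouette_area_mm2(mesh))
        out.distances = out.distances * s
        out.origin = np.zeros(3)
        mesh = build_polyhedron(out.habit, out)
        V = mesh.vertices
        half_w = (geometry.width - 1) / 2.0 / geometry.scale
        half_h = (geometry.height - 1) / 2.0 / geometry.scale
        lo_x = -half_w - V[:, 0].min()
        hi_x = half_w - V[:, 0].max()
        lo_y = -half_h - V[:, 1].min()
        hi_y = half_h - V[:, 1].max()
        if lo_x > hi_x or lo_y > hi_y:
            continue  # too large for the frame at this draw; retry
        out.origin = np.array(
            [rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y), -V[:, 2].min()]
        )
        out.refractive_index = float(rng.uniform(*prior.eta_range))
        out.roughness = float(rng.uniform(*prior.roughness_range))
        out.light = rng.uniform(*prior.light_range, size=3)
        return canonicalize(out)
    raise InfeasiblePriorError("could not fit the target silhouette inside the image")


def sample_configuration(
    habit: CrystalHabit,
    prior: MorphologyPrior,
    geometry: ImageGeometry,
    rng: np.random.Generator,
) -> CrystalConfiguration:
    """Full draw: distances, then pose/scale/material."""
    d = sample_distances(habit, prior, rng)
    return sample_pose_and_scale(
        CrystalConfiguration(habit, d), prior, geometry, rng
    )


@dataclass
class SyntheticSample:
    """One synthetic observation: configuration, projected keypoints (px)
    and the keypoint heatmap, with the seed that produced it."""

    configuration: CrystalConfiguration
    keypoints: np.ndarray
    heatmap: np.ndarray
    rng_seed: int | None = None


def sample_synthetic(
    habit: CrystalHabit,
    prior: MorphologyPrior,
    geometry: ImageGeometry,
    seed: int,
) -> SyntheticSample:
    """Draw a configuration and render its keypoints and heatmap."""
    from .projector import project_wireframe, render_heatmap

    rng = np.random.default_rng(seed)
    cfg = sample_configuration(habit, prior, geometry, rng)
    mesh = build_polyhedron(habit, cfg)
    wf = project_wireframe(mesh, cfg.refractive_index, geometry)
    return SyntheticSample(
        configuration=cfg,
        keypoints=wf.keypoints,
        heatmap=render_heatmap(wf.keypoints, geometry),
        rng_seed=seed,
    )


@dataclass
class GrowthSpec:
    """Monotone growth curves for a sequence: per-form affine rates.

    dbar_k(t) = mu_k * (1 + rate_k * t / (T - 1)): every form grows from its
    base value by the given relative amount over the whole sequence.
    """

    rates: np.ndarray  # (n_groups,) relative growth over the sequence, >= 0

    def __post_init__(self):
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if np.any(self.rates < 0):
            raise ValueError("growth rates must be nonnegative (no dissolution)")


def generate_sequence_truth(
    habit: CrystalHabit,
    prior: MorphologyPrior,
    T: int,
    growth: GrowthSpec,
    rng: np.random.Generator,
    geometry: ImageGeometry | None = None,
) -> list:
    """Ground-truth growth sequence: T canonical configurations with
    non-decreasing per-face distances and a fixed pose.

    The intra-form asymmetry is drawn once as *additive* offsets held fixed
    over time; together with complete symmetry forms this keeps the
    canonical origin constant along the sequence, so per-face monotonicity
    survives canonicalization exactly.  The pose is sampled at the final
    (largest) frame so the whole sequence stays inside the image.
    """
    if T < 2:
        raise ValueError("a sequence needs at least two frames")
    if len(growth.rates) != len(habit.face_groups):
        raise ValueError("growth spec must cover every face group")
    geometry = geometry or ImageGeometry()
    groups = habit.face_groups

    # base means obeying the prior constraints; per-face asymmetry as
    # additive offsets held fixed over time
    base = sample_distances(habit, prior, rng)
    means = np.array([np.mean(base[list(g)]) for g in groups])
    offsets = base.copy()
    for g in groups:
        offsets[list(g)] -= base[list(g)].mean()

    def frame_distances(t, scale=1.0):
        d = np.empty(habit.n_faces)
        for k, g in enumerate(groups):
            d[list(g)] = means[k] * (1.0 + growth.rates[k] * t / (T - 1))
        return np.maximum((d + offsets) * scale, 1e-3 * means.mean() * scale)

    area_img_mm2 = geometry.area_px / geometry.scale**2
    half_w = (geometry.width - 1) / 2.0 / geometry.scale
    half_h = (geometry.height - 1) / 2.0 / geometry.scale
    for _ in range(prior.rejection_budget):
        rot = random_rotvec(rng)
        a_target = rng.uniform(*prior.area_range) * area_img_mm2
        last = CrystalConfiguration(habit, frame_distances(T - 1), rotation=rot)
        mesh = build_polyhedron(habit, last)
        s = float(np.sqrt(a_target / silhouette_area_mm2(mesh)))
        last = CrystalConfiguration(habit, frame_distances(T - 1, s), rotation=rot)
        V = build_polyhedron(habit, last).vertices
        lo_x, hi_x = -half_w - V[:, 0].min(), half_w - V[:, 0].max()
        lo_y, hi_y = -half_h - V[:, 1].min(), half_h - V[:, 1].max()
        if lo_x > hi_x or lo_y > hi_y:
            continue
        origin = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y), 0.0])
        eta = float(rng.uniform(*prior.eta_range))
        rough = float(rng.uniform(*prior.roughness_range))
        light = rng.uniform(*prior.light_range, size=3)
        break
    else:
        raise InfeasiblePriorError("no sequence pose fits inside the image")

    frames = []
    for t in range(T):
        cfg = CrystalConfiguration(
            habit,
            frame_distances(t, s),
            origin=origin.copy(),
            rotation=rot.copy(),
            refractive_index=eta,
            roughness=rough,
            light=light.copy(),
        )
        cfg = canonicalize(cfg)
        # substrate contact: the bottom face stays on the glass as the
        # crystal grows, so only the origin's z-component varies with t
        mesh = build_polyhedron(habit, cfg)
        cfg.origin[2] -= float(mesh.vertices[:, 2].min())
        frames.append(cfg)
    return frames
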