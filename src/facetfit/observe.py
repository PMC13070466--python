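"""Synthetic keypoint observations with detector-like pathologies.

Stands in for a trained keypoint-detector network: true projected keypoints
are independently dropped, jittered with isotropic Gaussian noise, polluted
with spurious detections uniform over the image, merged within the detector
merge radius and clipped to the image bounds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyObservationError
from .habit import build_polyhedron
from .projector import ImageGeometry, project_wireframe, _merge_groups


@dataclass
class NoiseSpec:
    jitter_sigma: float = 2.0  # px
    dropout: float = 0.1  # per-keypoint probability
    spurious_rate: float = 0.0  # expected spurious points per frame (Poisson)
    merge_radius: float = 0.0  # px; 0 disables post-noise merging

    def __post_init__(self):
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be a probability")
        if self.jitter_sigma < 0 or self.spurious_rate < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    @classmethod
    def noiseless(cls):
        return cls(jitter_sigma=0.0, dropout=0.0, spurious_rate=0.0, merge_radius=0.0)


def observe_keypoints(
    true_K: np.ndarray,
    noise: NoiseSpec,
    geometry: ImageGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """One noisy detector observation of a true keypoint set."""
    K = np.asarray(true_K, dtype=float).reshape(-1, 2)
    keep = rng.uniform(size=len(K)) >= noise.dropout
    pts = K[keep]
    if noise.jitter_sigma > 0 and len(pts):
        pts = pts + rng.normal(0.0, noise.jitter_sigma, size=pts.shape)
    n_spur = rng.poisson(noise.spurious_rate) if noise.spurious_rate > 0 else 0
    if n_spur:
        spur = np.column_stack(
            [
                rng.uniform(0, geometry.width - 1, n_spur),
                rng.uniform(0, geometry.height - 1, n_spur),
            ]
        )
        pts = np.vstack([pts, spur]) if len(pts) else spur
    if len(pts) == 0:
        raise EmptyObservationError("all keypoints dropped and no spurious points")
    if noise.merge_radius > 0:
        groups = _merge_groups(pts, noise.merge_radius)
        pts = np.stack([pts[g].mean(axis=0) for g in groups])
    pts[:, 0] = np.clip(pts[:, 0], 0, geometry.width - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, geometry.height - 1)
    return pts


@dataclass
class ObservationCorpus:
    """Paired truth and observations for a simulated growth sequence."""

    truth: list  # CrystalConfiguration per frame (hidden from fitting)
    observations: list  # (n_t, 2) arrays or None for unusable frames
    geometry: ImageGeometry
    noise: NoiseSpec
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.truth)

    @property
    def usable(self) -> np.ndarray:
        return np.array([obs is not None for obs in self.observations])


def simulate_growth_observations(
    habit,
    prior,
    growth,
    noise: NoiseSpec,
    T: int,
    rng: np.random.Generator,
    geometry: ImageGeometry | None = None,
    merge_tol: float | None = None,
) -> ObservationCorpus:
    """Compose truth generation, projection and detector noise per frame.

    Frames whose observation comes out empty are flagged unusable (None)
    rather than failing the whole corpus.
    """
    from .sampler import generate_sequence_truth

    geometry = geometry or ImageGeometry()
    truth = generate_sequence_truth(habit, prior, T, growth, rng, geometry)
    observations = []
    for cfg in truth:
        mesh = build_polyhedron(habit, cfg)
        wf = project_wireframe(mesh, cfg.refractive_index, geometry, merge_tol=merge_tol)
        try:
            obs = observe_keypoints(wf.keypoints, noise, geometry, rng)
        except EmptyObservationError:
            obs = None
        observations.append(obs)
    return ObservationCorpus(truth, observations, geometry, noise)
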