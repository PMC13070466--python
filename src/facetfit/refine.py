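"""Single-frame shape refinement and the perturbation-recovery study.

``refine_frame`` improves a crystal configuration against a set of observed
2D keypoints by first-order gradient descent with adaptive moments (Adam)
on normalized parameters: face distances and in-plane origin are scaled by
the crystal size (mean center-to-plane distance of the initialization),
rotation stays in radians.  The vertical origin component is not a free
parameter — the substrate term of the loss keeps the crystal on the glass,
and the final result is snapped to exact contact (min_z = 0) before
canonicalization.

``perturbation_study`` measures basin-of-attraction robustness: starting
from controlled perturbations of a converged reference (rigid rotation,
in-plane shift, or distance noise), how often does refinement return to the
reference within a threshold on the size-normalized mean nearest-neighbor
vertex distance?
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import rotation_matrix, rotvec_from_matrix
from ._optim import Adam, clip_norm
from .fitloss import (
    DEFAULT_FREE,
    LossWeights,
    SinkhornDivergence,
    _pack,
    _unpack,
    total_loss_and_grad,
)
from .habit import CrystalConfiguration, build_polyhedron, canonicalize, vertex_distance
from .projector import ImageGeometry


@dataclass(frozen=True)
class RefinementStage:
    """One phase of the coarse-to-fine refinement schedule.

    ``frac`` is the share of the iteration budget; ``rigid`` restricts the
    phase to rotation and in-plane shift (shape frozen); ``blur``/``reach``
    override the transport settings for the phase (None keeps the
    configured loss); ``lr`` overrides the step size.
    """

    frac: float
    rigid: bool = False
    blur: float | None = None
    reach: float | None = None
    lr: float | None = None
    #: whether to apply block restarts (see ``OptimizerSettings.block_size``)
    #: within this stage; polish stages run contiguously so Adam can settle
    blocked: bool = True


#: Default schedule: rigid pre-alignment (joint descent from pose
#: perturbations walks into wrong-correspondence minima; rigid-first makes
#: the transport landscape effectively unimodal), a full coarse phase, and
#: two progressively tighter polish phases that cut the precision floor the
#: wide blur/reach would otherwise impose near the optimum.
DEFAULT_SCHEDULE = (
    RefinementStage(frac=0.24, rigid=True),
    RefinementStage(frac=0.36),
    RefinementStage(frac=0.20, blur=2.0, reach=20.0, lr=3e-3, blocked=False),
    RefinementStage(frac=0.20, blur=1.0, reach=10.0, lr=1e-3, blocked=False),
)

#: Single-phase schedule (plain Adam on all free parameters).
PLAIN_SCHEDULE = (RefinementStage(frac=1.0),)


@dataclass
class OptimizerSettings:
    lr: float = 1e-2  # step size on normalized parameters
    iterations: int = 300
    grad_clip: float = 10.0
    fd_step: float = 1e-6
    schedule: tuple = DEFAULT_SCHEDULE
    #: descent restarts: every ``block_size`` iterations the iterate is
    #: snapped to the substrate and canonicalized (a projection back onto
    #: the representative manifold — grown-out faces clamped, origin
    #: recentred) and the Adam moments reset.  Restarted, reprojected
    #: descent escapes the limit cycles that long uninterrupted runs fall
    #: into on this loss; 0 disables blocking.
    block_size: int = 50


@dataclass
class FitResult:
    initial: CrystalConfiguration
    final: CrystalConfiguration
    loss_trace: np.ndarray  # (iterations + 1,)
    iterations: int
    converged: bool
    seed: int | None = None

    @property
    def initial_loss(self) -> float:
        return float(self.loss_trace[0])

    @property
    def final_loss(self) -> float:
        return float(np.min(self.loss_trace))


@dataclass
class PerturbationSpec:
    """One perturbation mode of the recovery study.

    Exactly one of ``rotation_deg`` (3D rotation about a random axis),
    ``shift_frac`` (in-plane shift, fraction of crystal size) or
    ``distance_sigma`` (relative Gaussian noise on every distance) is
    typically nonzero; combined modes are allowed.
    """

    rotation_deg: float = 0.0
    shift_frac: float = 0.0
    distance_sigma: float = 0.0
    runs: int = 50
    tau: float = 0.1  # success threshold, size-normalized vertex distance
    iterations: int = 300

    def __post_init__(self):
        if self.tau <= 0 or self.runs < 1:
            raise ValueError("tau must be positive and runs >= 1")


def _snap_to_substrate(config: CrystalConfiguration) -> CrystalConfiguration:
    mesh = build_polyhedron(config.habit, config)
    out = config.copy()
    out.origin = out.origin.copy()
    out.origin[2] -= float(np.min(mesh.vertices[:, 2]))
    return out


def refine_frame(
    init_config: CrystalConfiguration,
    K_obs: np.ndarray,
    weights: LossWeights | None = None,
    settings: OptimizerSettings | None = None,
    geometry: ImageGeometry | None = None,
    free=DEFAULT_FREE,
    merge_tol: float | None = None,
    seed: int | None = None,
) -> FitResult:
    """Gradient-descent refinement of one frame against observed keypoints.

    Runs the configured number of Adam iterations, projecting distances to
    positive after every step, and returns the lowest-loss iterate (snapped
    to the substrate and canonicalized).  With ``iterations=0`` the
    initialization is returned unchanged.
    """
    from dataclasses import replace as _dc_replace

    weights = weights or LossWeights()
    settings = settings or OptimizerSettings()
    geometry = geometry or ImageGeometry()

    # the vertical origin is not a free parameter: growth-cell physics puts
    # the crystal on the glass, so start from exact substrate contact and
    # let L_z penalize shape/rotation updates that would break it
    original = init_config
    init_config = _snap_to_substrate(init_config)

    if settings.iterations == 0:
        return FitResult(original, original.copy(), np.asarray([np.nan]), 0, True, seed)

    # allocate the iteration budget across the schedule
    stages = []
    used = 0
    active = [
        s for s in settings.schedule
        if (tuple(f for f in free if f in ("origin_xy", "rotation")) if s.rigid else free)
    ]
    # rigid stages are pointless when the shape is frozen anyway
    if "distances" not in free:
        active = [s for s in active if not s.rigid] or list(active)
    for k, stage in enumerate(active):
        n = int(round(stage.frac * settings.iterations))
        if k == len(active) - 1:
            n = settings.iterations - used
        n = max(0, min(n, settings.iterations - used))
        used += n
        stages.append((stage, n))

    base_div = SinkhornDivergence(K_obs, weights.sinkhorn) if weights.w_K > 0 else None

    # brake criterion: the loss at minimal blur, which scores fine geometric
    # agreement (the coarse blur/reach deliberately smooth it away)
    sharp_w = weights
    sharp_div = base_div
    if weights.w_K > 0:
        sharp_sk = _dc_replace(weights.sinkhorn, blur=1.0)
        sharp_w = _dc_replace_weights(weights, sharp_sk)
        sharp_div = SinkhornDivergence(K_obs, sharp_sk)

    def sharp_loss(candidate):
        from .fitloss import total_loss

        try:
            val = total_loss(
                candidate, K_obs, sharp_w, geometry,
                merge_tol=merge_tol, divergence=sharp_div,
            ).total
        except Exception:
            return np.inf
        return val if np.isfinite(val) else np.inf

    cfg = init_config
    traces = []
    converged = True
    for stage, n in stages:
        if n == 0:
            continue
        stage_free = (
            tuple(f for f in free if f in ("origin_xy", "rotation")) if stage.rigid else free
        )
        w = weights
        div = base_div
        if stage.blur is not None or stage.reach is not None:
            sk = _dc_replace(
                weights.sinkhorn,
                blur=stage.blur if stage.blur is not None else weights.sinkhorn.blur,
                reach=stage.reach if stage.reach is not None else weights.sinkhorn.reach,
            )
            w = _dc_replace_weights(weights, sk)
            div = SinkhornDivergence(K_obs, sk) if w.w_K > 0 else None
        lr = stage.lr if stage.lr is not None else settings.lr
        block = settings.block_size if (settings.block_size > 0 and stage.blocked) else n
        done = 0
        while done < n:
            nb = min(block, n - done)
            cfg, tr, ok = _descend(
                cfg, K_obs, w, settings, geometry, stage_free, nb, merge_tol, div, lr
            )
            traces.append(tr)
            converged &= ok
            done += nb
            # reproject onto the representative manifold between blocks
            # (grown-out clamp, origin recentring, substrate contact) and
            # let the next block restart Adam from the projected iterate
            try:
                cfg = canonicalize(_snap_to_substrate(cfg))
            except Exception:
                pass

    # catastrophe brake: a refinement that ends with a *worse* fine-scale
    # loss than its (substrate-snapped) starting point returns the start —
    # a wrong-correspondence basin can undercut the coarse loss, but not
    # the fine-scale agreement of an initialization that was nearly right
    if sharp_loss(cfg) > sharp_loss(init_config):
        cfg = init_config
    final = canonicalize(_snap_to_substrate(cfg))
    # drop the duplicated loss evaluation at each phase boundary
    trace = np.concatenate([traces[0]] + [t[1:] for t in traces[1:]]) if len(traces) > 1 else traces[0]
    return FitResult(
        initial=original,
        final=final,
        loss_trace=np.asarray(trace),
        iterations=len(trace) - 1,
        converged=converged,
        seed=seed,
    )


def _dc_replace_weights(weights: LossWeights, sinkhorn) -> LossWeights:
    return LossWeights(
        w_K=weights.w_K, w_z=weights.w_z, w_R=weights.w_R, w_o=weights.w_o,
        sinkhorn=sinkhorn,
    )


def _descend(
    init_config, K_obs, weights, settings, geometry, free, iterations, merge_tol, div,
    lr=None,
):
    """Best-so-far Adam descent over one free-parameter set."""
    size = max(init_config.size, 1e-9)
    scale_vec = _param_scales(init_config, free, size)
    theta = _pack(init_config, free) / scale_vec
    adam = Adam(len(theta), lr=lr if lr is not None else settings.lr)
    m = len(init_config.distances)
    trace = []
    best_theta = theta.copy()
    best_loss = np.inf
    converged = True
    cfg = init_config.copy()
    for it in range(iterations + 1):
        try:
            breakdown, grad = total_loss_and_grad(
                cfg, K_obs, weights, geometry,
                free=free, merge_tol=merge_tol,
                fd_step=settings.fd_step, divergence=div,
            )
        except Exception:
            converged = False
            break
        loss = breakdown.total
        if not np.isfinite(loss):
            converged = False
            break
        trace.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_theta = theta.copy()
        if it == iterations:
            break
        g = clip_norm(grad * scale_vec, settings.grad_clip)
        theta = theta + adam.step(g)
        if "distances" in free:
            theta[:m] = np.maximum(theta[:m], 1e-3)  # normalized units
        cfg = _unpack(theta * scale_vec, init_config, free)

    best = _unpack(best_theta * scale_vec, init_config, free)
    return best, np.asarray(trace if trace else [np.nan]), converged


def _free_names(free):
    return tuple(free)


def _param_scales(config, free, size):
    parts = []
    if "distances" in free:
        parts.append(np.full(len(config.distances), size))
    if "origin_xy" in free:
        parts.append(np.full(2, size))
    if "rotation" in free:
        parts.append(np.ones(3))
    if "eta" in free:
        parts.append(np.ones(1))
    return np.concatenate(parts)


def perturb_config(
    config: CrystalConfiguration, spec: PerturbationSpec, rng: np.random.Generator
) -> CrystalConfiguration:
    """Apply the controlled perturbation of the recovery study."""
    out = config.copy()
    if spec.rotation_deg:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        dR = rotation_matrix(axis * np.radians(spec.rotation_deg))
        out.rotation = rotvec_from_matrix(dR @ rotation_matrix(out.rotation))
    if spec.shift_frac:
        ang = rng.uniform(0, 2 * np.pi)
        shift = spec.shift_frac * config.size * np.array([np.cos(ang), np.sin(ang), 0.0])
        out.origin = out.origin + shift
    if spec.distance_sigma:
        factors = 1.0 + rng.normal(0, spec.distance_sigma, len(out.distances))
        out.distances = np.maximum(out.distances * factors, 1e-3 * config.size)
    return out


@dataclass
class StudyResult:
    return_rate: float
    successes: int
    runs: int
    ci_low: float
    ci_high: float
    distances: np.ndarray  # final size-normalized vertex distances per run


def normalized_vertex_distance(
    config: CrystalConfiguration, reference: CrystalConfiguration
) -> float:
    """Bidirectional mean nearest-neighbor vertex distance / crystal size."""
    mesh_a = build_polyhedron(config.habit, config)
    mesh_b = build_polyhedron(reference.habit, reference)
    return vertex_distance(mesh_a.vertices, mesh_b.vertices) / max(reference.size, 1e-12)


def perturbation_study(
    reference: CrystalConfiguration,
    spec: PerturbationSpec,
    weights: LossWeights | None = None,
    rng: np.random.Generator | None = None,
    geometry: ImageGeometry | None = None,
    merge_tol: float | None = None,
) -> StudyResult:
    """Fraction of perturbed refinements that return to the reference.

    The reference is projected to noiseless keypoints; each run perturbs the
    reference per ``spec``, refines for ``spec.iterations`` and scores a
    success when the final size-normalized mean nearest-neighbor vertex
    distance to the reference is below ``spec.tau``.  The confidence
    interval is the 95% Wilson score interval.
    """
    from .projector import project_wireframe  # local import to avoid cycle noise

    weights = weights or LossWeights()
    rng = rng or np.random.default_rng()
    geometry = geometry or ImageGeometry()
    mesh = build_polyhedron(reference.habit, reference)
    K_ref = project_wireframe(mesh, reference.refractive_index, geometry, merge_tol=merge_tol).keypoints

    opt = OptimizerSettings(iterations=spec.iterations)
    dists = np.empty(spec.runs)
    successes = 0
    for run in range(spec.runs):
        start = perturb_config(reference, spec, rng)
        try:
            fit = refine_frame(
                start, K_ref, weights, opt, geometry, merge_tol=merge_tol
            )
            dist = normalized_vertex_distance(fit.final, reference)
        except Exception:
            dist = np.inf  # counted as a failure
        dists[run] = dist
        if dist < spec.tau:
            successes += 1
    rate = successes / spec.runs
    lo, hi = _wilson_interval(successes, spec.runs)
    return StudyResult(rate, successes, spec.runs, lo, hi, dists)


def _wilson_interval(k: int, n: int, z: float = 1.959964):
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)
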