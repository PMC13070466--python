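"""Growth-sequence fitting with a temporal sequence generator.

A small feed-forward network (the *sequence generator*) maps normalized
time t' = t/(T-1) to the dynamic shape parameters — the face distances —
while rotation is shared across the sequence as a static parameter and the
in-plane origin and refractive index stay frozen at reference values.  The
network is pretrained by plain regression onto per-frame initial estimates,
then trained end-to-end through the wireframe projection with the
refinement losses, an adaptive frame sampler that concentrates on
high-error frames, and a penalty on negative face growth.

Everything runs on NumPy with hand-written backpropagation for the network
and the envelope/finite-difference gradients of the projection losses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from ._optim import Adam
from .errors import FacetFitError
from .fitloss import LossWeights, SinkhornDivergence, total_loss_and_grad
from .habit import CrystalConfiguration, CrystalHabit, build_polyhedron, canonicalize
from .projector import ImageGeometry

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    phi = _INV_SQRT2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


class SequenceModel:
    """Static parameters plus the dynamic-distance network.

    Four GELU hidden layers of the configured width followed by a linear
    projection to the |D| normalized distances (units of ``size_scale`` mm).
    """

    N_HIDDEN_LAYERS = 4

    def __init__(
        self,
        habit: CrystalHabit,
        size_scale: float,
        rotation=None,
        origin=None,
        refractive_index: float = 1.7,
        hidden: int = 256,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.habit = habit
        self.size_scale = float(size_scale)
        self.rotation = np.zeros(3) if rotation is None else np.asarray(rotation, float).copy()
        self.origin = np.zeros(3) if origin is None else np.asarray(origin, float).copy()
        self.refractive_index = float(refractive_index)
        self.hidden = hidden
        m = habit.n_faces
        dims = [1] + [hidden] * self.N_HIDDEN_LAYERS + [m]
        self.weights = []
        self.biases = []
        for din, dout in zip(dims[:-1], dims[1:]):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
            self.biases.append(np.zeros(dout))
        # start the output near one crystal size rather than zero
        self.biases[-1][:] = 1.0

    # -- network ----------------------------------------------------------
    def forward(self, t_norm, cache=None):
        """Normalized distances for normalized times ``t_norm`` (B,) -> (B, m)."""
        a = np.atleast_1d(np.asarray(t_norm, float))[:, None]
        if cache is not None:
            cache.clear()
            cache.append(a)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if i < len(self.weights) - 1:
                a = _gelu(z)
            else:
                a = z
            if cache is not None:
                cache.append(z)
        return a

    def backward(self, cache, grad_out):
        """Gradients of sum(grad_out * output) w.r.t. weights and biases."""
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = grad_out
        for i in reversed(range(len(self.weights))):
            a_prev = cache[i] if i == 0 else _gelu(cache[i])
            gW[i] = a_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * _gelu_grad(cache[i])
        return gW, gb

    def distances(self, t_norm) -> np.ndarray:
        """Face distances in mm, clipped positive, (B, m)."""
        out = self.forward(t_norm) * self.size_scale
        return np.maximum(out, 1e-3 * self.size_scale)

    def config_at(self, t: int, T: int, snap_substrate: bool = True) -> CrystalConfiguration:
        d = self.distances(np.array([t / (T - 1)]))[0]
        cfg = CrystalConfiguration(
            self.habit,
            d,
            origin=self.origin.copy(),
            rotation=self.rotation.copy(),
            refractive_index=self.refractive_index,
        )
        if snap_substrate:
            mesh = build_polyhedron(self.habit, cfg)
            cfg.origin[2] -= float(mesh.vertices[:, 2].min())
        return cfg

    # -- flat parameter view (network + static rotation) ------------------
    def _flatten(self):
        parts = [w.ravel() for w in self.weights] + [b for b in self.biases] + [self.rotation]
        return np.concatenate(parts)

    def _unflatten(self, theta):
        i = 0
        for k, w in enumerate(self.weights):
            self.weights[k] = theta[i : i + w.size].reshape(w.shape).copy()
            i += w.size
        for k, b in enumerate(self.biases):
            self.biases[k] = theta[i : i + b.size].copy()
            i += b.size
        self.rotation = theta[i : i + 3].copy()

    def _flat_grad(self, gW, gb, g_rot):
        parts = [g.ravel() for g in gW] + list(gb) + [g_rot]
        return np.concatenate(parts)


def pretrain(
    model: SequenceModel,
    init_distances: np.ndarray,
    rng: np.random.Generator,
    batches: int = 1000,
    batch_size: int = 256,
    lr: float = 1e-3,
) -> SequenceModel:
    """Regress the network onto per-frame initial distance estimates.

    ``init_distances`` is (T, m) in mm.  Runs the configured number of
    batches of time points drawn uniformly from {0..T-1}, minimizing the
    squared error in normalized units.
    """
    targets = np.asarray(init_distances, float) / model.size_scale
    T = len(targets)
    n_static = 3
    flat0 = model._flatten()
    adam = Adam(len(flat0) - n_static, lr=lr)
    cache: list = []
    for _ in range(batches):
        idx = rng.integers(0, T, size=batch_size)
        t_norm = idx / (T - 1)
        out = model.forward(t_norm, cache)
        err = out - targets[idx]
        grad_out = 2.0 * err / batch_size
        gW, gb = model.backward(cache, grad_out)
        flat_g = model._flat_grad(gW, gb, np.zeros(3))[:-n_static]
        theta = model._flatten()
        theta[:-n_static] += adam.step(flat_g)
        model._unflatten(theta)
    return model


def negative_growth_penalty(distance_batch: np.ndarray, t_index: np.ndarray):
    """L+ = mean over ordered frame pairs (later, earlier) and faces of
    squared negative distance increments; returns (value, grad).

    ``distance_batch`` is (B, m), ``t_index`` the frame times (B,).  With
    fewer than two frames the penalty (and gradient) is zero.
    """
    D = np.atleast_2d(np.asarray(distance_batch, float))
    t = np.asarray(t_index)
    B, m = D.shape
    grad = np.zeros_like(D)
    if B < 2:
        return 0.0, grad
    pairs = [(g, h) for g in range(B) for h in range(B) if t[g] > t[h]]
    if not pairs:
        return 0.0, grad
    total = 0.0
    denom = len(pairs) * m
    for g, h in pairs:
        neg = np.minimum(0.0, D[g] - D[h])
        total += float(np.sum(neg**2))
        grad[g] += 2.0 * neg / denom
        grad[h] -= 2.0 * neg / denom
    return total / denom, grad


def apply_soft_constraints(distances: np.ndarray, manual: np.ndarray):
    """L_man contribution of one frame: mean squared distance deviation from
    a manual measurement; returns (value, grad w.r.t. distances)."""
    d = np.asarray(distances, float)
    man = np.asarray(manual, float)
    diff = d - man
    return float(np.mean(diff**2)), 2.0 * diff / len(d)


@dataclass
class SequenceFit:
    configurations: list  # canonical CrystalConfiguration per frame
    frame_losses: np.ndarray  # final L_ref per frame (nan for unusable)
    seq_loss_trace: np.ndarray  # L_seq per training step
    steps: int
    seed: int | None = None


@dataclass
class TrainSettings:
    steps: int = 1000
    batch_size: int = 16
    lr: float = 1e-4
    plateau_factor: float = 0.8
    plateau_patience: int = 200
    w_plus: float = 1e4
    w_manual: float = 1e4
    pretrain_batches: int = 1000
    pretrain_lr: float = 1e-3


def _sample_without_replacement(p: np.ndarray, k: int, rng: np.random.Generator):
    """Sequential multinomial sampling without replacement (renormalizing)."""
    p = p.astype(float).copy()
    out = []
    for _ in range(min(k, int(np.sum(p > 0)))):
        q = p / p.sum()
        i = int(rng.choice(len(p), p=q))
        out.append(i)
        p[i] = 0.0
    return np.asarray(out, dtype=int)


def train_sequence(
    model: SequenceModel,
    observations: list,
    weights: LossWeights,
    rng: np.random.Generator,
    geometry: ImageGeometry | None = None,
    settings: TrainSettings | None = None,
    manual_frames: dict | None = None,
    merge_tol: float | None = None,
    init_distances: np.ndarray | None = None,
) -> SequenceFit:
    """Train the sequence generator on per-frame observed keypoints.

    ``observations`` holds one (n_t, 2) keypoint array per frame (None for
    unusable frames).  If ``init_distances`` is given, the model is
    pretrained on them first.  Frames are drawn adaptively: per-frame errors
    (initialized uniform, refreshed lazily whenever a frame is evaluated)
    form a multinomial from which each batch is sampled without
    replacement.  The learning rate decays by ``plateau_factor`` whenever
    the sequence error has not improved for ``plateau_patience`` steps.
    """
    geometry = geometry or ImageGeometry()
    settings = settings or TrainSettings()
    manual_frames = manual_frames or {}
    T = len(observations)
    usable = np.array([obs is not None for obs in observations])
    if not np.any(usable):
        raise FacetFitError("no usable frames to fit")

    if init_distances is not None:
        pretrain(model, init_distances, rng, settings.pretrain_batches,
                 lr=settings.pretrain_lr)

    divergences = [
        SinkhornDivergence(obs, weights.sinkhorn) if obs is not None else None
        for obs in observations
    ]
    errors = np.where(usable, 1.0, 0.0)  # uniform before first evaluation
    cached_loss = np.full(T, np.nan)

    n_static = 3
    flat = model._flatten()
    adam = Adam(len(flat), lr=settings.lr)
    lr_scale = 1.0
    best_seq = np.inf
    since_improve = 0
    halved_on_nan = False
    seq_trace = []
    cache: list = []
    t_grid = np.arange(T) / (T - 1)

    for step in range(settings.steps):
        batch = _sample_without_replacement(errors, settings.batch_size, rng)
        t_norm = batch / (T - 1)
        out = model.forward(t_norm, cache)  # (B, m) normalized
        D_batch = np.maximum(out * model.size_scale, 1e-3 * model.size_scale)

        grad_D = np.zeros_like(D_batch)
        g_rot = np.zeros(3)
        batch_loss = 0.0
        failed = False
        for j, t in enumerate(batch):
            cfg = CrystalConfiguration(
                model.habit,
                D_batch[j],
                origin=model.origin.copy(),
                rotation=model.rotation.copy(),
                refractive_index=model.refractive_index,
            )
            mesh = build_polyhedron(model.habit, cfg)
            cfg.origin[2] -= float(mesh.vertices[:, 2].min())
            try:
                bd, g = total_loss_and_grad(
                    cfg, None, weights, geometry,
                    free=("distances", "rotation"),
                    merge_tol=merge_tol, divergence=divergences[t],
                )
            except Exception:
                failed = True
                break
            loss_t = bd.total
            g_d = g[: model.habit.n_faces]
            g_r = g[model.habit.n_faces :]
            if t in manual_frames:
                v_man, g_man = apply_soft_constraints(D_batch[j], manual_frames[t])
                loss_t += settings.w_manual * v_man
                g_d = g_d + settings.w_manual * g_man
            if not np.isfinite(loss_t):
                failed = True
                break
            cached_loss[t] = loss_t
            errors[t] = loss_t
            batch_loss += loss_t / len(batch)
            grad_D[j] += g_d / len(batch)
            g_rot += g_r / len(batch)

        if failed or not np.isfinite(batch_loss):
            if not halved_on_nan:
                lr_scale *= 0.5
                halved_on_nan = True
            seq_trace.append(seq_trace[-1] if seq_trace else np.nan)
            continue

        v_plus, g_plus = negative_growth_penalty(D_batch, batch)
        batch_loss += settings.w_plus * v_plus
        grad_D += settings.w_plus * g_plus

        grad_out = grad_D * model.size_scale  # chain through the unit scale
        grad_out[out * model.size_scale < 1e-3 * model.size_scale] = 0.0
        gW, gb = model.backward(cache, grad_out)
        flat_g = model._flat_grad(gW, gb, g_rot)
        theta = model._flatten()
        adam.lr = settings.lr * lr_scale
        theta += adam.step(flat_g)
        model._unflatten(theta)

        known = np.isfinite(cached_loss)
        L_seq = float(np.mean(cached_loss[known])) if np.any(known) else np.nan
        seq_trace.append(L_seq)
        if np.isfinite(L_seq) and L_seq < best_seq - 1e-12:
            best_seq = L_seq
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= settings.plateau_patience:
                lr_scale *= settings.plateau_factor
                since_improve = 0

    # recover the fitted sequence from the trained model
    configs = []
    frame_losses = np.full(T, np.nan)
    for t in range(T):
        cfg = model.config_at(t, T)
        if divergences[t] is not None:
            from .fitloss import total_loss

            frame_losses[t] = total_loss(
                cfg, None, weights, geometry,
                merge_tol=merge_tol, divergence=divergences[t],
            ).total
        configs.append(canonicalize(cfg))
    return SequenceFit(
        configurations=configs,
        frame_losses=frame_losses,
        seq_loss_trace=np.asarray(seq_trace),
        steps=settings.steps,
    )
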