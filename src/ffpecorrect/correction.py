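"""Artefact correction by partially fixed KL-NMF.

An observed FFPE mutation catalogue ``V`` (96 or 80 channels) is modelled
as a linear combination of a *fixed* artefact signature ``W1`` and a free
biological spectrum ``W2`` with non-negative activities ``H1, H2``::

    V  ≈  W1 * H1 + W2 * H2

``W2`` and ``H`` are inferred by minimizing the generalized Kullback–
Leibler divergence D(V || V̂) with Lee–Seung multiplicative updates, in
which the ``W1`` column is never updated.  Each restart draws a random
initialization; the final answer averages many restarts.  Iteration stops
once the mean divergence of the most recent batch of 20 iterations is at
least ``conv_ratio_threshold`` times that of the previous batch (the
divergence is non-increasing, so this ratio approaches 1 as progress
stalls), subject to a minimum and maximum iteration count.

Two corrected catalogues are emitted: ``corrected_subtract`` (the observed
counts minus the inferred noise, floored at zero — preserves observed
channel detail and is the primary output) and ``corrected_model`` (the
smooth model reconstruction ``H2·W2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalogue import Catalogue, reduce_to_80c

__all__ = [
    "CorrectionConfig",
    "CorrectionSolution",
    "CorrectionResult",
    "generalized_kl",
    "multiplicative_step",
    "run_restart",
    "correct",
]


@dataclass(frozen=True)
class CorrectionConfig:
    """Optimizer settings for correction and refitting.

    ``min_iter``/``max_iter`` bound the multiplicative-update iterations,
    ``batch`` is the window (in iterations) over which mean divergences are
    compared, and ``conv_ratio_threshold`` the recent/previous batch-mean
    ratio at which iteration stops.  ``epsilon`` guards divisions only and
    never enters reported outputs.
    """

    min_iter: int = 200
    max_iter: int = 3000
    batch: int = 20
    conv_ratio_threshold: float = 0.95
    n_restarts: int = 100
    epsilon: float = 1e-12
    base_seed: int = 0
    channel_mode: str = "96c"

    def __post_init__(self) -> None:
        if self.min_iter < 2 * self.batch:
            raise ValueError("min_iter must be at least two convergence batches")
        if not 0 < self.conv_ratio_threshold <= 1:
            raise ValueError("conv_ratio_threshold must be in (0, 1]")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.channel_mode not in ("96c", "80c"):
            raise ValueError("channel_mode must be '96c' or '80c'")


@dataclass
class CorrectionSolution:
    """One restart's inferred decomposition and its divergence trace."""

    W2: np.ndarray
    H1: float
    H2: float
    kl_trace: np.ndarray
    n_iter: int
    seed: int


@dataclass
class CorrectionResult:
    """Restart-averaged decomposition of an observed catalogue."""

    mean_W2: np.ndarray
    mean_H1: float
    mean_H2: float
    noise_profile: np.ndarray
    corrected_subtract: np.ndarray
    corrected_model: np.ndarray
    config: CorrectionConfig
    restart_H1: np.ndarray = field(default_factory=lambda: np.empty(0))
    restart_H2: np.ndarray = field(default_factory=lambda: np.empty(0))
    solutions: list[CorrectionSolution] = field(default_factory=list)


def generalized_kl(v: np.ndarray, vhat: np.ndarray, epsilon: float = 1e-12) -> float:
    """Generalized KL divergence ``Σ v·log(v/v̂) − v + v̂``.

    Zero entries of ``v`` contribute ``v̂`` (the ``v log v`` limit is 0);
    ``epsilon`` guards the logarithm where ``v̂`` underflows.
    """
    v = np.asarray(v, dtype=float)
    vhat = np.asarray(vhat, dtype=float)
    if np.any(v < 0) or np.any(vhat < 0):
        raise ValueError("generalized KL requires non-negative vectors")
    pos = v > 0
    out = float(np.sum(vhat) - np.sum(v))
    out += float(np.sum(v[pos] * np.log(v[pos] / np.maximum(vhat[pos], epsilon))))
    return out


def multiplicative_step(
    V: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    fixed_columns: frozenset[int] | set[int] = frozenset({0}),
    epsilon: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """One full KL-NMF iteration with some basis columns held fixed.

    First all activities are updated, then each free column of ``W`` is
    updated against the refreshed reconstruction and renormalized to sum 1
    with the scale factor absorbed into its activity.  The generalized KL
    divergence never increases across the step.
    """
    V = np.asarray(V, dtype=float)
    W = np.asarray(W, dtype=float).copy()
    H = np.asarray(H, dtype=float).copy()
    vhat = W @ H
    ratio = V / np.maximum(vhat, epsilon)
    H = H * (W.T @ ratio) / np.maximum(W.sum(axis=0), epsilon)
    free = [k for k in range(W.shape[1]) if k not in fixed_columns]
    if free:
        vhat = W @ H
        ratio = V / np.maximum(vhat, epsilon)
        for k in free:
            # numerator Σ_µ H_kµ (V/V̂); single-sample case: factor H_k cancels
            W[:, k] = W[:, k] * ratio
            scale = W[:, k].sum()
            if scale > 0:
                W[:, k] /= scale
                H[k] *= scale
    return W, H


def _iterate_restarts(
    V: np.ndarray,
    W1: np.ndarray,
    W2: np.ndarray,
    H: np.ndarray,
    cfg: CorrectionConfig,
    update_w2: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run multiplicative updates for a batch of restarts simultaneously.

    Shapes: ``V``/``W1`` are (C,), ``W2`` is (R, C), ``H`` is (R, 2).
    Returns updated ``W2``, ``H``, per-restart divergence traces
    (R, n_iter; NaN-padded past each restart's stop) and ``n_iter`` (R,).
    """
    eps = cfg.epsilon
    R = W2.shape[0]
    kl = np.full((R, cfg.max_iter), np.nan)
    n_iter = np.full(R, cfg.max_iter, dtype=int)
    active = np.ones(R, dtype=bool)
    w1sum = max(W1.sum(), eps)
    pos = V > 0
    const = float(np.sum(V[pos] * np.log(V[pos])) - V.sum())

    t = 0
    while t < cfg.max_iter and active.any():
        idx = np.flatnonzero(active)
        w2 = W2[idx]
        h = H[idx]
        vhat = h[:, :1] * W1[None, :] + h[:, 1:2] * w2
        ratio = V[None, :] / np.maximum(vhat, eps)
        h = h * np.stack(
            [(ratio @ W1) / w1sum, np.einsum("rc,rc->r", ratio, w2)], axis=1
        )
        if update_w2:
            vhat = h[:, :1] * W1[None, :] + h[:, 1:2] * w2
            ratio = V[None, :] / np.maximum(vhat, eps)
            w2 = w2 * ratio
            scale = w2.sum(axis=1)
            ok = scale > 0
            w2[ok] /= scale[ok, None]
            h[ok, 1] *= scale[ok]
        vhat = h[:, :1] * W1[None, :] + h[:, 1:2] * w2
        kl[idx, t] = (
            vhat.sum(axis=1)
            - np.log(np.maximum(vhat[:, pos], eps)) @ V[pos]
            + const
        )
        W2[idx] = w2
        H[idx] = h
        t += 1
        if t >= cfg.min_iter and t % cfg.batch == 0:
            recent = kl[idx, t - cfg.batch : t].mean(axis=1)
            previous = kl[idx, t - 2 * cfg.batch : t - cfg.batch].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio_conv = np.where(previous > 0, recent / previous, 1.0)
            done = ratio_conv >= cfg.conv_ratio_threshold
            n_iter[idx[done]] = t
            active[idx[done]] = False
    n_iter[active] = cfg.max_iter
    return W2, H, kl, n_iter


def _init_restarts(
    total: float, n_channels: int, seeds: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Random initialization per restart: activities start near an equal
    split of the observed total (uniform jitter in [0.8, 1.2]) and ``W2``
    from a flat Dirichlet so every channel has support (multiplicative
    updates cannot escape zero entries)."""
    W2 = np.empty((len(seeds), n_channels))
    H = np.empty((len(seeds), 2))
    for r, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        H[r] = total / 2.0 * rng.uniform(0.8, 1.2, size=2)
        W2[r] = rng.dirichlet(np.ones(n_channels))
    return W2, H


def _prepare(V, W1, cfg: CorrectionConfig) -> tuple[np.ndarray, np.ndarray]:
    from .noise_signature import NoiseSignature

    v = V.counts if isinstance(V, Catalogue) else np.asarray(V, dtype=float)
    w1 = (
        W1.probabilities
        if isinstance(W1, NoiseSignature)
        else np.asarray(W1, dtype=float)
    )
    if cfg.channel_mode == "80c":
        if v.shape == (96,):
            v = reduce_to_80c(v, renormalize=False)
        if w1.shape == (96,):
            w1 = reduce_to_80c(w1, renormalize=True)
    if v.shape != w1.shape:
        raise ValueError(f"catalogue/signature shape mismatch: {v.shape} vs {w1.shape}")
    if v.sum() == 0:
        raise ValueError("cannot correct an empty catalogue")
    return v, w1


def run_restart(V, W1, cfg: CorrectionConfig | None = None, seed: int = 0) -> CorrectionSolution:
    """A single random-restart decomposition of ``V`` against fixed ``W1``."""
    cfg = cfg or CorrectionConfig()
    v, w1 = _prepare(V, W1, cfg)
    W2, H = _init_restarts(v.sum(), v.shape[0], [seed])
    W2, H, kl, n_iter = _iterate_restarts(v, w1, W2, H, cfg)
    n = int(n_iter[0])
    return CorrectionSolution(
        W2=W2[0], H1=float(H[0, 0]), H2=float(H[0, 1]), kl_trace=kl[0, :n],
        n_iter=n, seed=seed,
    )


def correct(V, W1, cfg: CorrectionConfig | None = None) -> CorrectionResult:
    """Restart-averaged artefact correction of an observed catalogue.

    Runs ``cfg.n_restarts`` restarts with seeds ``base_seed ..
    base_seed+n−1``, averages ``W2`` (renormalized), ``H1`` and ``H2``
    across restarts, and derives the noise and corrected catalogues.
    """
    cfg = cfg or CorrectionConfig()
    v, w1 = _prepare(V, W1, cfg)
    seeds = [cfg.base_seed + r for r in range(cfg.n_restarts)]
    W2, H = _init_restarts(v.sum(), v.shape[0], seeds)
    W2, H, kl, n_iter = _iterate_restarts(v, w1, W2, H, cfg)

    mean_W2 = W2.mean(axis=0)
    s = mean_W2.sum()
    if s > 0:
        mean_W2 = mean_W2 / s
    mean_H1 = float(H[:, 0].mean())
    mean_H2 = float(H[:, 1].mean())
    noise_profile = mean_H1 * w1
    solutions = [
        CorrectionSolution(
            W2=W2[r], H1=float(H[r, 0]), H2=float(H[r, 1]),
            kl_trace=kl[r, : n_iter[r]], n_iter=int(n_iter[r]), seed=seeds[r],
        )
        for r in range(cfg.n_restarts)
    ]
    return CorrectionResult(
        mean_W2=mean_W2,
        mean_H1=mean_H1,
        mean_H2=mean_H2,
        noise_profile=noise_profile,
        corrected_subtract=np.maximum(v - noise_profile, 0.0),
        corrected_model=mean_H2 * mean_W2,
        config=cfg,
        restart_H1=H[:, 0].copy(),
        restart_H2=H[:, 1].copy(),
        solutions=solutions,
    )
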