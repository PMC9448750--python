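"""Signature activity refitting against a fixed reference set.

Given a mutation catalogue and an explicit set of active reference
signatures, activities are inferred by activity-only multiplicative KL
updates (every basis column is held fixed), sharing the convergence
machinery of the correction optimizer.  With the basis fixed the problem
is convex in the activities, so a deterministic equal-split initialization
suffices and no restarts are needed.

Downstream analyses covered here:

* binary presence calls at a relative-contribution threshold (present iff
  strictly above 0.1 by default) and their confusion-matrix metrics,
* activity error ε = |true − inferred| on relative activities,
* reconstruction accuracy (cosine of the reconstruction vs a designated
  truth profile on a channel mask),
* the 80-channel consistency analysis: rescaling 80c activities by the
  non-T>C mass of the corresponding 96c signature, and the
  log10(activity_80c / activity_96c) inconsistency rate with its
  "well-refitted" band of −0.30 .. 0.18 (activity ratio 0.5 .. 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import (
    Catalogue,
    ChannelMask,
    cosine_similarity,
    read_signature_matrix,
    reduce_to_80c,
)
from .correction import CorrectionConfig

__all__ = [
    "SignatureSet",
    "ActivityVector",
    "RefitResult",
    "PresenceMetrics",
    "refit_activities",
    "presence_calls",
    "score_presence",
    "activity_error",
    "reconstruction_accuracy",
    "rescale_80c_activity",
    "inconsistency_rate",
    "WELL_REFITTED_BAND",
]

#: log10 activity-ratio band treated as consistent between 80c and 96c fits
WELL_REFITTED_BAND = (-0.30, 0.18)


@dataclass
class SignatureSet:
    """Named reference signatures as a channels × signatures matrix."""

    names: list[str]
    matrix: np.ndarray
    channel_mode: str = "96c"

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        n_channels = {"96c": 96, "80c": 80}.get(self.channel_mode)
        if n_channels is None:
            raise ValueError("channel_mode must be '96c' or '80c'")
        if matrix.ndim != 2 or matrix.shape[0] != n_channels:
            raise ValueError(
                f"expected ({n_channels}, K) matrix, got {matrix.shape}"
            )
        if matrix.shape[1] != len(self.names):
            raise ValueError("one name per signature column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        if np.any(matrix < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            off = [self.names[k] for k in np.flatnonzero(np.abs(sums - 1) > 1e-9)]
            raise ValueError(f"signature columns must sum to 1: {off}")
        self.matrix = matrix
        self.names = list(self.names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, channel_mode: str = "96c") -> "SignatureSet":
        matrix = df.to_numpy(dtype=float)
        matrix = matrix / matrix.sum(axis=0, keepdims=True)
        return cls(list(df.columns), matrix, channel_mode)

    @classmethod
    def from_tsv(cls, path) -> "SignatureSet":
        return cls.from_dataframe(read_signature_matrix(path))

    def select(self, names: Sequence[str]) -> "SignatureSet":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"unknown signatures: {missing}")
        cols = [self.names.index(n) for n in names]
        return SignatureSet(list(names), self.matrix[:, cols], self.channel_mode)

    def to_80c(self) -> "SignatureSet":
        """Drop T>C channels and renormalize each signature to sum 1."""
        if self.channel_mode != "96c":
            raise ValueError("already in 80c mode")
        cols = np.stack(
            [reduce_to_80c(self.matrix[:, k], renormalize=True) for k in range(len(self.names))],
            axis=1,
        )
        return SignatureSet(list(self.names), cols, "80c")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class ActivityVector:
    """Absolute (mutation-count) and relative signature activities."""

    names: list[str]
    absolute: np.ndarray

    def __post_init__(self) -> None:
        absolute = np.asarray(self.absolute, dtype=float)
        if absolute.shape != (len(self.names),):
            raise ValueError("one activity per signature required")
        if np.any(absolute < 0):
            raise ValueError("activities must be non-negative")
        self.absolute = absolute

    @property
    def relative(self) -> np.ndarray:
        tot = self.absolute.sum()
        if tot == 0:
            return np.zeros_like(self.absolute)
        return self.absolute / tot

    def as_series(self) -> pd.Series:
        return pd.Series(self.absolute, index=self.names)


@dataclass
class RefitResult:
    activities: ActivityVector
    reconstruction: np.ndarray
    kl: float
    n_iter: int


@dataclass
class PresenceMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def error_rate(self) -> float:
        n = self.tp + self.fp + self.fn + self.tn
        return (self.fp + self.fn) / n if n else float("nan")


def refit_activities(
    cat: Catalogue | np.ndarray,
    sigs: SignatureSet,
    cfg: CorrectionConfig | None = None,
) -> RefitResult:
    """Infer non-negative activities of fixed signatures for one catalogue.

    Activity-only multiplicative KL updates from a deterministic equal
    split of the observed total; converges to the global optimum of this
    convex subproblem.
    """
    cfg = cfg or CorrectionConfig()
    v = cat.counts if isinstance(cat, Catalogue) else np.asarray(cat, dtype=float)
    M = sigs.matrix
    if v.shape != (M.shape[0],):
        raise ValueError(
            f"channel-mode mismatch: catalogue has {v.shape[0]} channels, "
            f"signatures {M.shape[0]} ({sigs.channel_mode})"
        )
    total = v.sum()
    if total == 0:
        raise ValueError("cannot refit an empty catalogue")
    eps = cfg.epsilon
    K = M.shape[1]
    h = np.full(K, total / K)
    colsum = np.maximum(M.sum(axis=0), eps)
    kl_hist = np.empty(cfg.max_iter)
    pos = v > 0
    const = float(np.sum(v[pos] * np.log(v[pos])) - total)
    n_iter = cfg.max_iter
    for t in range(cfg.max_iter):
        vhat = M @ h
        ratio = v / np.maximum(vhat, eps)
        h = h * (M.T @ ratio) / colsum
        vhat = M @ h
        kl_hist[t] = float(vhat.sum() - np.log(np.maximum(vhat[pos], eps)) @ v[pos] + const)
        if (t + 1) >= cfg.min_iter and (t + 1) % cfg.batch == 0:
            recent = kl_hist[t + 1 - cfg.batch : t + 1].mean()
            previous = kl_hist[t + 1 - 2 * cfg.batch : t + 1 - cfg.batch].mean()
            if previous <= 0 or recent / previous >= cfg.conv_ratio_threshold:
                n_iter = t + 1
                break
    activities = ActivityVector(list(sigs.names), h)
    return RefitResult(
        activities=activities,
        reconstruction=M @ h,
        kl=float(kl_hist[n_iter - 1]),
        n_iter=n_iter,
    )


def presence_calls(relative: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Binary presence per signature: present iff relative activity is
    strictly greater than ``threshold`` (a contribution of exactly 0.1 is
    called absent)."""
    relative = np.asarray(relative, dtype=float)
    return relative > threshold


def score_presence(calls: np.ndarray, truth: np.ndarray) -> PresenceMetrics:
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls/truth shape mismatch")
    return PresenceMetrics(
        tp=int(np.sum(calls & truth)),
        fp=int(np.sum(calls & ~truth)),
        fn=int(np.sum(~calls & truth)),
        tn=int(np.sum(~calls & ~truth)),
    )


def activity_error(
    true_rel: ActivityVector | Mapping[str, float] | np.ndarray,
    inferred_rel: ActivityVector | Mapping[str, float] | np.ndarray,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Per-signature ε = |true − inferred| on relative activities, and its
    mean.  Signature name orderings must agree."""

    def unpack(x, other_names):
        if isinstance(x, ActivityVector):
            return list(x.names), x.relative
        if isinstance(x, Mapping):
            ks = list(x)
            return ks, np.array([x[k] for k in ks], dtype=float)
        return list(other_names) if other_names else None, np.asarray(x, dtype=float)

    names_t, vt = unpack(true_rel, names)
    names_i, vi = unpack(inferred_rel, names)
    if names_t is not None and names_i is not None and names_t != names_i:
        raise ValueError(f"signature name mismatch: {names_t} vs {names_i}")
    if vt.shape != vi.shape:
        raise ValueError("activity vectors differ in length")
    eps_vec = np.abs(vt - vi)
    return eps_vec, float(eps_vec.mean())


def reconstruction_accuracy(
    refit: RefitResult | np.ndarray,
    truth: Catalogue | np.ndarray,
    mask: ChannelMask | None = None,
) -> float:
    """Cosine similarity of a refit reconstruction to a truth profile."""
    rec = refit.reconstruction if isinstance(refit, RefitResult) else np.asarray(refit)
    tru = truth.counts if isinstance(truth, Catalogue) else np.asarray(truth)
    if mask is not None and rec.shape != (96,):
        raise ValueError("channel masks apply to 96-channel vectors only")
    return cosine_similarity(rec, tru, mask)


def rescale_80c_activity(act80: float | np.ndarray, sig96: np.ndarray) -> float | np.ndarray:
    """Convert an 80c-fitted activity back to the 96c scale.

    The 80c signature only covers the non-T>C fraction of the 96c
    spectrum, so the fitted activity is divided by that fraction.
    """
    sig96 = np.asarray(sig96, dtype=float)
    if sig96.shape != (96,):
        raise ValueError("expected a 96-channel signature")
    act80 = np.asarray(act80, dtype=float)
    if np.any(act80 < 0):
        raise ValueError("activities must be non-negative")
    non_tc_mass = reduce_to_80c(sig96, renormalize=False).sum()
    if non_tc_mass <= 0:
        raise ValueError("signature has no non-T>C mass; rescaling undefined")
    out = act80 / non_tc_mass
    return float(out) if out.ndim == 0 else out


def inconsistency_rate(
    act80_rescaled: float, act96: float
) -> tuple[float, bool]:
    """log10 ratio of 80c to 96c activity, and the well-refitted flag.

    Zero or negative activity on either side yields a NaN sentinel (to be
    counted, not averaged) with ``well_refitted=False``.
    """
    if act80_rescaled <= 0 or act96 <= 0:
        return float("nan"), False
    r = float(np.log10(act80_rescaled / act96))
    lo, hi = WELL_REFITTED_BAND
    return r, bool(lo <= r <= hi)
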