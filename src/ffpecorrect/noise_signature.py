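"""Derivation of formalin-artefact signatures from labelled cohorts.

Formalin fixation deaminates cytosine (and, after UDG repair, leaves the
5-methylcytosine-derived lesions at CpG sites), producing artefactual C>T
calls.  Given a cohort of per-sample mutation profiles labelled by repair
protocol (``unrepaired`` / ``repaired``), the artefact signature for each
protocol is derived by:

1. zeroing the 16 T>C channels (batch-related artefacts of unclear origin
   are treated as missing data) and renormalizing each profile;
2. embedding the cohort in 2-D with t-SNE on the pairwise cosine-distance
   matrix of the 80 informative channels;
3. estimating point density in the embedding with a Gaussian kernel and
   keeping, within each protocol group, the densest half of the samples
   (outlier exclusion);
4. averaging the selected profiles into one candidate signature;
5. repeating steps 2–4 over many t-SNE seeds and averaging the candidates.

Two bundled signatures are shipped with the package.  They are *synthetic*
constructions that emulate the published qualitative structure of formalin
artefact spectra (C>T dominated; the repaired signature concentrated at
CpG contexts, the unrepaired one spread across C>T contexts; zero T>C
mass), for use in simulation and testing when no cohort is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE

from .catalogue import (
    NON_TC_MASK,
    TC_MASK,
    read_signature_matrix,
)

__all__ = [
    "SampleSet",
    "Embedding",
    "NoiseSignature",
    "build_sample_set",
    "embed_profiles",
    "select_representatives",
    "candidate_signature",
    "derive_noise_signature",
    "bundled_signatures",
    "PROTOCOLS",
]

PROTOCOLS = ("unrepaired", "repaired")
_TC_IDX = list(TC_MASK.indices)
_NON_TC_IDX = list(NON_TC_MASK.indices)


@dataclass
class SampleSet:
    """Cohort of 96-channel probability profiles with protocol labels.

    T>C entries must be exactly zero (enforced by
    :func:`build_sample_set`), each row summing to 1.
    """

    profiles: np.ndarray
    labels: list[str]
    study: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=float)
        if profiles.ndim != 2 or profiles.shape[1] != 96:
            raise ValueError("profiles must be an N x 96 matrix")
        if len(self.labels) != profiles.shape[0]:
            raise ValueError("one protocol label per profile required")
        bad = set(self.labels) - set(PROTOCOLS)
        if bad:
            raise ValueError(f"unknown protocol labels: {sorted(bad)}")
        if np.any(np.abs(profiles.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each profile must sum to 1")
        if np.any(profiles[:, _TC_IDX] != 0):
            raise ValueError("T>C channels must be exactly zero")
        if not self.study:
            self.study = ["<unknown>"] * profiles.shape[0]
        self.profiles = profiles
        self.labels = list(self.labels)

    def __len__(self) -> int:
        return self.profiles.shape[0]

    def subset(self, indices: Sequence[int]) -> "SampleSet":
        idx = list(indices)
        return SampleSet(
            self.profiles[idx],
            [self.labels[i] for i in idx],
            [self.study[i] for i in idx],
        )


def build_sample_set(
    counts: np.ndarray,
    labels: Sequence[str],
    study: Sequence[str] | None = None,
) -> SampleSet:
    """Normalize raw 96-channel counts/probabilities into a
    :class:`SampleSet`: T>C channels are zeroed and each row renormalized."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 96:
        raise ValueError("counts must be an N x 96 matrix")
    profiles = counts.copy()
    profiles[:, _TC_IDX] = 0.0
    sums = profiles.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("a sample has no non-T>C mass")
    profiles /= sums[:, None]
    return SampleSet(profiles, list(labels), list(study) if study else [])


@dataclass
class Embedding:
    """2-D t-SNE embedding of a cohort, reproducible from (profiles, seed)."""

    coords: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)


def _cosine_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    sub = profiles[:, _NON_TC_IDX]
    norms = np.linalg.norm(sub, axis=1)
    sim = (sub @ sub.T) / np.outer(norms, norms)
    dist = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def embed_profiles(
    sample_set: SampleSet, seed: int, perplexity: float | None = None
) -> Embedding:
    """t-SNE embedding from the 80-channel pairwise cosine distances.

    Deterministic for a fixed seed.  Perplexity defaults to
    ``min(30, (N−1)//3)`` so small cohorts remain embeddable.
    """
    n = len(sample_set)
    if n < 5:
        raise ValueError(f"at least 5 samples required for embedding, got {n}")
    if perplexity is None:
        perplexity = min(30, (n - 1) // 3)
    perplexity = max(perplexity, 1)
    dist = _cosine_distance_matrix(sample_set.profiles)
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    coords = tsne.fit_transform(dist)
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        seed=seed,
        params={"perplexity": perplexity, "n_components": 2, "metric": "cosine-precomputed"},
    )


def select_representatives(
    emb: Embedding | np.ndarray,
    labels: Sequence[str],
    fraction: float = 0.5,
) -> dict[str, np.ndarray]:
    """Densest ``fraction`` of samples per protocol group.

    Gaussian-kernel density (Scott's bandwidth) is evaluated at each
    embedded point within its label group.  Points strictly above the
    group's ``1−fraction`` density quantile are selected; ties at the
    threshold fill the quota ``ceil(n·fraction)`` in ascending original
    index order.  A degenerate group (all points coincident) is returned
    whole with a warning.
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = list(labels)
    if len(labels) != coords.shape[0]:
        raise ValueError("one label per embedded point required")
    out: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(labels):
        idx = np.array([i for i, l in enumerate(labels) if l == label])
        if len(idx) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
        pts = coords[idx].T  # (2, n)
        quota = math.ceil(len(idx) * fraction)
        if fraction == 1.0:
            out[label] = idx.copy()
            continue
        try:
            density = gaussian_kde(pts)(pts)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"group {label!r}: coincident points, keeping all", stacklevel=2
            )
            out[label] = idx.copy()
            continue
        threshold = np.quantile(density, 1.0 - fraction)
        above = density > threshold
        chosen = list(np.flatnonzero(above))
        ties = np.flatnonzero(np.isclose(density, threshold) & ~above)
        for j in ties:
            if len(chosen) >= quota:
                break
            chosen.append(j)
        chosen = sorted(chosen)[:max(quota, sum(above))]
        out[label] = idx[sorted(chosen)]
    return out


def candidate_signature(sample_set: SampleSet, indices: Sequence[int]) -> np.ndarray:
    """Mean of the selected profiles, renormalized to sum 1."""
    idx = list(indices)
    if not idx:
        raise ValueError("empty representative index set")
    mean = sample_set.profiles[idx].mean(axis=0)
    return mean / mean.sum()


@dataclass
class NoiseSignature:
    """A formalin-artefact signature: 96 probabilities, zero T>C mass."""

    probabilities: np.ndarray
    protocol: str
    provenance: str = "derived"
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (96,):
            raise ValueError("signature must have 96 channels")
        if np.any(p < 0):
            raise ValueError("signature probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("signature must sum to 1")
        if np.any(p[_TC_IDX] != 0):
            raise ValueError("signature must carry zero T>C mass")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        self.probabilities = p


def derive_noise_signature(
    sample_set: SampleSet,
    protocol: str,
    n_seeds: int = 100,
    fraction: float = 0.5,
) -> NoiseSignature:
    """Repeat embed → select → average over t-SNE seeds 0..n_seeds−1 and
    average the per-seed candidates into the final artefact signature."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    if protocol not in sample_set.labels:
        raise ValueError(f"no samples with protocol {protocol!r}")
    candidates = []
    for seed in range(n_seeds):
        emb = embed_profiles(sample_set, seed)
        reps = select_representatives(emb, sample_set.labels, fraction=fraction)
        candidates.append(candidate_signature(sample_set, reps[protocol]))
    final = np.mean(candidates, axis=0)
    final = final / final.sum()
    # candidates can carry float dust on T>C from renormalization arithmetic
    final[_TC_IDX] = 0.0
    final = final / final.sum()
    return NoiseSignature(final, protocol, provenance="derived", seeds=list(range(n_seeds)))


_FIXTURE_FILE = "synthetic_ffpe_signatures.tsv"
_FIXTURE_COLUMNS = {"unrepaired": "FFPE_unrepaired", "repaired": "FFPE_repaired"}


def bundled_signatures(protocol: str) -> NoiseSignature:
    """Load a packaged artefact signature (synthetic stand-in; see module
    docstring) for ``protocol`` in {'unrepaired', 'repaired'}."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    ref = resources.files("ffpecorrect.data").joinpath(_FIXTURE_FILE)
    with resources.as_file(ref) as path:
        df = read_signature_matrix(path)
    p = df[_FIXTURE_COLUMNS[protocol]].to_numpy(dtype=float)
    p = p / p.sum()
    return NoiseSignature(p, protocol, provenance="fixture")
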