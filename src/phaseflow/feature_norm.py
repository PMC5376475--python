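"""Normalization of topic mixtures into discrete observation symbols.

The phase HMM observes one categorical symbol per second.  Two normalizers
turn the K-simplex topic mixture theta_i into that symbol:

``top``
    one-hot at the argmax topic — alphabet size K;

``kmeans``
    a codebook of c cluster centers is fitted on the training mixtures
    (Lloyd's algorithm, greedy farthest-point seeding) and each second maps
    to its nearest center — alphabet size c.

Ties always break toward the lowest index so quantization is deterministic.
Test-time seconds are assigned with the training codebook unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .topic_model import TopicFeature

__all__ = [
    "ObservationSymbol",
    "KMeansCodebook",
    "top_one_hot",
    "kmeans_fit",
    "kmeans_one_hot",
    "symbols_from_thetas",
    "save_codebook",
    "load_codebook",
]


@dataclass
class ObservationSymbol:
    """One-hot normalized feature for one second: an index into [0, A)."""

    second_index: int
    symbol: int
    alphabet_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.symbol < self.alphabet_size:
            raise ValueError("symbol outside alphabet")

    @property
    def one_hot(self) -> np.ndarray:
        v = np.zeros(self.alphabet_size)
        v[self.symbol] = 1.0
        return v


@dataclass
class KMeansCodebook:
    """c cluster centers over K-dimensional topic mixtures."""

    centers: np.ndarray
    inertia: float
    inertia_trace: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or not np.isfinite(self.centers).all():
            raise ValueError("centers must be a finite 2-D array")

    @property
    def c(self) -> int:
        return len(self.centers)

    @property
    def K(self) -> int:
        return self.centers.shape[1]


def _theta(t: TopicFeature | np.ndarray) -> np.ndarray:
    return t.theta if isinstance(t, TopicFeature) else np.asarray(t, dtype=float)


def _second(t: TopicFeature | np.ndarray, default: int = 0) -> int:
    return t.second_index if isinstance(t, TopicFeature) else default


def top_one_hot(theta: TopicFeature | np.ndarray) -> ObservationSymbol:
    """One-hot at the largest topic weight; ties to the lowest index."""
    v = _theta(theta)
    return ObservationSymbol(second_index=_second(theta),
                             symbol=int(np.argmax(v)), alphabet_size=len(v))


def _farthest_point_seeds(X: np.ndarray, c: int) -> np.ndarray:
    """Greedy seeding: start at the point farthest from the data mean, then
    repeatedly add the point maximizing the distance to its nearest seed."""
    d0 = np.linalg.norm(X - X.mean(axis=0), axis=1)
    seeds = [int(np.argmax(d0))]
    min_d = np.linalg.norm(X - X[seeds[0]], axis=1)
    while len(seeds) < c:
        nxt = int(np.argmax(min_d))
        seeds.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(X - X[nxt], axis=1))
    return X[seeds].copy()


def kmeans_fit(
    thetas: Sequence[TopicFeature] | np.ndarray,
    c: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> KMeansCodebook:
    """Lloyd's k-means with greedy spread-out seeding.

    Seeding is deterministic (farthest-point); ``seed`` only matters for the
    degenerate situation of exactly duplicated points.  Empty clusters are
    re-seeded to the point currently farthest from its assigned center.  The
    within-cluster sum of squares recorded after every assignment step is
    returned as ``inertia_trace`` and is nonincreasing.
    """
    X = np.stack([_theta(t) for t in thetas]) if not isinstance(thetas, np.ndarray) else np.asarray(thetas, float)
    n = len(X)
    if c < 1 or c > n:
        raise ValueError(f"need 1 <= c <= n, got c={c}, n={n}")
    centers = _farthest_point_seeds(X, c)
    trace: list[float] = []
    labels = None
    for it in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(n), new_labels].sum())
        trace.append(inertia)
        # re-seed empty clusters to the worst-served point
        for k in range(c):
            if not (new_labels == k).any():
                worst = int(d2[np.arange(n), new_labels].argmax())
                new_labels[worst] = k
        if labels is not None and (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
        for k in range(c):
            pts = X[labels == k]
            if len(pts):
                centers[k] = pts.mean(axis=0)
        if len(trace) > 1 and trace[-2] - trace[-1] < tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2.min(axis=1).sum())
    return KMeansCodebook(centers=centers, inertia=inertia,
                          inertia_trace=np.asarray(trace), n_iter=len(trace))


def kmeans_one_hot(theta: TopicFeature | np.ndarray, codebook: KMeansCodebook) -> ObservationSymbol:
    """One-hot at the nearest codebook center (Euclidean, ties to lowest)."""
    v = _theta(theta)
    if len(v) != codebook.K:
        raise ValueError(f"theta has dim {len(v)}, codebook expects {codebook.K}")
    d2 = ((codebook.centers - v) ** 2).sum(axis=1)
    return ObservationSymbol(second_index=_second(theta),
                             symbol=int(np.argmin(d2)), alphabet_size=codebook.c)


def symbols_from_thetas(
    thetas: Sequence[TopicFeature],
    normalizer: str = "top",
    codebook: KMeansCodebook | None = None,
) -> list[ObservationSymbol]:
    """Apply a normalizer to a per-second theta sequence."""
    if normalizer == "top":
        return [top_one_hot(t) for t in thetas]
    if normalizer == "kmeans":
        if codebook is None:
            raise ValueError("kmeans normalizer requires a fitted codebook")
        return [kmeans_one_hot(t, codebook) for t in thetas]
    raise ValueError(f"unknown normalizer {normalizer!r}")


def save_codebook(codebook: KMeansCodebook, path: str | Path) -> None:
    np.savez(Path(path), centers=codebook.centers, inertia=codebook.inertia,
             inertia_trace=codebook.inertia_trace, n_iter=codebook.n_iter)


def load_codebook(path: str | Path) -> KMeansCodebook:
    data = np.load(Path(path))
    return KMeansCodebook(centers=data["centers"], inertia=float(data["inertia"]),
                          inertia_trace=data["inertia_trace"], n_iter=int(data["n_iter"]))
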