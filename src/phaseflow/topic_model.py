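"""Per-second topic features via latent Dirichlet allocation.

Each one-second bag of motion words is an LDA "document".  Fitting LDA on the
training corpus yields a topic-word matrix phi (K x V, rows on the simplex)
and, for every second i, a topic mixture theta_i on the K-simplex — the
motion feature handed to the normalizer.  Priors follow the symmetric
convention alpha = 50/K on document-topic mixtures and beta = 0.1 on
topic-word distributions.

Inference uses mean-field variational Bayes (scikit-learn's batch
implementation), which is deterministic given the seed.  Held-out seconds are
folded in with phi held fixed, exactly mirroring how test workflows are
featurized with the training-time topic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numbers import Real

from scipy.special import psi
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.utils._param_validation import Interval

from .motion_words import ClipDocument

__all__ = ["LDAModel", "TopicFeature", "fit_lda", "infer_theta", "save_model", "load_model"]


class _LDA(LatentDirichletAllocation):
    """Variational LDA accepting Dirichlet priors above 1.

    scikit-learn's interface restricts both priors to (0, 1] although the
    mean-field updates are valid for any positive concentration; the
    alpha = 50/K convention exceeds 1 whenever K < 50, so the constraint is
    relaxed to "any positive real" here.
    """

    _parameter_constraints = {
        **LatentDirichletAllocation._parameter_constraints,
        "doc_topic_prior": [Interval(Real, 0, None, closed="neither"), None],
        "topic_word_prior": [Interval(Real, 0, None, closed="neither"), None],
    }


@dataclass
class TopicFeature:
    """Topic mixture theta_i for second i; nonnegative, sums to one."""

    second_index: int
    theta: np.ndarray
    from_empty_document: bool = False

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1:
            raise ValueError("theta must be a vector")
        if (self.theta < -1e-12).any() or abs(self.theta.sum() - 1.0) > 1e-8:
            raise ValueError("theta must lie on the probability simplex")


@dataclass
class LDAModel:
    """Fitted topic model: K topics over a vocabulary of size V.

    ``phi`` is the row-normalized topic-word matrix; ``components`` keeps the
    unnormalized variational parameters needed for exact fold-in inference.
    """

    K: int
    V: int
    alpha: float
    beta: float
    phi: np.ndarray
    components: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (self.K, self.V):
            raise ValueError("phi must be K x V")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("phi rows must sum to 1")
        if self.K < 1 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("K >= 1 and positive priors required")
        self._sk = _rebuild_estimator(self)


def _rebuild_estimator(model: LDAModel) -> LatentDirichletAllocation:
    """Reconstruct a scikit-learn estimator able to fold in new documents."""
    lda = _LDA(
        n_components=model.K,
        doc_topic_prior=model.alpha,
        topic_word_prior=model.beta,
        learning_method="batch",
        random_state=model.seed,
    )
    lda.components_ = model.components
    lda.exp_dirichlet_component_ = np.exp(
        psi(model.components) - psi(model.components.sum(axis=1))[:, None]
    )
    lda.doc_topic_prior_ = model.alpha
    lda.topic_word_prior_ = model.beta
    lda.n_features_in_ = model.V
    return lda


def _as_matrix(corpus: Sequence[ClipDocument] | np.ndarray) -> np.ndarray:
    if isinstance(corpus, np.ndarray):
        return corpus
    return np.stack([d.counts for d in corpus])


def fit_lda(
    corpus: Sequence[ClipDocument] | np.ndarray,
    K: int,
    alpha: float | None = None,
    beta: float = 0.1,
    iterations: int = 100,
    seed: int = 0,
) -> tuple[LDAModel, list[TopicFeature]]:
    """Fit LDA on a document corpus and return per-document topic features.

    ``alpha`` defaults to ``50 / K``.  Empty documents are kept in the
    timeline but receive a uniform theta (flagged ``from_empty_document``).
    """
    X = _as_matrix(corpus)
    if K < 1:
        raise ValueError("K must be >= 1")
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("corpus must be a nonempty document-term matrix")
    totals = X.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("all documents are empty; nothing to fit")
    if alpha is None:
        alpha = 50.0 / K

    lda = _LDA(
        n_components=K,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        learning_method="batch",
        max_iter=iterations,
        random_state=seed,
    )
    lda.fit(X[totals > 0])
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    model = LDAModel(
        K=K, V=X.shape[1], alpha=alpha, beta=beta,
        phi=phi, components=lda.components_.copy(), seed=seed,
    )
    thetas = transform_corpus(model, X)
    return model, thetas


def transform_corpus(model: LDAModel, corpus: Sequence[ClipDocument] | np.ndarray) -> list[TopicFeature]:
    """Fold in every document of a corpus with phi fixed."""
    X = _as_matrix(corpus)
    totals = X.sum(axis=1)
    thetas = np.full((len(X), model.K), 1.0 / model.K)
    nonempty = totals > 0
    if nonempty.any():
        thetas[nonempty] = model._sk.transform(X[nonempty])
    return [
        TopicFeature(second_index=i, theta=thetas[i], from_empty_document=not nonempty[i])
        for i in range(len(X))
    ]


def infer_theta(model: LDAModel, doc: ClipDocument | np.ndarray) -> TopicFeature:
    """Topic mixture for a single held-out document (phi held fixed).

    An empty document falls back to the uniform mixture, flagged, so the
    per-second timeline never loses a slot.
    """
    counts = doc.counts if isinstance(doc, ClipDocument) else np.asarray(doc)
    second = doc.second_index if isinstance(doc, ClipDocument) else 0
    if len(counts) != model.V:
        raise ValueError("document vocabulary does not match model")
    if counts.sum() == 0:
        return TopicFeature(second_index=second,
                            theta=np.full(model.K, 1.0 / model.K),
                            from_empty_document=True)
    theta = model._sk.transform(counts[None, :])[0]
    return TopicFeature(second_index=second, theta=theta)


def save_model(model: LDAModel, path: str | Path) -> None:
    np.savez(
        Path(path),
        K=model.K, V=model.V, alpha=model.alpha, beta=model.beta,
        phi=model.phi, components=model.components, seed=model.seed,
    )


def load_model(path: str | Path) -> LDAModel:
    data = np.load(Path(path))
    return LDAModel(
        K=int(data["K"]), V=int(data["V"]),
        alpha=float(data["alpha"]), beta=float(data["beta"]),
        phi=data["phi"], components=data["components"], seed=int(data["seed"]),
    )
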