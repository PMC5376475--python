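"""Left-to-right hidden Markov model over surgical phases.

A workflow runs through its Q phases in a fixed order with no going back, so
the phase process is modelled as a left-to-right Markov chain: from state q
only the self-transition q -> q and the step q -> q+1 have positive
probability, the last state is absorbing, and the chain always starts in
state 0.  The per-second observation is the discrete normalized-feature
symbol, with a categorical emission distribution per state.

Training is supervised-then-refined:

1. transition probabilities are the maximum-likelihood self/next ratios
   counted from the per-second ground-truth labels;
2. emission probabilities are per-state symbol frequencies, lightly smoothed
   (count / (state total + epsilon), then every cell floored at epsilon and
   the row renormalized so unseen symbols stay decodable);
3. Baum-Welch (EM) refines both on the unlabeled symbol sequences, pooling
   expected counts across sequences.  The left-to-right zeros are structural:
   EM cannot resurrect them.

Decoding is Viterbi in log space (most probable state path); a per-second
forward-filtering argmax is available as an alternative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PhaseAnnotation",
    "PhaseHMM",
    "BaumWelchResult",
    "estimate_transitions",
    "initial_distribution",
    "estimate_emissions",
    "fit_supervised",
    "baum_welch",
    "viterbi_decode",
    "forward_argmax",
    "sample_sequence",
    "annotation_from_labels",
    "load_annotations",
    "save_annotations",
    "save_hmm",
    "load_hmm",
]


@dataclass
class PhaseAnnotation:
    """Ground-truth segmentation of one workflow.

    ``segments`` is an ordered list of ``(phase_index, start_second,
    length_seconds)`` with phases 1..Q contiguous and strictly increasing.
    """

    workflow_id: str
    segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("annotation needs at least one segment")
        expected_phase, expected_start = 1, self.segments[0][1]
        for phase, start, length in self.segments:
            if phase != expected_phase:
                raise ValueError(f"phase indices must run 1..Q without gaps, got {phase}")
            if start != expected_start:
                raise ValueError("segments must be contiguous and nonoverlapping")
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            expected_phase += 1
            expected_start = start + length

    @property
    def n_phases(self) -> int:
        return len(self.segments)

    @property
    def total_seconds(self) -> int:
        return sum(length for _, _, length in self.segments)

    @property
    def start_second(self) -> int:
        return self.segments[0][1]

    def to_labels(self) -> np.ndarray:
        """Per-second phase labels (1-based), one entry per annotated second."""
        return np.concatenate([
            np.full(length, phase, dtype=int) for phase, _, length in self.segments
        ])

    def phase_starts(self) -> np.ndarray:
        """Start second of each phase, relative to the annotation origin."""
        return np.asarray([start - self.start_second for _, start, _ in self.segments])


@dataclass
class PhaseHMM:
    """Left-to-right HMM: Q states, alphabet of A symbols."""

    Q: int
    A: int
    T: np.ndarray
    pi: np.ndarray
    E: np.ndarray
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.T.shape != (self.Q, self.Q) or self.E.shape != (self.Q, self.A):
            raise ValueError("T must be QxQ and E must be QxA")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(self.E.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("emission rows must sum to 1")
        off = self.T.copy()
        for q in range(self.Q):
            off[q, q] = 0.0
            if q + 1 < self.Q:
                off[q, q + 1] = 0.0
        if (off != 0).any():
            raise ValueError("left-to-right structure violated (only self/next allowed)")
        if abs(self.T[self.Q - 1, self.Q - 1] - 1.0) > 1e-12:
            raise ValueError("last state must be absorbing")


def initial_distribution(Q: int) -> np.ndarray:
    """The chain always starts in the first phase: pi = (1, 0, ..., 0)."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    pi = np.zeros(Q)
    pi[0] = 1.0
    return pi


def _label_sequences(annotations: Sequence[PhaseAnnotation]) -> list[np.ndarray]:
    return [a.to_labels() - 1 for a in annotations]  # 0-based states


def estimate_transitions(annotations: Sequence[PhaseAnnotation], Q: int) -> np.ndarray:
    """ML self/next transition probabilities from labeled sequences.

    T[q, q] = N(q->q) / N(q->any); T[q, q+1] takes the rest.  The last state
    is absorbing by construction.  A non-final state never observed leaving
    (or never observed at all) has an undefined row and raises.
    """
    self_counts = np.zeros(Q)
    out_counts = np.zeros(Q)
    for labels in _label_sequences(annotations):
        if labels.max() >= Q:
            raise ValueError("annotation contains a phase index above Q")
        pairs = np.stack([labels[:-1], labels[1:]])
        for q in range(Q):
            from_q = pairs[0] == q
            out_counts[q] += from_q.sum()
            self_counts[q] += (from_q & (pairs[1] == q)).sum()
    T = np.zeros((Q, Q))
    for q in range(Q - 1):
        if out_counts[q] == 0:
            raise ValueError(f"phase {q + 1} has no observed transitions; row undefined")
        T[q, q] = self_counts[q] / out_counts[q]
        T[q, q + 1] = 1.0 - T[q, q]
    T[Q - 1, Q - 1] = 1.0
    return T


def estimate_emissions(
    annotations: Sequence[PhaseAnnotation],
    symbol_sequences: Sequence[np.ndarray],
    A: int,
    epsilon: float = 1e-4,
    floor: bool = True,
) -> np.ndarray:
    """Per-state symbol frequencies with epsilon smoothing.

    Raw ratio = count(state q, symbol a) / (seconds in q + epsilon); every
    cell is then floored at epsilon and rows are renormalized so every symbol
    stays emittable during held-out decoding.  ``floor=False`` returns the
    raw ratios (rows then sum to slightly under 1).
    """
    Q = max(a.n_phases for a in annotations)
    counts = np.zeros((Q, A))
    totals = np.zeros(Q)
    for ann, syms in zip(annotations, symbol_sequences):
        labels = ann.to_labels() - 1
        syms = np.asarray(syms, dtype=int)
        if len(syms) != len(labels):
            raise ValueError(
                f"workflow {ann.workflow_id}: {len(syms)} symbols vs {len(labels)} labeled seconds"
            )
        if syms.min() < 0 or syms.max() >= A:
            raise ValueError("symbol outside alphabet")
        np.add.at(counts, (labels, syms), 1)
        np.add.at(totals, labels, 1)
    if (totals == 0).any():
        missing = np.nonzero(totals == 0)[0] + 1
        raise ValueError(f"phases with zero assigned seconds: {missing.tolist()}")
    E = counts / (totals + epsilon)[:, None]
    if not floor:
        return E
    E = np.maximum(E, epsilon)
    return E / E.sum(axis=1, keepdims=True)


def fit_supervised(
    annotations: Sequence[PhaseAnnotation],
    symbol_sequences: Sequence[np.ndarray],
    Q: int,
    A: int,
    epsilon: float = 1e-4,
) -> PhaseHMM:
    """Supervised initialization: transitions, pi and emissions from labels."""
    return PhaseHMM(
        Q=Q, A=A,
        T=estimate_transitions(annotations, Q),
        pi=initial_distribution(Q),
        E=estimate_emissions(annotations, symbol_sequences, A, epsilon),
        epsilon=epsilon,
    )


def _forward_backward(hmm: PhaseHMM, obs: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, log_likelihood)."""
    T_len = len(obs)
    B = hmm.E[:, obs].T  # (T, Q) emission likelihoods
    alpha = np.zeros((T_len, hmm.Q))
    scale = np.zeros(T_len)
    alpha[0] = hmm.pi * B[0]
    scale[0] = alpha[0].sum()
    if scale[0] == 0:
        raise ValueError("observation sequence has zero probability under the model")
    alpha[0] /= scale[0]
    for t in range(1, T_len):
        alpha[t] = (alpha[t - 1] @ hmm.T) * B[t]
        scale[t] = alpha[t].sum()
        if scale[t] == 0:
            raise ValueError("observation sequence has zero probability under the model")
        alpha[t] /= scale[t]
    beta = np.zeros((T_len, hmm.Q))
    beta[-1] = 1.0
    for t in range(T_len - 2, -1, -1):
        beta[t] = (hmm.T @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((hmm.Q, hmm.Q))
    for t in range(T_len - 1):
        xi = hmm.T * np.outer(alpha[t], B[t + 1] * beta[t + 1]) / scale[t + 1]
        xi_sum += xi
    return gamma, xi_sum, float(np.log(scale).sum())


@dataclass
class BaumWelchResult:
    """Outcome of EM refinement: refined model and log-likelihood trace."""

    hmm: PhaseHMM
    log_likelihoods: np.ndarray = field(repr=False)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.log_likelihoods)


def baum_welch(
    hmm: PhaseHMM,
    sequences: Sequence[np.ndarray],
    tol: float = 1e-4,
    max_iter: int = 100,
    floor_emissions: bool = True,
) -> BaumWelchResult:
    """Baum-Welch re-estimation pooled over several symbol sequences.

    Expected transition and emission counts are summed across sequences in
    each M-step.  The recorded per-iteration total log-likelihood is
    nondecreasing (EM guarantee) because the optional epsilon re-flooring of
    emission rows is applied once *after* convergence, not inside the loop.
    Structural zeros of the left-to-right transition matrix are preserved:
    a zero entry accumulates zero expected count.
    """
    if not sequences:
        raise ValueError("need at least one observation sequence")
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    for s in sequences:
        if s.min() < 0 or s.max() >= hmm.A:
            raise ValueError("symbol outside alphabet")
    current = hmm
    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        xi_total = np.zeros((hmm.Q, hmm.Q))
        gamma_from = np.zeros(hmm.Q)
        emit = np.zeros((hmm.Q, hmm.A))
        gamma_total = np.zeros(hmm.Q)
        ll = 0.0
        for obs in sequences:
            gamma, xi_sum, seq_ll = _forward_backward(current, obs)
            ll += seq_ll
            xi_total += xi_sum
            gamma_from += gamma[:-1].sum(axis=0)
            np.add.at(emit.T, obs, gamma)
            gamma_total += gamma.sum(axis=0)
        lls.append(ll)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break
        T_new = np.zeros_like(current.T)
        nz = gamma_from > 0
        T_new[nz] = xi_total[nz] / gamma_from[nz, None]
        T_new[~nz] = current.T[~nz]
        # guard against round-off: renormalize rows, keep absorbing last state
        T_new[-1] = 0.0
        T_new[-1, -1] = 1.0
        T_new /= T_new.sum(axis=1, keepdims=True)
        E_new = emit / gamma_total[:, None]
        E_new /= E_new.sum(axis=1, keepdims=True)
        current = replace(current, T=T_new, E=E_new)
    if floor_emissions:
        E = np.maximum(current.E, current.epsilon)
        current = replace(current, E=E / E.sum(axis=1, keepdims=True))
    return BaumWelchResult(hmm=current, log_likelihoods=np.asarray(lls), converged=converged)


def viterbi_decode(hmm: PhaseHMM, symbols: Sequence[int]) -> np.ndarray:
    """Most probable state path, returned as 1-based phase labels.

    Log-space dynamic program.  Under the left-to-right structure the result
    is always monotone nondecreasing with unit steps.
    """
    obs = np.asarray(symbols, dtype=int)
    if obs.min() < 0 or obs.max() >= hmm.A:
        raise ValueError("symbol outside alphabet")
    with np.errstate(divide="ignore"):
        logT = np.log(hmm.T)
        logE = np.log(hmm.E)
        logpi = np.log(hmm.pi)
    n = len(obs)
    delta = logpi + logE[:, obs[0]]
    back = np.zeros((n, hmm.Q), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + logT
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logE[:, obs[t]]
    if not np.isfinite(delta.max()):
        raise ValueError("observation sequence has zero probability under the model")
    states = np.zeros(n, dtype=int)
    states[-1] = int(delta.argmax())
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states + 1


def forward_argmax(hmm: PhaseHMM, symbols: Sequence[int]) -> np.ndarray:
    """Per-second argmax of the forward filtering distribution (1-based).

    Alternative decoder; it maximizes each second marginally given the past,
    so unlike Viterbi the label sequence is not guaranteed monotone — the
    filtered marginal can momentarily favour an earlier state.
    """
    obs = np.asarray(symbols, dtype=int)
    alpha = hmm.pi * hmm.E[:, obs[0]]
    alpha /= alpha.sum()
    out = np.zeros(len(obs), dtype=int)
    out[0] = int(alpha.argmax())
    for t in range(1, len(obs)):
        alpha = (alpha @ hmm.T) * hmm.E[:, obs[t]]
        s = alpha.sum()
        if s == 0:
            raise ValueError("observation sequence has zero probability under the model")
        alpha /= s
        out[t] = int(alpha.argmax())
    return out + 1


def sample_sequence(hmm: PhaseHMM, length: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample (symbols, 1-based state labels) of a given length."""
    states = np.zeros(length, dtype=int)
    symbols = np.zeros(length, dtype=int)
    q = rng.choice(hmm.Q, p=hmm.pi)
    for t in range(length):
        states[t] = q
        symbols[t] = rng.choice(hmm.A, p=hmm.E[q])
        q = rng.choice(hmm.Q, p=hmm.T[q])
    return symbols, states + 1


def annotation_from_labels(labels: Sequence[int], workflow_id: str = "wf") -> PhaseAnnotation:
    """Build an annotation from a monotone per-second label sequence."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    boundaries = np.nonzero(np.diff(labels))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(labels)]])
    segments = [
        (int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)
    ]
    return PhaseAnnotation(workflow_id=workflow_id, segments=segments)


def save_annotations(annotations: Sequence[PhaseAnnotation], path: str | Path) -> None:
    """CSV with columns workflow_id, phase_index, start_second, length_seconds."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["workflow_id", "phase_index", "start_second", "length_seconds"])
        for ann in annotations:
            for phase, start, length in ann.segments:
                writer.writerow([ann.workflow_id, phase, start, length])


def load_annotations(path: str | Path) -> list[PhaseAnnotation]:
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            rows.setdefault(row["workflow_id"], []).append(
                (int(row["phase_index"]), int(row["start_second"]), int(row["length_seconds"]))
            )
    return [
        PhaseAnnotation(workflow_id=wid, segments=sorted(segs, key=lambda s: s[0]))
        for wid, segs in rows.items()
    ]


def save_hmm(hmm: PhaseHMM, path: str | Path) -> None:
    np.savez(Path(path), Q=hmm.Q, A=hmm.A, T=hmm.T, pi=hmm.pi, E=hmm.E, epsilon=hmm.epsilon)


def load_hmm(path: str | Path) -> PhaseHMM:
    data = np.load(Path(path))
    return PhaseHMM(Q=int(data["Q"]), A=int(data["A"]), T=data["T"],
                    pi=data["pi"], E=data["E"], epsilon=float(data["epsilon"]))
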