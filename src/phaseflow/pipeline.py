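"""End-to-end orchestration: extraction, training, segmentation, evaluation.

A *workflow* is one recording session seen by all synchronized cameras plus
its ground-truth phase annotation; it is the unit of leave-one-out
cross-validation.  A :class:`PipelineConfig` names one of the eight method
combinations (foreground detector x flow extraction x normalizer) and carries
every tunable of the stack.  Training on a set of workflows fits, in order,
the LDA topic model, the optional k-means codebook, and the supervised-init +
Baum-Welch phase HMM; segmentation featurizes a held-out workflow with those
fitted models and Viterbi-decodes its per-second phase labels.

The evaluation metric is per-phase time accuracy: for each *true* phase, the
fraction of its annotated seconds that were labeled correctly; a workflow's
accuracy is the unweighted mean over its phases, and a method's accuracy is
the mean over held-out workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from . import feature_norm, motion_words, phase_hmm, topic_model
from .imaging import FrameDiffDetector, ForegroundMask, FrameSequence, gaussian_blur
from .motion_words import ClipDocument, GridSpec

logger = logging.getLogger("phaseflow")

__all__ = [
    "PipelineConfig",
    "Workflow",
    "TrainedModels",
    "EvalReport",
    "PRESETS",
    "extract_documents",
    "train_models",
    "segment_workflow",
    "run_pipeline",
    "loocv",
    "phase_accuracy",
    "boundary_deviation",
]

_FOREGROUND = {"framediff", "plugin"}
_EXTRACTION = {"gridintersect", "gridblock"}
_NORMALIZER = {"top", "kmeans"}

_NAME_PARTS = {
    "framediff": "FrameDiff",
    "gridintersect": "GridIntersect",
    "gridblock": "GridBlock",
    "top": "Top",
    "kmeans": "Kmeans",
    "plugin": "Plugin",
}


@dataclass
class PipelineConfig:
    """All tunables of one method combination.

    Defaults follow the reference operating-room setup: 7x7 blur, 64x48 grid,
    flow magnitude band [2, 20] px, minimum block count 5, LDA priors
    alpha = 50/K and beta = 0.1, HMM smoothing epsilon = 1e-4.
    """

    foreground: str = "framediff"
    extraction: str = "gridblock"
    normalizer: str = "kmeans"
    K: int = 20
    c: int = 230
    grid: GridSpec = field(default_factory=GridSpec)
    blur_kernel: int = 7
    diff_threshold: float = 15.0
    morph_cleanup: bool = False
    o_min: float = 2.0
    o_max: float = 20.0
    o_count: int = 5
    epsilon: float = 1e-4
    lda_iterations: int = 100
    bw_tol: float = 1e-4
    bw_max_iter: int = 100
    decoder: str = "viterbi"
    seed: int = 0
    foreground_plugin: Callable | None = None

    def __post_init__(self) -> None:
        if self.foreground not in _FOREGROUND:
            raise ValueError(f"unknown foreground method {self.foreground!r}")
        if self.extraction not in _EXTRACTION:
            raise ValueError(f"unknown extraction method {self.extraction!r}")
        if self.normalizer not in _NORMALIZER:
            raise ValueError(f"unknown normalizer {self.normalizer!r}")
        if self.decoder not in {"viterbi", "forward"}:
            raise ValueError(f"unknown decoder {self.decoder!r}")
        if self.foreground == "plugin" and self.foreground_plugin is None:
            raise ValueError("foreground='plugin' requires foreground_plugin")

    @property
    def name(self) -> str:
        """Combination name, e.g. ``FrameDiff_GridBlock_Kmeans``."""
        return "_".join(_NAME_PARTS[p] for p in (self.foreground, self.extraction, self.normalizer))

    @classmethod
    def from_name(cls, name: str, **overrides) -> "PipelineConfig":
        inverse = {v: k for k, v in _NAME_PARTS.items()}
        try:
            fg, ex, nm = (inverse[p] for p in name.split("_"))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"unrecognized combination name {name!r}") from exc
        return cls(foreground=fg, extraction=ex, normalizer=nm, **overrides)

    def to_dict(self) -> dict:
        d = {
            "foreground": self.foreground, "extraction": self.extraction,
            "normalizer": self.normalizer, "K": self.K, "c": self.c,
            "grid": [self.grid.cells_x, self.grid.cells_y],
            "blur_kernel": self.blur_kernel, "diff_threshold": self.diff_threshold,
            "morph_cleanup": self.morph_cleanup,
            "o_min": self.o_min, "o_max": self.o_max, "o_count": self.o_count,
            "epsilon": self.epsilon, "lda_iterations": self.lda_iterations,
            "bw_tol": self.bw_tol, "bw_max_iter": self.bw_max_iter,
            "decoder": self.decoder, "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid" in d:
            d["grid"] = GridSpec(*d["grid"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Named presets; the reference best setting is FrameDiff_GridBlock_Kmeans
#: with K=20 topics and c=230 clusters.
PRESETS: dict[str, PipelineConfig] = {
    "FrameDiff_GridBlock_Kmeans": PipelineConfig(
        foreground="framediff", extraction="gridblock", normalizer="kmeans", K=20, c=230),
    "FrameDiff_GridBlock_Top": PipelineConfig(
        foreground="framediff", extraction="gridblock", normalizer="top", K=80),
    "FrameDiff_GridIntersect_Kmeans": PipelineConfig(
        foreground="framediff", extraction="gridintersect", normalizer="kmeans", K=20, c=260),
    "FrameDiff_GridIntersect_Top": PipelineConfig(
        foreground="framediff", extraction="gridintersect", normalizer="top", K=100),
}


@dataclass
class Workflow:
    """One recording session: synchronized camera sequences plus truth."""

    workflow_id: str
    sequences: list[FrameSequence]
    annotation: phase_hmm.PhaseAnnotation

    def __post_init__(self) -> None:
        counts = {s.n_frames for s in self.sequences}
        if len(counts) > 1:
            raise ValueError("camera sequences are not synchronized")

    @property
    def cameras(self) -> int:
        return len(self.sequences)

    @property
    def fps(self) -> int:
        return self.sequences[0].fps


def extract_documents(
    sequences: Sequence[FrameSequence], config: PipelineConfig
) -> list[ClipDocument]:
    """Run foreground detection, flow extraction and quantization.

    Frames are Gaussian-smoothed once; the foreground mask and the flow field
    are both computed from the smoothed pair.  Words from all cameras pool
    into one document per whole second.
    """
    cameras = len(sequences)
    fps = sequences[0].fps
    n_frames = sequences[0].n_frames
    if config.foreground == "plugin":
        detector = config.foreground_plugin
    else:
        detector = FrameDiffDetector(config.diff_threshold, config.morph_cleanup)

    words: list[tuple[int, int]] = []
    for seq in sequences:
        prev_blur = gaussian_blur(seq.frames[0], config.blur_kernel)
        for f in range(1, seq.n_frames):
            curr_blur = gaussian_blur(seq.frames[f], config.blur_kernel)
            mask = detector(prev_blur, curr_blur)
            if isinstance(mask, np.ndarray):
                mask = ForegroundMask(mask)
            flow = motion_words.dense_flow(prev_blur, curr_blur) if mask.n_foreground else None
            if flow is not None:
                if config.extraction == "gridintersect":
                    ws = motion_words.grid_intersect_words(
                        prev_blur, curr_blur, mask, config.grid, seq.camera_id,
                        config.o_min, config.o_max, _flow=flow)
                else:
                    ws = motion_words.grid_block_words(
                        prev_blur, curr_blur, mask, config.grid, seq.camera_id,
                        config.o_min, config.o_max, config.o_count, _flow=flow)
                words.extend((f - 1, w.word_id(config.grid)) for w in ws)
            prev_blur = curr_blur
    docs = motion_words.build_documents(words, fps, n_frames, config.grid, cameras)
    n_empty = sum(d.is_empty for d in docs)
    logger.info("extracted %d words into %d documents (%d empty)", len(words), len(docs), n_empty)
    return docs


@dataclass
class TrainedModels:
    """Everything fitted on the training workflows."""

    config: PipelineConfig
    lda: topic_model.LDAModel
    codebook: feature_norm.KMeansCodebook | None
    hmm: phase_hmm.PhaseHMM
    baum_welch_log_likelihoods: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def alphabet_size(self) -> int:
        return self.hmm.A


def _symbols(thetas, config: PipelineConfig, codebook) -> np.ndarray:
    syms = feature_norm.symbols_from_thetas(thetas, config.normalizer, codebook)
    return np.asarray([s.symbol for s in syms], dtype=int)


def train_models(
    train_docs: Sequence[Sequence[ClipDocument]],
    train_annotations: Sequence[phase_hmm.PhaseAnnotation],
    config: PipelineConfig,
    refine: bool = True,
) -> TrainedModels:
    """Fit LDA, the normalizer codebook and the phase HMM on training data.

    ``train_docs`` holds one document list per training workflow.  The LDA
    corpus is the concatenation over workflows; training thetas are obtained
    by folding every workflow in with the fitted topics (the same operation
    applied to test workflows, so train and test features are exchangeable).
    """
    corpus = np.concatenate([motion_words.documents_to_matrix(d) for d in train_docs])
    lda, _ = topic_model.fit_lda(
        corpus, K=config.K, beta=0.1, iterations=config.lda_iterations, seed=config.seed)

    per_wf_thetas = [
        topic_model.transform_corpus(lda, motion_words.documents_to_matrix(d))
        for d in train_docs
    ]
    codebook = None
    if config.normalizer == "kmeans":
        all_thetas = [t for wf in per_wf_thetas for t in wf]
        codebook = feature_norm.kmeans_fit(all_thetas, c=config.c, seed=config.seed)
    alphabet = config.c if config.normalizer == "kmeans" else config.K

    symbol_seqs = [_symbols(th, config, codebook) for th in per_wf_thetas]
    # align to whole annotated seconds (documents already drop the partial tail)
    clipped = []
    for ann, syms in zip(train_annotations, symbol_seqs):
        n = min(len(syms), ann.total_seconds)
        clipped.append(syms[:n])
    anns = [
        ann if len(s) == ann.total_seconds else _clip_annotation(ann, len(s))
        for ann, s in zip(train_annotations, clipped)
    ]
    Q = max(a.n_phases for a in anns)
    hmm = phase_hmm.fit_supervised(anns, clipped, Q=Q, A=alphabet, epsilon=config.epsilon)
    ll = np.asarray([])
    if refine:
        result = phase_hmm.baum_welch(
            hmm, clipped, tol=config.bw_tol, max_iter=config.bw_max_iter)
        hmm, ll = result.hmm, result.log_likelihoods
        logger.info("Baum-Welch: %d iterations, log-likelihood %.2f -> %.2f",
                    result.n_iter, ll[0], ll[-1])
    return TrainedModels(config=config, lda=lda, codebook=codebook, hmm=hmm,
                         baum_welch_log_likelihoods=ll)


def _clip_annotation(ann: phase_hmm.PhaseAnnotation, n_seconds: int) -> phase_hmm.PhaseAnnotation:
    """Trim an annotation to the first n_seconds (drops the partial tail)."""
    segments, used = [], 0
    for phase, start, length in ann.segments:
        if used >= n_seconds:
            break
        take = min(length, n_seconds - used)
        segments.append((phase, start, take))
        used += take
    return phase_hmm.PhaseAnnotation(workflow_id=ann.workflow_id, segments=segments)


def segment_workflow(
    models: TrainedModels, docs: Sequence[ClipDocument]
) -> np.ndarray:
    """Decode per-second phase labels for one workflow's documents."""
    config = models.config
    thetas = topic_model.transform_corpus(models.lda, motion_words.documents_to_matrix(docs))
    symbols = _symbols(thetas, config, models.codebook)
    decode = phase_hmm.viterbi_decode if config.decoder == "viterbi" else phase_hmm.forward_argmax
    return decode(models.hmm, symbols)


def phase_accuracy(
    predicted: Sequence[int], truth: phase_hmm.PhaseAnnotation
) -> tuple[np.ndarray, float]:
    """Per-true-phase correct-time ratios and their unweighted mean.

    For each true phase, ratio = (seconds inside its true span labeled with
    that phase) / (its true length).  Misses count against the true phase
    only; a phase the decoder never produces scores 0.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth_labels = truth.to_labels()
    if len(predicted) != len(truth_labels):
        raise ValueError(
            f"prediction covers {len(predicted)} s but truth covers {len(truth_labels)} s")
    ratios = np.zeros(truth.n_phases)
    pos = 0
    for i, (phase, _, length) in enumerate(truth.segments):
        span = predicted[pos:pos + length]
        ratios[i] = float((span == phase).sum()) / length
        pos += length
    return ratios, float(ratios.mean())


def boundary_deviation(
    predicted: Sequence[int], truth: phase_hmm.PhaseAnnotation
) -> np.ndarray:
    """|predicted start - true start| per phase, in seconds.

    A phase absent from the prediction gets NaN (undetected).
    """
    predicted = np.asarray(predicted, dtype=int)
    true_starts = truth.phase_starts()
    out = np.full(truth.n_phases, np.nan)
    for i, (phase, _, _) in enumerate(truth.segments):
        hits = np.nonzero(predicted == phase)[0]
        if len(hits):
            out[i] = abs(int(hits[0]) - int(true_starts[i]))
    return out


@dataclass
class EvalReport:
    """Cross-validation outcome over held-out workflows."""

    method: str
    workflow_ids: list[str]
    per_phase_accuracy: list[np.ndarray]
    workflow_accuracies: np.ndarray
    per_phase_deviation: list[np.ndarray]
    decoded_labels: list[np.ndarray] | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.workflow_accuracies))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean_accuracy": self.mean_accuracy,
            "workflows": [
                {
                    "workflow_id": wid,
                    "accuracy": float(acc),
                    "per_phase_accuracy": [float(x) for x in pp],
                    "boundary_deviation_seconds": [
                        None if np.isnan(x) else float(x) for x in dev
                    ],
                }
                for wid, acc, pp, dev in zip(
                    self.workflow_ids, self.workflow_accuracies,
                    self.per_phase_accuracy, self.per_phase_deviation)
            ],
        }


def run_pipeline(
    train_workflows: Sequence[Workflow],
    test_workflow: Workflow,
    config: PipelineConfig,
    _train_docs: Sequence[Sequence[ClipDocument]] | None = None,
    _test_docs: Sequence[ClipDocument] | None = None,
) -> tuple[np.ndarray, EvalReport]:
    """Train on some workflows, segment and score one held-out workflow."""
    train_docs = (
        _train_docs if _train_docs is not None
        else [extract_documents(w.sequences, config) for w in train_workflows]
    )
    test_docs = (
        _test_docs if _test_docs is not None
        else extract_documents(test_workflow.sequences, config)
    )
    models = train_models(train_docs, [w.annotation for w in train_workflows], config)
    labels = segment_workflow(models, test_docs)
    truth = test_workflow.annotation
    if len(labels) != truth.total_seconds:
        truth = _clip_annotation(truth, len(labels))
    ratios, acc = phase_accuracy(labels, truth)
    dev = boundary_deviation(labels, truth)
    report = EvalReport(
        method=config.name,
        workflow_ids=[test_workflow.workflow_id],
        per_phase_accuracy=[ratios],
        workflow_accuracies=np.asarray([acc]),
        per_phase_deviation=[dev],
    )
    return labels, report


def loocv(workflows: Sequence[Workflow], config: PipelineConfig) -> EvalReport:
    """Leave-one-out cross-validation over workflows.

    Documents are extracted once per workflow and shared across folds; all
    model fitting (LDA, codebook, HMM) is redone per fold on the training
    side only, so no fold ever sees its held-out workflow's documents.
    """
    if len(workflows) < 2:
        raise ValueError("leave-one-out needs at least two workflows")
    docs = [extract_documents(w.sequences, config) for w in workflows]
    ids, accs, per_phase, devs, decoded = [], [], [], [], []
    for held in range(len(workflows)):
        train_idx = [i for i in range(len(workflows)) if i != held]
        labels, rep = run_pipeline(
            [workflows[i] for i in train_idx], workflows[held], config,
            _train_docs=[docs[i] for i in train_idx], _test_docs=docs[held])
        ids.append(workflows[held].workflow_id)
        accs.append(rep.workflow_accuracies[0])
        per_phase.append(rep.per_phase_accuracy[0])
        devs.append(rep.per_phase_deviation[0])
        decoded.append(labels)
        logger.info("fold %s: accuracy %.3f", workflows[held].workflow_id, accs[-1])
    return EvalReport(
        method=config.name, workflow_ids=ids, per_phase_accuracy=per_phase,
        workflow_accuracies=np.asarray(accs), per_phase_deviation=devs,
        decoded_labels=decoded)
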