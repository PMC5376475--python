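"""Synthetic phase-scripted recordings and symbol streams with known truth.

No public recordings of the multi-camera operating-room setup exist, so every
stage of the pipeline is exercised on synthetic data built here:

* **video mode** — each phase of a scripted workflow renders a textured blob
  drifting in a phase-specific direction inside a phase-specific region of
  each camera's view, over a noisy static background.  This emulates the one
  property the pipeline actually feeds on: phases differ in where and in
  which direction things move.  What it does *not* emulate: articulated
  humans, lighting changes, occlusions, camera shake.
* **symbol mode** — observation/label sequences sampled directly from a known
  left-to-right HMM, for testing the estimator stack in isolation.

The blob carries a fixed random blocky texture so Lucas-Kanade tracking has
gradients to hold on to; a flat blob would defeat optical flow entirely.
Blobs wrap around inside their region; the single wrap frame produces one
oversized displacement that the magnitude filter then discards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imaging import FrameSequence
from .phase_hmm import PhaseAnnotation, PhaseHMM, initial_distribution, sample_sequence

__all__ = [
    "CameraMotion",
    "PhaseSpec",
    "PhaseScript",
    "default_script",
    "make_dataset",
    "generate_phase_videos",
    "make_left_to_right_hmm",
    "generate_symbol_sequences",
]

_STEPS = {"up": (0, -1), "down": (0, 1), "left": (-1, 0), "right": (1, 0)}


@dataclass(frozen=True)
class CameraMotion:
    """Motion of one phase in one camera view.

    ``region`` is (x0, y0, x1, y1) in fractions of the frame; the blob drifts
    at ``speed`` px/frame along ``direction`` within it, wrapping around.
    """

    direction: str
    speed: float = 3.0
    region: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.direction not in _STEPS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.speed <= 0:
            raise ValueError("speed must be positive")


@dataclass(frozen=True)
class PhaseSpec:
    phase_index: int
    duration_seconds: int
    motions: tuple[CameraMotion, ...]  # one per camera

    def __post_init__(self) -> None:
        if self.duration_seconds < 1:
            raise ValueError("phase durations must be positive")


@dataclass
class PhaseScript:
    """Full specification of one synthetic workflow recording."""

    phases: list[PhaseSpec]
    cameras: int = 2
    fps: int = 5
    frame_size: tuple[int, int] = (120, 160)  # (height, width)
    noise_sigma: float = 2.0
    blob_size: int = 40
    seed: int = 0
    workflow_id: str = "wf0"

    def __post_init__(self) -> None:
        for i, p in enumerate(self.phases, start=1):
            if p.phase_index != i:
                raise ValueError("phase indices must run 1..Q in order")
            if len(p.motions) != self.cameras:
                raise ValueError("each phase needs one motion spec per camera")

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def total_seconds(self) -> int:
        return sum(p.duration_seconds for p in self.phases)

    @property
    def n_frames(self) -> int:
        """Frames per camera: total scripted seconds times frame rate."""
        return self.total_seconds * self.fps

    def annotation(self) -> PhaseAnnotation:
        segments, start = [], 0
        for p in self.phases:
            segments.append((p.phase_index, start, p.duration_seconds))
            start += p.duration_seconds
        return PhaseAnnotation(workflow_id=self.workflow_id, segments=segments)


#: Region layout cycled over phases: four quadrants plus center.
_REGIONS = [
    (0.05, 0.05, 0.5, 0.5),
    (0.5, 0.05, 0.95, 0.5),
    (0.05, 0.5, 0.5, 0.95),
    (0.5, 0.5, 0.95, 0.95),
    (0.25, 0.25, 0.75, 0.75),
]
_DIR_CYCLE = ("right", "down", "left", "up")


def default_script(
    n_phases: int = 12,
    cameras: int = 2,
    duration_range: tuple[int, int] = (6, 10),
    fps: int = 5,
    frame_size: tuple[int, int] = (120, 160),
    noise_sigma: float = 2.0,
    speed: float = 3.0,
    seed: int = 0,
    workflow_id: str = "wf0",
) -> PhaseScript:
    """A workflow script whose phases have distinct (region, direction) motion.

    Phase p moves in direction ``p mod 4`` inside region ``p mod 5``; the
    combination is unique for up to 20 phases.  Camera k >= 1 sees the
    direction cycle rotated by k, emulating viewpoints that disagree on
    apparent motion direction.  Durations are drawn per phase from
    ``duration_range`` (inclusive) with the script's own seed.
    """
    rng = np.random.default_rng(seed)
    phases = []
    for p in range(n_phases):
        motions = tuple(
            CameraMotion(
                direction=_DIR_CYCLE[(p + cam) % 4],
                speed=speed,
                region=_REGIONS[p % len(_REGIONS)],
            )
            for cam in range(cameras)
        )
        duration = int(rng.integers(duration_range[0], duration_range[1] + 1))
        phases.append(PhaseSpec(phase_index=p + 1, duration_seconds=duration, motions=motions))
    return PhaseScript(phases=phases, cameras=cameras, fps=fps, frame_size=frame_size,
                       noise_sigma=noise_sigma, seed=seed, workflow_id=workflow_id)


def make_dataset(
    participants: int = 7,
    recordings_per_participant: int = 4,
    cameras: int = 3,
    n_phases: int = 12,
    seed: int = 0,
    **script_kwargs,
) -> list[PhaseScript]:
    """Factory mirroring the recorded-study design: participants x recordings.

    Returns one script per workflow (participant/recording pair); each script
    renders ``cameras`` synchronized streams, so the default 7 x 4 x 3 design
    yields 28 workflows and 84 video streams.  Scripts differ in seed (and
    hence phase durations, textures and noise) but share the phase structure.
    """
    scripts = []
    for p in range(participants):
        for r in range(recordings_per_participant):
            idx = p * recordings_per_participant + r
            scripts.append(
                default_script(
                    n_phases=n_phases,
                    cameras=cameras,
                    seed=seed + idx,
                    workflow_id=f"p{p}r{r}",
                    **script_kwargs,
                )
            )
    return scripts


def _blob_texture(rng: np.random.Generator, size: int) -> np.ndarray:
    """Blocky random checkerboard patch with strong gradients."""
    cells = max(size // 5, 2)
    patch = rng.integers(0, 2, size=(cells, cells)).astype(float)
    tex = np.kron(patch, np.ones((5, 5)))[:size, :size]
    return 40.0 + 180.0 * tex


def generate_phase_videos(script: PhaseScript) -> tuple[list[FrameSequence], PhaseAnnotation]:
    """Render the scripted workflow into per-camera frame sequences.

    Deterministic given the script's seed.  Emits a warning-level check: blob
    speeds outside the (2, 20) px magnitude band mean the flow filter will
    discard most words.
    """
    import warnings

    for p in script.phases:
        for m in p.motions:
            if not (2.0 < m.speed < 20.0):
                warnings.warn(
                    f"phase {p.phase_index}: speed {m.speed} px/frame is outside the "
                    "(2, 20) magnitude band; its motion words may vanish",
                    stacklevel=2,
                )
    rng = np.random.default_rng(script.seed)
    h, w = script.frame_size
    bs = script.blob_size
    background = rng.uniform(100, 156, size=(h, w))
    textures = [_blob_texture(rng, bs) for _ in range(script.cameras)]

    frames = np.zeros((script.cameras, script.n_frames, h, w), dtype=np.uint8)
    offsets = np.zeros(script.cameras)  # per-camera travel along current direction
    f = 0
    for phase in script.phases:
        offsets[:] = 0.0
        for _ in range(phase.duration_seconds * script.fps):
            for cam in range(script.cameras):
                motion = phase.motions[cam]
                x0, y0, x1, y1 = motion.region
                rx0, ry0 = int(x0 * w), int(y0 * h)
                rx1, ry1 = int(x1 * w), int(y1 * h)
                # clamp the blob to 60% of the region span so it always has
                # room to travel, however small the frame
                bs_x = max(min(bs, int(0.6 * (rx1 - rx0))), 5)
                bs_y = max(min(bs, int(0.6 * (ry1 - ry0))), 5)
                span_x = max(rx1 - rx0 - bs_x, 1)
                span_y = max(ry1 - ry0 - bs_y, 1)
                sx, sy = _STEPS[motion.direction]
                travel = offsets[cam]
                bx = rx0 + (int(sx * travel) % span_x if sx else (span_x // 2))
                by = ry0 + (int(sy * travel) % span_y if sy else (span_y // 2))
                canvas = background.copy()
                canvas[by:by + bs_y, bx:bx + bs_x] = textures[cam][:bs_y, :bs_x]
                if script.noise_sigma > 0:
                    canvas = canvas + rng.normal(0, script.noise_sigma, size=(h, w))
                frames[cam, f] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
                offsets[cam] += motion.speed
            f += 1
    sequences = [
        FrameSequence(camera_id=cam, frames=frames[cam], fps=script.fps)
        for cam in range(script.cameras)
    ]
    return sequences, script.annotation()


def make_left_to_right_hmm(
    Q: int = 12,
    A: int = 20,
    mean_duration: float = 64.0,
    emission_strength: float = 0.6,
    epsilon: float = 1e-4,
    seed: int = 0,
) -> PhaseHMM:
    """A well-separated left-to-right generating model.

    Self-transition probability is ``1 - 1/mean_duration`` (geometric state
    durations with the given mean, in seconds).  Each state's emission row
    puts ``emission_strength`` on its own dominant symbol — distinct across
    states when A >= Q — and spreads the rest by a Dirichlet draw.
    """
    if not 0 < emission_strength < 1:
        raise ValueError("emission_strength must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_stay = 1.0 - 1.0 / mean_duration
    T = np.zeros((Q, Q))
    for q in range(Q - 1):
        T[q, q], T[q, q + 1] = p_stay, 1.0 - p_stay
    T[Q - 1, Q - 1] = 1.0
    dominant = rng.permutation(A)[:Q] if A >= Q else rng.integers(0, A, size=Q)
    E = rng.dirichlet(np.full(A, 0.5), size=Q) * (1.0 - emission_strength)
    E[np.arange(Q), dominant] += emission_strength
    E /= E.sum(axis=1, keepdims=True)
    return PhaseHMM(Q=Q, A=A, T=T, pi=initial_distribution(Q), E=E, epsilon=epsilon)


def generate_symbol_sequences(
    hmm: PhaseHMM,
    n_sequences: int,
    length_range: tuple[int, int],
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Sample (symbol, label) sequence pairs from a left-to-right model."""
    rng = np.random.default_rng(seed)
    symbols, labels = [], []
    for _ in range(n_sequences):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        s, l = sample_sequence(hmm, length, rng)
        symbols.append(s)
        labels.append(l)
    return symbols, labels
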