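"""Optical-flow extraction, 4-direction quantization and per-second documents.

Motion between consecutive smoothed frames is measured with an iterative
Lucas-Kanade optical-flow field and quantized into discrete *motion words*.
A word is the tuple ``(camera, grid cell, direction)`` where direction is one
of up/down/left/right; the vocabulary therefore has ``cameras * cells_x *
cells_y * 4`` entries.  Words from all cameras are pooled into one bag-of-words
*document* per second of video — the unit the topic model operates on.

Two extraction variants are provided:

``grid_intersect_words``
    flow sampled at one grid-line intersection per cell (the cell's top-left
    corner), kept only where the foreground mask is on;

``grid_block_words``
    flow sampled at *every* foreground pixel, pooled per grid block: blocks
    with fewer than ``o_count`` surviving vectors are dropped, the rest emit
    one word from their average flow vector.

Coordinate convention (documented because it decides what "up" means): image
origin is the top-left corner, x grows rightward, y grows *downward*.  "Up"
is therefore negative dy.  Flow magnitudes outside ``[o_min, o_max]`` pixels
(inclusive on both ends) are discarded as noise before any pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk

from .imaging import ForegroundMask

__all__ = [
    "DIRECTIONS",
    "GridSpec",
    "FlowVector",
    "MotionWord",
    "ClipDocument",
    "dense_flow",
    "compute_sparse_flow",
    "filter_by_magnitude",
    "normalize_direction",
    "grid_intersect_words",
    "grid_block_words",
    "vocabulary_size",
    "encode_word_id",
    "decode_word_id",
    "build_documents",
    "save_documents",
    "load_documents",
    "save_vocabulary",
]

#: Direction alphabet; index order is part of the word-id encoding.
DIRECTIONS = ("up", "down", "left", "right")
_DIR_INDEX = {d: i for i, d in enumerate(DIRECTIONS)}


@dataclass(frozen=True)
class GridSpec:
    """Grid of equal cells laid over a frame (e.g. 64 x 48 on 640 x 480)."""

    cells_x: int = 64
    cells_y: int = 48

    def __post_init__(self) -> None:
        if self.cells_x < 1 or self.cells_y < 1:
            raise ValueError("grid must have at least one cell per axis")

    def cell_size(self, frame_shape: tuple[int, int]) -> tuple[int, int]:
        """(cell_width, cell_height) in pixels; frame must divide evenly."""
        h, w = frame_shape
        if w % self.cells_x or h % self.cells_y:
            raise ValueError(
                f"frame {w}x{h} not divisible by grid {self.cells_x}x{self.cells_y}"
            )
        return w // self.cells_x, h // self.cells_y

    @property
    def n_cells(self) -> int:
        return self.cells_x * self.cells_y


@dataclass(frozen=True)
class FlowVector:
    """One optical-flow vector: origin pixel and displacement in pixels."""

    x: float
    y: float
    dx: float
    dy: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))


@dataclass(frozen=True)
class MotionWord:
    """A quantized flow token: camera, grid cell and one of four directions."""

    camera: int
    gx: int
    gy: int
    direction: str

    def word_id(self, grid: GridSpec) -> int:
        return encode_word_id(self.camera, self.gx, self.gy, self.direction, grid)


@dataclass
class ClipDocument:
    """Word-count vector for one one-second clip, pooled over all cameras."""

    second_index: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("word counts must be nonnegative")

    @property
    def total_words(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total_words == 0


def encode_word_id(camera: int, gx: int, gy: int, direction: str | int, grid: GridSpec) -> int:
    """Bijective word id: ((camera*cells_x + gx)*cells_y + gy)*4 + direction."""
    d = direction if isinstance(direction, int) else _DIR_INDEX[direction]
    if not (0 <= gx < grid.cells_x and 0 <= gy < grid.cells_y and 0 <= d < 4):
        raise ValueError("cell or direction index out of range")
    return ((camera * grid.cells_x + gx) * grid.cells_y + gy) * 4 + d


def decode_word_id(word_id: int, grid: GridSpec) -> tuple[int, int, int, str]:
    """Inverse of :func:`encode_word_id` -> (camera, gx, gy, direction)."""
    word_id, d = divmod(word_id, 4)
    word_id, gy = divmod(word_id, grid.cells_y)
    camera, gx = divmod(word_id, grid.cells_x)
    return camera, gx, gy, DIRECTIONS[d]


def vocabulary_size(cameras: int, grid: GridSpec) -> int:
    """Vocabulary size = cameras * cells_x * cells_y * 4 directions.

    With 2 cameras and a 10 x 10 grid this is 2 * 10 * 10 * 4 = 800.
    """
    if cameras < 1:
        raise ValueError("need at least one camera")
    return cameras * grid.n_cells * 4


def dense_flow(
    prev: np.ndarray, curr: np.ndarray, radius: int = 7, num_warp: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Dense iterative Lucas-Kanade flow between two grayscale frames.

    Returns ``(dx, dy)`` arrays in pixels, image-coordinate convention
    (positive dx rightward, positive dy downward).  Five warp iterations
    resolve the displacement magnitudes the word filter accepts (2-20 px)
    to well under half a pixel.
    """
    prev = np.asarray(prev, dtype=np.float32)
    curr = np.asarray(curr, dtype=np.float32)
    if prev.shape != curr.shape:
        raise ValueError("frame shapes differ")
    v, u = optical_flow_ilk(prev, curr, radius=radius, num_warp=num_warp)
    return u, v


def compute_sparse_flow(
    prev: np.ndarray,
    curr: np.ndarray,
    points: Sequence[tuple[int, int]] | np.ndarray,
    radius: int = 7,
) -> list[FlowVector]:
    """Flow vectors at the given ``(x, y)`` pixel locations.

    Points on textureless regions come back with (near-)zero displacement;
    downstream magnitude filtering removes them, so no explicit "untracked"
    state is needed.
    """
    points = np.asarray(points, dtype=int)
    if points.size == 0:
        return []
    h, w = np.asarray(prev).shape
    if (points[:, 0] < 0).any() or (points[:, 0] >= w).any() or (points[:, 1] < 0).any() or (points[:, 1] >= h).any():
        raise ValueError("points must lie inside the image")
    u, v = dense_flow(prev, curr, radius=radius)
    xs, ys = points[:, 0], points[:, 1]
    return [
        FlowVector(x=float(x), y=float(y), dx=float(u[y, x]), dy=float(v[y, x]))
        for x, y in zip(xs, ys)
    ]


def filter_by_magnitude(
    flows: Iterable[FlowVector], o_min: float = 2.0, o_max: float = 20.0
) -> list[FlowVector]:
    """Keep flows with ``o_min <= |v| <= o_max`` (both bounds inclusive)."""
    if o_min > o_max:
        raise ValueError("o_min must not exceed o_max")
    return [f for f in flows if o_min <= f.magnitude <= o_max]


def normalize_direction(dx: float, dy: float) -> str:
    """Quantize a displacement into up/down/left/right.

    Ties (|dx| == |dy|) resolve to the vertical axis so quantization is
    deterministic.  Image coordinates: "up" is negative dy.
    """
    if dx == 0 and dy == 0:
        raise ValueError("zero vector has no direction")
    if abs(dx) > abs(dy):
        return "right" if dx > 0 else "left"
    return "up" if dy < 0 else "down"


def _mask_array(mask: ForegroundMask | np.ndarray) -> np.ndarray:
    return mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)


def grid_intersect_words(
    prev: np.ndarray,
    curr: np.ndarray,
    mask: ForegroundMask | np.ndarray,
    grid: GridSpec,
    camera: int,
    o_min: float = 2.0,
    o_max: float = 20.0,
    _flow: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[MotionWord]:
    """Motion words from flow at one grid intersection per cell.

    The representative intersection of cell ``(gx, gy)`` is its top-left
    corner ``(gx*cell_w, gy*cell_h)`` — all grid-line crossings except the
    right and bottom frame borders, giving exactly one candidate point per
    cell.  Points outside the foreground mask are ignored; survivors of the
    magnitude filter each emit one word.
    """
    h, w = np.asarray(prev).shape
    cw, ch = grid.cell_size((h, w))
    m = _mask_array(mask)
    u, v = _flow if _flow is not None else dense_flow(prev, curr)

    ys = np.arange(grid.cells_y) * ch
    xs = np.arange(grid.cells_x) * cw
    sub_m = m[np.ix_(ys, xs)]
    gys, gxs = np.nonzero(sub_m)
    words: list[MotionWord] = []
    for gy, gx in zip(gys, gxs):
        dx = float(u[ys[gy], xs[gx]])
        dy = float(v[ys[gy], xs[gx]])
        mag = float(np.hypot(dx, dy))
        if o_min <= mag <= o_max:
            words.append(MotionWord(camera=camera, gx=int(gx), gy=int(gy),
                                    direction=normalize_direction(dx, dy)))
    return words


def grid_block_words(
    prev: np.ndarray,
    curr: np.ndarray,
    mask: ForegroundMask | np.ndarray,
    grid: GridSpec,
    camera: int,
    o_min: float = 2.0,
    o_max: float = 20.0,
    o_count: int = 5,
    _flow: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[MotionWord]:
    """Motion words from block-averaged flow at all foreground pixels.

    Per block: flows at every foreground pixel are magnitude-filtered, blocks
    with fewer than ``o_count`` survivors are dropped, and each remaining
    block emits one word from the direction of its average flow vector.
    """
    h, w = np.asarray(prev).shape
    cw, ch = grid.cell_size((h, w))
    m = _mask_array(mask)
    if not m.any():
        return []
    u, v = _flow if _flow is not None else dense_flow(prev, curr)

    ys, xs = np.nonzero(m)
    du, dv = u[ys, xs], v[ys, xs]
    mag = np.hypot(du, dv)
    keep = (mag >= o_min) & (mag <= o_max)
    if not keep.any():
        return []
    ys, xs, du, dv = ys[keep], xs[keep], du[keep], dv[keep]

    block = (xs // cw) * grid.cells_y + (ys // ch)
    n_blocks = grid.n_cells
    counts = np.bincount(block, minlength=n_blocks)
    sum_u = np.bincount(block, weights=du, minlength=n_blocks)
    sum_v = np.bincount(block, weights=dv, minlength=n_blocks)

    words: list[MotionWord] = []
    for b in np.nonzero(counts >= o_count)[0]:
        adx, ady = sum_u[b] / counts[b], sum_v[b] / counts[b]
        if adx == 0 and ady == 0:
            continue  # opposing flows cancelled exactly; no direction
        gx, gy = divmod(int(b), grid.cells_y)
        words.append(MotionWord(camera=camera, gx=gx, gy=gy,
                                direction=normalize_direction(float(adx), float(ady))))
    return words


def build_documents(
    words: Iterable[tuple[int, MotionWord | int]],
    fps: int,
    n_frames: int,
    grid: GridSpec,
    cameras: int,
) -> list[ClipDocument]:
    """Group a time-stamped word stream into one document per whole second.

    ``words`` yields ``(frame_index, word)`` pairs where the frame index is
    the *earlier* frame of the pair the flow was computed from; the pair
    straddling a second boundary is attributed to the earlier second.  The
    trailing partial second is dropped.  Seconds with no words yield all-zero
    documents so the timeline stays aligned with the annotations.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    n_seconds = n_frames // fps
    V = vocabulary_size(cameras, grid)
    counts = np.zeros((n_seconds, V), dtype=np.int64)
    for frame_index, word in words:
        sec = frame_index // fps
        if sec >= n_seconds:
            continue
        wid = word if isinstance(word, (int, np.integer)) else word.word_id(grid)
        if not 0 <= wid < V:
            raise ValueError(f"word id {wid} outside vocabulary of size {V}")
        counts[sec, wid] += 1
    return [ClipDocument(second_index=i, counts=counts[i]) for i in range(n_seconds)]


def documents_to_matrix(docs: Sequence[ClipDocument]) -> np.ndarray:
    """Stack documents into an (n_seconds, V) count matrix."""
    return np.stack([d.counts for d in docs])


def save_documents(docs: Sequence[ClipDocument], path: str | Path) -> None:
    """Write documents as sparse text triplets: second_index word_id count."""
    path = Path(path)
    with path.open("w") as fh:
        V = len(docs[0].counts) if docs else 0
        fh.write(f"%%phaseflow documents n_seconds={len(docs)} vocabulary={V}\n")
        for doc in docs:
            for wid in np.nonzero(doc.counts)[0]:
                fh.write(f"{doc.second_index} {wid} {doc.counts[wid]}\n")


def load_documents(path: str | Path) -> list[ClipDocument]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
        n_seconds, V = int(meta["n_seconds"]), int(meta["vocabulary"])
        counts = np.zeros((n_seconds, V), dtype=np.int64)
        for line in fh:
            s, w, c = line.split()
            counts[int(s), int(w)] = int(c)
    return [ClipDocument(second_index=i, counts=counts[i]) for i in range(n_seconds)]


def save_vocabulary(path: str | Path, cameras: int, grid: GridSpec) -> None:
    """Write the word table as TSV: word_id, camera, gx, gy, direction."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("word_id\tcamera\tgx\tgy\tdirection\n")
        for wid in range(vocabulary_size(cameras, grid)):
            cam, gx, gy, d = decode_word_id(wid, grid)
            fh.write(f"{wid}\t{cam}\t{gx}\t{gy}\t{d}\n")
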