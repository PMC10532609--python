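"""Coded pattern construction: symbol alphabet, grid generation, codeword book.

The projected pattern is a lattice of small binary symbols drawn from a
6-letter alphabet (rectangle, L, T, triangle, X, Pi).  Every 3x3 window of
symbols ("subpattern") is flattened to a 9-symbol codeword, and the lattice
is constructed so that any two codewords differ in at least 3 positions.
That minimum Hamming distance of 3 is what later permits the decoder to
correct a single misclassified symbol per codeword.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "SYMBOL_NAMES",
    "SYMBOL_SIZE",
    "SymbolClass",
    "SYMBOL_CLASSES",
    "build_symbol_rasters",
    "hamming_distance",
    "PatternGrid",
    "CodewordBook",
    "generate_pattern",
    "render_pattern",
    "render_offsets",
    "subpattern_at",
    "flatten_window",
    "unflatten_codeword",
    "build_codeword_book",
    "verify_min_distance",
]

SYMBOL_NAMES = ("rectangle", "L", "T", "triangle", "X", "Pi")
SYMBOL_SIZE = 20          # side of one symbol cell, pixels
_STROKE = 4               # stroke width for drawn symbols, pixels
MIN_CODE_DISTANCE = 3     # required pairwise Hamming distance between codewords
SEPARABILITY_FLOOR = 0.7  # required min pairwise normalized SAD of the rasters


@dataclass(frozen=True)
class SymbolClass:
    """One of the 6 symbol shapes; ``id`` is the label used everywhere."""

    id: int
    name: str


SYMBOL_CLASSES = tuple(SymbolClass(i, n) for i, n in enumerate(SYMBOL_NAMES))


def _raster_rectangle() -> np.ndarray:
    g = np.zeros((SYMBOL_SIZE, SYMBOL_SIZE), bool)
    g[5:15, 3:17] = True
    return g


def _raster_L() -> np.ndarray:
    g = np.zeros((SYMBOL_SIZE, SYMBOL_SIZE), bool)
    g[1:19, 2:2 + _STROKE] = True
    g[19 - _STROKE:19, 2:18] = True
    return g


def _raster_T() -> np.ndarray:
    g = np.zeros((SYMBOL_SIZE, SYMBOL_SIZE), bool)
    g[1:1 + _STROKE, 1:19] = True
    g[1:19, 8:8 + _STROKE] = True
    return g


def _raster_triangle() -> np.ndarray:
    rr, cc = np.mgrid[0:SYMBOL_SIZE, 0:SYMBOL_SIZE]
    t = (rr - 2) / 15.0
    return (rr >= 2) & (rr <= 17) & (np.abs(cc - 9.5) <= t * 8.5)


def _raster_X() -> np.ndarray:
    rr, cc = np.mgrid[0:SYMBOL_SIZE, 0:SYMBOL_SIZE]
    d1 = np.abs(rr - cc)
    d2 = np.abs(rr + cc - (SYMBOL_SIZE - 1))
    body = (d1 <= _STROKE / 2) | (d2 <= _STROKE / 2)
    return body & (rr >= 1) & (rr <= 18) & (cc >= 1) & (cc <= 18)


def _raster_Pi() -> np.ndarray:
    g = np.zeros((SYMBOL_SIZE, SYMBOL_SIZE), bool)
    g[2:2 + _STROKE, 1:19] = True
    g[2:18, 3:3 + _STROKE] = True
    g[2:18, 13:13 + _STROKE] = True
    return g


def _raw_normalized_sad(x: np.ndarray, y: np.ndarray) -> float:
    # same-shape fast path used only for the build-time separability check;
    # the general (padding) version lives in cslight.classify
    return float(np.abs(x.astype(np.int64) - y.astype(np.int64)).sum()
                 / max(x.sum(), y.sum()))


def build_symbol_rasters() -> list[np.ndarray]:
    """Return the 6 binary 20x20 symbol rasters, in class-id order.

    Raises ``RuntimeError`` if the drawn shapes fail the pairwise
    separability floor (normalized SAD >= 0.7 for every distinct pair),
    which would signal bad stroke parameters.
    """
    rasters = [
        _raster_rectangle(), _raster_L(), _raster_T(),
        _raster_triangle(), _raster_X(), _raster_Pi(),
    ]
    for i in range(6):
        if rasters[i].sum() == 0:
            raise RuntimeError(f"symbol raster {SYMBOL_NAMES[i]} is empty")
        for j in range(i + 1, 6):
            d = _raw_normalized_sad(rasters[i], rasters[j])
            if d < SEPARABILITY_FLOOR:
                raise RuntimeError(
                    f"symbol rasters {SYMBOL_NAMES[i]}/{SYMBOL_NAMES[j]} "
                    f"too similar (normalized SAD {d:.3f} < {SEPARABILITY_FLOOR})"
                )
    return rasters


def hamming_distance(a, b) -> int:
    """Number of positions at which two 9-symbol codewords differ."""
    a = tuple(a)
    b = tuple(b)
    if len(a) != 9 or len(b) != 9:
        raise ValueError(f"codewords must have length 9, got {len(a)} and {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class PatternGrid:
    """Lattice of symbol-class labels plus rendering geometry.

    ``labels`` is a ``rows x cols`` integer matrix of class ids.  Symbols are
    rendered on a pitch of ``symbol_px + gap_px`` pixels.
    """

    rows: int
    cols: int
    labels: np.ndarray
    symbol_px: int = SYMBOL_SIZE
    gap_px: int = 5
    seed: int = 0

    @property
    def pitch_px(self) -> int:
        return self.symbol_px + self.gap_px

    @property
    def rendered_size(self) -> tuple[int, int]:
        """(width, height) of the tight pattern raster in pixels."""
        w = self.cols * self.pitch_px - self.gap_px
        h = self.rows * self.pitch_px - self.gap_px
        return w, h

    def to_json(self) -> str:
        return json.dumps({
            "rows": self.rows, "cols": self.cols,
            "symbol_px": self.symbol_px, "gap_px": self.gap_px,
            "seed": self.seed,
            "labels": self.labels.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PatternGrid":
        d = json.loads(text)
        return cls(rows=d["rows"], cols=d["cols"],
                   labels=np.asarray(d["labels"], dtype=np.int8),
                   symbol_px=d["symbol_px"], gap_px=d["gap_px"],
                   seed=d["seed"])


@dataclass
class CodewordBook:
    """All codewords of a pattern, keyed by 9-tuple, mapped to window origin."""

    entries: dict[tuple, tuple[int, int]]
    _array: np.ndarray = field(default=None, repr=False)
    _origins: list = field(default=None, repr=False)

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def array(self) -> np.ndarray:
        """(count, 9) uint8 array of all codewords, in insertion order."""
        if self._array is None:
            self._array = np.array(list(self.entries.keys()), dtype=np.uint8)
            self._origins = list(self.entries.values())
        return self._array

    @property
    def origins(self) -> list:
        self.array
        return self._origins


def subpattern_at(grid: PatternGrid, r: int, c: int) -> np.ndarray:
    """The 3x3 label window whose top-left symbol sits at (r, c)."""
    if not (0 <= r <= grid.rows - 3 and 0 <= c <= grid.cols - 3):
        raise IndexError(f"subpattern origin ({r}, {c}) out of range")
    return grid.labels[r:r + 3, c:c + 3]


def flatten_window(window) -> tuple:
    """Flatten a 3x3 window to a 9-tuple codeword (row-major traversal)."""
    w = np.asarray(window)
    if w.shape != (3, 3):
        raise ValueError(f"expected 3x3 window, got {w.shape}")
    return tuple(int(v) for v in w.ravel())


def unflatten_codeword(codeword) -> np.ndarray:
    """Inverse of :func:`flatten_window`."""
    cw = tuple(codeword)
    if len(cw) != 9:
        raise ValueError("codeword must have length 9")
    return np.asarray(cw).reshape(3, 3)


def build_codeword_book(grid: PatternGrid) -> CodewordBook:
    entries: dict[tuple, tuple[int, int]] = {}
    for r in range(grid.rows - 2):
        for c in range(grid.cols - 2):
            cw = flatten_window(subpattern_at(grid, r, c))
            if cw in entries:
                raise ValueError(f"duplicate codeword at {entries[cw]} and {(r, c)}")
            entries[cw] = (r, c)
    return CodewordBook(entries)


def verify_min_distance(grid: PatternGrid, chunk: int = 256) -> int:
    """Exact minimum pairwise Hamming distance over all 3x3 subpatterns.

    Exhaustive (all-pairs) scan, blocked to bound memory.
    """
    book = build_codeword_book(grid)
    arr = book.array  # (n, 9)
    n = arr.shape[0]
    if n < 2:
        return 9
    best = 9
    for i0 in range(0, n, chunk):
        block = arr[i0:i0 + chunk]
        # distances of this block against all entries
        d = (block[:, None, :] != arr[None, :, :]).sum(axis=2)
        ii = np.arange(block.shape[0])
        d[ii, i0 + ii] = 9  # mask self-comparisons
        best = min(best, int(d.min()))
    return best


def _try_fill(rows: int, cols: int, rng: np.random.Generator,
              max_nodes: int) -> np.ndarray | None:
    """One backtracking attempt at filling the label lattice.

    Cells are filled in raster order.  Placing the symbol at (r, c) with
    r, c >= 2 completes exactly one 3x3 window (origin (r-2, c-2)); the
    candidate is accepted only if that window's codeword stays at Hamming
    distance >= 3 from every previously completed window.
    """
    labels = np.full((rows, cols), -1, dtype=np.int8)
    ncells = rows * cols
    nwin_max = (rows - 2) * (cols - 2)
    book = np.empty((nwin_max, 9), dtype=np.uint8)
    nbook = 0
    cand: list[list[int] | None] = [None] * ncells
    pos = 0
    nodes = 0
    while pos < ncells:
        r, c = divmod(pos, cols)
        if cand[pos] is None:
            cand[pos] = list(rng.permutation(6))
        placed = False
        while cand[pos]:
            nodes += 1
            if nodes > max_nodes:
                return None
            sym = cand[pos].pop()
            closes = r >= 2 and c >= 2
            if closes:
                win = labels[r - 2:r + 1, c - 2:c + 1].copy()
                win[2, 2] = sym
                word = win.ravel().astype(np.uint8)
                if nbook and int((book[:nbook] != word).sum(axis=1).min()) < MIN_CODE_DISTANCE:
                    continue
            labels[r, c] = sym
            if closes:
                book[nbook] = word
                nbook += 1
            placed = True
            break
        if placed:
            pos += 1
        else:
            cand[pos] = None
            pos -= 1
            if pos < 0:
                return None
            rb, cb = divmod(pos, cols)
            if rb >= 2 and cb >= 2:
                nbook -= 1
            labels[rb, cb] = -1
    return labels


def generate_pattern(rows: int, cols: int, seed: int = 0, *,
                     symbol_px: int = SYMBOL_SIZE, gap_px: int = 5,
                     restarts: int = 50, max_nodes: int = 500_000) -> PatternGrid:
    """Generate a label lattice whose codeword book has min Hamming distance >= 3.

    Seeded randomized backtracking fill; deterministic for a fixed
    (rows, cols, seed).  Raises ``RuntimeError`` if no valid lattice is found
    within the restart budget (signals an infeasible size/alphabet combination).
    """
    if rows < 3 or cols < 3:
        raise ValueError("pattern must be at least 3x3 symbols")
    master = np.random.default_rng(seed)
    for _ in range(restarts):
        sub = np.random.default_rng(master.integers(0, 2**31))
        labels = _try_fill(rows, cols, sub, max_nodes)
        if labels is not None:
            return PatternGrid(rows=rows, cols=cols, labels=labels,
                               symbol_px=symbol_px, gap_px=gap_px, seed=seed)
    raise RuntimeError(
        f"pattern search failed for {rows}x{cols} after {restarts} restarts")


def default_pattern(seed: int = 0) -> PatternGrid:
    """The default projector pattern: 76x43 symbols for a 1920x1080 canvas."""
    return generate_pattern(rows=43, cols=76, seed=seed)


def render_offsets(grid: PatternGrid, canvas_w: int, canvas_h: int) -> tuple[int, int]:
    """(x, y) offset that centers the tight pattern raster on the canvas."""
    w, h = grid.rendered_size
    if w > canvas_w or h > canvas_h:
        raise ValueError(f"pattern {w}x{h} does not fit canvas {canvas_w}x{canvas_h}")
    return (canvas_w - w) // 2, (canvas_h - h) // 2


def render_pattern(grid: PatternGrid, canvas_w: int = 1920,
                   canvas_h: int = 1080,
                   rasters: list[np.ndarray] | None = None) -> np.ndarray:
    """Render the lattice as a binary raster (white symbols on black).

    Returns a (canvas_h, canvas_w) boolean array with the pattern centered.
    """
    if rasters is None:
        rasters = build_symbol_rasters()
    off_x, off_y = render_offsets(grid, canvas_w, canvas_h)
    out = np.zeros((canvas_h, canvas_w), dtype=bool)
    pitch = grid.pitch_px
    for r in range(grid.rows):
        for c in range(grid.cols):
            y = off_y + r * pitch
            x = off_x + c * pitch
            ras = rasters[int(grid.labels[r, c])]
            if grid.symbol_px != SYMBOL_SIZE:
                raise ValueError("non-default symbol_px rendering is not supported")
            out[y:y + SYMBOL_SIZE, x:x + SYMBOL_SIZE] = ras
    return out


def symbol_centroids(grid: PatternGrid, canvas_w: int = 1920, canvas_h: int = 1080,
                     rasters: list[np.ndarray] | None = None) -> np.ndarray:
    """(rows, cols, 2) array of rendered symbol centroids as (x, y) pixels."""
    if rasters is None:
        rasters = build_symbol_rasters()
    cents = np.empty((6, 2))
    for i, ras in enumerate(rasters):
        rr, cc = np.nonzero(ras)
        cents[i] = (cc.mean(), rr.mean())  # (x, y) within the cell
    off_x, off_y = render_offsets(grid, canvas_w, canvas_h)
    pitch = grid.pitch_px
    out = np.empty((grid.rows, grid.cols, 2))
    for r in range(grid.rows):
        for c in range(grid.cols):
            cx, cy = cents[int(grid.labels[r, c])]
            out[r, c] = (off_x + c * pitch + cx, off_y + r * pitch + cy)
    return out


def iter_windows(grid: PatternGrid) -> Iterator[tuple[tuple[int, int], tuple]]:
    """Yield ((r, c), codeword) for every 3x3 window origin."""
    for r in range(grid.rows - 2):
        for c in range(grid.cols - 2):
            yield (r, c), flatten_window(subpattern_at(grid, r, c))
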