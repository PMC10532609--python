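"""Codeword decoding with single-error correction and correction propagation.

Valid 3x3 arrangements are flattened (same traversal as the encoder) and
matched against the pattern's codeword book.  Because the book has minimum
pairwise Hamming distance 3, a word within distance 1 of a book entry has a
unique nearest entry, so one misclassified symbol per codeword can be
corrected.  Each correction is propagated to every other codeword that
contains the repaired symbol, and decoding iterates to a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pattern import CodewordBook, PatternGrid, flatten_window, symbol_centroids
from .topology import SubpatternCandidate

__all__ = [
    "DecodedCodeword",
    "decode",
    "propagate_corrections",
    "Correspondence",
    "extract_correspondences",
    "codeword_participation_map",
]

log = logging.getLogger(__name__)


@dataclass
class DecodedCodeword:
    candidate: SubpatternCandidate
    origin: tuple[int, int]          # (row, col) of the window in the pattern
    hd: int                          # 0 or 1
    corrected_position: int | None   # flat index 0..8 when hd == 1
    corrected_class: int | None      # book symbol at that position


def _flat_members(candidate: SubpatternCandidate) -> list:
    return [m for row in candidate.arrangement for m in row]


def decode(candidate: SubpatternCandidate, book: CodewordBook,
           labels: dict[int, int]) -> DecodedCodeword | None:
    """Match one candidate against the book; accept at Hamming distance 0 or 1.

    ``labels`` maps component id -> current class label.  Returns ``None``
    (reject) when the nearest book entry is at distance >= 2.  A distance-1
    match is necessarily unique (two book entries within distance 1 of the
    same word would be within distance 2 of each other, contradicting the
    book's minimum distance of 3); this is asserted.
    """
    if not candidate.valid:
        return None
    members = _flat_members(candidate)
    word = tuple(labels[m.id] for m in members)
    origin = book.entries.get(word)
    if origin is not None:
        return DecodedCodeword(candidate, origin, 0, None, None)
    arr = book.array
    w = np.asarray(word, dtype=np.uint8)
    d = (arr != w).sum(axis=1)
    dmin = int(d.min())
    if dmin != 1:
        return None
    hits = np.flatnonzero(d == 1)
    assert hits.size == 1, "book min distance 3 violated: ambiguous HD-1 match"
    i = int(hits[0])
    entry = arr[i]
    pos = int(np.flatnonzero(entry != w)[0])
    return DecodedCodeword(candidate, book.origins[i], 1, pos, int(entry[pos]))


def propagate_corrections(
    candidates: list[SubpatternCandidate],
    book: CodewordBook,
    labels: dict[int, int],
    max_iter: int | None = None,
) -> tuple[list[DecodedCodeword], dict[int, int], list[int]]:
    """Iteratively decode all candidates, applying single-symbol corrections
    globally until a fixed point.

    Every distance-1 acceptance identifies one misclassified symbol; its
    label is overwritten everywhere, which can lower the distance of other
    codewords containing it and unlock further corrections.  Conflicting
    corrections for the same symbol (different codewords implying different
    classes) are resolved by abstention: the label is left unchanged and the
    symbol id is reported in the conflicts list.

    Returns (decoded codewords at the fixed point, final labels, conflicts).
    """
    labels = dict(labels)
    if max_iter is None:
        max_iter = len(labels) + 1
    conflicts: list[int] = []
    decoded: list[DecodedCodeword] = []
    for _ in range(max_iter):
        decoded = [d for d in (decode(c, book, labels) for c in candidates)
                   if d is not None]
        proposals: dict[int, set[int]] = {}
        for d in decoded:
            if d.hd == 1:
                comp = _flat_members(d.candidate)[d.corrected_position]
                proposals.setdefault(comp.id, set()).add(d.corrected_class)
        changed = False
        for comp_id, classes in proposals.items():
            if len(classes) > 1:
                if comp_id not in conflicts:
                    conflicts.append(comp_id)
                    log.warning("conflicting corrections for symbol %d: %s",
                                comp_id, sorted(classes))
                continue
            new = next(iter(classes))
            if labels[comp_id] != new:
                labels[comp_id] = new
                changed = True
        if not changed:
            break
    return decoded, labels, conflicts


@dataclass
class Correspondence:
    """A matched pattern point / image point pair (both as (x, y) pixels)."""

    pattern_point: tuple[float, float]
    image_point: tuple[float, float]
    grid_pos: tuple[int, int]        # (row, col) of the symbol in the lattice
    component_id: int
    best_hd: int                     # smallest hd of any codeword covering it


def extract_correspondences(
    decoded: list[DecodedCodeword],
    grid: PatternGrid,
    canvas_w: int = 1920,
    canvas_h: int = 1080,
) -> list[Correspondence]:
    """One correspondence per distinct decoded image symbol.

    A symbol is fully decoded when it belongs to at least one decoded
    codeword; overlapping codewords are deduplicated.  If two codewords
    imply different lattice positions for the same image symbol, the symbol
    is dropped and the inconsistency logged.
    """
    cents = symbol_centroids(grid, canvas_w, canvas_h)
    by_comp: dict[int, dict] = {}
    inconsistent: set[int] = set()
    for d in decoded:
        r0, c0 = d.origin
        for i in range(3):
            for j in range(3):
                m = d.candidate.arrangement[i][j]
                gp = (r0 + i, c0 + j)
                rec = by_comp.get(m.id)
                if rec is None:
                    by_comp[m.id] = {"comp": m, "grid_pos": gp, "hd": d.hd}
                else:
                    if rec["grid_pos"] != gp:
                        inconsistent.add(m.id)
                    rec["hd"] = min(rec["hd"], d.hd)
    out: list[Correspondence] = []
    for comp_id, rec in sorted(by_comp.items()):
        if comp_id in inconsistent:
            log.warning("symbol %d decoded at inconsistent lattice positions; dropped",
                        comp_id)
            continue
        r, c = rec["grid_pos"]
        px, py = cents[r, c]
        m = rec["comp"]
        out.append(Correspondence(
            pattern_point=(float(px), float(py)),
            image_point=(m.centroid[1], m.centroid[0]),
            grid_pos=(r, c),
            component_id=comp_id,
            best_hd=rec["hd"],
        ))
    return out


def codeword_participation_map(decoded: list[DecodedCodeword]) -> dict[int, int]:
    """Per image symbol: in how many decoded codewords it appears (0..9).

    Symbols near the object outline participate in fewer codewords, which is
    the boundary-loss diagnostic of the method.
    """
    counts: dict[int, int] = {}
    for d in decoded:
        for m in _flat_members(d.candidate):
            counts[m.id] = counts.get(m.id, 0) + 1
    return counts
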