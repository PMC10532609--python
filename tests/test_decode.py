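"""Codeword matching, single-error correction and correspondence extraction."""

import numpy as np
import pytest

from cslight.decode import (codeword_participation_map, decode,
                            extract_correspondences, propagate_corrections)
from cslight.pattern import build_codeword_book
from cslight.topology import SubpatternCandidate

from conftest import lattice_components


def build_scene(grid, flips=None):
    """Fabricate perfect subpattern candidates for every window of a grid.

    One synthetic component per lattice symbol; ``flips`` maps lattice
    (row, col) -> wrong class label, simulating misclassification.
    Returns (candidates, labels, components-by-position).
    """
    comps, truth = lattice_components(grid.rows, grid.cols)
    by_pos = {truth[c.id]: c for c in comps}
    labels = {}
    for c in comps:
        r, col = truth[c.id]
        lab = int(grid.labels[r, col])
        if flips and (r, col) in flips:
            lab = flips[(r, col)]
        labels[c.id] = lab
    candidates = []
    for r in range(grid.rows - 2):
        for c in range(grid.cols - 2):
            arr = [[by_pos[(r + i, c + j)] for j in range(3)] for i in range(3)]
            candidates.append(SubpatternCandidate(
                center=arr[1][1], arrangement=arr, valid=True,
                failure_reason="none"))
    return candidates, labels, by_pos


@pytest.fixture(scope="module")
def small_book(small_grid):
    return build_codeword_book(small_grid)


class TestDecode:
    def test_verbatim_codeword_hd0(self, small_grid, small_book):
        cands, labels, _ = build_scene(small_grid)
        for cand in cands[:5]:
            d = decode(cand, small_book, labels)
            assert d is not None and d.hd == 0
        # origins recovered correctly
        d = decode(cands[0], small_book, labels)
        assert d.origin == (0, 0)

    def test_invalid_candidate_rejected(self, small_grid, small_book):
        cands, labels, _ = build_scene(small_grid)
        bad = SubpatternCandidate(center=cands[0].center, arrangement=None,
                                  valid=False, failure_reason="dual_check")
        assert decode(bad, small_book, labels) is None

    def test_single_flip_recovers_origin(self, small_grid, small_book):
        """Any single symbol error is corrected to the true origin: the
        book's minimum distance of 3 makes the distance-1 match unique."""
        rng = np.random.default_rng(17)
        words = list(small_book.entries.items())
        for _ in range(100):
            word, origin = words[rng.integers(len(words))]
            pos = int(rng.integers(9))
            wrong = (int(word[pos]) + int(rng.integers(1, 6))) % 6
            damaged = list(word)
            damaged[pos] = wrong
            cands, labels, by_pos = build_scene(small_grid)
            # flip that symbol's label in the fabricated scene
            r0, c0 = origin
            comp = by_pos[(r0 + pos // 3, c0 + pos % 3)]
            labels[comp.id] = wrong
            idx = r0 * (small_grid.cols - 2) + c0
            d = decode(cands[idx], small_book, labels)
            assert d is not None
            assert d.origin == origin
            assert d.hd == 1
            assert d.corrected_position == pos
            assert d.corrected_class == word[pos]

    def test_rejects_words_far_from_book(self, small_grid, small_book):
        """Words at minimum distance >= 2 from every book entry are rejected
        (verified against an exhaustive distance scan)."""
        rng = np.random.default_rng(29)
        arr = small_book.array
        rejected = 0
        trials = 0
        while rejected < 50 and trials < 500:
            trials += 1
            word = rng.integers(0, 6, 9).astype(np.uint8)
            dmin = int((arr != word).sum(axis=1).min())
            if dmin < 2:
                continue
            cands, labels, _ = build_scene(small_grid)
            flat = [m for row in cands[0].arrangement for m in row]
            for m, w in zip(flat, word):
                labels[m.id] = int(w)
            assert decode(cands[0], small_book, labels) is None
            rejected += 1
        assert rejected == 50


class TestPropagation:
    def test_no_errors_fixed_point_immediately(self, small_grid, small_book):
        cands, labels, _ = build_scene(small_grid)
        decoded, final, conflicts = propagate_corrections(cands, small_book, labels)
        assert len(decoded) == len(cands)
        assert final == labels
        assert conflicts == []

    def test_shared_error_corrected_everywhere(self, small_grid, small_book):
        """One misclassified interior symbol appears in up to 9 codewords;
        after propagation every one of them decodes at distance 0."""
        pos = (4, 4)
        true_class = int(small_grid.labels[pos])
        cands, labels, by_pos = build_scene(
            small_grid, flips={pos: (true_class + 1) % 6})
        decoded, final, conflicts = propagate_corrections(cands, small_book, labels)
        assert conflicts == []
        assert final[by_pos[pos].id] == true_class
        assert len(decoded) == len(cands)
        covering = [d for d in decoded
                    if d.origin[0] in (2, 3, 4) and d.origin[1] in (2, 3, 4)]
        assert len(covering) == 9
        assert all(d.hd == 0 for d in covering)

    def test_double_error_codeword_recovered_in_later_pass(self, small_grid,
                                                           small_book):
        """Two errors in one codeword, each covered by clean codewords
        elsewhere: both get corrected and the double-error codeword is
        recovered by iteration."""
        # symbols (4,2) and (4,4) are both inside the window at origin (2,2)
        # but also in many other windows that contain only one of them
        f1, f2 = (4, 2), (4, 4)
        flips = {p: (int(small_grid.labels[p]) + 1) % 6 for p in (f1, f2)}
        cands, labels, by_pos = build_scene(small_grid, flips=flips)
        idx = 2 * (small_grid.cols - 2) + 2
        first_pass = decode(cands[idx], small_book, labels)
        assert first_pass is None   # two errors: unrecoverable alone
        decoded, final, conflicts = propagate_corrections(cands, small_book, labels)
        for p in (f1, f2):
            assert final[by_pos[p].id] == int(small_grid.labels[p])
        assert any(d.origin == (2, 2) for d in decoded)

    def test_accepted_set_monotone(self, small_grid, small_book):
        """The set of decoded codewords never shrinks across iterations."""
        flips = {(4, 4): (int(small_grid.labels[4, 4]) + 2) % 6}
        cands, labels, _ = build_scene(small_grid, flips=flips)
        first = [d for d in (decode(c, small_book, labels) for c in cands) if d]
        decoded, _, _ = propagate_corrections(cands, small_book, labels)
        assert len(decoded) >= len(first)


class TestCorrespondences:
    def test_single_codeword_gives_nine(self, small_grid, small_book):
        cands, labels, _ = build_scene(small_grid)
        d = decode(cands[0], small_book, labels)
        corrs = extract_correspondences([d], small_grid, 400, 400)
        assert len(corrs) == 9
        assert {c.grid_pos for c in corrs} == {(i, j) for i in range(3)
                                               for j in range(3)}

    def test_overlapping_codewords_deduplicate(self, small_grid, small_book):
        """Two windows sharing a 3x2 block of symbols yield 12 distinct
        correspondences."""
        cands, labels, _ = build_scene(small_grid)
        d0 = decode(cands[0], small_book, labels)   # origin (0, 0)
        d1 = decode(cands[1], small_book, labels)   # origin (0, 1)
        corrs = extract_correspondences([d0, d1], small_grid, 400, 400)
        assert len(corrs) == 12

    def test_pattern_points_match_rendered_centroids(self, small_grid,
                                                     small_book, rasters):
        from cslight.pattern import symbol_centroids
        cands, labels, _ = build_scene(small_grid)
        d = decode(cands[0], small_book, labels)
        cents = symbol_centroids(small_grid, 400, 400)
        for corr in extract_correspondences([d], small_grid, 400, 400):
            r, c = corr.grid_pos
            assert corr.pattern_point == pytest.approx(tuple(cents[r, c]))

    def test_participation_counts(self, small_grid, small_book):
        """Participation histogram on the full lattice matches the closed
        form: a symbol at (r, c) lies in a(r) * a(c) windows, where
        a(i) = min(i, R-3) - max(0, i-2) + 1."""
        cands, labels, by_pos = build_scene(small_grid)
        decoded = [decode(c, small_book, labels) for c in cands]
        counts = codeword_participation_map(decoded)

        def a(i, n):
            return min(i, n - 3) - max(0, i - 2) + 1

        R = C = 10
        for (r, c), comp in by_pos.items():
            expected = a(r, R) * a(c, C)
            assert counts.get(comp.id, 0) == expected
        assert max(counts.values()) == 9
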