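"""Subpattern assembly from detected symbol centroids.

For each symbol the 8 nearest neighbors are gathered and traversed by a
nearest-unvisited chain.  The chain closes four overlapping 2x2 grids of
symbols (after 3, +2, +2 and +1 visits); corner roles are assigned twice --
once to the four quad centroids and once to the members of each quad -- by
greedy minimum-distance projection onto the corners of their bounding box.
Middle symbols are determined twice and the central symbol four times, so
positional consistency yields a validity check on the assembled 3x3
arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import QhullError, ConvexHull, cKDTree

from .binarize import DetectedComponent

__all__ = [
    "eight_nearest",
    "NeighborChain",
    "chain_traverse",
    "assign_corners",
    "DegenerateQuadError",
    "SubpatternCandidate",
    "assemble_subpattern",
    "extract_candidates",
]

CORNERS = ("top-left", "top-right", "bottom-left", "bottom-right")

# a chain step longer than this multiple of the median step length is taken
# as evidence that the 8-nearest-neighborhood assumption failed
CHAIN_BREAK_FACTOR = 1.8


class DegenerateQuadError(ValueError):
    """Raised when 4 points are too degenerate for corner assignment."""


def eight_nearest(center: DetectedComponent,
                  all_components: list[DetectedComponent]) -> list[DetectedComponent]:
    """The 8 components nearest to ``center`` by centroid Euclidean distance.

    Ties are broken lexicographically by (row, col).  Raises ``ValueError``
    if fewer than 8 other components exist (boundary symbol: no subpattern).
    """
    others = [c for c in all_components if c is not center]
    if len(others) < 8:
        raise ValueError("fewer than 8 neighbor candidates")
    cr, cc = center.centroid
    ranked = sorted(
        others,
        key=lambda c: ((c.centroid[0] - cr) ** 2 + (c.centroid[1] - cc) ** 2,
                       c.centroid[0], c.centroid[1]),
    )
    return ranked[:8]


@dataclass
class NeighborChain:
    center: DetectedComponent
    visits: list[DetectedComponent]  # 8 entries, visit order

    @property
    def step_lengths(self) -> np.ndarray:
        pts = [self.center.centroid] + [v.centroid for v in self.visits]
        pts = np.asarray(pts)
        return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def chain_traverse(center: DetectedComponent,
                   neighbors: list[DetectedComponent]) -> NeighborChain:
    """Visit all 8 neighbors: nearest to the center first, then repeatedly
    the nearest not-yet-visited neighbor of the last visited symbol."""
    if len(neighbors) != 8:
        raise ValueError("chain traversal needs exactly 8 neighbors")
    remaining = list(neighbors)
    visits: list[DetectedComponent] = []
    last = center
    while remaining:
        lr, lc = last.centroid
        nxt = min(remaining,
                  key=lambda c: ((c.centroid[0] - lr) ** 2 + (c.centroid[1] - lc) ** 2,
                                 c.centroid[0], c.centroid[1]))
        remaining.remove(nxt)
        visits.append(nxt)
        last = nxt
    return NeighborChain(center=center, visits=visits)


def assign_corners(points: np.ndarray) -> list[int]:
    """Greedy assignment of 4 points to the 4 corners of their bounding box.

    Repeatedly pairs the globally closest (point, corner) and removes both.
    Returns, for each point index, the corner index into :data:`CORNERS`.
    Raises :class:`DegenerateQuadError` for point sets that do not form a
    convex quadrilateral (collinear or coincident points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError("assign_corners expects 4 (row, col) points")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise DegenerateQuadError("points are collinear or coincident") from e
    if len(hull.vertices) != 4:
        raise DegenerateQuadError("points do not form a convex quadrilateral")
    top, left = pts[:, 0].min(), pts[:, 1].min()
    bottom, right = pts[:, 0].max(), pts[:, 1].max()
    corners = np.array([(top, left), (top, right), (bottom, left), (bottom, right)])
    d = np.linalg.norm(pts[:, None, :] - corners[None, :, :], axis=2)
    assignment = [-1] * 4
    d = d.copy()
    for _ in range(4):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        assignment[int(i)] = int(j)
        d[i, :] = np.inf
        d[:, j] = np.inf
    return assignment


@dataclass
class SubpatternCandidate:
    """A (possibly invalid) 3x3 arrangement of components around a center."""

    center: DetectedComponent
    arrangement: list | None   # 3x3 nested list of components when valid
    valid: bool
    failure_reason: str        # none | chain_break | dual_check | quadruple_check | degenerate


def _role_map(members: list[DetectedComponent]) -> dict[str, DetectedComponent] | None:
    """Corner role ('top-left', ...) -> member, via assign_corners."""
    pts = np.asarray([m.centroid for m in members])
    try:
        asg = assign_corners(pts)
    except DegenerateQuadError:
        return None
    return {CORNERS[c]: members[i] for i, c in enumerate(asg)}


def assemble_subpattern(chain: NeighborChain) -> SubpatternCandidate:
    """Assemble and validate the 3x3 arrangement implied by a neighbor chain.

    The four overlapping 2x2 quads are, in visit order: {center, v1..v3},
    {center, v3..v5}, {center, v5..v7}, {center, v7, v8, v1}.  Corner roles
    are assigned to the quad centroids and, within each quad, to its
    members; the corner rules then place every symbol.  Middle symbols must
    agree across their two determinations (dual check) and the central
    symbol across all four (quadruple check); any disagreement invalidates
    the candidate.
    """
    c = chain.center
    v = chain.visits

    steps = chain.step_lengths
    pitch = float(np.median(steps))
    if pitch <= 0 or float(steps.max()) > CHAIN_BREAK_FACTOR * pitch:
        return SubpatternCandidate(c, None, False, "chain_break")

    quads = [
        [c, v[0], v[1], v[2]],
        [c, v[2], v[3], v[4]],
        [c, v[4], v[5], v[6]],
        [c, v[6], v[7], v[0]],
    ]
    quad_centroids = np.asarray([
        np.mean([m.centroid for m in q], axis=0) for q in quads
    ])
    try:
        quad_asg = assign_corners(quad_centroids)
    except DegenerateQuadError:
        return SubpatternCandidate(c, None, False, "degenerate")
    quad_by_role = {CORNERS[r]: quads[i] for i, r in enumerate(quad_asg)}

    roles: dict[str, dict[str, DetectedComponent]] = {}
    for role, q in quad_by_role.items():
        rm = _role_map(q)
        if rm is None:
            return SubpatternCandidate(c, None, False, "degenerate")
        roles[role] = rm

    tl, tr = roles["top-left"], roles["top-right"]
    bl, br = roles["bottom-left"], roles["bottom-right"]

    # quadruple check: the center belongs to all four quads at fixed corners
    centers = (tl["bottom-right"], tr["bottom-left"],
               bl["top-right"], br["top-left"])
    if any(m is not c for m in centers):
        return SubpatternCandidate(c, None, False, "quadruple_check")

    # dual checks: each middle symbol is determined twice
    top_mid = (tl["top-right"], tr["top-left"])
    left_mid = (tl["bottom-left"], bl["top-left"])
    right_mid = (tr["bottom-right"], br["top-right"])
    bottom_mid = (bl["bottom-right"], br["bottom-left"])
    for a, b in (top_mid, left_mid, right_mid, bottom_mid):
        if a is not b:
            return SubpatternCandidate(c, None, False, "dual_check")

    arrangement = [
        [tl["top-left"], top_mid[0], tr["top-right"]],
        [left_mid[0], c, right_mid[0]],
        [bl["bottom-left"], bottom_mid[0], br["bottom-right"]],
    ]
    flat = [m for row in arrangement for m in row]
    if len({id(m) for m in flat}) != 9:
        return SubpatternCandidate(c, None, False, "dual_check")
    return SubpatternCandidate(c, arrangement, True, "none")


def extract_candidates(components: list[DetectedComponent]) -> list[SubpatternCandidate]:
    """Assemble a subpattern candidate around every component with at least
    8 neighbors, using a KD-tree for the nearest-neighbor queries."""
    if len(components) < 9:
        return []
    pts = np.asarray([c.centroid for c in components])
    tree = cKDTree(pts)
    out: list[SubpatternCandidate] = []
    k = min(9, len(components))
    dists, idxs = tree.query(pts, k=k)
    for i, comp in enumerate(components):
        neigh_idx = [j for j in idxs[i] if j != i][:8]
        if len(neigh_idx) < 8:
            continue
        # re-rank with the deterministic tie-break of eight_nearest
        cr, cc = comp.centroid
        neigh = sorted(
            (components[j] for j in neigh_idx),
            key=lambda c: ((c.centroid[0] - cr) ** 2 + (c.centroid[1] - cc) ** 2,
                           c.centroid[0], c.centroid[1]),
        )
        chain = chain_traverse(comp, neigh)
        out.append(assemble_subpattern(chain))
    return out
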