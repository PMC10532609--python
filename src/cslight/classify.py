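"""Symbol classification by rotation/scale-normalized template dissimilarity.

Each detected component is compared against every symbol class rotated over
a +/-22 degree sweep (1 degree steps, 45 variants per class).  Each rotated
template is anisotropically rescaled so its bounding box matches the
component's, and the dissimilarity is the sum of absolute pixel differences
normalized by the larger foreground count (range [0, 2]).  Rotation + scale
is sufficient for smooth fusiform surfaces, where symbol distortion is mild;
no projective search is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate

from .binarize import DetectedComponent
from .pattern import build_symbol_rasters

__all__ = [
    "rotate_raster",
    "scale_to_bbox",
    "normalized_sad",
    "ClassifierConfig",
    "ClassificationResult",
    "classify",
    "classify_all",
]


def rotate_raster(raster: np.ndarray, theta: float) -> np.ndarray:
    """Rotate a binary raster by ``theta`` degrees (counterclockwise) about
    its center, expanding the canvas, and re-threshold to binary.

    Bilinear resampling followed by a 0.5 threshold keeps thin diagonal
    strokes connected (nearest-neighbor resampling can fragment them).
    """
    if theta == 0:
        return np.asarray(raster, dtype=bool)
    out = rotate(np.asarray(raster, dtype=float), angle=theta, resize=True,
                 order=1, preserve_range=True)
    return out > 0.5


def crop_to_bbox(raster: np.ndarray) -> np.ndarray:
    """Tight bounding-box crop of a binary raster's foreground."""
    rr, cc = np.nonzero(raster)
    if rr.size == 0:
        raise ValueError("empty raster has no bounding box")
    return np.asarray(raster, bool)[rr.min():rr.max() + 1, cc.min():cc.max() + 1]


def scale_to_bbox(raster: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Anisotropically resize a raster's bounding-box content to
    ``target_h x target_w`` and re-threshold to binary."""
    if target_h < 3 or target_w < 3:
        raise ValueError(f"degenerate target size {target_h}x{target_w}")
    crop = crop_to_bbox(raster)
    if crop.shape == (target_h, target_w):
        return crop
    out = resize(crop.astype(float), (target_h, target_w), order=1,
                 anti_aliasing=False, preserve_range=True)
    return out > 0.5


def _pad_to(raster: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center a raster on a background canvas of the given shape."""
    h, w = raster.shape
    H, W = shape
    out = np.zeros(shape, dtype=bool)
    top, left = (H - h) // 2, (W - w) // 2
    out[top:top + h, left:left + w] = raster
    return out


def normalized_sad(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of absolute differences of two binary rasters, normalized by the
    larger foreground pixel count.

    Rasters of unequal size are centered on a common background canvas
    first.  Identical rasters score 0; disjoint rasters of equal foreground
    area score 2.  Undefined (raises) when both rasters are empty.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    fx, fy = int(x.sum()), int(y.sum())
    if fx == 0 and fy == 0:
        raise ValueError("normalized SAD undefined for two empty rasters")
    if x.shape != y.shape:
        shape = (max(x.shape[0], y.shape[0]), max(x.shape[1], y.shape[1]))
        x, y = _pad_to(x, shape), _pad_to(y, shape)
    return float((x != y).sum() / max(fx, fy))


@dataclass
class ClassifierConfig:
    """Template cache for the rotation-sweep classifier."""

    theta_min: float = -22.0
    theta_max: float = 22.0
    theta_step: float = 1.0
    # per (class, angle): bbox-cropped rotated template
    _templates: list = field(default=None, repr=False)
    _angles: np.ndarray = field(default=None, repr=False)
    _scaled_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._angles = np.arange(self.theta_min, self.theta_max + 1e-9,
                                 self.theta_step)
        rasters = build_symbol_rasters()
        self._templates = [
            [crop_to_bbox(rotate_raster(ras, th)) for th in self._angles]
            for ras in rasters
        ]
        # tie-break order: lowest class id, then smallest |theta|
        keys = [(cls, abs(th), th)
                for cls in range(6) for th in self._angles]
        self._order = np.lexsort((
            np.array([k[2] for k in keys]),
            np.array([k[1] for k in keys]),
            np.array([k[0] for k in keys]),
        ))

    @property
    def n_rotations(self) -> int:
        return len(self._angles)

    @property
    def angles(self) -> np.ndarray:
        return self._angles

    def scaled_stack(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        """All 6 * n_rotations templates rescaled to an h x w bounding box.

        Returns (stack, foreground_counts); cached by target size, since
        components on a regular lattice share few distinct bbox shapes.
        """
        key = (h, w)
        hit = self._scaled_cache.get(key)
        if hit is not None:
            return hit
        n = 6 * self.n_rotations
        stack = np.empty((n, h, w), dtype=bool)
        i = 0
        for cls in range(6):
            for t in self._templates[cls]:
                stack[i] = scale_to_bbox(t, h, w)
                i += 1
        fg = stack.sum(axis=(1, 2))
        self._scaled_cache[key] = (stack, fg)
        return stack, fg


@dataclass
class ClassificationResult:
    component: DetectedComponent
    assigned_class: int
    dissimilarity: float
    best_angle: float


def classify(component: DetectedComponent,
             config: ClassifierConfig) -> ClassificationResult:
    """Assign a component to the symbol class of global minimum dissimilarity
    over all class x rotation candidates (ties: lowest class id, then
    smallest rotation magnitude)."""
    crop = crop_to_bbox(component.mask)
    h, w = crop.shape
    stack, fg_t = config.scaled_stack(h, w)
    fg_c = int(crop.sum())
    sad = (stack != crop[None]).sum(axis=(1, 2))
    nsad = sad / np.maximum(fg_t, fg_c)
    # evaluate in tie-break order so the first argmin wins deterministically
    ordered = nsad[config._order]
    j = int(np.argmin(ordered))
    idx = int(config._order[j])
    cls, rot = divmod(idx, config.n_rotations)
    return ClassificationResult(
        component=component,
        assigned_class=cls,
        dissimilarity=float(nsad[idx]),
        best_angle=float(config.angles[rot]),
    )


def classify_all(components: list[DetectedComponent],
                 config: ClassifierConfig | None = None) -> list[ClassificationResult]:
    if config is None:
        config = ClassifierConfig()
    return [classify(c, config) for c in components]
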