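"""Adaptive binarization and connected-component extraction.

Captured images of the projected pattern are unevenly illuminated, so a
single global threshold (Otsu) merges symbols in bright areas and loses them
in dim ones.  Sauvola's method computes a per-pixel threshold from local
mean and standard deviation and is the default here; Otsu is kept for
comparison.  Components smaller than 50 pixels are discarded as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu, threshold_sauvola
from skimage.measure import label, regionprops

__all__ = [
    "to_grayscale",
    "sauvola_binarize",
    "otsu_binarize",
    "DetectedComponent",
    "extract_components",
]

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grayscale (ITU-R 601 luma).

    Grayscale input is passed through unchanged.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise ValueError(f"expected HxW or HxWx3 image, got shape {img.shape}")
    gray = img[..., :3].astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def sauvola_binarize(image: np.ndarray, window: int = 31, k: float = 0.2,
                     r: float = 128.0, min_std: float = 0.0,
                     polarity: str = "bright") -> np.ndarray:
    """Adaptive (Sauvola) binarization; bright foreground on dark background.

    Per-pixel threshold t = m * (1 + k * (s / r - 1)) with m, s the local
    mean and standard deviation over a ``window`` x ``window`` neighborhood
    and ``r`` the dynamic-range constant.  A pixel is foreground where its
    value exceeds t.  On constant images s = 0 everywhere, so t < m and the
    whole image comes out foreground; that degenerate output is accepted.

    Sauvola's rule was designed for dark text on a light background, where
    the threshold sits just below the local mean.  Captured pattern images
    are the opposite -- bright symbols on a dark background -- so with
    ``polarity="bright"`` (the default) the threshold is computed on the
    photometrically inverted image and the comparison inverted back; this
    keeps the cut close to the background level instead of hovering just
    under the local mean, where dim-region sensor noise would cross it.
    ``polarity="dark"`` gives the textbook rule on the image as-is.

    ``min_std`` guards against the degenerate failure mode on signal-free
    regions: windows whose local standard deviation stays below it carry no
    pattern contrast (only sensor noise) and are forced to background.  The
    default of 0 disables the guard.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if not 0.0 < k < 1.0:
        raise ValueError(f"k must be in (0, 1), got {k}")
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("sauvola_binarize expects a grayscale image")
    imgf = img.astype(np.float64)
    if polarity == "bright":
        inv = 255.0 - imgf
        t = threshold_sauvola(inv, window_size=window, k=k, r=r)
        out = inv < t
    else:
        t = threshold_sauvola(imgf, window_size=window, k=k, r=r)
        out = imgf > t
    if min_std > 0.0:
        from scipy.ndimage import uniform_filter
        m = uniform_filter(imgf, window)
        s2 = uniform_filter(imgf * imgf, window) - m * m
        out &= np.sqrt(np.maximum(s2, 0.0)) >= min_std
    return out


def otsu_binarize(image: np.ndarray) -> np.ndarray:
    """Global Otsu binarization; bright foreground on dark background."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("otsu_binarize expects a grayscale image")
    if img.min() == img.max():
        raise ValueError("Otsu threshold undefined for a constant image")
    t = threshold_otsu(img)
    return img > t


@dataclass
class DetectedComponent:
    """An 8-connected foreground blob: candidate symbol observation.

    ``bbox`` is (top, left, bottom, right), inclusive; ``mask`` is the
    boolean crop of the component over its bounding box; ``centroid`` is the
    (row, col) mean of the member pixels.
    """

    id: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    mask: np.ndarray

    @property
    def bbox_shape(self) -> tuple[int, int]:
        t, l, b, r = self.bbox
        return b - t + 1, r - l + 1

    @property
    def pixels(self) -> np.ndarray:
        """(n, 2) array of absolute (row, col) member pixel coordinates."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.bbox[0], cc + self.bbox[1]])


def extract_components(mask: np.ndarray, min_area: int = 50,
                       max_area: int | None = None) -> list[DetectedComponent]:
    """8-connected component labeling with small-blob rejection.

    Components with area < ``min_area`` are treated as noise ("fewer than 50
    pixels" with the default).  ``max_area``, when given, additionally drops
    oversized blobs that cannot be individual symbols (e.g. a merged or
    percolated background region).
    """
    lab = label(np.asarray(mask, dtype=bool), connectivity=2)
    out: list[DetectedComponent] = []
    for p in regionprops(lab):
        if p.area < min_area:
            continue
        if max_area is not None and p.area > max_area:
            continue
        top, left, bottom, right = p.bbox[0], p.bbox[1], p.bbox[2] - 1, p.bbox[3] - 1
        out.append(DetectedComponent(
            id=len(out), area=int(p.area),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            bbox=(top, left, bottom, right),
            mask=p.image.astype(bool),
        ))
    return out
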