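"""Projector-camera triangulation, depth maps and morphometrics.

The camera sits at the origin of a right-handed frame, optical axis along
+z, x toward the projector, y down (image-row direction).  The projector is
at (baseline, 0, 0) with its axis toed in by ``convergence_deg`` toward the
camera axis.  Both devices are pinhole models; the focal length in pixels
follows from the horizontal field of view, f = (W/2) / tan(hfov/2).
A 3D point is recovered as the midpoint of the common perpendicular between
the camera ray and projector ray of a correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .decode import Correspondence

__all__ = [
    "CalibrationModel",
    "pixel_to_ray",
    "triangulate",
    "triangulate_correspondences",
    "PointCloud",
    "Morphometrics",
    "measure",
]


@dataclass
class CalibrationModel:
    """Geometry of the projector-camera rig.

    Defaults describe a rig with a 53.4 cm baseline, a 3328x2496 camera with
    78.7 degree horizontal field of view, and a 1920x1080 projector with a
    42.5 degree horizontal field of view, working at about 72 cm.
    """

    baseline_cm: float = 53.4
    cam_resolution: tuple[int, int] = (3328, 2496)     # (width, height) px
    proj_resolution: tuple[int, int] = (1920, 1080)
    cam_hfov_deg: float = 78.7
    proj_hfov_deg: float = 42.5
    convergence_deg: float = 20.0   # projector toe-in toward the camera axis
    cam_principal: tuple[float, float] | None = None   # (cx, cy); image center if None
    proj_principal: tuple[float, float] | None = None

    def __post_init__(self):
        if self.baseline_cm <= 0:
            raise ValueError("baseline must be positive")

    @property
    def cam_focal_px(self) -> float:
        return (self.cam_resolution[0] / 2.0) / np.tan(np.radians(self.cam_hfov_deg) / 2.0)

    @property
    def proj_focal_px(self) -> float:
        return (self.proj_resolution[0] / 2.0) / np.tan(np.radians(self.proj_hfov_deg) / 2.0)

    def principal(self, device: str) -> tuple[float, float]:
        if device == "camera":
            if self.cam_principal is not None:
                return self.cam_principal
            w, h = self.cam_resolution
        elif device == "projector":
            if self.proj_principal is not None:
                return self.proj_principal
            w, h = self.proj_resolution
        else:
            raise ValueError(f"unknown device {device!r}")
        return (w / 2.0, h / 2.0)

    @property
    def proj_rotation(self) -> np.ndarray:
        """World-from-projector rotation (yaw about +y by the convergence)."""
        th = np.radians(self.convergence_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, 0.0, -s],
                         [0.0, 1.0, 0.0],
                         [s, 0.0, c]])

    @property
    def proj_origin(self) -> np.ndarray:
        return np.array([self.baseline_cm, 0.0, 0.0])

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "baseline_cm": self.baseline_cm,
            "cam_resolution": list(self.cam_resolution),
            "proj_resolution": list(self.proj_resolution),
            "cam_hfov_deg": self.cam_hfov_deg,
            "proj_hfov_deg": self.proj_hfov_deg,
            "convergence_deg": self.convergence_deg,
        })

    @classmethod
    def from_yaml(cls, text: str) -> "CalibrationModel":
        d = yaml.safe_load(text)
        for k in ("cam_resolution", "proj_resolution"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def pixel_to_ray(device: str, px: tuple[float, float],
                 calib: CalibrationModel) -> tuple[np.ndarray, np.ndarray]:
    """Back-project a pixel (x, y) of a device into a world ray.

    Returns (origin, unit direction).  Raises for pixels outside the device
    resolution (half a pixel of slack at the borders).
    """
    x, y = float(px[0]), float(px[1])
    if device == "camera":
        w, h = calib.cam_resolution
        f = calib.cam_focal_px
        origin = np.zeros(3)
        rot = np.eye(3)
    elif device == "projector":
        w, h = calib.proj_resolution
        f = calib.proj_focal_px
        origin = calib.proj_origin
        rot = calib.proj_rotation
    else:
        raise ValueError(f"unknown device {device!r}")
    if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
        raise ValueError(f"pixel ({x}, {y}) outside {device} resolution {w}x{h}")
    cx, cy = calib.principal(device)
    d = np.array([(x - cx) / f, (y - cy) / f, 1.0])
    d = rot @ d
    return origin, d / np.linalg.norm(d)


def _rays_to_point(o1, d1, o2, d2, min_denom: float = 1e-12):
    """Midpoint of the common perpendicular between two rays, plus the skew
    distance.  Returns None for near-parallel rays."""
    w0 = o1 - o2
    a = d1 @ d1
    b = d1 @ d2
    c = d2 @ d2
    denom = a * c - b * b
    if denom < min_denom:
        return None
    d = d1 @ w0
    e = d2 @ w0
    t = (b * e - c * d) / denom
    s = (a * e - b * d) / denom
    p1 = o1 + t * d1
    p2 = o2 + s * d2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def triangulate(corr: Correspondence, calib: CalibrationModel):
    """Triangulate one correspondence into a 3D point (cm, camera frame).

    Returns (point, skew_distance) or ``None`` when the rays are
    near-parallel or the intersection falls behind the camera.
    """
    o1, d1 = pixel_to_ray("camera", corr.image_point, calib)
    o2, d2 = pixel_to_ray("projector", corr.pattern_point, calib)
    res = _rays_to_point(o1, d1, o2, d2)
    if res is None:
        return None
    p, skew = res
    if p[2] <= 0:
        return None
    return p, skew


@dataclass
class PointCloud:
    """Triangulated 3D points (cm) with per-point provenance."""

    points: np.ndarray                     # (n, 3)
    skew_cm: np.ndarray                    # (n,) common-perpendicular lengths
    correspondences: list[Correspondence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


def triangulate_correspondences(correspondences: list[Correspondence],
                                calib: CalibrationModel,
                                max_skew_cm: float | None = None) -> PointCloud:
    """Triangulate a correspondence set, optionally gating on ray skew.

    The common-perpendicular length is ~0 for a geometrically consistent
    pair and grows with off-epipolar mismatch, so ``max_skew_cm`` acts as an
    outlier gate on wrongly decoded correspondences.
    """
    pts, skews, kept = [], [], []
    for corr in correspondences:
        res = triangulate(corr, calib)
        if res is None:
            continue
        p, skew = res
        if max_skew_cm is not None and skew > max_skew_cm:
            continue
        pts.append(p)
        skews.append(skew)
        kept.append(corr)
    return PointCloud(points=np.asarray(pts).reshape(-1, 3),
                      skew_cm=np.asarray(skews), correspondences=kept)


@dataclass
class Morphometrics:
    total_length_cm: float
    height_cm: float


def measure(cloud: PointCloud | np.ndarray,
            percentile: float | None = None) -> Morphometrics:
    """Principal-axis extents of a point cloud.

    Total length is the extent along the first principal axis of the point
    covariance, height along the second.  ``percentile`` switches the
    max-min extent to a (p, 100-p) percentile range for noisy clouds.
    Raises for fewer than 10 points or a degenerate (collinear) cloud.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else pts_arg(cloud)
    if len(pts) < 10:
        raise ValueError(f"need at least 10 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] < 1e-12 * max(evals[0], 1e-30):
        raise ValueError("degenerate (collinear) point cloud")
    proj = centered @ evecs[:, :2]
    if percentile is None:
        ext = proj.max(axis=0) - proj.min(axis=0)
    else:
        lo = np.percentile(proj, percentile, axis=0)
        hi = np.percentile(proj, 100.0 - percentile, axis=0)
        ext = hi - lo
    return Morphometrics(total_length_cm=float(ext[0]), height_cm=float(ext[1]))


def pts_arg(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected an (n, 3) point array")
    return a
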