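"""Synthetic capture simulator with exact ground truth.

Renders the camera's view of the pattern projected onto a parametric
surface (fronto-parallel plane or fusiform ellipsoid) by inverse ray
casting: for every camera pixel, the camera ray is intersected with the
surface and the hit point is mapped into projector pixel coordinates, where
the pattern raster is sampled.  Degradations mimic real captures: a
multiplicative illumination ramp, Gaussian defocus blur, and additive
Gaussian noise scaled to a target SNR (captures of live fish measure in the
13-16 dB range, so that is the default operating band).  Alongside the
image, the simulator emits per-pixel ground-truth depth and the true image
centroid of every projected symbol, which downstream metrics compare
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import CalibrationModel
from .pattern import PatternGrid, render_pattern, symbol_centroids

__all__ = [
    "SceneConfig",
    "RenderedScene",
    "render",
    "evaluate",
    "render_symbol_observation",
]

FOREGROUND_LEVEL = 230.0   # projected symbol intensity before degradation
BACKGROUND_LEVEL = 25.0    # lit background intensity


@dataclass
class SceneConfig:
    """Capture conditions for one synthetic scene.

    ``illumination_gradient`` g applies a horizontal multiplicative ramp
    from 1.0 at the left image edge down to 1/g at the right (g = 1 means
    uniform lighting, g = 2 the uneven-lighting comparison condition).
    ``snr_db`` of ``None`` disables noise; ``blur_sigma_px`` of 0 disables
    blur.  The surface is centered on the projector's optical axis at
    ``depth_cm`` so that both frusta cover it.
    """

    surface: str = "plane"                  # "plane" | "ellipsoid"
    depth_cm: float = 72.0
    plane_extent_cm: tuple[float, float] = (40.0, 30.0)
    ellipsoid_semiaxes_cm: tuple[float, float, float] = (15.0, 5.5, 2.0)
    snr_db: float | None = 13.68
    blur_sigma_px: float = 1.5
    illumination_gradient: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.snr_db is not None and self.snr_db <= 0:
            raise ValueError("snr_db must be positive (or None for noiseless)")
        if self.surface not in ("plane", "ellipsoid"):
            raise ValueError(f"unknown surface {self.surface!r}")


@dataclass
class RenderedScene:
    camera_image: np.ndarray                # (H, W) uint8
    gt_depth: np.ndarray                    # (H, W) float32, NaN off-surface
    # (row, col) -> dict(image_xy, pattern_xy, depth_cm)
    gt_correspondences: dict = field(default_factory=dict)
    config: SceneConfig = None
    calib: CalibrationModel = None
    grid: PatternGrid = None
    measured_snr_db: float | None = None

    def interior_symbols(self) -> set[tuple[int, int]]:
        """Ground-truth symbols whose 8 lattice neighbors are also rendered."""
        vis = set(self.gt_correspondences)
        return {
            (r, c) for (r, c) in vis
            if all((r + dr, c + dc) in vis
                   for dr in (-1, 0, 1) for dc in (-1, 0, 1))
        }


def _surface_center(config: SceneConfig, calib: CalibrationModel) -> np.ndarray:
    """Point where the projector's optical axis meets the z = depth plane."""
    th = np.radians(calib.convergence_deg)
    x = calib.baseline_cm - config.depth_cm * np.tan(th)
    return np.array([x, 0.0, config.depth_cm])


def _intersect(config: SceneConfig, calib: CalibrationModel,
               origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Ray-surface intersection for a batch of rays.

    ``origins`` (n, 3), ``dirs`` (n, 3); returns (n, 3) hit points with NaN
    rows where the ray misses the surface.
    """
    n = dirs.shape[0]
    hits = np.full((n, 3), np.nan)
    cx, cy, cz = _surface_center(config, calib)
    if config.surface == "plane":
        dz = dirs[:, 2]
        ok = dz > 1e-12
        t = np.where(ok, (config.depth_cm - origins[:, 2]) / np.where(ok, dz, 1.0), np.nan)
        p = origins + t[:, None] * dirs
        half_w, half_h = config.plane_extent_cm[0] / 2, config.plane_extent_cm[1] / 2
        inside = ok & (np.abs(p[:, 0] - cx) <= half_w) & (np.abs(p[:, 1] - cy) <= half_h)
        hits[inside] = p[inside]
        return hits
    # ellipsoid centered one semi-axis behind the nominal depth so its front
    # surface starts at depth_cm
    a, b, c = config.ellipsoid_semiaxes_cm
    center = np.array([cx, cy, config.depth_cm + c])
    scale = np.array([a, b, c])
    o = (origins - center) / scale
    d = dirs / scale
    A = (d * d).sum(axis=1)
    B = 2.0 * (o * d).sum(axis=1)
    C = (o * o).sum(axis=1) - 1.0
    disc = B * B - 4 * A * C
    ok = disc >= 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t = (-B - sq) / (2 * A)       # nearer root: front surface
    ok &= t > 0
    p = origins + t[:, None] * dirs
    hits[ok] = p[ok]
    return hits


def _project_to_device(points: np.ndarray, device: str,
                       calib: CalibrationModel) -> np.ndarray:
    """World points -> (x, y) pixel coordinates of a device (NaN-safe)."""
    if device == "camera":
        local = points
        f = calib.cam_focal_px
    else:
        local = (points - calib.proj_origin) @ calib.proj_rotation
        f = calib.proj_focal_px
    cx, cy = calib.principal(device)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = f * local[:, 0] / local[:, 2] + cx
        y = f * local[:, 1] / local[:, 2] + cy
    return np.column_stack([x, y])


def render(config: SceneConfig, grid: PatternGrid,
           calib: CalibrationModel) -> RenderedScene:
    """Render one synthetic capture with full ground truth."""
    W, H = calib.cam_resolution
    pw, ph = calib.proj_resolution
    pattern = render_pattern(grid, pw, ph)

    # camera rays through every pixel
    cx, cy = calib.principal("camera")
    f = calib.cam_focal_px
    xs, ys = np.meshgrid(np.arange(W), np.arange(H))
    dirs = np.column_stack([
        ((xs - cx) / f).ravel(), ((ys - cy) / f).ravel(),
        np.ones(W * H),
    ])
    origins = np.zeros_like(dirs)
    hits = _intersect(config, calib, origins, dirs)
    on_surface = ~np.isnan(hits[:, 2])

    gt_depth = np.full(W * H, np.nan, dtype=np.float32)
    gt_depth[on_surface] = hits[on_surface, 2]
    gt_depth = gt_depth.reshape(H, W)

    # map the hit points into the projector and sample the pattern
    proj_px = _project_to_device(hits, "projector", calib)
    img = np.zeros(W * H, dtype=np.float64)
    finite = np.isfinite(proj_px[:, 0]) & np.isfinite(proj_px[:, 1])
    px = np.rint(np.where(finite, proj_px[:, 0], -1)).astype(np.int64)
    py = np.rint(np.where(finite, proj_px[:, 1], -1)).astype(np.int64)
    lit = on_surface & (px >= 0) & (px < pw) & (py >= 0) & (py < ph)
    fg = np.zeros(W * H, dtype=bool)
    fg[lit] = pattern[py[lit], px[lit]]
    img[lit & ~fg] = BACKGROUND_LEVEL
    img[fg] = FOREGROUND_LEVEL
    img = img.reshape(H, W)

    g = config.illumination_gradient
    if g != 1.0:
        ramp = np.linspace(1.0, 1.0 / g, W)
        img = img * ramp[None, :]
    if config.blur_sigma_px > 0:
        img = gaussian_filter(img, config.blur_sigma_px)

    measured_snr = None
    if config.snr_db is not None:
        rng = np.random.default_rng(config.seed)
        p_signal = img.var()
        sigma = np.sqrt(p_signal / 10.0 ** (config.snr_db / 10.0))
        noise = rng.normal(0.0, sigma, img.shape)
        measured_snr = float(10.0 * np.log10(p_signal / noise.var()))
        img = img + noise
    camera_image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # ground-truth correspondences: cast the projector ray of each rendered
    # symbol centroid and project its surface hit into the camera
    pat_cents = symbol_centroids(grid, pw, ph)        # (rows, cols, 2) x,y
    flat = pat_cents.reshape(-1, 2)
    pcx, pcy = calib.principal("projector")
    pf = calib.proj_focal_px
    pdirs_local = np.column_stack([
        (flat[:, 0] - pcx) / pf, (flat[:, 1] - pcy) / pf, np.ones(len(flat)),
    ])
    pdirs = pdirs_local @ calib.proj_rotation.T
    porig = np.broadcast_to(calib.proj_origin, pdirs.shape).copy()
    phits = _intersect(config, calib, porig, pdirs)
    cam_px = _project_to_device(phits, "camera", calib)
    gt_correspondences = {}
    for k in range(len(flat)):
        if np.isnan(phits[k, 2]):
            continue
        x, y = cam_px[k]
        if not (0 <= x <= W - 1 and 0 <= y <= H - 1):
            continue
        r, c = divmod(k, grid.cols)
        gt_correspondences[(r, c)] = {
            "image_xy": (float(x), float(y)),
            "pattern_xy": (float(flat[k, 0]), float(flat[k, 1])),
            "depth_cm": float(phits[k, 2]),
        }

    return RenderedScene(camera_image=camera_image, gt_depth=gt_depth,
                         gt_correspondences=gt_correspondences,
                         config=config, calib=calib, grid=grid,
                         measured_snr_db=measured_snr)


def evaluate(correspondences, scene: RenderedScene,
             cloud=None) -> dict:
    """Score decoded correspondences against scene ground truth.

    A decoded symbol is matched to the ground-truth symbol with the nearest
    true image centroid; the match is false when the decoded lattice
    position disagrees with that symbol's true position.  Reported metrics:
    overall and interior decode rates, false-match rate, mean centroid
    error (px) and, when a triangulated cloud is supplied, depth RMSE (cm).
    """
    from scipy.spatial import cKDTree

    gt = scene.gt_correspondences
    if not gt:
        raise ValueError("scene has no ground-truth symbols")
    gt_keys = list(gt)
    gt_xy = np.asarray([gt[k]["image_xy"] for k in gt_keys])
    tree = cKDTree(gt_xy)
    interior = scene.interior_symbols()

    decoded_true: set[tuple[int, int]] = set()
    false_matches = 0
    cent_err = []
    for corr in correspondences:
        d, i = tree.query(corr.image_point)
        true_pos = gt_keys[int(i)]
        if corr.grid_pos == true_pos:
            decoded_true.add(true_pos)
            cent_err.append(d)
        else:
            false_matches += 1
    n_dec = len(correspondences)
    metrics = {
        "n_gt_symbols": len(gt_keys),
        "n_interior_gt": len(interior),
        "n_decoded": n_dec,
        "decode_rate": len(decoded_true) / len(gt_keys),
        "interior_decode_rate": (
            len(decoded_true & interior) / len(interior) if interior else float("nan")),
        "false_match_rate": false_matches / n_dec if n_dec else 0.0,
        "mean_centroid_error_px": float(np.mean(cent_err)) if cent_err else float("nan"),
    }
    if cloud is not None and len(cloud):
        errs = []
        for p, corr in zip(cloud.points, cloud.correspondences):
            if corr.grid_pos in gt:
                errs.append(p[2] - gt[corr.grid_pos]["depth_cm"])
        metrics["depth_rmse_cm"] = float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")
        metrics["depth_range_cm"] = (float(cloud.points[:, 2].min()),
                                     float(cloud.points[:, 2].max()))
    return metrics


def render_symbol_observation(class_id: int, theta: float, scale: float,
                              snr_db: float | None = None, seed: int = 0,
                              canvas: int = 72) -> np.ndarray:
    """Grayscale observation of a single rotated/scaled symbol.

    Utility for classifier studies: draws one symbol (foreground 230 on
    background 25) rotated by ``theta`` degrees and scaled by ``scale`` on a
    square canvas, optionally adding Gaussian noise at the given SNR.
    """
    from .classify import crop_to_bbox, rotate_raster, scale_to_bbox
    from .pattern import build_symbol_rasters

    ras = build_symbol_rasters()[class_id]
    m = crop_to_bbox(rotate_raster(ras, theta))
    h = max(3, round(m.shape[0] * scale))
    w = max(3, round(m.shape[1] * scale))
    m = scale_to_bbox(m, h, w)
    if h > canvas or w > canvas:
        raise ValueError("symbol larger than canvas")
    img = np.full((canvas, canvas), BACKGROUND_LEVEL)
    top, left = (canvas - h) // 2, (canvas - w) // 2
    img[top:top + h, left:left + w][m] = FOREGROUND_LEVEL
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(img.var() / 10.0 ** (snr_db / 10.0))
        img = img + rng.normal(0.0, sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
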