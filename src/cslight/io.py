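"""File-format plumbing: images, CSV tables, PLY/XYZ clouds, depth maps."""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "write_mask_png",
    "write_pgm",
    "write_components_csv",
    "write_classifications_csv",
    "write_correspondences_csv",
    "write_ply",
    "write_xyz",
    "write_depth_csv",
    "render_depth_png",
]


def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB raster (PNG/PGM/TIFF)."""
    img = iio.imread(path)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_mask_png(path, mask: np.ndarray) -> None:
    """Binary mask as an 8-bit black/white PNG."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def write_pgm(path, image: np.ndarray) -> None:
    """Binary (P5) PGM writer; masks are scaled to 0/255."""
    img = np.asarray(image)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    img = img.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(f"P5\n{img.shape[1]} {img.shape[0]}\n255\n".encode())
        fh.write(img.tobytes())


def read_pgm(path) -> np.ndarray:
    return read_image(path)


def _write_csv(path, header, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_components_csv(path, components) -> None:
    _write_csv(path,
               ["id", "area", "centroid_r", "centroid_c",
                "bbox_top", "bbox_left", "bbox_bottom", "bbox_right"],
               [(c.id, c.area, f"{c.centroid[0]:.3f}", f"{c.centroid[1]:.3f}",
                 *c.bbox) for c in components])


def write_classifications_csv(path, results) -> None:
    _write_csv(path,
               ["component_id", "class", "dissimilarity", "best_angle"],
               [(r.component.id, r.assigned_class,
                 f"{r.dissimilarity:.4f}", r.best_angle) for r in results])


def write_subpatterns_csv(path, candidates) -> None:
    rows = []
    for cand in candidates:
        members = ([m.id for row in cand.arrangement for m in row]
                   if cand.valid else [""] * 9)
        rows.append((cand.center.id, *members, int(cand.valid),
                     cand.failure_reason))
    _write_csv(path,
               ["center_id", *[f"member_{i}" for i in range(9)],
                "valid", "failure_reason"], rows)


def write_correspondences_csv(path, correspondences) -> None:
    _write_csv(path,
               ["pattern_x", "pattern_y", "image_x", "image_y",
                "grid_row", "grid_col", "best_hd"],
               [(f"{c.pattern_point[0]:.3f}", f"{c.pattern_point[1]:.3f}",
                 f"{c.image_point[0]:.3f}", f"{c.image_point[1]:.3f}",
                 c.grid_pos[0], c.grid_pos[1], c.best_hd)
                for c in correspondences])


def write_ply(path, points: np.ndarray) -> None:
    """ASCII PLY point-cloud writer."""
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def write_xyz(path, points: np.ndarray) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.6f")


def write_depth_csv(path, correspondences, cloud) -> None:
    """Sparse depth samples at decoded symbol image positions."""
    rows = [(f"{c.image_point[0]:.3f}", f"{c.image_point[1]:.3f}",
             f"{p[2]:.4f}") for c, p in zip(cloud.correspondences, cloud.points)]
    _write_csv(path, ["image_x", "image_y", "depth_cm"], rows)


def render_depth_png(path, cloud, point_size: float = 8.0) -> None:
    """Scatter depth map with a color bar (matplotlib Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [c.image_point[0] for c in cloud.correspondences]
    ys = [c.image_point[1] for c in cloud.correspondences]
    zs = cloud.points[:, 2]
    fig, ax = plt.subplots(figsize=(8, 6))
    sc = ax.scatter(xs, ys, c=zs, s=point_size, cmap="viridis")
    ax.invert_yaxis()
    ax.set_xlabel("image x (px)")
    ax.set_ylabel("image y (px)")
    fig.colorbar(sc, ax=ax, label="depth (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
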