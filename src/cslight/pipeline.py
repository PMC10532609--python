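"""End-to-end decoding pipeline: image -> correspondences -> point cloud."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import binarize, geometry, topology
from .classify import ClassifierConfig, classify_all
from .decode import extract_correspondences, propagate_corrections
from .pattern import CodewordBook, PatternGrid, build_codeword_book

__all__ = ["PipelineParams", "PipelineResult", "reconstruct_image"]

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable knobs of the decoding pipeline (defaults follow the method)."""

    sauvola_window: int = 31
    sauvola_k: float = 0.1
    sauvola_r: float = 128.0
    sauvola_min_std: float = 25.0   # noise-floor guard for signal-free regions
    min_component_area: int = 50
    max_component_area: int | None = 5000   # reject merged/percolated blobs
    max_skew_cm: float | None = 0.05        # triangulation ray-skew outlier gate
    use_otsu: bool = False                  # comparison mode


@dataclass
class PipelineResult:
    mask: np.ndarray
    components: list
    classifications: list
    candidates: list
    decoded: list
    correspondences: list
    cloud: geometry.PointCloud | None
    conflicts: list
    stage_counts: dict = field(default_factory=dict)


def reconstruct_image(image: np.ndarray, grid: PatternGrid,
                      calib: geometry.CalibrationModel,
                      params: PipelineParams | None = None,
                      book: CodewordBook | None = None,
                      classifier: classify.ClassifierConfig | None = None,
                      triangulate: bool = True) -> PipelineResult:
    """Run the full decode on a captured (or simulated) image.

    Stages: grayscale -> adaptive binarization -> component extraction ->
    symbol classification -> subpattern assembly -> codeword decoding with
    correction propagation -> correspondence extraction -> triangulation.
    """
    params = params or PipelineParams()
    gray = binarize.to_grayscale(image)
    if params.use_otsu:
        mask = binarize.otsu_binarize(gray)
    else:
        mask = binarize.sauvola_binarize(gray, window=params.sauvola_window,
                                         k=params.sauvola_k, r=params.sauvola_r,
                                         min_std=params.sauvola_min_std)
    components = binarize.extract_components(
        mask, min_area=params.min_component_area,
        max_area=params.max_component_area)
    log.info("components found: %d", len(components))

    classifier = classifier or ClassifierConfig()
    classifications = classify_all(components, classifier)
    labels = {r.component.id: r.assigned_class for r in classifications}

    candidates = topology.extract_candidates(components)
    n_valid = sum(c.valid for c in candidates)
    log.info("subpattern candidates: %d (%d valid)", len(candidates), n_valid)

    if book is None:
        book = build_codeword_book(grid)
    decoded, final_labels, conflicts = propagate_corrections(
        candidates, book, labels)
    log.info("codewords decoded: %d (%d corrections in conflict)",
             len(decoded), len(conflicts))

    pw, ph = calib.proj_resolution
    correspondences = extract_correspondences(decoded, grid, pw, ph)
    log.info("correspondences: %d", len(correspondences))

    cloud = None
    if triangulate and correspondences:
        cloud = geometry.triangulate_correspondences(
            correspondences, calib, max_skew_cm=params.max_skew_cm)
        log.info("points triangulated: %d", len(cloud))

    stage_counts = {
        "symbols_in_image": len(components),
        "valid_codewords": len(decoded),
        "corresponding_points": len(correspondences),
    }
    return PipelineResult(
        mask=mask, components=components, classifications=classifications,
        candidates=candidates, decoded=decoded,
        correspondences=correspondences, cloud=cloud, conflicts=conflicts,
        stage_counts=stage_counts,
    )
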