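import numpy as np
import pytest

from cslight.classify import ClassifierConfig
from cslight.geometry import CalibrationModel
from cslight.pattern import build_symbol_rasters, default_pattern, generate_pattern


@pytest.fixture(scope="session")
def rasters():
    return build_symbol_rasters()


@pytest.fixture(scope="session")
def small_grid():
    """10x10 lattice: 64 subpatterns, cheap to scan exhaustively."""
    return generate_pattern(10, 10, seed=1)


@pytest.fixture(scope="session")
def full_grid():
    """The default 76x43-symbol projector pattern."""
    return default_pattern(seed=0)


@pytest.fixture(scope="session")
def classifier():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def calib():
    return CalibrationModel()


def make_component(i, r, c, mask=None):
    """Synthetic detected component at a given centroid, for topology tests."""
    from cslight.binarize import DetectedComponent

    if mask is None:
        mask = np.ones((3, 3), dtype=bool)
    return DetectedComponent(id=i, area=int(mask.sum()), centroid=(float(r), float(c)),
                             bbox=(0, 0, mask.shape[0] - 1, mask.shape[1] - 1),
                             mask=mask)


def lattice_components(rows, cols, pitch=25.0, jitter=0.0, rng=None):
    """Regular (optionally jittered) centroid lattice of fake components."""
    comps = []
    truth = {}
    for r in range(rows):
        for c in range(cols):
            rr, cc = r * pitch, c * pitch
            if jitter > 0:
                rr += rng.normal(0.0, jitter * pitch)
                cc += rng.normal(0.0, jitter * pitch)
            comp = make_component(len(comps), rr, cc)
            comps.append(comp)
            truth[comp.id] = (r, c)
    return comps, truth
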