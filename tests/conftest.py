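import numpy as np
import pytest

from kneekl.model import BranchSpec, build
from kneekl.patches import PatchGeometry, PatchPair
from kneekl.preprocess import KneeROI, NormalizedImage


@pytest.fixture
def default_geom() -> PatchGeometry:
    return PatchGeometry.default()


@pytest.fixture
def tiny_spec() -> BranchSpec:
    """A branch small enough for exhaustive numeric checks (2x2 pre-GAP maps at 40 px)."""
    return BranchSpec(widths=(3, 3, 4, 4, 4), pool_after=frozenset({2}))


@pytest.fixture
def tiny_geom() -> PatchGeometry:
    return PatchGeometry(resized_px=40, S=40, K=0,
                         lateral_origin=(0, 0), medial_origin=(0, 0))


@pytest.fixture
def tiny_net(tiny_spec):
    return build(tiny_spec, dropout=0.0, input_px=40, seed=7)


@pytest.fixture
def tiny_pair(tiny_geom) -> PatchPair:
    rng = np.random.default_rng(11)
    return PatchPair(rng.uniform(0, 255, (40, 40)), rng.uniform(0, 255, (40, 40)),
                     tiny_geom)


@pytest.fixture
def random_roi() -> KneeROI:
    rng = np.random.default_rng(3)
    pixels = rng.integers(500, 30_000, size=(280, 280)).astype(np.uint16)
    return KneeROI(pixels=pixels, spacing_mm=0.5, side="right", kl_grade=2,
                   source_id="fixture")


@pytest.fixture
def ramp_image() -> NormalizedImage:
    """8-bit horizontal ramp, 280 px at 0.5 mm/px (140 mm extent)."""
    col = np.clip(np.arange(280) * 255 / 279, 0, 255)
    pixels = np.tile(np.rint(col).astype(np.uint8), (280, 1))
    return NormalizedImage(pixels=pixels, spacing_mm=0.5, source_id="ramp")
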