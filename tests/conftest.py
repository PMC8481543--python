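"""Shared fixtures: small hand-built layers with known geometry."""

import pytest
from shapely.geometry import box

from fireselect import OwnershipLayer, StudyArea, VegetationLayer


@pytest.fixture
def study_20km() -> StudyArea:
    return StudyArea(boundary=box(0.0, 0.0, 20_000.0, 20_000.0))


@pytest.fixture
def halves_ownership() -> OwnershipLayer:
    """Two classes splitting the 20 km square left/right."""
    return OwnershipLayer.from_pairs(
        [
            (box(0.0, 0.0, 10_000.0, 20_000.0), "A"),
            (box(10_000.0, 0.0, 20_000.0, 20_000.0), "B"),
        ]
    )


@pytest.fixture
def all_burnable_veg() -> VegetationLayer:
    return VegetationLayer(
        patches=((box(0.0, 0.0, 20_000.0, 20_000.0), "forest"),)
    )
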