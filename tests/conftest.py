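import math

import pytest

from tractomics.phantom import (
    CrossingSpec,
    PhantomConfig,
    ROISpec,
    TractSpec,
    generate_bundle,
    make_phantom,
)
from tractomics.volume import AffineTransform


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic bundle (phantom, samples, expression, PPI)."""
    return generate_bundle(seed=0)


def straight_tube_config(kappa: float = math.inf) -> PhantomConfig:
    """Single straight tube along +x between two same-hemisphere ROIs."""
    return PhantomConfig(
        shape=(24, 10, 10),
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
        rois=[
            ROISpec("seed_left", "left", (4.0, 5.0, 5.0), 2.0),
            ROISpec("target_left", "left", (20.0, 5.0, 5.0), 2.0),
        ],
        tracts=[
            TractSpec(
                seed_roi="seed_left",
                target_roi="target_left",
                control_points=((4.0, 5.0, 5.0), (20.0, 5.0, 5.0)),
                tube_radius=2.0,
                fiber_fraction=0.8,
                kappa=kappa,
            )
        ],
        crossings=[],
    )


@pytest.fixture
def straight_tube_phantom():
    return make_phantom(straight_tube_config())


def crossing_config(kappa: float = math.inf) -> PhantomConfig:
    """Two straight tubes crossing at ~53 degrees with a crossing box.

    Tube A runs (3, 6) -> (21, 15) in the x-y plane, tube B
    (3, 15) -> (21, 6); they intersect near (12, 10.5).  In the box the
    two populations carry fractions 0.5 (A) and 0.4 (B) so a
    single-population reduction keeps A's axis.
    """
    na = 1.0 / math.sqrt(18**2 + 9**2)
    dir_a = (18 * na, 9 * na, 0.0)
    dir_b = (18 * na, -9 * na, 0.0)
    return PhantomConfig(
        shape=(24, 21, 9),
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
        rois=[
            ROISpec("seed_a_left", "left", (3.0, 6.0, 4.5), 1.0),
            ROISpec("target_a_left", "left", (21.0, 15.0, 4.5), 2.0),
            ROISpec("seed_b_left", "left", (3.0, 15.0, 4.5), 1.0),
            ROISpec("target_b_left", "left", (21.0, 6.0, 4.5), 2.0),
        ],
        tracts=[
            TractSpec(
                seed_roi="seed_a_left",
                target_roi="target_a_left",
                control_points=((3.0, 6.0, 4.5), (21.0, 15.0, 4.5)),
                tube_radius=1.5,
                fiber_fraction=0.5,
                kappa=kappa,
            ),
            TractSpec(
                seed_roi="seed_b_left",
                target_roi="target_b_left",
                control_points=((3.0, 15.0, 4.5), (21.0, 6.0, 4.5)),
                tube_radius=1.5,
                fiber_fraction=0.4,
                kappa=kappa,
            ),
        ],
        crossings=[
            CrossingSpec(
                box_min=(9, 8, 2),
                box_max=(16, 14, 7),
                direction_a=dir_a,
                direction_b=dir_b,
                fraction_a=0.5,
                fraction_b=0.4,
                kappa=kappa,
            )
        ],
    )


@pytest.fixture
def crossing_phantom():
    return make_phantom(crossing_config())


@pytest.fixture
def identity_affine():
    return AffineTransform.identity()
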