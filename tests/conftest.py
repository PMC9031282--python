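"""Shared fixtures: small axes and synthetic datasets reused across tests.

Most tests run on a 300-channel axis spanning the same 466-1667 cm^-1 range
as the emulated instrument; the full 1022-channel grid is reserved for the
few tests whose contract depends on it.
"""

import numpy as np
import pytest

import ramancellmap as rm


@pytest.fixture(scope="session")
def axis_small() -> rm.SpectralAxis:
    return rm.make_axis(466.0, 1667.0, 300)


@pytest.fixture(scope="session")
def axis_default() -> rm.SpectralAxis:
    return rm.default_axis()


@pytest.fixture(scope="session")
def melanoma_set_small(axis_small) -> rm.LabeledSpectraSet:
    """Raw (contaminated) two-class set on the small axis, 80 per class."""
    return rm.make_labeled_classes(
        80, 80, rm.MELANOMA_EFFECT, rm.melanoma_noise(seed=7), seed=7, axis=axis_small
    )


@pytest.fixture(scope="session")
def melanoma_purified_small(melanoma_set_small) -> rm.LabeledSpectraSet:
    return rm.purify_set(melanoma_set_small)


@pytest.fixture(scope="session")
def two_cell_cube(axis_small):
    """Observed + truth cubes and the scene for a two-cell 31x43 map."""
    scene = rm.make_scene(31, 43, 2, seed=3)
    components = rm.melanoma_components(axis_small)
    observed, truth = rm.render_cube(scene, components, rm.melanoma_noise(seed=3))
    return scene, observed, truth


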