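"""Shared fixtures: phantom subjects and the session-wide trained model.

The trained CNN and the validation threshold sweeps are expensive, so they
are session-scoped and built lazily on first use.
"""

from __future__ import annotations

import numpy as np
import pytest

from pmihub.phantom import PhantomSpec, analysis_spec, make_phantom
from pmihub.pipeline import choose_threshold, train_default_model


@pytest.fixture(scope="session")
def trained_model():
    """The patch CNN trained under the package's standard phantom conditions."""
    model = train_default_model(seed=0)
    assert model.report is not None
    return model


@pytest.fixture(scope="session")
def threshold_selections(trained_model):
    """Validation threshold sweeps for three independent validation seeds."""
    return [choose_threshold(trained_model, seed=s) for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def working_threshold(threshold_selections):
    return threshold_selections[0][0]


@pytest.fixture()
def tiny_subject():
    """A small, quick phantom subject (noise-free, vasogenic)."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        core_radius_vox=3.0,
        edema_thickness_vox=8.0,
        phenotype="vasogenic",
        noise_sd=0.0,
        center_jitter_vox=1.0,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture()
def tiny_infiltrative():
    """A small infiltrative phantom with a handful of pockets, no noise."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        core_radius_vox=3.0,
        edema_thickness_vox=8.0,
        phenotype="infiltrative",
        pocket_count=3,
        pocket_radius_vox=1.5,
        noise_sd=0.0,
        center_jitter_vox=1.0,
        seed=11,
    )
    return make_phantom(spec)


@pytest.fixture()
def analysis_subject():
    """One analysis-condition infiltrative subject (full size)."""
    return make_phantom(analysis_spec("infiltrative", seed=4242))
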