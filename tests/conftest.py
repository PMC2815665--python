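"""Shared fixtures: one small synthetic experiment reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from rotred.calib import defpix, detector_noise, gain_table, initial_background
from rotred.simulate import GroundTruth, default_experiment, make_intensities, render_stack


@pytest.fixture(scope="session")
def baseline_models():
    return default_experiment(orientation_seed=7)


@pytest.fixture(scope="session")
def stack(baseline_models):
    """40-frame orthorhombic stack with beamstop shadow and its manifest."""
    models = baseline_models
    truth = GroundTruth(
        models,
        make_intensities(models, (20.0, 2.6), mean_intensity=8000.0, seed=3),
        background_level=20.0,
        shadow=(127.5, 127.5, 10.0),
        resolution_range=(20.0, 2.6),
        seed=11,
    )
    frames, manifest = render_stack(truth, 40)
    return frames, manifest, truth


@pytest.fixture(scope="session")
def tables(stack, baseline_models):
    """BLANK/GAIN/BKGINIT/BKGPIX tables of the shared stack."""
    frames, _, _ = stack
    blank = detector_noise(data_images=frames[:2])
    gain = gain_table(frames[:5], blank)
    bkginit = initial_background(frames[:5], blank, gain)
    bkgpix, abs_img = defpix(bkginit, baseline_models.detector, 1.0)
    return {"blank": blank, "gain": gain, "bkginit": bkginit, "bkgpix": bkgpix, "abs": abs_img}


@pytest.fixture(scope="session")
def found_spots(stack, tables):
    from rotred.spotfind import find_spots

    frames, _, _ = stack
    return find_spots(frames, 1, tables["bkgpix"], tables["gain"])


@pytest.fixture(scope="session")
def idxref_result(baseline_models, found_spots):
    from rotred.indexing import run_idxref

    blind = baseline_models.copy()
    blind.crystal = None
    return run_idxref(blind, found_spots)


@pytest.fixture(scope="session")
def integration(stack, tables, idxref_result):
    from rotred.integrate import integrate_range

    frames, _, _ = stack
    return integrate_range(
        frames, idxref_result.models, tables["bkgpix"], tables["gain"],
        resolution_range=(20.0, 2.6), spots_for_shape=idxref_result.spots,
    )


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
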