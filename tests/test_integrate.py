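"""Profile-fitting integration."""

import numpy as np
import pytest

from rotred.integrate import (
    GRID_DIMS,
    IntegrationDomain,
    MappedObservation,
    ProfileFitError,
    ProfileGrid,
    estimate_spot_shape,
    fit_profile,
    learn_templates,
)
from rotred.validate import match_intensities


def _gaussian_grid(sigma_vox=1.2, dims=GRID_DIMS):
    n3, n2, n1 = dims
    z, y, x = np.mgrid[0:n3, 0:n2, 0:n1]
    c = ((x - (n1 - 1) / 2) ** 2 + (y - (n2 - 1) / 2) ** 2 + (z - (n3 - 1) / 2) ** 2)
    return np.exp(-c / (2 * sigma_vox**2))


def _obs_from(counts, weight=None, background=0.0, bg_var=1.0):
    w = np.ones_like(counts) if weight is None else weight
    return MappedObservation(counts=counts + background * w, weight=w,
                             background=background, bg_variance=bg_var, spilled=0.0,
                             n_pixels=float(counts.size))


def test_template_mask_respects_cut():
    g = _gaussian_grid()
    tpl = ProfileGrid.from_counts(g, cut_percent=2.0)
    assert tpl.support_mask.any()
    assert tpl.values[tpl.support_mask].min() > 0
    # cut = 0 keeps every positive voxel
    tpl0 = ProfileGrid.from_counts(g, cut_percent=0.0)
    assert tpl0.support_mask.sum() == (g > 0).sum()


def test_noiseless_fit_is_exact_fixed_point():
    g = _gaussian_grid()
    tpl = ProfileGrid.from_counts(g, 2.0)
    i0 = 5000.0
    obs = _obs_from(i0 * tpl.values)
    intensity, variance, partiality = fit_profile(obs, tpl, minpk=50.0)
    np.testing.assert_allclose(intensity, i0, rtol=1e-9)
    assert partiality > 0.9


def test_fit_monte_carlo_mean_and_variance():
    """Poisson replicates: mean within 1%, empirical vs reported variance
    within 20%."""
    rng = np.random.default_rng(0)
    g = _gaussian_grid()
    tpl = ProfileGrid.from_counts(g, 2.0)
    i0, bg = 10_000.0, 5.0
    fitted, reported = [], []
    for _ in range(300):
        lam = i0 * tpl.values + bg
        counts = rng.poisson(lam).astype(float)
        obs = MappedObservation(counts=counts, weight=np.ones_like(counts),
                                background=bg, bg_variance=bg, spilled=0.0,
                                n_pixels=float(counts.size))
        intensity, variance, _ = fit_profile(obs, tpl, minpk=50.0)
        fitted.append(intensity)
        reported.append(variance)
    fitted = np.array(fitted)
    assert abs(fitted.mean() - i0) / i0 < 0.01
    assert abs(fitted.var(ddof=1) / np.mean(reported) - 1.0) < 0.2


def test_minpk_threshold_bracketing():
    g = _gaussian_grid()
    tpl = ProfileGrid.from_counts(g, 2.0)
    weight = np.zeros_like(g)
    # cover ~60% of the template mass
    order = np.argsort(tpl.values.ravel())[::-1]
    cum = np.cumsum(tpl.values.ravel()[order])
    keep = order[cum <= 0.60]
    weight.ravel()[keep] = 1.0
    obs = MappedObservation(counts=1000 * tpl.values * weight, weight=weight,
                            background=0.0, bg_variance=1.0, spilled=0.0, n_pixels=10)
    with pytest.raises(ProfileFitError, match="MINPK"):
        fit_profile(obs, tpl, minpk=75.0)
    intensity, _, partiality = fit_profile(obs, tpl, minpk=50.0)
    assert 0.5 < partiality < 0.75
    assert intensity > 0


def test_minpk_monotone_subset(integration, stack, tables, idxref_result):
    """Records kept at a stricter MINPK are a subset of the looser run."""
    from rotred.integrate import integrate_range

    frames, _, _ = stack
    loose = integrate_range(frames, idxref_result.models, tables["bkgpix"], tables["gain"],
                            resolution_range=(20, 2.6), minpk=50.0)
    strict = integrate_range(frames, idxref_result.models, tables["bkgpix"], tables["gain"],
                             resolution_range=(20, 2.6), minpk=90.0)
    loose_keys = {(r.hkl, round(r.zd, 2)) for r in loose.records}
    strict_keys = {(r.hkl, round(r.zd, 2)) for r in strict.records}
    assert strict_keys <= loose_keys


def test_nine_templates_per_batch(integration):
    for batch, count in integration.n_templates_per_batch.items():
        if count:
            assert count == 9


def _shape_stack(sigma_M, sigma_D, delta_phi=0.5, n_frames=60):
    """Finely sliced stack so the rocking width is resolvable."""
    from rotred.calib import defpix, detector_noise, gain_table, initial_background
    from rotred.simulate import GroundTruth, default_experiment, make_intensities, render_stack
    from rotred.spotfind import find_spots

    m = default_experiment(orientation_seed=7, sigma_M=sigma_M, sigma_D=sigma_D)
    m.gonio.delta_phi = delta_phi
    truth = GroundTruth(m, make_intensities(m, (20, 2.6), 8000.0, seed=3),
                        background_level=20.0, resolution_range=(20, 2.6), seed=11)
    frames, _ = render_stack(truth, n_frames)
    blank = detector_noise(data_images=frames[:2])
    gain = gain_table(frames[:5], blank)
    bkginit = initial_background(frames[:5], blank, gain)
    bkgpix, _ = defpix(bkginit, m.detector, 1.0)
    return frames, find_spots(frames, 1, bkgpix, gain), m


def test_shape_estimate_recovers_generator_widths():
    frames, spots, models = _shape_stack(0.2, 0.3)
    domain = estimate_spot_shape(frames, spots, models)
    assert abs(domain.sigma_M - 0.2) / 0.2 < 0.15
    assert abs(domain.sigma_D - 0.3) / 0.3 < 0.15
    assert 6 <= domain.delta_M / domain.sigma_M <= 10
    assert 6 <= domain.delta_D / domain.sigma_D <= 10


def test_doubling_divergence_doubles_estimate():
    frames1, spots1, m1 = _shape_stack(0.2, 0.3)
    frames2, spots2, m2 = _shape_stack(0.2, 0.6)
    d1 = estimate_spot_shape(frames1, spots1, m1)
    d2 = estimate_spot_shape(frames2, spots2, m2)
    assert abs(d2.sigma_D / d1.sigma_D - 2.0) < 0.3


def test_user_override_takes_precedence(stack, found_spots, baseline_models):
    frames, _, _ = stack
    domain = estimate_spot_shape(frames, found_spots, baseline_models,
                                 user_delta_M=2.5, user_delta_D=1.25)
    assert domain.delta_M == 2.5 and domain.delta_D == 1.25


def test_too_few_spots_falls_back_to_model(stack, baseline_models):
    frames, _, _ = stack
    domain = estimate_spot_shape(frames, [], baseline_models)
    assert domain.sigma_M == baseline_models.crystal.sigma_M


def test_learned_templates_borrow_global_when_sparse():
    g = _gaussian_grid()
    obs = _obs_from(1000 * g / g.sum())
    templates = learn_templates([(4, obs)] * 12)  # only the centre region is populated
    assert len(templates) == 9
    np.testing.assert_allclose(templates[0].values, templates[8].values)


def test_intensity_recovery_against_manifest(integration, stack, idxref_result,
                                             baseline_models):
    _, manifest, _ = stack
    got, want = match_intensities(integration.records, manifest, idxref_result.models,
                                  baseline_models)
    assert len(got) > 100
    corr = np.corrcoef(got, want)[0, 1]
    assert corr > 0.99
    rel = np.median(np.abs(got - want) / np.maximum(want, 1.0))
    assert rel < 0.1


def test_integration_conserves_counts(integration, stack, idxref_result, baseline_models):
    """Fitted intensities track the summed deposited counts closely."""
    _, manifest, _ = stack
    got, want = match_intensities(integration.records, manifest, idxref_result.models,
                                  baseline_models)
    ratio = np.median(got / np.maximum(want, 1.0))
    assert abs(ratio - 1.0) < 0.05
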