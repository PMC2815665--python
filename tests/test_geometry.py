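"""Geometry: forward prediction, inverse mapping, Ewald frames, refinement."""

import numpy as np
import pytest

from rotred.geometry import (
    BeamModel,
    CrystalModel,
    DetectorModel,
    ExperimentModel,
    GoniometerModel,
    ewald_frame,
    pixel_to_lab,
    predict_reflections,
    refine_geometry,
    scattering_vector,
)


@pytest.fixture(scope="module")
def models():
    from rotred.simulate import default_experiment

    return default_experiment(orientation_seed=3)


@pytest.fixture(scope="module")
def predictions(models):
    return [p for p in predict_reflections(models, (1, 30), (20.0, 2.6)) if p.on_detector]


def test_origin_pixel_maps_to_normal_point(models):
    det = models.detector
    np.testing.assert_allclose(pixel_to_lab(det, det.orgx, det.orgy), det.distance * det.d3)


def test_unit_pixel_offset_moves_along_fast_axis(models):
    det = models.detector
    delta = pixel_to_lab(det, det.orgx + 1, det.orgy) - pixel_to_lab(det, det.orgx, det.orgy)
    np.testing.assert_allclose(delta, det.qx * det.d1, atol=1e-12)


def test_random_pixel_matches_affine_expansion(models):
    det = models.detector
    rng = np.random.default_rng(0)
    x, y = rng.uniform(0, 255, 2)
    expected = det.distance * det.d3 + (x - det.orgx) * det.qx * det.d1 + (y - det.orgy) * det.qy * det.d2
    np.testing.assert_allclose(pixel_to_lab(det, x, y), expected, atol=1e-12)


def test_forward_inverse_consistency(models, predictions):
    """Every prediction back-maps through scattering_vector to integer hkl."""
    for p in predictions[::7]:
        ps = scattering_vector(models, p.x, p.y, p.z)
        idx = np.linalg.solve(models.crystal.rec_basis.T, ps)
        assert np.abs(idx - np.array(p.hkl)).max() < 0.05


def test_direct_beam_centroid_flagged_zero(models):
    det = models.detector
    ps = scattering_vector(models, det.orgx, det.orgy, 5.0)
    assert np.linalg.norm(ps) < 1e-10


def test_full_turn_periodicity(models):
    frames_per_turn = 360.0 / models.gonio.delta_phi
    a = scattering_vector(models, 50.0, 80.0, 3.0)
    b = scattering_vector(models, 50.0, 80.0, 3.0 + frames_per_turn)
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_empty_prediction_range_is_not_an_error():
    # huge d_min excludes every reflection
    from rotred.simulate import default_experiment

    models = default_experiment()
    preds = predict_reflections(models, (1, 1), (20.0, 19.0))
    assert isinstance(preds, list)


def test_blind_region_excluded(models, predictions):
    # reflections whose p* is (anti)parallel to the axis never appear
    for p in predictions:
        ps = models.crystal.pstar(p.hkl)
        cos = abs(ps @ models.gonio.axis) / np.linalg.norm(ps)
        assert cos < 1.0 - 1e-9
        assert abs(p.zeta) >= 1e-6


def test_ewald_frame_orthogonality():
    rng = np.random.default_rng(1)
    s0 = np.array([0.0, 0.0, 1.0])
    for _ in range(20):
        s1 = rng.normal(size=3)
        s1 /= np.linalg.norm(s1)
        if np.linalg.norm(np.cross(s1, s0)) < 1e-6:
            continue
        e1, e2, e3 = ewald_frame(s1, s0)
        assert abs(e1 @ s1) < 1e-12
        assert abs(e2 @ s1) < 1e-12
        assert abs(np.linalg.norm(e3) - 1) < 1e-12


def test_ewald_frame_degenerate_forward_scattering():
    s0 = np.array([0.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="degenerate"):
        ewald_frame(s0.copy(), s0)


def test_refine_noiseless_is_fixed_point(models, predictions):
    hkls = np.array([p.hkl for p in predictions[:150]])
    xyz = np.array([[p.x, p.y, p.z] for p in predictions[:150]])
    refined, rms_xy, rms_z = refine_geometry(models, hkls, xyz, {"CELL", "ORIENTATION"})
    assert rms_xy < 1e-6 and rms_z < 1e-6
    np.testing.assert_allclose(refined.crystal.cell, models.crystal.cell, rtol=1e-6)


def test_refine_recovers_perturbed_cell(models, predictions):
    hkls = np.array([p.hkl for p in predictions[:200]])
    xyz = np.array([[p.x, p.y, p.z] for p in predictions[:200]])
    pert = models.copy()
    pert.crystal.rec_basis = pert.crystal.rec_basis * 1.01  # 1% cell error
    refined, _, _ = refine_geometry(pert, hkls, xyz, {"CELL", "ORIENTATION"})
    np.testing.assert_allclose(
        np.array(refined.crystal.cell[:3]), np.array(models.crystal.cell[:3]), rtol=5e-4
    )


def test_refine_empty_selection_returns_models_unchanged(models, predictions):
    hkls = np.array([p.hkl for p in predictions[:50]])
    xyz = np.array([[p.x, p.y, p.z] for p in predictions[:50]])
    refined, _, _ = refine_geometry(models, hkls, xyz, set())
    np.testing.assert_allclose(refined.crystal.rec_basis, models.crystal.rec_basis)


def test_refine_never_worsens_residuals(models, predictions):
    rng = np.random.default_rng(2)
    hkls = np.array([p.hkl for p in predictions[:150]])
    xyz = np.array([[p.x, p.y, p.z] for p in predictions[:150]])
    noisy = xyz + rng.normal(0, 0.5, xyz.shape)
    _, rms0_xy, rms0_z = refine_geometry(models, hkls, noisy, set())
    _, rms_xy, rms_z = refine_geometry(models, hkls, noisy, {"CELL", "ORIENTATION", "BEAM", "ORGXY"})
    assert rms_xy <= rms0_xy + 1e-9


def test_unknown_refinement_class_rejected(models, predictions):
    hkls = np.array([p.hkl for p in predictions[:50]])
    xyz = np.array([[p.x, p.y, p.z] for p in predictions[:50]])
    with pytest.raises(ValueError, match="unknown refinement"):
        refine_geometry(models, hkls, xyz, {"WAVELENGTH"})
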