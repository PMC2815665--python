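"""Correction stage: filters, physical factors, symmetry, scaling, statistics."""

import math

import gemmi
import numpy as np
import pytest

from rotred.correct import (
    accept_reflections,
    consistent_lattices,
    correction_factors,
    fit_correction_surfaces,
    fit_variance_model,
    flag_outliers,
    propose_space_group,
    r_factors,
    compute_statistics,
    symmetry_key,
)
from rotred.files import ReflectionRecord
from rotred.geometry import cell_to_reciprocal_basis
from rotred.simulate import default_experiment

CELL_TET = (17.0, 17.0, 24.0, 90.0, 90.0, 90.0)
OPS422 = gemmi.SpaceGroup(89).operations().sym_ops


def _tetragonal_records(rng, noise="poisson", decay=0.0, n_range=8):
    rec_basis = cell_to_reciprocal_basis(CELL_TET)
    truth, records = {}, []
    for h in range(-n_range, n_range + 1):
        for k in range(-n_range, n_range + 1):
            for l in range(-10, 11):
                if h == k == l == 0:
                    continue
                d = 1.0 / np.linalg.norm(np.array([h, k, l], float) @ rec_basis)
                if not 2.2 <= d <= 15:
                    continue
                key = symmetry_key((h, k, l), OPS422, True)
                truth.setdefault(key, rng.exponential(5000.0))
                i0 = truth[key]
                z = rng.uniform(0, 40)
                i = i0 * math.exp(-decay * z)
                sigma = math.sqrt(i + 400)
                obs = i + rng.normal(0, sigma) if noise == "poisson" else i
                records.append(ReflectionRecord((h, k, l), obs, sigma,
                                                rng.uniform(1, 256), rng.uniform(1, 256), z))
    return records, truth


@pytest.fixture(scope="module")
def tet_records():
    return _tetragonal_records(np.random.default_rng(2))


def test_accept_reflections_tally():
    cell = CELL_TET
    recs = [ReflectionRecord((1, 0, 0), 100, 5, peak=99, zd=5) for _ in range(8)]
    recs.append(ReflectionRecord((6, 3, 5), 100, 5, peak=99, zd=5))  # d ~ 2.24: ice shell
    recs.append(ReflectionRecord((1, 1, 0), 1e9, 5, peak=99, zd=5))  # overloaded
    out, tally = accept_reflections(
        recs, cell, minpk=75.0, exclude_resolution_ranges=[(2.3, 2.2)], overload=1e6
    )
    assert len(out) == 8
    assert tally["ice"] == 1 and tally["overload"] == 1


def test_accept_remove_hkl():
    recs = [ReflectionRecord((1, 0, 0), 10, 1, peak=99), ReflectionRecord((2, 0, 0), 10, 1, peak=99)]
    out, tally = accept_reflections(recs, CELL_TET, remove={(2, 0, 0)})
    assert [r.hkl for r in out] == [(1, 0, 0)]
    assert tally["removed"] == 1
    out2, tally2 = accept_reflections(recs, CELL_TET, remove=set())
    assert len(out2) == 2 and tally2["removed"] == 0


def test_polarization_factor_unpolarized_forward():
    """(1 + cos^2 2theta)/2 -> 1 at 2theta ~ 0 for an unpolarized beam."""
    models = default_experiment()
    r = ReflectionRecord((0, 0, 1), 100, 5, xd=models.detector.orgx + 1.5,
                         yd=models.detector.orgy + 1.0, zd=1.0)
    lorentz, pol, air, eff = correction_factors(r, models)
    assert abs(pol - 1.0) < 1e-3
    assert air == 1.0 and eff == 1.0


def test_absorption_limits():
    models = default_experiment()
    r = ReflectionRecord((1, 2, 3), 100, 5, xd=60.0, yd=80.0, zd=1.0)
    _, _, air0, eff0 = correction_factors(r, models, air_mu=0.0, sensor_mu=1e9,
                                          sensor_thickness=1.0)
    assert air0 == 1.0 and abs(eff0 - 1.0) < 1e-12


def test_factor_product_matches_independent_formula():
    """Cross-check against a scalar re-derivation over random geometries."""
    models = default_experiment()
    det, beam, gonio = models.detector, models.beam, models.gonio
    rng = np.random.default_rng(3)
    for _ in range(200):
        x, y = rng.uniform(10, 245, 2)
        if np.hypot(x - det.orgx, y - det.orgy) < 5:
            continue
        r = ReflectionRecord((1, 1, 1), 100, 5, xd=x + 1, yd=y + 1, zd=1.0)
        lorentz, pol, air, eff = correction_factors(r, models, air_mu=1e-3,
                                                    sensor_mu=2.0, sensor_thickness=0.3)
        # independent scalar formulas
        pos = (det.distance * det.d3 + (x - det.orgx) * det.qx * det.d1
               + (y - det.orgy) * det.qy * det.d2)
        dist = np.linalg.norm(pos)
        s1u = pos / dist
        cos2t = float(s1u @ beam.direction)
        zeta = float(np.cross(s1u / beam.wavelength, beam.s0)
                     / np.linalg.norm(np.cross(s1u / beam.wavelength, beam.s0)) @ gonio.axis)
        # hand expansion for this geometry (beam along z, plane normal y):
        # fraction p has E along x, the rest along y
        p = beam.polarization_fraction
        pol_ref = p * (1 - s1u[0] ** 2) + (1 - p) * (1 - s1u[1] ** 2)
        np.testing.assert_allclose(lorentz, 1 / abs(zeta), rtol=1e-9)
        np.testing.assert_allclose(pol, pol_ref, rtol=1e-9)
        np.testing.assert_allclose(air, math.exp(-1e-3 * dist), rtol=1e-9)
        cos_inc = float(s1u @ det.d3)
        np.testing.assert_allclose(eff, 1 - math.exp(-2.0 * 0.3 / cos_inc), rtol=1e-9)


def test_consistent_lattices_exact_cubic():
    out = consistent_lattices((20, 20, 20, 90, 90, 90))
    symbols = {ch.bravais for ch, _ in out}
    assert {"cP", "tP", "oP", "aP"} <= symbols
    # zero tolerances keep only exact fits
    strict = consistent_lattices((20, 20.3, 20.9, 90, 90, 90), 1e-6, 1e-6)
    assert {ch.bravais for ch, _ in strict} <= {"aP", "mP", "oP"}
    # huge tolerances admit all 44
    assert len(consistent_lattices((20, 20, 20, 90, 90, 90), 10.0, 180.0)) == 44


def test_propose_422_symmetry(tet_records):
    records, _ = tet_records
    hyp = propose_space_group(records, CELL_TET)
    assert hyp.space_group_number == 89  # P422
    assert hyp.r_meas < 0.05
    np.testing.assert_allclose(hyp.cell[:2], (17.0, 17.0), atol=0.01)


def test_broken_symmetry_falls_back(tet_records):
    """Breaking non-Friedel mates (Friedel pairs stay intact) must push the
    proposal toward lower symmetry."""
    rng = np.random.default_rng(5)
    records, _ = tet_records
    factor = {}
    rec2 = []
    for r in records:
        key = max(r.hkl, tuple(-v for v in r.hkl))
        factor.setdefault(key, rng.uniform(0.3, 3.0) if rng.random() < 0.5 else 1.0)
        rec2.append(ReflectionRecord(r.hkl, r.iobs * factor[key], r.sigma, r.xd, r.yd, r.zd))
    hyp = propose_space_group(rec2, CELL_TET)
    assert hyp.space_group_number == 1


def test_user_space_group_respected(tet_records):
    records, _ = tet_records
    hyp = propose_space_group(records, CELL_TET, user_space_group=75)
    assert hyp.space_group_number == 75


def test_decay_factors_recovered(tet_records):
    rng = np.random.default_rng(6)
    records, _ = _tetragonal_records(rng, decay=0.01)
    _, rme0, *_ = r_factors(records, OPS422, True)
    corrected, surf = fit_correction_surfaces(records, 89, CELL_TET, keys={"DECAY"})
    _, rme1, *_ = r_factors(corrected, OPS422, True)
    assert rme1 < rme0
    z = np.array([r.zd for r in records])
    ratio = np.log(surf.g_total / np.exp(-0.01 * z))
    assert np.std(ratio) < 0.02  # decay recovered within 2% rms


def test_scaling_gauge_invariance(tet_records):
    records, _ = tet_records
    _, surf1 = fit_correction_surfaces(records, 89, CELL_TET, keys={"DECAY"})
    scaled = [ReflectionRecord(r.hkl, 3.0 * r.iobs, 3.0 * r.sigma, r.xd, r.yd, r.zd)
              for r in records]
    _, surf2 = fit_correction_surfaces(scaled, 89, CELL_TET, keys={"DECAY"})
    np.testing.assert_allclose(surf1.g_total, surf2.g_total, rtol=1e-4)
    assert abs(np.mean(np.log(list(surf1.decay.values())))) < 1e-6


def test_no_mates_means_unit_factors():
    # unique triclinic data: no symmetry information at all
    rng = np.random.default_rng(7)
    records = [ReflectionRecord((h, 2, 3), rng.uniform(100, 1000), 5.0, zd=rng.uniform(0, 40))
               for h in range(1, 60)]
    _, surf = fit_correction_surfaces(records, 1, CELL_TET, keys={"DECAY"}, friedel=False)
    np.testing.assert_allclose(surf.g_total, 1.0, atol=1e-6)


def test_variance_model_clean_and_multiplicative(tet_records):
    records, _ = tet_records
    _, vm = fit_variance_model(records, 89)
    assert 0.9 <= vm.a <= 1.1
    assert vm.b <= 1e-4
    rng = np.random.default_rng(8)
    noisy = [ReflectionRecord(r.hkl, r.iobs * (1 + 0.05 * rng.normal()), r.sigma,
                              r.xd, r.yd, r.zd) for r in records]
    _, vm2 = fit_variance_model(noisy, 89)
    assert abs(vm2.b - 0.0025) / 0.0025 < 0.30


def test_variance_model_needs_multiplicity():
    records = [ReflectionRecord((h, 2, 3), 100.0, 5.0) for h in range(1, 40)]
    with pytest.raises(ValueError, match="multiplicity"):
        fit_variance_model(records, 1, friedel=False)


def test_identical_mates_never_flagged():
    base = [ReflectionRecord((1, 2, 3), 100.0, 5.0)] * 6
    flagged = flag_outliers(base, 1, wfac1=0.5)
    assert not any(r.misfit for r in flagged)


def test_single_deviant_flagged():
    base = [ReflectionRecord((1, 2, 3), 100.0, 5.0)] * 5 + [ReflectionRecord((1, 2, 3), 300.0, 5.0)]
    flagged = flag_outliers(base, 1, wfac1=1.5)
    assert [r.misfit for r in flagged] == [False] * 5 + [True]


def test_lower_wfac1_more_misfits_lower_r(tet_records):
    rng = np.random.default_rng(9)
    records, _ = tet_records
    noisy = [ReflectionRecord(r.hkl, r.iobs * (1 + 0.05 * rng.normal()), r.sigma,
                              r.xd, r.yd, r.zd) for r in records]
    f15 = flag_outliers(noisy, 89, wfac1=1.5)
    f10 = flag_outliers(noisy, 89, wfac1=1.0)
    assert sum(r.misfit for r in f10) >= sum(r.misfit for r in f15)
    assert r_factors(f10, OPS422, True)[1] <= r_factors(f15, OPS422, True)[1]


def test_r_factor_hand_formula():
    recs = [ReflectionRecord((1, 2, 3), 10.0, 1.0), ReflectionRecord((1, 2, 3), 12.0, 1.0)]
    ops = gemmi.SpaceGroup(1).operations().sym_ops
    r_merge, r_meas, *_ = r_factors(recs, ops, True)
    np.testing.assert_allclose(r_merge, 2.0 / 22.0)
    np.testing.assert_allclose(r_meas, math.sqrt(2.0) * 2.0 / 22.0)


def test_r_meas_at_least_r_merge(tet_records):
    records, _ = tet_records
    r_merge, r_meas, *_ = r_factors(records, OPS422, True)
    assert r_meas >= r_merge > 0


def test_noise_free_data_zero_r():
    rng = np.random.default_rng(10)
    records, _ = _tetragonal_records(rng, noise="none")
    r_merge, r_meas, *_ = r_factors(records, OPS422, True)
    assert r_merge < 1e-12 and r_meas < 1e-12


def test_statistics_invariant_to_order_and_scale(tet_records):
    records, _ = tet_records
    shells1, _, _ = compute_statistics(records, 89, CELL_TET, n_shells=5)
    reordered = list(reversed([ReflectionRecord(r.hkl, 2.5 * r.iobs, 2.5 * r.sigma,
                                                r.xd, r.yd, r.zd) for r in records]))
    shells2, _, _ = compute_statistics(reordered, 89, CELL_TET, n_shells=5)
    for s1, s2 in zip(shells1, shells2):
        np.testing.assert_allclose(s1.r_meas, s2.r_meas, rtol=1e-9)
        assert s1.n_obs == s2.n_obs and s1.n_unique == s2.n_unique
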