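"""Multi-dataset scaling, merging and zero-dose extrapolation."""

import math

import gemmi
import numpy as np
import pytest

from rotred.correct import r_factors, symmetry_key
from rotred.files import AsciiReflectionFile, ReflectionRecord
from rotred.xscale import (
    InputSet,
    OutputGroup,
    ScaleJob,
    merge_observations,
    scale_sets,
    zero_dose_extrapolate,
)

CELL = (17.0, 17.0, 24.0, 90.0, 90.0, 90.0)
OPS = gemmi.SpaceGroup(89).operations().sym_ops


def _records(rng, decay=0.0, scale=1.0):
    from rotred.geometry import cell_to_reciprocal_basis

    rb = cell_to_reciprocal_basis(CELL)
    truth, out = {}, []
    for h in range(-7, 8):
        for k in range(-7, 8):
            for l in range(-9, 10):
                if h == k == l == 0:
                    continue
                d = 1.0 / np.linalg.norm(np.array([h, k, l], float) @ rb)
                if not 2.4 <= d <= 15:
                    continue
                key = symmetry_key((h, k, l), OPS, True)
                truth.setdefault(key, rng.exponential(5000.0))
                z = rng.uniform(0, 30)
                i = truth[key] * math.exp(-decay * z) * scale
                s = math.sqrt(i + 400)
                out.append(ReflectionRecord((h, k, l), i + rng.normal(0, s), s, zd=z))
    return out, truth


def _file(records):
    f = AsciiReflectionFile.new(CELL, 89, 1.0)
    f.records = records
    return f


def test_single_noise_free_set_is_identity_up_to_gauge():
    rng = np.random.default_rng(0)
    recs, _ = _records(rng)
    noise_free = [ReflectionRecord(r.hkl, r.iobs, r.sigma, zd=r.zd) for r in recs]
    job = ScaleJob([OutputGroup("out", [InputSet(_file(noise_free))])])
    res = scale_sets(job)
    out = res.outputs["out"].records
    gauge = np.median([o.iobs / r.iobs for o, r in zip(out, noise_free)])
    for o, r in zip(out, noise_free):
        np.testing.assert_allclose(o.iobs / r.iobs, gauge, rtol=0.05)


def test_relative_scale_recovered():
    rng = np.random.default_rng(1)
    recs, _ = _records(rng)
    doubled = [ReflectionRecord(r.hkl, 2.0 * r.iobs, 2.0 * r.sigma, zd=r.zd) for r in recs]
    job = ScaleJob([OutputGroup("out", [InputSet(_file(recs)), InputSet(_file(doubled))])])
    res = scale_sets(job)
    s1 = np.exp(np.mean(np.log(res.set_scales[0])))
    s2 = np.exp(np.mean(np.log(res.set_scales[1])))
    assert abs(s2 / s1 - 2.0) < 0.02


def test_two_output_groups_share_one_scale():
    """MAD-style: the intensity ratio of shared reflections across groups
    is preserved by the joint scaling."""
    rng = np.random.default_rng(2)
    recs, _ = _records(rng)
    wl2 = [ReflectionRecord(r.hkl, 1.7 * r.iobs, 1.7 * r.sigma, zd=r.zd) for r in recs]
    job = ScaleJob([
        OutputGroup("peak", [InputSet(_file(recs))], merge=True),
        OutputGroup("remote", [InputSet(_file(wl2))], merge=True),
    ])
    res = scale_sets(job)
    a = {r.hkl: r.iobs for r in res.outputs["peak"].records}
    b = {r.hkl: r.iobs for r in res.outputs["remote"].records}
    shared = [h for h in a if h in b and a[h] > 500]
    ratios = np.array([b[h] / a[h] for h in shared])
    assert np.median(np.abs(ratios / np.median(ratios) - 1)) < 0.05


def test_merge_weighted_mean_and_sigma_floor():
    recs = [ReflectionRecord((1, 2, 3), 10.0, 1.0), ReflectionRecord((1, 2, 3), 12.0, 1.0)]
    merged = merge_observations(recs, merge=True, friedel=True, space_group_number=1)
    assert len(merged) == 1
    np.testing.assert_allclose(merged[0].iobs, 11.0)
    # sigma >= inverse-variance bound, with a scatter guard
    assert merged[0].sigma >= 1.0 / math.sqrt(2.0) - 1e-12


def test_unmerged_preserves_count():
    rng = np.random.default_rng(3)
    recs, _ = _records(rng)
    out = merge_observations(recs, merge=False, friedel=True, space_group_number=89)
    assert len(out) == len(recs)


def test_friedel_false_keeps_mates_distinct():
    recs = [ReflectionRecord((1, 2, 3), 10.0, 1.0), ReflectionRecord((-1, -2, -3), 20.0, 1.0)]
    merged_f = merge_observations(recs, True, True, 1)
    merged_nf = merge_observations(recs, True, False, 1)
    assert len(merged_f) == 1
    assert len(merged_nf) == 2


def test_gauge_invariance_of_merged_output():
    rng = np.random.default_rng(4)
    recs, _ = _records(rng)
    job1 = ScaleJob([OutputGroup("o", [InputSet(_file(recs))], merge=True)])
    scaled_in = [ReflectionRecord(r.hkl, 5.0 * r.iobs, 5.0 * r.sigma, zd=r.zd) for r in recs]
    job2 = ScaleJob([OutputGroup("o", [InputSet(_file(scaled_in))], merge=True)])
    r1 = scale_sets(job1).outputs["o"].records
    r2 = scale_sets(job2).outputs["o"].records
    ratios = [b.iobs / a.iobs for a, b in zip(r1, r2) if a.iobs > 100]
    assert np.std(np.log(ratios)) < 0.02  # only the overall gauge differs


def test_zero_dose_extrapolation_removes_decay_bias():
    rng = np.random.default_rng(5)
    recs, truth = _records(rng, decay=0.02)

    def merged_bias(records):
        cls = {}
        for r in records:
            cls.setdefault(symmetry_key(r.hkl, OPS, True), []).append(r.iobs)
        rels = [np.mean(v) / truth[k] - 1 for k, v in cls.items() if len(v) >= 3]
        return abs(np.median(rels))

    corrected, slopes = zero_dose_extrapolate(recs, OPS)
    assert merged_bias(corrected) < 0.2 * merged_bias(recs)  # >= 80% of the bias removed


def test_zero_decay_leaves_data_unchanged():
    rng = np.random.default_rng(6)
    recs, _ = _records(rng)
    corrected, slopes = zero_dose_extrapolate(recs, OPS)
    rel = [abs(c.iobs - r.iobs) / max(abs(r.iobs), 1) for c, r in zip(corrected, recs)]
    assert np.median(rel) < 0.25  # fitted slopes are pure noise around zero


def test_small_class_unchanged_and_flagged():
    recs = [ReflectionRecord((9, 9, 9), 100.0, 5.0, zd=1.0),
            ReflectionRecord((9, 9, 9), 90.0, 5.0, zd=10.0)]
    corrected, slopes = zero_dose_extrapolate(recs, gemmi.SpaceGroup(1).operations().sym_ops)
    assert [c.iobs for c in corrected] == [100.0, 90.0]
    assert list(slopes.values()) == [None]


def test_disjoint_sets_raise_cross_link_error():
    f1 = _file([ReflectionRecord((1, 0, 0), 10, 1, zd=1)])
    f2 = _file([ReflectionRecord((5, 5, 5), 10, 1, zd=1)])
    with pytest.raises(ValueError, match="cross-links"):
        scale_sets(ScaleJob([OutputGroup("o", [InputSet(f1), InputSet(f2)])]))


def test_r_meas_consistent_with_correct_module():
    rng = np.random.default_rng(7)
    recs, _ = _records(rng)
    _, r_meas_direct, *_ = r_factors(recs, OPS, True)
    res = scale_sets(ScaleJob([OutputGroup("o", [InputSet(_file(recs))])]))
    # a single set gains only its own batch factors; R_meas barely moves
    assert abs(res.r_meas - r_meas_direct) < 0.01
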