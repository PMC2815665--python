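"""French-Wilson conversion, free-R sets and structure-format output."""

import math

import gemmi
import numpy as np
import pytest

from rotred.convert import (
    AmplitudeRecord,
    assign_free_set,
    convert_to_amplitudes,
    french_wilson,
    is_centric,
    read_plain_amplitudes,
    write_structure_format,
)
from rotred.files import AsciiReflectionFile, ReflectionRecord


def quadrature_oracle(i_obs, sig_i, sigma_mean, centric):
    """Brute-force trapezoid in F-space (smooth priors, no singularity)."""
    f = np.linspace(1e-6, math.sqrt(max(i_obs + 10 * sig_i, 12 * sig_i, 6 * sigma_mean)), 300_000)
    j = f * f
    if centric:
        logp = -j / (2 * sigma_mean)
    else:
        logp = np.log(2 * f / sigma_mean) - j / sigma_mean
    log_post = logp - 0.5 * ((i_obs - j) / sig_i) ** 2
    w = np.exp(log_post - log_post.max())
    ef = np.trapezoid(w * f, f) / np.trapezoid(w, f)
    ej = np.trapezoid(w * j, f) / np.trapezoid(w, f)
    return ef, math.sqrt(max(ej - ef * ef, 0))


def test_high_snr_limit():
    f, sig_f = french_wilson(10_000.0, 100.0, 5000.0, centric=False)
    assert abs(f - 100.0) / 100.0 < 0.005
    assert abs(sig_f - 0.5) / 0.5 < 0.05


def test_negative_intensity_gives_positive_f_below_prior_mean():
    f, sig_f = french_wilson(-200.0, 100.0, 5000.0, centric=False)
    prior_mean = math.sqrt(math.pi * 5000.0) / 2.0
    assert 0 < f < prior_mean
    assert sig_f > 0


@pytest.mark.parametrize("centric", [False, True])
def test_matches_quadrature_oracle(centric):
    for ratio in np.linspace(-4, 4, 9):
        i_obs = ratio * 100.0
        f, sig_f = french_wilson(i_obs, 100.0, 5000.0, centric)
        f_ref, sig_ref = quadrature_oracle(i_obs, 100.0, 5000.0, centric)
        assert abs(f - f_ref) / f_ref < 1e-3
        assert abs(sig_f - sig_ref) / sig_ref < 1e-3


def test_monotone_in_intensity():
    vals = [french_wilson(i, 100.0, 5000.0, False)[0] for i in np.linspace(-500, 500, 21)]
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_centricity_agrees_with_brute_force_enumeration():
    for sg in (3, 16, 89, 146):
        ops = gemmi.SpaceGroup(sg).operations().sym_ops
        for h in range(-3, 4):
            for k in range(-3, 4):
                for l in range(-3, 4):
                    if h == k == l == 0:
                        continue
                    brute = any(
                        tuple(op.apply_to_hkl([h, k, l])) == (-h, -k, -l) for op in ops
                    )
                    assert is_centric((h, k, l), ops) == brute


def _amplitudes(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    seen = set()
    while len(out) < n:
        hkl = (int(rng.integers(1, 14)), int(rng.integers(-12, 13)), int(rng.integers(-12, 13)))
        if hkl in seen:  # h >= 1 keeps Friedel mates out of the sample
            continue
        seen.add(hkl)
        out.append(AmplitudeRecord(hkl, float(rng.uniform(1, 500)), 1.0))
    return out


def test_fresh_free_set_fraction_and_reproducibility():
    records = _amplitudes(1000)
    a = assign_free_set(records, fraction=0.05, seed=3)
    b = assign_free_set(records, fraction=0.05, seed=3)
    n_free = sum(r.free_flag for r in a)
    assert n_free == 50
    assert [r.free_flag for r in a] == [r.free_flag for r in b]


def test_inherit_roundtrip_identical_flags():
    records = _amplitudes(300)
    flagged = assign_free_set(records, fraction=0.1, seed=1)
    inherited = assign_free_set(records, reference=flagged)
    assert [r.free_flag for r in inherited] == [r.free_flag for r in flagged]


def test_inherit_across_reindexing_transform():
    records = _amplitudes(300)
    flagged = assign_free_set(records, fraction=0.1, seed=2)
    # reference recorded in a permuted setting: h_ref = h @ P
    P = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])
    reference = [AmplitudeRecord(tuple(int(v) for v in np.array(r.hkl) @ P), r.f, r.sig_f,
                                 free_flag=r.free_flag) for r in flagged]
    # inherit mapping the reference back: reindex must invert P
    inherited = assign_free_set(records, reference=reference,
                                reindex=np.linalg.inv(P).astype(int))
    assert [r.free_flag for r in inherited] == [r.free_flag for r in flagged]


def test_convert_pipeline_output(tmp_path):
    data = AsciiReflectionFile.new((17, 17, 24, 90, 90, 90), 89, 1.0)
    rng = np.random.default_rng(5)
    for h in range(1, 6):
        for k in range(0, 5):
            for l in range(0, 6):
                data.records.append(
                    ReflectionRecord((h, k, l), float(rng.exponential(4000)) - 50.0,
                                     float(rng.uniform(20, 60)))
                )
    amplitudes = convert_to_amplitudes(data)
    assert all(r.f > 0 and r.sig_f > 0 for r in amplitudes)
    # write all three dialects and round-trip the plain one
    for dialect in ("plain", "shelx", "cns"):
        write_structure_format(amplitudes, tmp_path / f"out.{dialect}", dialect)
    back = read_plain_amplitudes(tmp_path / "out.plain")
    assert len(back) == len(amplitudes)
    np.testing.assert_allclose([r.f for r in back], [round(r.f, 3) for r in amplitudes],
                               atol=5e-4)


def test_shelx_fixed_columns(tmp_path):
    records = [AmplitudeRecord((1, 2, 3), 123.45, 6.78), AmplitudeRecord((-1, -2, -3), 9.99, 0.5)]
    path = tmp_path / "f.hkl"
    write_structure_format(records, path, "shelx")
    lines = path.read_text().splitlines()
    assert lines[0] == "   1   2   3  123.45    6.78"
    assert lines[-1].startswith("   0   0   0")


def test_cns_test_flag_complement_convention(tmp_path):
    records = [AmplitudeRecord((1, 0, 0), 10.0, 1.0, free_flag=1),
               AmplitudeRecord((2, 0, 0), 10.0, 1.0, free_flag=0)]
    path = tmp_path / "f.cv"
    write_structure_format(records, path, "cns")
    text = path.read_text()
    assert "TEST= 0" in text.splitlines()[-2]  # free reflection -> working flag 0
    assert "TEST= 1" in text.splitlines()[-1]


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError, match="fraction"):
        assign_free_set(_amplitudes(10), fraction=0.9)
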