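"""Calibration tables: spatial corrections, noise, gain, background, masking."""

import numpy as np
import pytest

from rotred.calib import (
    UNTRUSTED,
    CalibrationError,
    PixelTable,
    defpix,
    detector_noise,
    gain_table,
    initial_background,
    spatial_corrections,
)
from rotred.cbf import CbfImage
from rotred.simulate import default_experiment, render_calibration_image


@pytest.fixture(scope="module")
def det():
    return default_experiment().detector


def test_zero_offsets_give_zero_tables(det):
    xcorr, ycorr, overlay = spatial_corrections(det, roff=0.0, toff=0.0)
    assert np.all(xcorr.values == 0) and np.all(ycorr.values == 0)
    assert overlay.sum() == 0


def test_radial_field_recovered_from_calibration_image(det):
    field = lambda x, y: (0.01 * (x - 127.5), 0.01 * (y - 127.5))
    img, nodes = render_calibration_image((256, 256), 32.0, distortion=field, seed=1)
    xcorr, ycorr, overlay = spatial_corrections(det, calibration=img, grid_spacing=32.0)
    # at each true node the correction points back to the ideal grid
    errs = []
    for gx, gy, px, py in nodes:
        ix, iy = int(round(px)), int(round(py))
        errs.append(np.hypot(xcorr.values[iy, ix] - (gx - px), ycorr.values[iy, ix] - (gy - py)))
    assert np.sqrt(np.mean(np.square(errs))) < 0.2
    assert overlay.sum() == len(nodes)


def test_underexposed_calibration_raises(det):
    img = CbfImage(np.full((256, 256), 10, dtype=np.int32))  # no peaks at all
    with pytest.raises((CalibrationError, ValueError)):
        spatial_corrections(det, calibration=img, grid_spacing=32.0)


def test_blank_from_dark_image():
    dark = CbfImage(np.full((64, 64), 12, dtype=np.int32))
    blank = detector_noise(dark=dark)
    assert (blank.values == 12).all()


def test_blank_from_corners_is_mean_of_corner_means():
    img = np.zeros((100, 100), dtype=np.int32)
    img[:50, :50] = 10; img[:50, 50:] = 10
    img[50:, :50] = 14; img[50:, 50:] = 14
    blank = detector_noise(data_images=[CbfImage(img)], corner=30)
    np.testing.assert_allclose(blank.values[0, 0], 12.0)


@pytest.mark.parametrize("true_gain", [1.0, 4.0])
def test_gain_estimate(true_gain):
    rng = np.random.default_rng(5)
    frames = [CbfImage((true_gain * rng.poisson(80 / true_gain, (192, 192)) + 10).astype(np.int32))
              for _ in range(5)]
    blank = PixelTable(np.full((192, 192), 10.0), "BLANK")
    gain = gain_table(frames, blank)
    est = np.median(gain.values[gain.trusted])
    assert abs(est - true_gain) / true_gain < 0.1


def test_gain_scale_equivariance():
    rng = np.random.default_rng(6)
    base = [rng.poisson(60, (160, 160)) for _ in range(4)]
    blank0 = PixelTable(np.zeros((160, 160)), "BLANK")
    g1 = np.median(gain_table([CbfImage(b.astype(np.int32)) for b in base], blank0).values)
    for c in (2, 4):
        gc = np.median(gain_table([CbfImage((c * b).astype(np.int32)) for b in base], blank0).values)
        assert abs(gc / g1 - c) / c < 0.1


def test_constant_image_gain_untrusted():
    frames = [CbfImage(np.full((64, 64), 50, dtype=np.int32))] * 3
    blank = PixelTable(np.full((64, 64), 50.0), "BLANK")
    gain = gain_table(frames, blank)
    assert not gain.trusted.any()


def _flat_setup(level=5, n=2, shape=(128, 128)):
    frames = [CbfImage(np.full(shape, level, dtype=np.int32)) for _ in range(n)]
    blank = PixelTable(np.zeros(shape), "BLANK")
    gain = PixelTable(np.ones(shape), "GAIN")
    return frames, blank, gain


def test_background_additivity():
    frames, blank, gain = _flat_setup(level=5, n=2)
    bkg = initial_background(frames, blank, gain)
    inner = bkg.values[40:88, 40:88]
    np.testing.assert_allclose(inner, 10.0)  # two frames of 5 sum to 10


def test_spoiled_frame_rejected():
    frames, blank, gain = _flat_setup(level=5, n=4)
    spoiled = CbfImage(np.full((128, 128), 1500, dtype=np.int32))
    bkg = initial_background(frames + [spoiled], blank, gain)
    assert len(bkg.rejected_images) == 1
    assert bkg.n_summed == 4


def test_shadow_pixels_marked_untrusted(stack, tables):
    bkginit = tables["bkginit"]
    assert bkginit.values[127, 127] == UNTRUSTED  # under the beamstop
    assert bkginit.trusted[127, 40]


def test_defpix_plateau_normalized_to_10000(tables):
    abs_img = tables["abs"]
    bkgpix = tables["bkgpix"]
    trusted = abs_img.trusted & bkgpix.trusted
    median = np.median(abs_img.values[trusted])
    assert abs(median - 10000) / 10000 < 0.02


def test_defpix_noop_bounds_keep_mask(det, tables):
    bkginit = tables["bkginit"]
    bkgpix, _ = defpix(bkginit, det, 1.0, value_range=(0.0, np.inf),
                       resolution_range=(np.inf, 0.0))
    assert (bkgpix.trusted == bkginit.trusted).all()
    np.testing.assert_allclose(bkgpix.values[bkgpix.trusted], bkginit.values[bkginit.trusted])


def test_defpix_masks_low_plateau_shadow(det):
    shape = (det.ny, det.nx)
    values = np.full(shape, 100.0)
    values[100:120, 100:120] = 30.0  # 30% plateau: ABS ~ 3000 < 6000
    bkg = PixelTable(values, "BKGINIT")
    bkgpix, abs_img = defpix(bkg, det, 1.0)
    assert (bkgpix.values[105:115, 105:115] == UNTRUSTED).all()


def test_sentinel_propagation_is_monotone(tables):
    """A pixel untrusted in BKGINIT stays untrusted in BKGPIX."""
    assert not (tables["bkgpix"].trusted & ~tables["bkginit"].trusted).any()


def test_everything_masked_raises(det):
    bkg = PixelTable(np.full((det.ny, det.nx), UNTRUSTED), "BKGINIT")
    with pytest.raises(CalibrationError, match="empty trusted region"):
        defpix(bkg, det, 1.0)
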