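"""Per-pixel lookup tables: spatial corrections, noise, gain, background.

The tables built here (XCORR/YCORR, BLANK, GAIN, BKGINIT, BKGPIX, ABS)
feed every later stage.  Untrusted pixels carry the sentinel value ``-3``
in the background tables, and once a pixel is untrusted no later table
may resurrect it (monotone masking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from .cbf import CbfImage
from .geometry import DetectorModel, pixel_to_lab

__all__ = [
    "UNTRUSTED",
    "PixelTable",
    "CalibrationError",
    "spatial_corrections",
    "detector_noise",
    "gain_table",
    "initial_background",
    "defpix",
]

UNTRUSTED = -3.0


class CalibrationError(RuntimeError):
    pass


@dataclass
class PixelTable:
    values: np.ndarray  # 2D float table
    kind: str  # XCORR, YCORR, BLANK, GAIN, BKGINIT, BKGPIX, ABS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def dims(self):
        return self.values.shape

    @property
    def trusted(self) -> np.ndarray:
        return self.values != UNTRUSTED

    def to_cbf(self, scale: float = 1.0) -> CbfImage:
        """Render as an integer CBF table; the sentinel stays exactly -3."""
        vals = np.rint(self.values * scale).astype(np.int32)
        vals[~self.trusted] = int(UNTRUSTED)
        return CbfImage(vals, {"kind": self.kind, "scale": f"{scale:g}"})


# ---------------------------------------------------------------------------
# spatial corrections

def spatial_corrections(
    det: DetectorModel,
    roff: float | None = None,
    toff: float | None = None,
    calibration: CbfImage | None = None,
    grid_spacing: float | None = None,
    min_peak_fraction: float = 0.5,
):
    """Additive pixel-position corrections (XCORR, YCORR), in pixels.

    Exactly one mode applies: analytic radial/tangential scanner offsets
    (``roff``/``toff``, mm), or a calibration image showing a regular grid
    of bright peaks whose displacement from the ideal grid is interpolated
    over the face.  Returns (xcorr, ycorr, overlay) where ``overlay``
    marks accepted calibration peaks (empty in analytic mode).
    """
    if calibration is not None and (roff is not None or toff is not None):
        raise ValueError("choose either analytic offsets or a calibration image")
    ny, nx = det.ny, det.nx
    overlay = np.zeros((ny, nx), dtype=np.int32)
    if calibration is None:
        roff = roff or 0.0
        toff = toff or 0.0
        yy, xx = np.mgrid[0:ny, 0:nx]
        dx_mm = (xx - det.orgx) * det.qx
        dy_mm = (yy - det.orgy) * det.qy
        r = np.hypot(dx_mm, dy_mm)
        with np.errstate(invalid="ignore", divide="ignore"):
            ur_x, ur_y = np.where(r > 0, dx_mm / r, 0.0), np.where(r > 0, dy_mm / r, 0.0)
        # radial offset displaces along the radius, tangential across it
        xcorr = (roff * ur_x - toff * ur_y) / det.qx
        ycorr = (roff * ur_y + toff * ur_x) / det.qy
        return PixelTable(xcorr, "XCORR"), PixelTable(ycorr, "YCORR"), overlay

    if grid_spacing is None:
        raise ValueError("calibration mode requires the nominal grid spacing (pixels)")
    counts = calibration.counts.astype(float)
    background = np.median(counts)
    noise = math.sqrt(max(background, 1.0))
    mask = counts > background + 10 * noise
    labels, nlab = ndimage.label(mask)
    peaks = ndimage.center_of_mass(counts - background, labels, range(1, nlab + 1))
    peaks = [(px, py) for (py, px) in peaks]

    # ideal grid nodes (same layout as the calibration plate)
    nodes = [
        (gx, gy)
        for gy in np.arange(grid_spacing / 2.0, ny, grid_spacing)
        for gx in np.arange(grid_spacing / 2.0, nx, grid_spacing)
    ]
    matched = []
    for gx, gy in nodes:
        best = None
        for px, py in peaks:
            d2 = (px - gx) ** 2 + (py - gy) ** 2
            if d2 < (grid_spacing / 2.0) ** 2 and (best is None or d2 < best[0]):
                best = (d2, px, py)
        if best is not None:
            matched.append((gx, gy, best[1], best[2]))
            overlay[int(round(best[2])), int(round(best[1]))] = 1
    if len(matched) < min_peak_fraction * len(nodes):
        raise CalibrationError(
            f"underexposed/incomplete calibration: matched {len(matched)} of "
            f"{len(nodes)} expected grid peaks"
        )
    pts = np.array([(m[2], m[3]) for m in matched])  # observed positions
    dxs = np.array([m[0] - m[2] for m in matched])  # ideal - observed
    dys = np.array([m[1] - m[3] for m in matched])
    yy, xx = np.mgrid[0:ny, 0:nx]
    xcorr = griddata(pts, dxs, (xx, yy), method="linear")
    ycorr = griddata(pts, dys, (xx, yy), method="linear")
    # outside the peak hull: nearest-neighbour fill
    xnear = griddata(pts, dxs, (xx, yy), method="nearest")
    ynear = griddata(pts, dys, (xx, yy), method="nearest")
    xcorr = np.where(np.isfinite(xcorr), xcorr, xnear)
    ycorr = np.where(np.isfinite(ycorr), ycorr, ynear)
    return PixelTable(xcorr, "XCORR"), PixelTable(ycorr, "YCORR"), overlay


# ---------------------------------------------------------------------------
# INIT tables

def detector_noise(
    dark: CbfImage | None = None,
    data_images: list[CbfImage] | None = None,
    corner: int = 30,
) -> PixelTable:
    """BLANK table: per-pixel dark counts, or a constant from the mean
    recorded value in each corner of the data images."""
    if dark is not None:
        return PixelTable(dark.counts.astype(float), "BLANK")
    if not data_images:
        raise ValueError("need a dark image or data images")
    means = []
    for img in data_images:
        c = img.counts
        w = min(corner, c.shape[0] // 2, c.shape[1] // 2)
        for block in (c[:w, :w], c[:w, -w:], c[-w:, :w], c[-w:, -w:]):
            means.append(block.mean())
    level = float(np.mean(means))
    return PixelTable(np.full(data_images[0].dims, level), "BLANK")


def _box_stats(values: np.ndarray, include: np.ndarray, nbx: int, nby: int):
    """Local mean and variance over a (2nbx+1)x(2nby+1) box of included pixels."""
    size = (2 * nby + 1, 2 * nbx + 1)
    w = include.astype(float)
    count = ndimage.uniform_filter(w, size=size, mode="nearest")
    s1 = ndimage.uniform_filter(values * w, size=size, mode="nearest")
    s2 = ndimage.uniform_filter(values**2 * w, size=size, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / count, 0.0)
        var = np.where(count > 0, s2 / count - mean**2, 0.0)
    n_eff = count * size[0] * size[1]
    var = np.where(n_eff > 1, var * n_eff / np.maximum(n_eff - 1, 1), 0.0)
    return mean, np.maximum(var, 0.0), n_eff


def gain_table(
    images: list[CbfImage],
    blank: PixelTable,
    nbx: int = 5,
    nby: int = 5,
    n_trim_iterations: int = 3,
) -> PixelTable:
    """GAIN table: local variance / local (mean - blank) of background pixels.

    The variance of a background pixel is gain * (contents - noise); strong
    pixels would bias both moments upward, so they are excluded by iterated
    trimming: pixels far above the current local mean are dropped and the
    box statistics recomputed.  Pixels whose box mean does not exceed the
    detector noise are marked untrusted.
    """
    if nbx < 1 or nby < 1:
        raise ValueError("nbx and nby must be >= 1")
    stack = np.stack([img.counts.astype(float) for img in images])
    values = stack.mean(axis=0)
    # averaging n frames scales the per-frame variance by 1/n
    nf = len(images)
    include = np.ones_like(values, dtype=bool)
    mean = var = None
    for _ in range(n_trim_iterations):
        mean, var, _ = _box_stats(values, include, nbx, nby)
        sigma = np.sqrt(np.maximum(var, 1e-12))
        strong = values - mean > 2.5 * sigma
        # grow the exclusion to swallow the faint tails around spots
        strong = ndimage.binary_dilation(strong, iterations=2)
        include = ~strong
    signal = mean - blank.values
    # undo the variance shrinkage of the one-sided 2.5-sigma trim
    # (truncated-normal variance factor 1 - t*phi(t)/Phi(t) - (phi(t)/Phi(t))^2)
    trim_correction = 1.0 / 0.9556
    gain = np.where(signal > 1e-6, trim_correction * var * nf / np.maximum(signal, 1e-6), 0.0)
    table = np.where(signal > 1e-6, gain, UNTRUSTED)
    return PixelTable(table, "GAIN")


def initial_background(
    images: list[CbfImage],
    blank: PixelTable,
    gain: PixelTable,
    trusted_region: tuple[float, float] = (0.0, 1.05),
    xcorr: PixelTable | None = None,
    ycorr: PixelTable | None = None,
    spoiled_factor: float = 5.0,
    nbx: int = 5,
    nby: int = 5,
) -> PixelTable:
    """BKGINIT: the summed X-ray background of the selected images.

    Strong pixels are excluded and refilled from their local surroundings
    before summing.  Untrusted (-3): outside the ``trusted_region`` radius
    annulus (fractions of the inscribed-circle radius, measured from the
    face centre), in beamstop shadow (summed counts consistent with the
    detector noise alone), or with undefined spatial correction.  Images
    whose mean contents exceed ``spoiled_factor`` times the median of the
    set are rejected with a diagnostic.
    """
    if not images:
        raise ValueError("need at least one background image")
    means = np.array([img.counts.mean() for img in images])
    median = np.median(means)
    kept, rejected = [], []
    for img, m in zip(images, means):
        if m > spoiled_factor * median:
            rejected.append(f"image mean {m:.1f} vs set median {median:.1f}")
        else:
            kept.append(img)
    if rejected and not kept:
        raise CalibrationError("all background images rejected: unexpected high mean pixel contents")

    total = np.zeros(kept[0].counts.shape, dtype=float)
    gain_safe = np.where(gain.trusted, np.maximum(gain.values, 1e-6), 1.0)
    for img in kept:
        values = img.counts.astype(float)
        mean, _, _ = _box_stats(values, np.ones_like(values, bool), nbx, nby)
        expected_sd = np.sqrt(np.maximum(gain_safe * np.maximum(mean - blank.values, 0.0), 1.0))
        strong = values - mean > 3.0 * expected_sd
        mean2, _, _ = _box_stats(values, ~strong, nbx, nby)
        total += np.where(strong, mean2, values)

    ny, nx = total.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    radius = np.hypot(xx - cx, yy - cy) / (min(nx, ny) / 2.0)
    untrusted = (radius < trusted_region[0]) | (radius > trusted_region[1])
    # beamstop shadow: response indistinguishable from detector noise
    n = len(kept)
    blank_sum = n * blank.values
    untrusted |= total < blank_sum + 3.0 * np.sqrt(np.maximum(gain_safe * blank_sum, 1.0))
    if xcorr is not None:
        untrusted |= ~np.isfinite(xcorr.values)
    if ycorr is not None:
        untrusted |= ~np.isfinite(ycorr.values)
    untrusted |= ~gain.trusted
    table = np.where(untrusted, UNTRUSTED, total)
    result = PixelTable(table, "BKGINIT")
    result.rejected_images = rejected  # type: ignore[attr-defined]
    result.n_summed = n  # type: ignore[attr-defined]
    return result


def _plateau(values: np.ndarray, nbins: int = 256, trim: float = 0.2) -> float:
    """Trimmed-mode estimate of the unshaded background plateau."""
    lo, hi = np.quantile(values, [trim / 2.0, 1.0 - trim / 2.0])
    if hi <= lo:
        return float(np.median(values))
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    # smooth away per-bin shot noise before taking the mode
    smooth = ndimage.uniform_filter1d(hist.astype(float), size=max(nbins // 16, 3))
    peak = int(np.argmax(smooth))
    return float(0.5 * (edges[peak] + edges[peak + 1]))


def defpix(
    bkginit: PixelTable,
    det: DetectorModel,
    wavelength: float,
    value_range: tuple[float, float] = (6000.0, 30000.0),
    resolution_range: tuple[float, float] = (20.0, 0.0),
):
    """DEFPIX: normalize the background to the ABS control image and mask.

    ABS holds ``10000 * value / plateau`` so unshaded pixels sit at about
    10 000 and shaded pixels lower.  Pixels whose ABS value falls outside
    ``value_range`` or whose resolution lies outside ``resolution_range``
    are marked -3 in the returned BKGPIX; all other values are copied from
    BKGINIT unchanged.
    """
    trusted = bkginit.trusted
    if not trusted.any():
        raise CalibrationError("empty trusted region")
    plateau = _plateau(bkginit.values[trusted])
    if plateau <= 0:
        raise CalibrationError("background plateau is not positive")
    abs_vals = np.where(trusted, 10000.0 * bkginit.values / plateau, UNTRUSTED)

    ny, nx = bkginit.dims
    yy, xx = np.mgrid[0:ny, 0:nx]
    pos = pixel_to_lab(det, xx.ravel().astype(float), yy.ravel().astype(float))
    r = np.linalg.norm(pos, axis=1).reshape(ny, nx)
    cos2t = np.clip(det.distance / np.maximum(r, 1e-9), -1.0, 1.0)
    theta = 0.5 * np.arccos(cos2t)
    with np.errstate(divide="ignore"):
        d = np.where(theta > 1e-9, wavelength / (2.0 * np.sin(theta)), np.inf)
    d_max, d_min = resolution_range
    bad_res = d > d_max if np.isfinite(d_max) and d_max > 0 else np.zeros_like(d, bool)
    if d_min > 0:
        bad_res |= d < d_min
    lo, hi = value_range
    bad_val = (abs_vals < lo) | (abs_vals > hi)
    mask = ~trusted | bad_val | bad_res
    bkgpix = np.where(mask, UNTRUSTED, bkginit.values)
    return PixelTable(bkgpix, "BKGPIX"), PixelTable(abs_vals, "ABS")
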