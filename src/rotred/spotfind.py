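"""Strong-pixel classification and 3D spot assembly.

A pixel is strong when its counts exceed the local background by a
multiple (the STRONG_PIXEL decision constant) of the expected background
standard deviation sqrt(gain * background).  The local background is a
two-pass box mean over the frame itself: candidate signal pixels found in
the first pass (controlled by the BACKGROUND_PIXEL constant) are excluded
from the second.  Strong pixels adjacent in three dimensions (6-neighbour,
face-adjacent, spanning frame boundaries) form a spot; spots need a
minimum pixel count and a centroid close to their strongest pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calib import PixelTable, _box_stats
from .cbf import CbfImage
from .files import SpotRecord

__all__ = ["StrongPixel", "classify_strong", "cap_strong", "assemble_spots", "find_spots"]


@dataclass(frozen=True)
class StrongPixel:
    x: int
    y: int
    z: int  # 0-based frame index
    signal: float  # counts above local background, > 0


def classify_strong(
    image: CbfImage,
    frame_index: int,
    bkg: PixelTable,
    gain: PixelTable,
    strong_pixel: float = 3.0,
    background_pixel: float = 6.0,
    nbx: int = 5,
    nby: int = 5,
) -> list[StrongPixel]:
    """Strong pixels of one frame; pixels untrusted in ``bkg`` never qualify."""
    if bkg.dims != image.dims or gain.dims != image.dims:
        raise ValueError("tables must share dimensions with the image")
    values = image.counts.astype(float)
    trusted = bkg.trusted
    gain_safe = np.where(gain.trusted, np.maximum(gain.values, 1e-6), 1.0)

    mean1, _, _ = _box_stats(values, trusted, nbx, nby)
    sd1 = np.sqrt(np.maximum(gain_safe * np.maximum(mean1, 1.0), 1.0))
    candidate = values - mean1 > background_pixel / 2.0 * sd1
    mean2, _, _ = _box_stats(values, trusted & ~candidate, nbx, nby)
    sd2 = np.sqrt(np.maximum(gain_safe * np.maximum(mean2, 1.0), 1.0))
    strong = trusted & (values - mean2 > strong_pixel * sd2)

    ys, xs = np.nonzero(strong)
    signals = values[ys, xs] - mean2[ys, xs]
    return [
        StrongPixel(int(x), int(y), int(frame_index), float(s))
        for x, y, s in zip(xs, ys, signals)
    ]


def cap_strong(pixels: list[StrongPixel], maximum_number: int) -> list[StrongPixel]:
    """Keep the ``maximum_number`` strongest pixels; deterministic
    lexicographic (z, y, x) tie-break."""
    if len(pixels) <= maximum_number:
        return list(pixels)
    ranked = sorted(pixels, key=lambda p: (-p.signal, p.z, p.y, p.x))
    return ranked[:maximum_number]


def assemble_spots(
    pixels: list[StrongPixel],
    min_pixels: int = 3,
    max_centroid_offset: float = 3.0,
) -> list[SpotRecord]:
    """Group strong pixels into spots by 3D connectivity and filter.

    Components under face-adjacency in (x, y, z); the centroid is the
    signal-weighted mean.  Components with fewer than ``min_pixels``
    members, or whose centroid strays more than ``max_centroid_offset``
    pixels from the strongest member (the ice-ring / sharp-edge guard),
    are rejected.  The result is invariant to pixel input order.
    """
    if not pixels:
        return []
    xs = np.array([p.x for p in pixels])
    ys = np.array([p.y for p in pixels])
    zs = np.array([p.z for p in pixels])
    sig = np.array([p.signal for p in pixels])
    x0, y0, z0 = xs.min(), ys.min(), zs.min()
    shape = (zs.max() - z0 + 1, ys.max() - y0 + 1, xs.max() - x0 + 1)
    volume = np.zeros(shape, dtype=bool)
    weight = np.zeros(shape, dtype=float)
    volume[zs - z0, ys - y0, xs - x0] = True
    np.maximum.at(weight, (zs - z0, ys - y0, xs - x0), sig)

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, nlab = ndimage.label(volume, structure=structure)
    if nlab == 0:
        return []
    lab_of_pixel = labels[zs - z0, ys - y0, xs - x0]

    spots: list[SpotRecord] = []
    order = np.argsort(lab_of_pixel, kind="stable")
    boundaries = np.searchsorted(lab_of_pixel[order], np.arange(1, nlab + 2))
    for lab in range(1, nlab + 1):
        members = order[boundaries[lab - 1] : boundaries[lab]]
        if len(members) < min_pixels:
            continue
        w = sig[members]
        total = w.sum()
        cx = float((xs[members] * w).sum() / total)
        cy = float((ys[members] * w).sum() / total)
        cz = float((zs[members] * w).sum() / total)
        peak = members[np.lexsort((xs[members], ys[members], zs[members], -w))[0]]
        off = np.sqrt((cx - xs[peak]) ** 2 + (cy - ys[peak]) ** 2 + (cz - zs[peak]) ** 2)
        if off > max_centroid_offset:
            continue
        # continuous frame coordinate: pixel of frame f covers z in [f-1, f]
        spots.append(SpotRecord(cx, cy, cz + 0.5, float(total)))
    spots.sort(key=lambda s: (-s.intensity, s.z, s.y, s.x))
    return spots


def find_spots(
    frames: list[CbfImage],
    first_frame: int,
    bkg: PixelTable,
    gain: PixelTable,
    strong_pixel: float = 3.0,
    background_pixel: float = 6.0,
    max_strong_pixels: int = 1_500_000,
    min_pixels: int = 3,
    max_centroid_offset: float = 3.0,
    nbx: int = 5,
    nby: int = 5,
) -> list[SpotRecord]:
    """COLSPOT over a contiguous frame range starting at ``first_frame`` (1-based)."""
    pixels: list[StrongPixel] = []
    for i, frame in enumerate(frames):
        pixels.extend(
            classify_strong(
                frame, first_frame - 1 + i, bkg, gain, strong_pixel, background_pixel, nbx, nby
            )
        )
    pixels = cap_strong(pixels, max_strong_pixels)
    return assemble_spots(pixels, min_pixels, max_centroid_offset)
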