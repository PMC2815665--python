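"""Profile-fitting integration.

Every reflection predicted in the data range is integrated in two passes.
Pass one learns reference profiles: the contributing pixels of strong
reflections are mapped into a per-reflection coordinate frame anchored on
the Ewald sphere (angular offsets along the e1/e2 directions of
:func:`rotred.geometry.ewald_frame`, plus the spindle offset phi - phi_c),
accumulated on a 9x9x9 grid spanning (+-delta_D, +-delta_D, +-delta_M),
and averaged within nine equal detector regions per rotation batch.  Grid
points above the CUT percentage of the template maximum form the
integration support.  Pass two fits each observation as
``counts = I * profile + background`` by weighted least squares; a
reflection whose observed support covers less than MINPK percent of the
profile is discarded, otherwise the missing intensity is estimated by
rescaling with the observed profile fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calib import PixelTable
from .cbf import CbfImage
from .files import ReflectionRecord
from .geometry import (
    ExperimentModel,
    Prediction,
    ewald_frame,
    pixel_to_lab,
    predict_reflections,
    refine_geometry,
    rotation_matrix,
)

__all__ = [
    "ProfileGrid",
    "IntegrationDomain",
    "estimate_spot_shape",
    "map_to_profile",
    "learn_templates",
    "fit_profile",
    "integrate_range",
]

GRID_DIMS = (9, 9, 9)  # odd, centred; (e1, e2, spindle) voxels
N_DETECTOR_REGIONS = 9  # 3x3 partition of the face


@dataclass
class IntegrationDomain:
    sigma_M: float  # deg
    sigma_D: float  # deg
    delta_M: float  # deg, reflecting-range half-width of the grid
    delta_D: float  # deg, divergence half-width

    def __post_init__(self):
        if self.sigma_M <= 0 or self.sigma_D <= 0:
            raise ValueError("sigma_M and sigma_D must be positive")


@dataclass
class ProfileGrid:
    values: np.ndarray  # (n3, n2, n1) non-negative, sums to 1 over the mask
    support_mask: np.ndarray  # CUT-thresholded booleans

    @classmethod
    def from_counts(cls, counts: np.ndarray, cut_percent: float) -> "ProfileGrid":
        """Normalize over *all* positive voxels so the support mask carries
        less than unit mass: the deficit is exactly the profile fraction
        the CUT threshold excludes, and dividing a fitted intensity by the
        observed mask mass restores it."""
        raw = np.asarray(counts, dtype=float)
        c = np.maximum(raw, 0.0)
        mask = c > cut_percent / 100.0 * c.max() if c.max() > 0 else np.zeros_like(c, bool)
        # normalize by the signed total: negative noise voxels cancel the
        # spurious mass that clipping would otherwise add
        total = raw.sum()
        values = c / total if total > 0 else np.zeros_like(c)
        return cls(values, mask)


@dataclass
class MappedObservation:
    """One reflection's pixels deposited on the profile grid."""

    counts: np.ndarray  # (n3, n2, n1) observed counts
    weight: np.ndarray  # trilinear coverage weight per voxel
    background: float  # background level per pixel (counts)
    bg_variance: float  # variance of one background pixel
    spilled: float  # counts mapping outside the grid
    n_pixels: float = 0.0

    @property
    def covered(self) -> np.ndarray:
        return self.weight > 1e-6


def estimate_spot_shape(
    frames: list[CbfImage],
    spots,  # SpotRecords (centroids); the strongest are examined
    models: ExperimentModel,
    max_spots: int = 200,
    delta_factor: float = 8.0,
    user_delta_M: float | None = None,
    user_delta_D: float | None = None,
) -> IntegrationDomain:
    """Auto-set sigma_D / sigma_M from the observed extents of strong spots.

    sigma_D follows from the second moment of the detector footprint,
    sigma_M from the second moment of the rocking profile across frames.
    Falls back to the crystal-model defaults when fewer than 50 spots are
    available.  ``delta_factor`` (default 8, the middle of the customary
    6-10 band) sets the integration-domain half-widths; explicit user
    values take precedence.
    """
    det, gonio = models.detector, models.gonio
    ranked = sorted(spots, key=lambda s: -s.intensity)[:max_spots]
    sig_d, sidebands, phases = [], [], []
    if len(ranked) >= 50:
        for s in ranked:
            if not 3.0 < s.z < len(frames) - 3.0:
                continue  # truncated rocking curves bias the estimate
            stats = _spot_moments(frames, s, det)
            if stats is None:
                continue
            var_px, sideband = stats
            if var_px > 0.05:
                sigma_mm = math.sqrt(var_px) * det.qx
                sig_d.append(math.degrees(math.atan(sigma_mm / det.distance)))
            if sideband is not None:
                sidebands.append(sideband)
                phases.append(s.z % 1.0)
    if sig_d and sidebands:
        sigma_D = float(np.median(sig_d))
        # rocking width by fitting the per-spot sideband fractions with
        # the known phase of each centroid within its frame: conditioning
        # on the phases removes most of the estimator variance
        sigma_M = _fit_rocking_width(np.array(sidebands), np.array(phases)) * gonio.delta_phi
    else:
        sigma_D = models.crystal.sigma_D
        sigma_M = models.crystal.sigma_M
    delta_D = user_delta_D if user_delta_D is not None else delta_factor * sigma_D
    delta_M = user_delta_M if user_delta_M is not None else delta_factor * sigma_M
    return IntegrationDomain(sigma_M, sigma_D, delta_M, delta_D)


def _model_sideband(phases: np.ndarray, s: float) -> np.ndarray:
    """Expected sideband fraction versus *measured* phase.

    The measured phase (count-weighted mean of frame centres) is itself a
    discretized function of the true phase, so the model is tabulated as
    a parametric curve (measured phase, sideband) over the true phase and
    interpolated at the observations.
    """
    from scipy.special import ndtr as _ndtr

    j = np.arange(-5, 7)
    # exploit symmetry about the frame centre: parametrize by the measured
    # distance from the centre, d in [0, 0.5]
    u_true = np.linspace(0.5, 0.999, 120)
    d_meas = np.empty_like(u_true)
    sb = np.empty_like(u_true)
    for i, u in enumerate(u_true):
        p = _ndtr((j + 1 - u) / s) - _ndtr((j - u) / s)
        peak = int(np.argmax(p))
        tri = p[max(peak - 1, 0) : peak + 2]
        sb[i] = (tri.sum() - p[peak]) / max(tri.sum(), 1e-12)
        centroid = float((p * (j + 0.5)).sum())
        d_meas[i] = abs(centroid % 1.0 - 0.5)
    order = np.argsort(d_meas)
    d_obs = np.abs(np.asarray(phases) % 1.0 - 0.5)
    return np.interp(d_obs, d_meas[order], sb[order])


def _fit_rocking_width(sidebands: np.ndarray, phases: np.ndarray) -> float:
    """Least-squares rocking width (frames) over a 1D grid."""
    widths = np.linspace(0.03, 1.5, 120)
    costs = [float(((sidebands - _model_sideband(phases, s)) ** 2).sum()) for s in widths]
    return float(widths[int(np.argmin(costs))])


def _spot_moments(frames, spot, det, half: int = 6, zhalf: int = 3):
    """(detector footprint variance, rocking sideband fraction) of one spot."""
    x0, y0 = int(round(spot.x)), int(round(spot.y))
    f_c = int(math.floor(spot.z)) + 1  # frame containing the centroid
    xs = slice(max(x0 - half, 0), min(x0 + half + 1, det.nx))
    ys = slice(max(y0 - half, 0), min(y0 + half + 1, det.ny))
    flo, fhi = max(f_c - zhalf, 1), min(f_c + zhalf, len(frames))
    windows = [frames[f - 1].counts[ys, xs].astype(float) for f in range(flo, fhi + 1)]
    if not windows:
        return None
    cube = np.stack(windows)
    bg = np.median([w[0, :].mean() + w[-1, :].mean() for w in windows]) / 2.0
    w = cube - bg
    # keep only pixels clearly above the noise, otherwise the clipped
    # noise floor dominates the second moments of weak tails
    noise = math.sqrt(max(bg, 1.0))
    w[w < 3.0 * noise] = 0.0
    total = w.sum()
    if total <= 0:
        return None
    # detector footprint from the peak frame only (clean of rocking)
    frame_sums = w.sum(axis=(1, 2))
    peak = int(np.argmax(frame_sums))
    wp = w[peak]
    tp = wp.sum()
    if tp <= 0:
        return None
    yy, xx = np.mgrid[0 : wp.shape[0], 0 : wp.shape[1]]
    mx = (wp * xx).sum() / tp
    my = (wp * yy).sum() / tp
    var_x = (wp * (xx - mx) ** 2).sum() / tp
    var_y = (wp * (yy - my) ** 2).sum() / tp
    var_px = max(0.5 * (var_x + var_y) - 1.0 / 12.0, 0.0)
    # undo the shrinkage from thresholding a 2D Gaussian at fraction q of
    # its peak: per-axis variance scales by 1 - L e^-L / (1 - e^-L),
    # L = ln(1/q)
    peak_val = float(wp.max())
    q = min(3.0 * noise / max(peak_val, 1e-9), 0.9)
    if q > 1e-6:
        L = math.log(1.0 / q)
        shrink = 1.0 - L * math.exp(-L) / (1.0 - math.exp(-L))
        if shrink > 0.1:
            var_px /= shrink
    # rocking: raw background-subtracted counts over the peak-frame
    # footprint, without any threshold, so faint sidebands are unbiased
    mask = wp > 0
    raw_sums = np.array([(frame - bg)[mask].sum() for frame in cube])
    raw_sums = np.maximum(raw_sums, 0.0)
    lo = max(peak - 1, 0)
    tri = raw_sums[lo : peak + 2]
    sideband = float((tri.sum() - raw_sums[peak]) / max(tri.sum(), 1e-12))
    return var_px, sideband


# ---------------------------------------------------------------------------
# mapping pixels onto the profile grid

def map_to_profile(
    pixel_xy: np.ndarray,  # (n, 2) pixel coordinates
    pixel_counts: np.ndarray,  # (n,) background-subtracted counts
    pixel_frames: np.ndarray,  # (n,) 1-based frame numbers
    prediction: Prediction,
    domain: IntegrationDomain,
    models: ExperimentModel,
    grid_dims: tuple[int, int, int] = GRID_DIMS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Deposit pixel counts on the (e1, e2, spindle) grid with trilinear weights.

    Returns (counts grid, coverage-weight grid, spilled counts).  The grid
    spans (+-delta_D, +-delta_D, +-delta_M); counts falling outside are
    tallied as spilled (the profile-truncation diagnostic).
    """
    beam, gonio = models.beam, models.gonio
    s0 = beam.s0
    phi_c = prediction.phi_c
    rp = rotation_matrix(gonio.axis, phi_c) @ models.crystal.pstar(prediction.hkl)
    s1 = s0 + rp
    e1, e2, _ = ewald_frame(s1, s0)
    lam = beam.wavelength

    # 2x2 sub-pixel subdivision smooths the deposition of footprints that
    # are narrow compared with the voxel size (anti-aliasing); the same
    # treatment applies to template and observation alike
    offsets = np.array([[-0.25, -0.25], [-0.25, 0.25], [0.25, -0.25], [0.25, 0.25]])
    pixel_xy = (pixel_xy[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    pixel_counts = np.repeat(np.asarray(pixel_counts, dtype=float) / 4.0, 4)
    pixel_frames = np.repeat(np.asarray(pixel_frames, dtype=float), 4)

    pos = pixel_to_lab(models.detector, pixel_xy[:, 0], pixel_xy[:, 1])
    sp = pos / np.linalg.norm(pos, axis=1)[:, None] / lam
    dvec = sp - s1
    to_deg = math.degrees(1.0) * lam  # angular offset on the sphere of radius 1/lambda
    eps1 = (dvec @ e1) * to_deg
    eps2 = (dvec @ e2) * to_deg

    # a frame integrates over its whole phi interval: distribute each
    # pixel's counts across sub-steps of that interval, weighted by the
    # predicted rocking density, so observations share the template's
    # phase-free shape regardless of where phi_c falls within the frame
    n_sub = 5
    phi_start = gonio.phi_of_z(pixel_frames - 1.0)
    sub = (np.arange(n_sub) + 0.5) / n_sub * gonio.delta_phi
    phi_s = phi_start[:, None] + sub[None, :]
    rock = np.exp(-0.5 * ((phi_s - phi_c) / max(domain.sigma_M, 1e-6)) ** 2)
    norm = rock.sum(axis=1, keepdims=True)
    rock = np.where(norm > 1e-12, rock / np.maximum(norm, 1e-12), 1.0 / n_sub)
    eps3 = (phi_s - phi_c).ravel()
    eps1 = np.repeat(eps1, n_sub)
    eps2 = np.repeat(eps2, n_sub)
    pixel_counts = (np.asarray(pixel_counts, dtype=float)[:, None] * rock).ravel()

    n1, n2, n3 = grid_dims
    # continuous grid coordinates; voxel centres at integers 0..n-1
    g1 = (eps1 / domain.delta_D + 1.0) * (n1 - 1) / 2.0
    g2 = (eps2 / domain.delta_D + 1.0) * (n2 - 1) / 2.0
    g3 = (eps3 / domain.delta_M + 1.0) * (n3 - 1) / 2.0
    grid = np.zeros((n3, n2, n1))
    weight = np.zeros((n3, n2, n1))
    inside = (
        (g1 >= 0) & (g1 <= n1 - 1) & (g2 >= 0) & (g2 <= n2 - 1) & (g3 >= 0) & (g3 <= n3 - 1)
    )
    spilled = float(np.maximum(pixel_counts[~inside], 0.0).sum())
    c = np.asarray(pixel_counts, dtype=float)[inside]
    x1, x2, x3 = g1[inside], g2[inside], g3[inside]
    i1 = np.minimum(x1.astype(int), n1 - 2)
    i2 = np.minimum(x2.astype(int), n2 - 2)
    i3 = np.minimum(x3.astype(int), n3 - 2)
    f1, f2, f3 = x1 - i1, x2 - i2, x3 - i3
    for d3 in (0, 1):
        w3 = f3 if d3 else 1.0 - f3
        for d2 in (0, 1):
            w2 = f2 if d2 else 1.0 - f2
            for d1 in (0, 1):
                w1 = f1 if d1 else 1.0 - f1
                w = w1 * w2 * w3
                np.add.at(grid, (i3 + d3, i2 + d2, i1 + d1), c * w)
                np.add.at(weight, (i3 + d3, i2 + d2, i1 + d1), w)
    return grid, weight, spilled


def detector_region(x: float, y: float, det) -> int:
    """0..8 index of the 3x3 partition of the detector face."""
    cx = min(int(3 * x / det.nx), 2)
    cy = min(int(3 * y / det.ny), 2)
    return 3 * cy + cx


def learn_templates(
    observations: list[tuple[int, MappedObservation]],  # (region, mapped strong reflection)
    cut_percent: float = 2.0,
) -> dict[int, ProfileGrid]:
    """Average the mapped strong reflections of each detector region.

    Returns one template per region (9 per batch); regions with fewer
    than 10 contributors borrow the global template.
    """
    by_region: dict[int, np.ndarray] = {}
    global_sum = None
    counts_per_region = {r: 0 for r in range(N_DETECTOR_REGIONS)}
    for region, obs in observations:
        # signed residuals: background noise cancels across reflections,
        # clipping happens only once on the accumulated template
        bg_removed = obs.counts - obs.background * obs.weight
        by_region[region] = by_region.get(region, 0.0) + bg_removed
        global_sum = bg_removed if global_sum is None else global_sum + bg_removed
        counts_per_region[region] += 1
    templates: dict[int, ProfileGrid] = {}
    global_template = (
        ProfileGrid.from_counts(global_sum, cut_percent) if global_sum is not None else None
    )
    for region in range(N_DETECTOR_REGIONS):
        if counts_per_region[region] >= 10:
            templates[region] = ProfileGrid.from_counts(by_region[region], cut_percent)
        elif global_template is not None:
            templates[region] = global_template
        else:
            raise ValueError("no strong reflections to learn templates from")
    return templates


def fit_profile(
    obs: MappedObservation,
    template: ProfileGrid,
    minpk: float = 75.0,
):
    """Weighted least-squares profile fit.

    Solves for (I, b) in ``counts = I * p + b * weight`` over the covered
    support voxels.  Returns (intensity, variance, partiality) or raises
    ``ProfileFitError`` when the observation is degenerate or covers less
    than MINPK percent of the template.
    """
    mask = template.support_mask
    if not mask.any():
        raise ProfileFitError("empty template support")
    covered = obs.covered & mask
    p_covered = template.values[covered]
    # recorded fraction of the profile; the fit below estimates the full
    # intensity from the recorded part, so partiality gates acceptance
    # (MINPK) rather than rescaling
    partiality = float(template.values[obs.covered].sum())
    if partiality * 100.0 < minpk:
        raise ProfileFitError(f"partial reflection: {partiality * 100:.1f}% < MINPK", partiality)
    c = obs.counts[covered] - obs.background * obs.weight[covered]
    w_cov = obs.weight[covered]
    p = p_covered

    def solve(var):
        wls = 1.0 / var
        a11 = float((wls * p * p).sum())
        a12 = float((wls * p * w_cov).sum())
        a22 = float((wls * w_cov * w_cov).sum())
        b1 = float((wls * p * c).sum())
        b2 = float((wls * w_cov * c).sum())
        det = a11 * a22 - a12 * a12
        if det <= 1e-12 * max(a11 * a22, 1e-30):
            raise ProfileFitError("singular profile-fit normal matrix", partiality)
        return (b1 * a22 - b2 * a12) / det, a22 / det

    # two passes: the second pass weights by the fitted model rather than
    # the observed counts, avoiding the attenuation bias of weights that
    # are correlated with the noise
    var0 = obs.bg_variance * np.maximum(w_cov, 0.25) + 1.0
    intensity, _ = solve(var0)
    model = np.maximum(intensity, 0.0) * p + obs.background * w_cov
    var1 = np.maximum(model, 0.0) + obs.bg_variance * np.maximum(w_cov, 0.25) + 1.0
    intensity, var_i = solve(var1)
    return intensity, var_i, partiality


class ProfileFitError(RuntimeError):
    def __init__(self, message, partiality: float | None = None):
        super().__init__(message)
        self.partiality = partiality


# ---------------------------------------------------------------------------
# the INTEGRATE driver

@dataclass
class IntegrationResult:
    records: list[ReflectionRecord]
    domain: IntegrationDomain
    n_discarded: int
    n_templates_per_batch: dict[int, int]
    batch_of_record: list[int] = field(default_factory=list)
    frame_overlay: CbfImage | None = None
    log: str = ""


def integrate_range(
    frames: list[CbfImage],
    models: ExperimentModel,
    bkgpix: PixelTable,
    gain: PixelTable,
    data_range: tuple[int, int] | None = None,
    resolution_range: tuple[float, float] = (20.0, 2.0),
    delphi: float | None = None,
    cut: float = 2.0,
    minpk: float = 75.0,
    refine_classes: set[str] | None = None,
    strong_sigma: float = 10.0,
    spots_for_shape=None,
    min_zeta: float = 0.1,
) -> IntegrationResult:
    """Predict, learn profiles and fit every reflection in the data range.

    Frames are processed in rotation batches at least as wide as the
    integration domain; templates are learned per batch in nine detector
    regions; reflections spanning a batch boundary are integrated in the
    batch containing their centroid, using pixels from both sides.
    """
    det, gonio = models.detector, models.gonio
    if data_range is None:
        data_range = (1, len(frames))
    if spots_for_shape is not None:
        domain = estimate_spot_shape(frames, spots_for_shape, models)
    else:
        c = models.crystal
        domain = IntegrationDomain(c.sigma_M, c.sigma_D, 8 * c.sigma_M, 8 * c.sigma_D)

    # batch width: smallest whole number of frames covering the domain
    if delphi is None:
        delphi = max(2 * domain.delta_M + gonio.delta_phi, 5 * gonio.delta_phi)
    batch_frames = max(int(math.ceil(delphi / gonio.delta_phi)), 1)
    first, last = data_range
    batches = []
    f = first
    while f <= last:
        batches.append((f, min(f + batch_frames - 1, last)))
        f += batch_frames

    # reflections too close to the spindle axis carry extreme Lorentz
    # factors and unreliable intensities; they are excluded up front
    preds = [
        p
        for p in predict_reflections(models, data_range, resolution_range)
        if p.on_detector and first - 1 <= p.z <= last and abs(p.zeta) >= min_zeta
    ]
    work = models
    records: list[ReflectionRecord] = []
    batch_ids: list[int] = []
    n_templates: dict[int, int] = {}
    n_discarded = 0
    log_lines = [f"integration domain: sigma_D={domain.sigma_D:.4f} deg, "
                 f"sigma_M={domain.sigma_M:.4f} deg, delta_D={domain.delta_D:.4f}, "
                 f"delta_M={domain.delta_M:.4f}", f"batch width: {batch_frames} frames"]

    for batch_no, (b0, b1) in enumerate(batches, start=1):
        z_hi = b1 if batch_no == len(batches) else b1 - 1e-9
        batch_preds = [p for p in preds if b0 - 1 <= p.z <= z_hi]
        if not batch_preds:
            log_lines.append(f"batch {batch_no}: no predictions")
            n_templates[batch_no] = 0
            continue
        if refine_classes:
            work = _refine_on_batch(frames, work, batch_preds, bkgpix, gain, refine_classes,
                                    b0, b1, domain)
            batch_preds = _repredict(work, batch_preds, (b0, b1), resolution_range)
        mapped = []
        for p in batch_preds:
            obs = _collect_observation(frames, p, domain, work, bkgpix, gain)
            mapped.append(obs)
        strong = []
        for p, obs in zip(batch_preds, mapped):
            if obs is None:
                continue
            total = float((obs.counts - obs.background * obs.weight).sum())
            noise = math.sqrt(max(obs.bg_variance * obs.n_pixels, 1.0))
            if total > strong_sigma * noise:
                strong.append((detector_region(p.x, p.y, det), obs))
        try:
            templates = learn_templates(strong, cut)
        except ValueError:
            log_lines.append(f"batch {batch_no}: no strong reflections; batch skipped")
            n_templates[batch_no] = 0
            n_discarded += sum(o is not None for o in mapped)
            continue
        n_templates[batch_no] = len(templates)
        for p, obs in zip(batch_preds, mapped):
            if obs is None:
                n_discarded += 1
                continue
            region = detector_region(p.x, p.y, det)
            try:
                intensity, variance, partiality = fit_profile(obs, templates[region], minpk)
            except ProfileFitError:
                n_discarded += 1
                continue
            records.append(
                ReflectionRecord(
                    hkl=p.hkl,
                    iobs=intensity,
                    sigma=math.sqrt(max(variance, 1e-12)),
                    xd=p.x + 1.0,
                    yd=p.y + 1.0,
                    zd=p.z,
                    rlp=p.rlp,
                    peak=partiality * 100.0,
                    corr=0.0,
                    psi=0.0,
                )
            )
            batch_ids.append(batch_no)
        log_lines.append(
            f"batch {batch_no}: frames {b0}-{b1}, {len(batch_preds)} predictions, "
            f"{len(strong)} strong, {len(templates)} templates"
        )

    overlay = _frame_overlay(frames[last - 1], [p for p in preds if last - 1 <= p.z <= last], det)
    return IntegrationResult(records, domain, n_discarded, n_templates, batch_ids, overlay,
                             "\n".join(log_lines) + "\n")


def _collect_observation(frames, prediction, domain, models, bkgpix, gain):
    """Gather the contributing pixels of one reflection."""
    det, gonio = models.detector, models.gonio
    # collect within 0.8 of the full domain radius: still > 6 sigma_D for
    # the default 8-sigma domain, but keeps the tails of neighbouring
    # reflections out of the mapped grid
    r_px = int(math.ceil(
        0.8 * det.distance * math.tan(math.radians(domain.delta_D)) / det.qx)) + 1
    zeta = abs(prediction.zeta)
    dz_frames = domain.delta_M / gonio.delta_phi
    f_c = prediction.z  # continuous
    f_lo = max(int(math.floor(f_c - dz_frames)) + 1, 1)
    f_hi = min(int(math.ceil(f_c + dz_frames)), len(frames))
    if f_hi < f_lo:
        return None
    x0, y0 = int(round(prediction.x)), int(round(prediction.y))
    xs = slice(max(x0 - r_px, 0), min(x0 + r_px + 1, det.nx))
    ys = slice(max(y0 - r_px, 0), min(y0 + r_px + 1, det.ny))
    if xs.start >= xs.stop or ys.start >= ys.stop:
        return None
    trust = bkgpix.trusted[ys, xs]
    if not trust.any():
        return None
    gx, gy = np.meshgrid(np.arange(xs.start, xs.stop), np.arange(ys.start, ys.stop))
    rad2 = (gx - prediction.x) ** 2 + (gy - prediction.y) ** 2
    # a reflection whose peak area touches untrusted pixels (beamstop,
    # face edge) cannot be measured reliably and is discarded outright
    r_core = 0.5 * r_px + 2.0
    if (~trust & (rad2 <= r_core**2)).any():
        return None
    # the window itself must not be clipped by the detector edge either
    if (prediction.x - r_core < 0 or prediction.x + r_core > det.nx - 1
            or prediction.y - r_core < 0 or prediction.y + r_core > det.ny - 1):
        return None
    inner = rad2 <= r_px**2
    border = (~inner | (rad2 > (0.75 * r_px) ** 2)) & trust

    pix_list, cnt_list, frm_list = [], [], []
    bgs = []
    for f in range(f_lo, f_hi + 1):
        window = frames[f - 1].counts[ys, xs].astype(float)
        if border.any():
            bgs.append(np.median(window[border]))
        sel = inner & trust
        pix_list.append(np.column_stack([gx[sel], gy[sel]]))
        cnt_list.append(window[sel])
        frm_list.append(np.full(sel.sum(), f))
    if not pix_list:
        return None
    background = float(np.median(bgs)) if bgs else 0.0
    g = float(np.median(gain.values[gain.trusted])) if gain.trusted.any() else 1.0
    bg_var = max(g * background, 1.0)
    xy = np.concatenate(pix_list)
    counts = np.concatenate(cnt_list) - background
    frames_arr = np.concatenate(frm_list)
    grid, weight, spilled = map_to_profile(
        xy.astype(float), counts, frames_arr.astype(float), prediction, domain, models
    )
    obs = MappedObservation(
        counts=grid + background * weight,  # keep raw counts; bg handled downstream
        weight=weight,
        background=background,
        bg_variance=bg_var,
        spilled=spilled,
        n_pixels=float(len(counts)),
    )
    return obs


def _refine_on_batch(frames, models, batch_preds, bkgpix, gain, classes, b0, b1, domain):
    """Refine geometry on strong spots of this batch (REFINE(INTEGRATE)=)."""
    from .spotfind import find_spots

    try:
        spots = find_spots(frames[b0 - 1 : b1], b0, bkgpix, gain)
    except Exception:
        return models
    if len(spots) < 20:
        return models
    from .indexing import index_with_model

    xyz = np.array([[s.x, s.y, s.z] for s in spots])
    pstars = _pstars(models, xyz)
    hkls, ok = index_with_model(models, pstars)
    if ok.sum() < 20:
        return models
    try:
        refined, _, _ = refine_geometry(models, hkls[ok], xyz[ok], set(classes))
        return refined
    except (ValueError, np.linalg.LinAlgError):
        return models


def _pstars(models, xyz):
    from .geometry import scattering_vector

    return scattering_vector(models, xyz[:, 0], xyz[:, 1], xyz[:, 2])


def _repredict(models, batch_preds, frame_window, resolution_range):
    preds = predict_reflections(models, frame_window, resolution_range)
    return [p for p in preds if p.on_detector]


def _frame_overlay(frame: CbfImage, preds, det) -> CbfImage:
    """Copy of the last frame with predicted spots encircled."""
    out = frame.counts.copy()
    high = int(out.max()) + 1000
    radius = 5
    theta = np.linspace(0, 2 * math.pi, 32, endpoint=False)
    for p in preds:
        cx, cy = p.x, p.y
        px = np.clip(np.round(cx + radius * np.cos(theta)).astype(int), 0, det.nx - 1)
        py = np.clip(np.round(cy + radius * np.sin(theta)).astype(int), 0, det.ny - 1)
        out[py, px] = high
    return CbfImage(out, dict(frame.header, overlay="predicted spots encircled"))
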