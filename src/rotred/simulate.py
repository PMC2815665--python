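"""Ground-truth rotation-stack simulator.

Renders Bragg spots of a known lattice as separable Gaussians: the rocking
profile (width ``sigma_M`` degrees about the diffracting angle) splits each
reflection's counts over adjacent frames, and the detector footprint is an
isotropic Gaussian whose width follows from the beam divergence
``sigma_D`` at the given crystal-to-detector distance.  Poisson background
with configurable gain, a beamstop shadow, optional ice rings, alien spots
and dose-dependent intensity decay emulate the blemishes the reduction
pipeline has to cope with.

Every stack comes with a manifest listing each rendered reflection's true
centroid, true intensity and per-frame fractions, so all later stages can
be scored against known truth.  Regenerating with the same seed is
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .cbf import CbfImage, write_cbf
from .geometry import ExperimentModel, predict_reflections

__all__ = [
    "GroundTruth",
    "TrueSpot",
    "make_intensities",
    "render_stack",
    "render_calibration_image",
    "render_dark_image",
    "write_manifest",
    "read_manifest",
]


@dataclass
class TrueSpot:
    hkl: tuple[int, int, int]
    x: float
    y: float
    z: float
    intensity: float  # counts deposited over all frames (pre-Poisson)
    fractions: dict[int, float]  # 1-based frame -> fraction of the profile


@dataclass
class GroundTruth:
    models: ExperimentModel
    intensities: dict[tuple[int, int, int], float]
    background_level: float = 20.0  # counts / pixel / frame above dark
    dark_level: float = 10.0
    gain: float = 1.0  # variance / mean of the counting statistics
    dose_decay: float = 0.0  # per-frame exponential decay rate of intensities
    shadow: tuple[float, float, float] | None = None  # beamstop circle (x, y, radius)
    ice_rings: tuple[float, ...] = ()  # d-spacings (Angstrom) of powder rings
    aliens: list[tuple[float, float, float, float]] = field(default_factory=list)  # x, y, z, I
    overload: int = 1_000_000
    resolution_range: tuple[float, float] = (20.0, 2.0)
    face_fraction: float = 1.0  # sensitive-face radius / inscribed-circle radius
    seed: int = 0


def make_intensities(
    models: ExperimentModel,
    resolution_range: tuple[float, float] = (20.0, 2.0),
    mean_intensity: float = 5000.0,
    b_factor: float = 15.0,
    seed: int = 0,
    space_group_number: int = 1,
) -> dict[tuple[int, int, int], float]:
    """Wilson-distributed true intensities with B-factor falloff.

    Intensities are constant on symmetry classes of the requested space
    group (Friedel mates included), so merging statistics of noise-free
    renders vanish under the true symmetry.
    """
    import gemmi

    rng = np.random.default_rng(seed)
    xtal = models.crystal
    d_max, d_min = resolution_range
    a, b, c, *_ = xtal.cell
    hmax = int(a / d_min) + 1
    kmax = int(b / d_min) + 1
    lmax = int(c / d_min) + 1
    gops = gemmi.SpaceGroup(int(space_group_number)).operations()
    out: dict[tuple[int, int, int], float] = {}
    class_value: dict[tuple[int, int, int], float] = {}
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == k == l == 0:
                    continue
                d = 1.0 / np.linalg.norm(xtal.pstar((h, k, l)))
                if not d_min <= d <= d_max:
                    continue
                mates = _sym_mates((h, k, l), gops)
                rep = max(mates)
                if rep not in class_value:
                    scale = math.exp(-b_factor / (2.0 * d * d))
                    class_value[rep] = float(rng.exponential(mean_intensity) * scale)
                out[(h, k, l)] = class_value[rep]
    return out


def _sym_mates(hkl, gops) -> list[tuple[int, int, int]]:
    mates = set()
    for op in gops.sym_ops:
        m = tuple(op.apply_to_hkl(list(hkl)))
        mates.add(m)
        mates.add(tuple(-v for v in m))  # Friedel
    return sorted(mates)


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, gain: float) -> np.ndarray:
    """Poisson counts with gain g emulated as g * Poisson(mu / g)."""
    return gain * rng.poisson(np.maximum(mu, 0.0) / gain)


def render_stack(truth: GroundTruth, n_frames: int):
    """Render frames 1..n_frames.  Returns (frames, manifest).

    Before Poisson sampling the deposited spot counts are exactly the true
    intensity times the per-frame profile fractions (energy bookkeeping).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    models = truth.models
    xtal = models.crystal
    if xtal.sigma_M <= 0 or xtal.sigma_D <= 0:
        raise ValueError("sigma_M and sigma_D must be positive")
    det, gonio = models.detector, models.gonio
    rng = np.random.default_rng(truth.seed)
    mu = np.zeros((n_frames, det.ny, det.nx))  # expected counts above dark

    preds = predict_reflections(models, (1, n_frames), truth.resolution_range)
    sigma_px = _footprint_sigma_px(models)
    sigma_z = xtal.sigma_M / gonio.delta_phi  # rocking width in frames

    # dead zone: beamstop shadow plus the corners outside the circular
    # sensitive face; spots whose footprint would be clipped by a dead
    # region are neither rendered nor listed in the manifest, so the
    # manifest intensity is always fully recorded
    yy, xx = np.mgrid[0 : det.ny, 0 : det.nx]
    face_r = truth.face_fraction * min(det.nx, det.ny) / 2.0
    cx, cy = (det.nx - 1) / 2.0, (det.ny - 1) / 2.0
    dead = np.hypot(xx - cx, yy - cy) > face_r
    if truth.shadow is not None:
        sx, sy, sr = truth.shadow
        dead |= (xx - sx) ** 2 + (yy - sy) ** 2 <= sr**2
    margin = 3.0 * sigma_px + 1.0

    def clipped(px, py):
        if np.hypot(px - cx, py - cy) > face_r - margin:
            return True
        if truth.shadow is not None and np.hypot(px - sx, py - sy) < sr + margin:
            return True
        return False

    manifest: list[TrueSpot] = []
    for p in preds:
        if not p.on_detector:
            continue
        if clipped(p.x, p.y):
            continue
        intensity = truth.intensities.get(p.hkl)
        if intensity is None:
            continue
        if truth.dose_decay:
            intensity = intensity * math.exp(-truth.dose_decay * p.z)
        # recorded counts carry the Lorentz-polarization modulation
        # (slow Ewald crossings near the axis accumulate more counts);
        # the correction stage divides it back out
        intensity = intensity / p.rlp
        fractions = _frame_fractions(p.z, sigma_z, n_frames)
        if not fractions:
            continue
        for f, frac in fractions.items():
            _deposit_gaussian(mu[f - 1], p.x, p.y, sigma_px, intensity * frac)
        manifest.append(TrueSpot(p.hkl, p.x, p.y, p.z, intensity * sum(fractions.values()), fractions))

    for x, y, z, inten in truth.aliens:
        fractions = _frame_fractions(z, sigma_z, n_frames)
        for f, frac in fractions.items():
            _deposit_gaussian(mu[f - 1], x, y, sigma_px, inten * frac)

    background = np.full((det.ny, det.nx), float(truth.background_level))
    if truth.ice_rings:
        radius = np.hypot((xx - det.orgx) * det.qx, (yy - det.orgy) * det.qy)
        for d in truth.ice_rings:
            theta = math.asin(models.beam.wavelength / (2.0 * d))
            r_ring = det.distance * math.tan(2.0 * theta)
            background = background + 8.0 * truth.background_level * np.exp(
                -0.5 * ((radius - r_ring) / (2.0 * det.qx)) ** 2
            )
    frames: list[CbfImage] = []
    for i in range(n_frames):
        expected = np.where(dead, 0.0, mu[i] + background)
        counts = _sample_counts(rng, expected, truth.gain) + truth.dark_level
        counts = np.minimum(counts, truth.overload)
        img = CbfImage(np.rint(counts).astype(np.int32), {"frame": str(i + 1)})
        frames.append(img)
    return frames, manifest


def _footprint_sigma_px(models: ExperimentModel) -> float:
    """Detector-plane spot width (pixels) from the divergence sigma_D."""
    det = models.detector
    sigma_mm = models.detector.distance * math.tan(math.radians(models.crystal.sigma_D))
    return max(sigma_mm / det.qx, 0.3)


def _frame_fractions(z: float, sigma_z: float, n_frames: int) -> dict[int, float]:
    """Gaussian rocking-curve fraction falling on each frame."""
    lo = max(1, int(math.floor(z - 5 * sigma_z)))
    hi = min(n_frames, int(math.ceil(z + 5 * sigma_z)) + 1)
    out: dict[int, float] = {}
    for f in range(lo, hi + 1):
        if not 1 <= f <= n_frames:
            continue
        frac = float(ndtr((f - z) / sigma_z) - ndtr((f - 1 - z) / sigma_z))
        if frac > 1e-6:
            out[f] = frac
    return out


def _deposit_gaussian(image: np.ndarray, x: float, y: float, sigma: float, counts: float) -> None:
    """Add an integrated-Gaussian footprint of total ``counts`` at (x, y)."""
    ny, nx = image.shape
    half = max(3, int(math.ceil(4 * sigma)))
    x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
    y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, nx)
    y0c, y1c = max(y0, 0), min(y1, ny)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    # integrate the Gaussian over each pixel (pixel centres at integers)
    fx = ndtr((xs + 0.5 - x) / sigma) - ndtr((xs - 0.5 - x) / sigma)
    fy = ndtr((ys + 0.5 - y) / sigma) - ndtr((ys - 0.5 - y) / sigma)
    image[y0c:y1c, x0c:x1c] += counts * np.outer(fy, fx)


def render_calibration_image(
    det_shape: tuple[int, int],
    grid_spacing: float,
    distortion=None,
    peak_counts: float = 5000.0,
    background: float = 10.0,
    sigma: float = 1.5,
    seed: int = 0,
):
    """Calibration-plate image: bright peaks at (possibly distorted) grid nodes.

    ``distortion(x, y) -> (dx, dy)`` displaces each node; None means the
    identity.  Returns (image, true node positions after distortion).
    """
    ny, nx = det_shape
    rng = np.random.default_rng(seed)
    mu = np.zeros((ny, nx))
    nodes = []
    margin = 3 * sigma
    for gy in np.arange(grid_spacing / 2.0, ny, grid_spacing):
        for gx in np.arange(grid_spacing / 2.0, nx, grid_spacing):
            dx, dy = distortion(gx, gy) if distortion is not None else (0.0, 0.0)
            px, py = gx + dx, gy + dy
            if margin <= px <= nx - 1 - margin and margin <= py <= ny - 1 - margin:
                _deposit_gaussian(mu, px, py, sigma, peak_counts)
                nodes.append((gx, gy, px, py))
    counts = rng.poisson(mu + background)
    return CbfImage(counts.astype(np.int32)), nodes


def render_dark_image(det_shape: tuple[int, int], level: float, poisson: bool = True, seed: int = 0):
    """Detector dark frame: constant level with optional counting noise."""
    ny, nx = det_shape
    if level < 0:
        raise ValueError("dark level must be non-negative")
    if poisson and level > 0:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(level, size=(ny, nx))
    else:
        counts = np.full((ny, nx), int(round(level)))
    return CbfImage(counts.astype(np.int32))


# ---------------------------------------------------------------------------
# manifest I/O (plain text, so the pipeline itself only ever sees CBF input)

def write_manifest(manifest: list[TrueSpot], path) -> None:
    with open(path, "w") as fh:
        fh.write("# h k l x y z intensity frame:fraction...\n")
        for s in manifest:
            fracs = " ".join(f"{f}:{v:.6f}" for f, v in sorted(s.fractions.items()))
            fh.write(
                f"{s.hkl[0]} {s.hkl[1]} {s.hkl[2]} {s.x:.4f} {s.y:.4f} {s.z:.4f} "
                f"{s.intensity:.4f} {fracs}\n"
            )


def read_manifest(path) -> list[TrueSpot]:
    out: list[TrueSpot] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            hkl = tuple(int(v) for v in parts[:3])
            x, y, z, inten = (float(v) for v in parts[3:7])
            fractions = {}
            for token in parts[7:]:
                f, v = token.split(":")
                fractions[int(f)] = float(v)
            out.append(TrueSpot(hkl, x, y, z, inten, fractions))
    return out


def default_experiment(
    cell=(16.0, 19.0, 22.0, 90.0, 90.0, 90.0),
    orientation_seed: int | None = None,
    sigma_M: float = 0.2,
    sigma_D: float = 0.3,
) -> ExperimentModel:
    """The baseline virtual experiment used throughout the test suite.

    A 256x256 detector of 0.3 mm pixels at 96 mm with a 1 Angstrom beam
    covers about 22 degrees of scattering angle at the face edge; small
    cells (15-25 Angstrom) then separate neighbouring reflections by
    well over the integration domain.  The crystal orientation is drawn
    uniformly from the seed.
    """
    from scipy.spatial.transform import Rotation

    from .geometry import BeamModel, CrystalModel, DetectorModel, GoniometerModel

    orientation = None
    if orientation_seed is not None:
        rng = np.random.default_rng(orientation_seed)
        orientation = Rotation.random(random_state=rng).as_matrix()
    beam = BeamModel(wavelength=1.0)
    gonio = GoniometerModel(axis=[1.0, 0.0, 0.0], phi0=0.0, delta_phi=1.0)
    det = DetectorModel(nx=256, ny=256, qx=0.3, qy=0.3, orgx=127.5, orgy=127.5, distance=96.0)
    xtal = CrystalModel.from_cell(cell, orientation, sigma_M=sigma_M, sigma_D=sigma_D)
    return ExperimentModel(beam, gonio, det, xtal)


def write_simulation_workdir(
    workdir,
    cell=(16.0, 19.0, 22.0, 90.0, 90.0, 90.0),
    n_frames: int = 40,
    seed: int = 0,
    dose_decay: float = 0.0,
    resolution_range=(20.0, 2.6),
    background_level: float = 20.0,
    mean_intensity: float = 8000.0,
    space_group_number: int = 1,
    shadow=(127.5, 127.5, 10.0),
):
    """Render a stack plus a matching keyword file into ``workdir``.

    Writes frame_####.cbf, XDS.INP, the ground-truth manifest and an
    XPARM-style file of the true geometry (for scoring only; the
    pipeline never reads it).
    """
    from pathlib import Path

    from .files import write_xparm

    workdir = Path(workdir)
    models = default_experiment(cell, orientation_seed=seed)
    intensities = make_intensities(models, resolution_range, mean_intensity,
                                   seed=seed + 1, space_group_number=space_group_number)
    truth = GroundTruth(models, intensities, background_level=background_level,
                        dose_decay=dose_decay, shadow=shadow,
                        resolution_range=resolution_range, seed=seed + 2)
    frames, manifest = render_stack(truth, n_frames)
    for i, frame in enumerate(frames, start=1):
        write_cbf(frame, workdir / f"frame_{i:04d}.cbf")
    write_manifest(manifest, workdir / "ground_truth_manifest.txt")
    write_xparm(models, workdir / "ground_truth_geometry.txt")
    (workdir / "XDS.INP").write_text(
        "! synthetic rotation stack\n"
        "JOB= XDS\n"
        "NAME_TEMPLATE_OF_DATA_FRAMES= frame_????.cbf\n"
        f"DATA_RANGE= 1 {n_frames}\n"
        f"BACKGROUND_RANGE= 1 {min(5, n_frames)}\n"
        f"SPOT_RANGE= 1 {n_frames}\n"
        "OSCILLATION_RANGE= 1.0\n"
        "STARTING_ANGLE= 0.0\n"
        "X-RAY_WAVELENGTH= 1.0\n"
        "NX= 256 NY= 256 QX= 0.3 QY= 0.3\n"
        "ORGX= 128.5 ORGY= 128.5\n"
        "DETECTOR_DISTANCE= 96.0\n"
        "ROTATION_AXIS= 1 0 0\n"
        "INCIDENT_BEAM_DIRECTION= 0 0 1\n"
        f"INCLUDE_RESOLUTION_RANGE= {resolution_range[0]} {resolution_range[1]}\n"
    )
    return manifest


def write_stack(frames: list[CbfImage], template: str) -> list[str]:
    """Write frames to ``template`` containing one ``{:0Nd}``-style field."""
    paths = []
    for i, frame in enumerate(frames, start=1):
        path = template.format(i)
        write_cbf(frame, path)
        paths.append(path)
    return paths
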