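"""Experiment geometry: beam, goniometer, detector and crystal models.

Conventions (locked by tests):

* right-handed lab frame, lengths in mm, reciprocal space in 1/Angstrom;
* the incident beam wavevector ``s0`` points from source to crystal with
  ``|s0| = 1/wavelength``; a diffracted wavevector ``S1`` has the same
  modulus and the scattering vector is ``p* = S1 - s0``;
* the spindle rotates by the right-hand rule about the unit axis ``m2``;
  the continuous frame coordinate ``z`` (in frames from the start of the
  data range) maps to the spindle angle ``phi = phi0 + z * delta_phi`` so
  frame number ``f`` (1-based in files) spans ``z`` in ``[f-1, f]``;
* detector pixels are addressed as (x = fast, y = slow), pixel centres at
  integer coordinates, 0-based in memory and 1-based in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

__all__ = [
    "BeamModel",
    "GoniometerModel",
    "DetectorModel",
    "CrystalModel",
    "ExperimentModel",
    "Prediction",
    "rotation_matrix",
    "pixel_to_lab",
    "lab_to_pixel",
    "scattering_vector",
    "predict_reflections",
    "ewald_frame",
    "refine_geometry",
    "cell_parameters",
    "cell_to_reciprocal_basis",
]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-hand-rule rotation about ``axis`` by ``angle_deg`` degrees."""
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * _unit(axis)).as_matrix()


@dataclass
class BeamModel:
    wavelength: float  # Angstrom
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    polarization_fraction: float = 0.5
    polarization_plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self):
        self.direction = _unit(self.direction)
        self.polarization_plane_normal = _unit(self.polarization_plane_normal)
        if not 0.5 <= self.polarization_fraction <= 1.0:
            raise ValueError("polarization fraction must lie in [0.5, 1]")

    @property
    def s0(self) -> np.ndarray:
        """Incident wavevector, |s0| = 1/wavelength."""
        return self.direction / self.wavelength


@dataclass
class GoniometerModel:
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    phi0: float = 0.0  # deg, spindle angle at the start of frame 1
    delta_phi: float = 0.1  # deg per frame, > 0

    def __post_init__(self):
        self.axis = _unit(self.axis)
        if self.delta_phi <= 0:
            raise ValueError("each frame must cover the same positive rotation")

    def phi_of_z(self, z):
        """Spindle angle at continuous frame coordinate ``z``."""
        return self.phi0 + np.asarray(z, dtype=float) * self.delta_phi

    def z_of_phi(self, phi):
        return (np.asarray(phi, dtype=float) - self.phi0) / self.delta_phi


@dataclass
class DetectorModel:
    nx: int  # fast pixels
    ny: int  # slow pixels
    qx: float  # mm / pixel, fast
    qy: float  # mm / pixel, slow
    orgx: float  # beam-centre pixel (fast), 0-based
    orgy: float  # beam-centre pixel (slow), 0-based
    distance: float  # mm, crystal to detector plane
    d1: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    d2: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self):
        self.d1 = _unit(self.d1)
        self.d2 = _unit(self.d2)
        if abs(self.d1 @ self.d2) > 1e-10:
            raise ValueError("detector basis must be orthogonal")

    @property
    def d3(self) -> np.ndarray:
        """Detector normal; the origin pixel is the point nearest the crystal."""
        return np.cross(self.d1, self.d2)


def cell_to_reciprocal_basis(cell: tuple[float, ...]) -> np.ndarray:
    """Reciprocal basis (rows a*, b*, c*) of a cell (a,b,c,alpha,beta,gamma).

    The direct basis is laid out conventionally: a along x, b in the x-y
    plane; the actual lab orientation is applied separately.
    """
    a, b, c, al, be, ga = cell
    al, be, ga = np.deg2rad([al, be, ga])
    av = np.array([a, 0.0, 0.0])
    bv = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    direct = np.array([av, bv, [cx, cy, cz]])
    return np.linalg.inv(direct).T


def cell_parameters(direct_basis: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(a, b, c, alpha, beta, gamma) of a direct basis given as rows."""
    a, b, c = (np.linalg.norm(v) for v in direct_basis)
    al = np.degrees(np.arccos(np.clip(direct_basis[1] @ direct_basis[2] / (b * c), -1, 1)))
    be = np.degrees(np.arccos(np.clip(direct_basis[0] @ direct_basis[2] / (a * c), -1, 1)))
    ga = np.degrees(np.arccos(np.clip(direct_basis[0] @ direct_basis[1] / (a * b), -1, 1)))
    return (a, b, c, al, be, ga)


@dataclass
class CrystalModel:
    """Reciprocal basis at phi = 0 (rows a*, b*, c*) plus spot-shape widths."""

    rec_basis: np.ndarray  # 3x3, rows a*, b*, c*, 1/Angstrom
    sigma_M: float = 0.1  # deg, mosaic reflecting-range e.s.d.
    sigma_D: float = 0.05  # deg, beam-divergence e.s.d.

    def __post_init__(self):
        self.rec_basis = np.asarray(self.rec_basis, dtype=float)
        if abs(np.linalg.det(self.rec_basis)) < 1e-15:
            raise ValueError("degenerate reciprocal basis")

    @classmethod
    def from_cell(cls, cell, orientation: np.ndarray | None = None, **kw) -> "CrystalModel":
        rec = cell_to_reciprocal_basis(cell)
        if orientation is not None:
            rec = rec @ np.asarray(orientation).T
        return cls(rec, **kw)

    @property
    def direct_basis(self) -> np.ndarray:
        return np.linalg.inv(self.rec_basis).T

    @property
    def cell(self) -> tuple[float, float, float, float, float, float]:
        return cell_parameters(self.direct_basis)

    def pstar(self, hkl) -> np.ndarray:
        """Reciprocal vector(s) of integer indices at phi = 0."""
        return np.asarray(hkl, dtype=float) @ self.rec_basis


@dataclass
class ExperimentModel:
    beam: BeamModel
    gonio: GoniometerModel
    detector: DetectorModel
    crystal: CrystalModel | None = None

    def copy(self) -> "ExperimentModel":
        return ExperimentModel(
            replace(self.beam, direction=self.beam.direction.copy(),
                    polarization_plane_normal=self.beam.polarization_plane_normal.copy()),
            replace(self.gonio, axis=self.gonio.axis.copy()),
            replace(self.detector, d1=self.detector.d1.copy(), d2=self.detector.d2.copy()),
            None if self.crystal is None else replace(
                self.crystal, rec_basis=self.crystal.rec_basis.copy()),
        )


@dataclass
class Prediction:
    hkl: tuple[int, int, int]
    x: float  # fast pixel, 0-based
    y: float  # slow pixel, 0-based
    z: float  # continuous frame coordinate
    phi_c: float  # diffracting spindle angle, deg
    d_spacing: float  # Angstrom
    zeta: float  # rotation-axis component of e1; Lorentz factor is 1/|zeta|
    rlp: float  # reciprocal Lorentz-polarization factor (multiply I by it)
    on_detector: bool = True


def pixel_to_lab(det: DetectorModel, x, y) -> np.ndarray:
    """Lab position (mm) of detector pixel(s) (x fast, y slow)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (
        det.distance * det.d3
        + np.multiply.outer((x - det.orgx) * det.qx, det.d1)
        + np.multiply.outer((y - det.orgy) * det.qy, det.d2)
    )


def lab_to_pixel(det: DetectorModel, s1: np.ndarray):
    """Intersect diffracted ray(s) ``s1`` with the detector plane.

    Returns (x, y, hits) where ``hits`` is False for rays moving away from
    the detector plane.
    """
    s1 = np.atleast_2d(s1)
    t3 = s1 @ det.d3
    hits = t3 > 1e-12
    scale = np.where(hits, det.distance / np.where(hits, t3, 1.0), np.nan)
    point = s1 * scale[:, None]
    x = det.orgx + (point @ det.d1) / det.qx
    y = det.orgy + (point @ det.d2) / det.qy
    return x, y, hits


def scattering_vector(models: ExperimentModel, x, y, z) -> np.ndarray:
    """p*0 of the unrotated crystal from an observed centroid (x, y, z).

    A centroid at the direct-beam position yields the zero vector; callers
    flag those rather than erroring.
    """
    beam, gonio, det = models.beam, models.gonio, models.detector
    pos = pixel_to_lab(det, x, y)
    squeeze = pos.ndim == 1
    pos = np.atleast_2d(pos)
    norms = np.linalg.norm(pos, axis=1)
    s1 = pos / norms[:, None] / beam.wavelength
    prot = s1 - beam.s0
    phi = gonio.phi_of_z(np.atleast_1d(np.asarray(z, dtype=float)))
    # rotate each p* back by -phi about the spindle axis
    out = np.empty_like(prot)
    rots = Rotation.from_rotvec(np.deg2rad(-phi)[:, None] * gonio.axis)
    out = rots.apply(prot)
    # degenerate: observation at the exact beam centre
    direct = np.linalg.norm(prot, axis=1) < 1e-12
    out[direct] = 0.0
    return out[0] if squeeze else out


def _diffracting_angles(pstars: np.ndarray, s0: np.ndarray, axis: np.ndarray):
    """Spindle angles (deg, in [0, 360)) at which each p* crosses the Ewald sphere.

    Returns an (n, 2) array with NaN where no solution exists (blind region).
    """
    m = axis
    p_par = np.outer(pstars @ m, m)
    p_perp = pstars - p_par
    A = p_perp @ s0
    B = np.cross(np.broadcast_to(m, pstars.shape), p_perp) @ s0
    rhs = -0.5 * np.einsum("ij,ij->i", pstars, pstars) - p_par @ s0
    amp = np.hypot(A, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = rhs / amp
    ok = (amp > 0) & (np.abs(ratio) <= 1.0)
    base = np.arctan2(B, A)
    delta = np.arccos(np.where(ok, np.clip(ratio, -1, 1), 0.0))
    phis = np.degrees(np.stack([base + delta, base - delta], axis=1))
    phis = np.mod(phis, 360.0)
    phis[~ok] = np.nan
    return phis


def predict_reflections(
    models: ExperimentModel,
    frame_range: tuple[int, int],
    resolution_range: tuple[float, float] = (20.0, 2.0),
) -> list[Prediction]:
    """All reflections diffracting within ``frame_range`` (1-based, inclusive).

    Both Ewald-sphere crossings of every reciprocal-lattice point inside
    the resolution window are generated; solutions falling off the
    detector face are returned flagged rather than dropped.
    """
    xtal = models.crystal
    if xtal is None:
        raise ValueError("prediction requires a crystal model")
    beam, gonio, det = models.beam, models.gonio, models.detector
    d_max, d_min = resolution_range
    if d_min <= 0:
        d_min = 1e-6
    a, b, c, *_ = xtal.cell
    hmax = int(np.floor(a / d_min)) + 1
    kmax = int(np.floor(b / d_min)) + 1
    lmax = int(np.floor(c / d_min)) + 1
    hs, ks, ls = np.meshgrid(
        np.arange(-hmax, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkls = np.column_stack([hs.ravel(), ks.ravel(), ls.ravel()])
    hkls = hkls[np.any(hkls != 0, axis=1)]
    pstars = hkls @ xtal.rec_basis
    p2 = np.einsum("ij,ij->i", pstars, pstars)
    keep = (p2 >= 1.0 / d_max**2) & (p2 <= 1.0 / d_min**2)
    hkls, pstars, p2 = hkls[keep], pstars[keep], p2[keep]

    phis = _diffracting_angles(pstars, beam.s0, gonio.axis)
    z_lo, z_hi = frame_range[0] - 1.0, float(frame_range[1])
    phi_lo = gonio.phi_of_z(z_lo)
    phi_hi = gonio.phi_of_z(z_hi)

    predictions: list[Prediction] = []
    s0 = beam.s0
    axis = gonio.axis
    for i in range(len(hkls)):
        d = 1.0 / np.sqrt(p2[i])
        for phi in phis[i]:
            if not np.isfinite(phi):
                continue
            # unfold the periodic solution into the covered rotation interval
            n_lo = int(np.ceil((phi_lo - phi) / 360.0))
            n_hi = int(np.floor((phi_hi - phi) / 360.0))
            for n in range(n_lo, n_hi + 1):
                phi_c = phi + 360.0 * n
                rp = rotation_matrix(axis, phi_c) @ pstars[i]
                s1 = s0 + rp
                x, y, hits = lab_to_pixel(det, s1)
                e1_raw = np.cross(s1, s0)
                norm_e1 = np.linalg.norm(e1_raw)
                if norm_e1 < 1e-12:
                    continue  # forward-scattering degenerate
                zeta = float((e1_raw / norm_e1) @ axis)
                if abs(zeta) < 1e-6:
                    continue  # blind region: p* (anti)parallel to the axis
                on_det = bool(hits[0]) and 0 <= x[0] <= det.nx - 1 and 0 <= y[0] <= det.ny - 1
                rlp = _rlp_factor(s1, s0, axis, models.beam)
                predictions.append(
                    Prediction(
                        hkl=tuple(int(v) for v in hkls[i]),
                        x=float(x[0]) if hits[0] else np.nan,
                        y=float(y[0]) if hits[0] else np.nan,
                        z=float(gonio.z_of_phi(phi_c)),
                        phi_c=float(phi_c),
                        d_spacing=float(d),
                        zeta=zeta,
                        rlp=rlp,
                        on_detector=on_det,
                    )
                )
    return predictions


def polarization_factor(s1u: np.ndarray, beam: BeamModel) -> float:
    """Dipole polarization factor for a diffracted unit direction.

    The fraction ``p`` of the beam has its electric vector along
    ``u0 x n`` (in the plane whose normal is ``n``), the remainder along
    the complementary transverse direction; each component scatters with
    ``1 - (e . s1)^2``.  Reduces to ``(1 + cos^2 2theta)/2`` for an
    unpolarized beam.
    """
    u0 = beam.direction
    e_p = np.cross(u0, beam.polarization_plane_normal)
    norm = np.linalg.norm(e_p)
    if norm < 1e-9:
        raise ValueError("polarization plane normal parallel to the beam")
    e_p = e_p / norm
    e_s = np.cross(u0, e_p)
    p = beam.polarization_fraction
    pol = p * (1.0 - float(e_p @ s1u) ** 2) + (1.0 - p) * (1.0 - float(e_s @ s1u) ** 2)
    return max(pol, 1e-6)


def _rlp_factor(s1: np.ndarray, s0: np.ndarray, axis: np.ndarray, beam: BeamModel) -> float:
    """Reciprocal Lorentz-polarization factor: I_true = I_meas * rlp."""
    e1 = _unit(np.cross(s1, s0))
    zeta = e1 @ axis
    s1u = s1 / np.linalg.norm(s1)
    return abs(zeta) / polarization_factor(s1u, beam)


def ewald_frame(s1: np.ndarray, s0: np.ndarray):
    """Per-reflection orthonormal-ish frame anchored on the Ewald sphere.

    e1 is normal to the plane of s1 and s0, e2 completes a frame
    perpendicular to s1, e3 bisects s1 and s0.  Raises for the
    forward-scattering direction where the frame is undefined.
    """
    cross = np.cross(s1, s0)
    if np.linalg.norm(cross) < 1e-12 * np.linalg.norm(s1) * np.linalg.norm(s0):
        raise ValueError("degenerate Ewald frame at 2theta = 0")
    e1 = _unit(cross)
    e2 = _unit(np.cross(s1, e1))
    e3 = _unit(s1 + s0)
    return e1, e2, e3


# ---------------------------------------------------------------------------
# geometry refinement

_CLASSES = ("CELL", "ORIENTATION", "BEAM", "DISTANCE", "ORGXY", "AXIS")


def _pack(models: ExperimentModel, select: set[str]) -> np.ndarray:
    params = []
    if "CELL" in select:
        params.extend(models.crystal.cell)
    if "ORIENTATION" in select:
        params.extend([0.0, 0.0, 0.0])  # incremental rotation vector, deg
    if "BEAM" in select:
        params.extend([0.0, 0.0])  # small tilts about two transverse axes
    if "DISTANCE" in select:
        params.append(models.detector.distance)
    if "ORGXY" in select:
        params.extend([models.detector.orgx, models.detector.orgy])
    if "AXIS" in select:
        params.extend([0.0, 0.0])
    return np.array(params, dtype=float)


def _unpack(models: ExperimentModel, select: set[str], params: np.ndarray) -> ExperimentModel:
    out = models.copy()
    i = 0
    rec0 = models.crystal.rec_basis
    # orientation of the stored basis relative to its conventional setting
    conv = cell_to_reciprocal_basis(models.crystal.cell)
    # rec0 = conv @ U.T  =>  U.T = pinv(conv) @ rec0
    ut = np.linalg.solve(conv, rec0)
    if "CELL" in select:
        cell = tuple(params[i : i + 6])
        i += 6
        rec = cell_to_reciprocal_basis(cell) @ ut
    else:
        rec = rec0.copy()
    if "ORIENTATION" in select:
        rvec = np.deg2rad(params[i : i + 3])
        i += 3
        rec = rec @ Rotation.from_rotvec(rvec).as_matrix().T
    out.crystal.rec_basis = rec
    if "BEAM" in select:
        t1, t2 = np.deg2rad(params[i : i + 2])
        i += 2
        b = models.beam.direction
        perp1 = _unit(np.cross(b, [1.0, 0.0, 0.0] if abs(b[0]) < 0.9 else [0.0, 1.0, 0.0]))
        perp2 = np.cross(b, perp1)
        newdir = _unit(b + t1 * perp1 + t2 * perp2)
        out.beam.direction = newdir
    if "DISTANCE" in select:
        out.detector.distance = float(params[i])
        i += 1
    if "ORGXY" in select:
        out.detector.orgx = float(params[i])
        out.detector.orgy = float(params[i + 1])
        i += 2
    if "AXIS" in select:
        t1, t2 = np.deg2rad(params[i : i + 2])
        i += 2
        m = models.gonio.axis
        perp1 = _unit(np.cross(m, [0.0, 0.0, 1.0] if abs(m[2]) < 0.9 else [0.0, 1.0, 0.0]))
        perp2 = np.cross(m, perp1)
        out.gonio.axis = _unit(m + t1 * perp1 + t2 * perp2)
    return out


def predict_positions_for_hkls(models: ExperimentModel, hkls: np.ndarray, z_guess: np.ndarray):
    """Predicted (x, y, z) for known indices, choosing the Ewald crossing
    closest to ``z_guess`` (in frames)."""
    beam, gonio, det = models.beam, models.gonio, models.detector
    pstars = np.asarray(hkls, dtype=float) @ models.crystal.rec_basis
    phis = _diffracting_angles(pstars, beam.s0, gonio.axis)
    phi_guess = gonio.phi_of_z(np.asarray(z_guess, dtype=float))
    # unfold both solutions to the turn nearest the guess
    diff = phis - phi_guess[:, None]
    phis_near = phis - 360.0 * np.round(diff / 360.0)
    gap = np.abs(phis_near - phi_guess[:, None])
    all_nan = np.all(~np.isfinite(gap), axis=1)
    gap[all_nan] = 0.0  # placeholder; flagged as bad below
    pick = np.nanargmin(np.where(np.isfinite(gap), gap, np.inf), axis=1)
    phi_c = phis_near[np.arange(len(phis)), pick]
    phi_c[all_nan] = np.nan
    bad = ~np.isfinite(phi_c)
    phi_safe = np.where(bad, phi_guess, phi_c)
    rots = Rotation.from_rotvec(np.deg2rad(phi_safe)[:, None] * gonio.axis)
    s1 = beam.s0 + rots.apply(pstars)
    x, y, hits = lab_to_pixel(det, s1)
    z = gonio.z_of_phi(phi_safe)
    x = np.where(bad | ~hits, np.nan, x)
    y = np.where(bad | ~hits, np.nan, y)
    z = np.where(bad, np.nan, z)
    return x, y, z


def refine_geometry(
    models: ExperimentModel,
    hkls: np.ndarray,
    observed_xyz: np.ndarray,
    select: set[str] | None = None,
    z_weight: float = 1.0,
):
    """Least-squares refinement of selected parameter classes.

    ``select`` mirrors the REFINE()= keyword lists; an empty set returns
    the models unchanged.  Returns (models, rms_xy_pixels, rms_z_frames).
    """
    if select is None:
        select = {"CELL", "ORIENTATION", "BEAM", "ORGXY"}
    select = {s.upper() for s in select}
    bad = select - set(_CLASSES)
    if bad:
        raise ValueError(f"unknown refinement classes: {sorted(bad)}")
    hkls = np.asarray(hkls, dtype=float)
    observed_xyz = np.asarray(observed_xyz, dtype=float)

    def _rms(m):
        x, y, z = predict_positions_for_hkls(m, hkls, observed_xyz[:, 2])
        dx = x - observed_xyz[:, 0]
        dy = y - observed_xyz[:, 1]
        dz = z - observed_xyz[:, 2]
        ok = np.isfinite(dx) & np.isfinite(dy) & np.isfinite(dz)
        rms_xy = float(np.sqrt(np.mean(dx[ok] ** 2 + dy[ok] ** 2))) if ok.any() else np.inf
        rms_z = float(np.sqrt(np.mean(dz[ok] ** 2))) if ok.any() else np.inf
        return rms_xy, rms_z

    if not select:
        rms_xy, rms_z = _rms(models)
        return models.copy(), rms_xy, rms_z

    x0 = _pack(models, select)
    if len(hkls) < len(x0):
        raise ValueError(
            f"{len(hkls)} observations cannot constrain {len(x0)} parameters"
        )

    def residuals(params):
        m = _unpack(models, select, params)
        x, y, z = predict_positions_for_hkls(m, hkls, observed_xyz[:, 2])
        res = np.concatenate(
            [x - observed_xyz[:, 0], y - observed_xyz[:, 1], z_weight * (z - observed_xyz[:, 2])]
        )
        return np.where(np.isfinite(res), res, 10.0)

    result = least_squares(residuals, x0, method="lm", xtol=1e-10, ftol=1e-10, max_nfev=2000)
    refined = _unpack(models, select, result.x)
    # monotone acceptance: never return a model worse than the input
    if np.sum(residuals(result.x) ** 2) > np.sum(residuals(x0) ** 2):
        refined = models.copy()
    rms_xy, rms_z = _rms(refined)
    return refined, rms_xy, rms_z
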