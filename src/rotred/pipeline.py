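"""The eight-step pipeline driver.

Steps run in their canonical order (XYCORR, INIT, COLSPOT, IDXREF,
DEFPIX, XPLAN, INTEGRATE, CORRECT) regardless of how JOB= lists them;
information travels between steps exclusively through files with fixed
names in the working directory, so individual steps can be repeated with
different parameters.  Reruns overwrite earlier outputs.  Every step
writes a .LP log that records the effective value of each keyword it
consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calib, convert, correct, indexing, integrate, spotfind
from .cbf import CbfImage, read_cbf, write_cbf
from .config import ALL_STEPS, KeywordConfig
from .files import (
    read_spot_file,
    read_reflection_file,
    read_xparm,
    write_reflection_file,
    write_spot_file,
    write_xparm,
    AsciiReflectionFile,
    ReflectionRecord,
)
from .geometry import (
    BeamModel,
    DetectorModel,
    ExperimentModel,
    GoniometerModel,
    predict_reflections,
)

__all__ = ["PipelineError", "StepPlan", "run", "plan_completeness", "models_from_config"]


class PipelineError(RuntimeError):
    pass


@dataclass
class StepPlan:
    steps: list[str]
    workdir: Path


@dataclass
class PipelineResult:
    completed: list[str] = field(default_factory=list)
    failed_step: str | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.failed_step is None


def models_from_config(config: KeywordConfig) -> ExperimentModel:
    beam = BeamModel(
        wavelength=config.get_scalar("X-RAY_WAVELENGTH=", 1.0),
        direction=np.array(config.get("INCIDENT_BEAM_DIRECTION=", [0.0, 0.0, 1.0])),
        polarization_fraction=config.get_scalar("FRACTION_OF_POLARIZATION=", 0.5),
        polarization_plane_normal=np.array(
            config.get("POLARIZATION_PLANE_NORMAL=", [0.0, 1.0, 0.0])
        ),
    )
    gonio = GoniometerModel(
        axis=np.array(config.get("ROTATION_AXIS=", [1.0, 0.0, 0.0])),
        phi0=config.get_scalar("STARTING_ANGLE=", 0.0),
        delta_phi=config.get_scalar("OSCILLATION_RANGE=", 1.0),
    )
    det = DetectorModel(
        nx=int(config.get_scalar("NX=", 256)),
        ny=int(config.get_scalar("NY=", 256)),
        qx=config.get_scalar("QX=", 0.3),
        qy=config.get_scalar("QY=", 0.3),
        orgx=config.get_scalar("ORGX=", 128.5) - 1.0,  # keyword values are 1-based
        orgy=config.get_scalar("ORGY=", 128.5) - 1.0,
        distance=config.get_scalar("DETECTOR_DISTANCE=", 100.0),
        d1=np.array(config.get("DIRECTION_OF_DETECTOR_X-AXIS=", [1.0, 0.0, 0.0])),
        d2=np.array(config.get("DIRECTION_OF_DETECTOR_Y-AXIS=", [0.0, 1.0, 0.0])),
    )
    return ExperimentModel(beam, gonio, det, None)


def _frame_path(template: str, number: int) -> str:
    q = template.count("?")
    if q == 0:
        return template.format(number)
    return template.replace("?" * q, str(number).zfill(q))


def load_frames(config: KeywordConfig, workdir: Path, frame_range: tuple[int, int]):
    template = config.get_scalar("NAME_TEMPLATE_OF_DATA_FRAMES=")
    if template is None:
        raise PipelineError("NAME_TEMPLATE_OF_DATA_FRAMES= is required")
    path = Path(template)
    if not path.is_absolute():
        path = workdir / template
    frames = []
    for f in range(frame_range[0], frame_range[1] + 1):
        p = Path(_frame_path(str(path), f))
        if not p.exists():
            raise PipelineError(f"data frame {p} missing (produced by the simulator or beamline)")
        frames.append(read_cbf(p))
    return frames


def _log(workdir: Path, name: str, lines: list[str], config_used: dict) -> None:
    with open(workdir / name, "w") as fh:
        fh.write(f"{name.split('.')[0]} log\n\n")
        fh.write("effective keyword values:\n")
        for key in sorted(config_used):
            fh.write(f"  {key} {config_used[key]}\n")
        fh.write("\n")
        fh.write("\n".join(str(line) for line in lines) + "\n")


def _require(workdir: Path, filename: str, producer: str):
    p = workdir / filename
    if not p.exists():
        raise PipelineError(f"{filename} missing: run the {producer} step first")
    return p


def run(config: KeywordConfig, workdir) -> PipelineResult:
    """Execute the requested steps in canonical order."""
    workdir = Path(workdir)
    if not workdir.is_dir():
        raise PipelineError(f"working directory {workdir} does not exist")
    result = PipelineResult()
    steps = config.job_list
    if not steps:
        raise PipelineError("JOB= names no steps")
    for step in ALL_STEPS:
        if step not in steps:
            continue
        try:
            _STEP_FUNCS[step](config, workdir)
        except (indexing.IndexingError, PipelineError, calib.CalibrationError) as exc:
            result.failed_step = step
            result.message = str(exc)
            return result
        result.completed.append(step)
    return result


# ---------------------------------------------------------------------------
# individual steps

def _step_xycorr(config: KeywordConfig, workdir: Path) -> None:
    models = models_from_config(config)
    roff = config.get_scalar("ROFF=")
    toff = config.get_scalar("TOFF=")
    brass = config.get_scalar("BRASS_PLATE_IMAGE=")
    used = {"ROFF=": roff or 0.0, "TOFF=": toff or 0.0, "BRASS_PLATE_IMAGE=": brass}
    if brass is not None:
        image = read_cbf(workdir / brass)
        spacing = config.get_scalar("HOLE_DISTANCE=", 32.0)
        xcorr, ycorr, overlay = calib.spatial_corrections(
            models.detector, calibration=image, grid_spacing=spacing
        )
    else:
        xcorr, ycorr, overlay = calib.spatial_corrections(models.detector, roff=roff, toff=toff)
    # corrections stored in units of 0.01 pixel, matching table precision
    write_cbf(xcorr.to_cbf(scale=100.0), workdir / "X-CORRECTIONS.cbf")
    write_cbf(ycorr.to_cbf(scale=100.0), workdir / "Y-CORRECTIONS.cbf")
    write_cbf(CbfImage(overlay.astype(np.int32)), workdir / "FRAME.cbf")
    _log(workdir, "XYCORR.LP",
         [f"mean |xcorr| {np.abs(xcorr.values).mean():.4f} px",
          f"mean |ycorr| {np.abs(ycorr.values).mean():.4f} px"], used)


def _table_from_cbf(path, kind: str, scale: float = 1.0) -> calib.PixelTable:
    img = read_cbf(path)
    values = img.counts.astype(float)
    untrusted = img.counts == int(calib.UNTRUSTED)
    values = values / scale
    values[untrusted] = calib.UNTRUSTED
    return calib.PixelTable(values, kind)


def _step_init(config: KeywordConfig, workdir: Path) -> None:
    _require(workdir, "X-CORRECTIONS.cbf", "XYCORR")
    bkg_range = config.get("BACKGROUND_RANGE=") or config.get("DATA_RANGE=") or [1, 5]
    frames = load_frames(config, workdir, (int(bkg_range[0]), int(bkg_range[1])))
    dark_name = config.get_scalar("DARK_CURRENT_IMAGE=")
    nbx = int(config.get_scalar("NBX=", 5))
    nby = int(config.get_scalar("NBY=", 5))
    used = {"BACKGROUND_RANGE=": bkg_range, "DARK_CURRENT_IMAGE=": dark_name,
            "NBX=": nbx, "NBY=": nby,
            "TRUSTED_REGION=": config.get("TRUSTED_REGION=", [0.0, 1.05])}
    if dark_name:
        blank = calib.detector_noise(dark=read_cbf(workdir / dark_name))
    else:
        blank = calib.detector_noise(data_images=frames)
    gain = calib.gain_table(frames, blank, nbx, nby)
    trusted_region = tuple(config.get("TRUSTED_REGION=", [0.0, 1.05]))
    bkginit = calib.initial_background(frames, blank, gain, trusted_region, nbx=nbx, nby=nby)
    write_cbf(blank.to_cbf(), workdir / "BLANK.cbf")
    write_cbf(gain.to_cbf(scale=100.0), workdir / "GAIN.cbf")
    write_cbf(bkginit.to_cbf(), workdir / "BKGINIT.cbf")
    lines = [f"{len(frames)} background images summed",
             f"median gain {np.median(gain.values[gain.trusted]):.3f}",
             f"trusted fraction {bkginit.trusted.mean():.3f}"]
    lines += [f"rejected image: {r}" for r in getattr(bkginit, "rejected_images", [])]
    _log(workdir, "INIT.LP", lines, used)


def _step_colspot(config: KeywordConfig, workdir: Path) -> None:
    blank = _table_from_cbf(_require(workdir, "BLANK.cbf", "INIT"), "BLANK")
    gain = _table_from_cbf(_require(workdir, "GAIN.cbf", "INIT"), "GAIN", scale=100.0)
    bkginit = _table_from_cbf(_require(workdir, "BKGINIT.cbf", "INIT"), "BKGINIT")
    ranges = [tuple(map(int, r)) for r in config.get_all("SPOT_RANGE=")]
    if not ranges:
        dr = config.get("DATA_RANGE=") or [1, 5]
        ranges = [(int(dr[0]), int(dr[1]))]
    strong = config.get_scalar("STRONG_PIXEL=", 3.0)
    background_pixel = config.get_scalar("BACKGROUND_PIXEL=", 6.0)
    cap = int(config.get_scalar("MAXIMUM_NUMBER_OF_STRONG_PIXELS=", 1_500_000))
    min_pixels = int(config.get_scalar("MINIMUM_NUMBER_OF_PIXELS_IN_A_SPOT=", 3))
    max_off = config.get_scalar("SPOT_MAXIMUM-CENTROID=", 3.0)
    used = {"SPOT_RANGE=": ranges, "STRONG_PIXEL=": strong,
            "BACKGROUND_PIXEL=": background_pixel,
            "MAXIMUM_NUMBER_OF_STRONG_PIXELS=": cap,
            "MINIMUM_NUMBER_OF_PIXELS_IN_A_SPOT=": min_pixels,
            "SPOT_MAXIMUM-CENTROID=": max_off}
    pixels = []
    for lo, hi in ranges:
        frames = load_frames(config, workdir, (lo, hi))
        for i, frame in enumerate(frames):
            pixels.extend(
                spotfind.classify_strong(frame, lo - 1 + i, bkginit, gain, strong,
                                         background_pixel)
            )
    pixels = spotfind.cap_strong(pixels, cap)
    spots = spotfind.assemble_spots(pixels, min_pixels, max_off)
    write_spot_file(spots, workdir / "SPOT.XDS")
    _log(workdir, "COLSPOT.LP",
         [f"{len(pixels)} strong pixels", f"{len(spots)} spots saved"], used)


def _step_idxref(config: KeywordConfig, workdir: Path) -> None:
    spots = read_spot_file(_require(workdir, "SPOT.XDS", "COLSPOT"))
    models = models_from_config(config)
    params = indexing.IndexingParams(
        sepmin=config.get_scalar("SEPMIN="),
        cluster_radius=config.get_scalar("CLUSTER_RADIUS="),
        error_eps=config.get_scalar("INDEX_ERROR=", 0.05),
        magnitude_phi=config.get_scalar("INDEX_MAGNITUDE=", 8.0),
        quality_lmin=1.0 - config.get_scalar("INDEX_QUALITY=", 0.8),
        origin=tuple(config.get("INDEX_ORIGIN=", [0, 0, 0])),
        max_spot_error=config.get_scalar("MAXIMUM_ERROR_OF_SPOT_POSITION=", 3.0),
    )
    used = {"SEPMIN=": params.sepmin, "CLUSTER_RADIUS=": params.cluster_radius,
            "INDEX_ERROR=": params.error_eps, "INDEX_MAGNITUDE=": params.magnitude_phi,
            "INDEX_QUALITY=": 1.0 - params.quality_lmin, "INDEX_ORIGIN=": params.origin,
            "MAXIMUM_ERROR_OF_SPOT_POSITION=": params.max_spot_error}
    result = indexing.run_idxref(models, spots, params)
    write_spot_file(result.spots, workdir / "SPOT.XDS")
    write_xparm(result.models, workdir / "XPARM.XDS")
    with open(workdir / "IDXREF.LP", "w") as fh:
        fh.write("effective keyword values:\n")
        for key in sorted(used):
            fh.write(f"  {key} {used[key]}\n")
        fh.write("\n" + result.log)
    if not result.gate.success:
        raise indexing.IndexingError(
            f"only {result.gate.fraction * 100:.1f}% of the spots were explained. "
            + result.gate.message
        )


def _step_defpix(config: KeywordConfig, workdir: Path) -> None:
    bkginit = _table_from_cbf(_require(workdir, "BKGINIT.cbf", "INIT"), "BKGINIT")
    models = read_xparm(_require(workdir, "XPARM.XDS", "IDXREF"))
    value_range = tuple(config.get("VALUE_RANGE_FOR_TRUSTED_DETECTOR_PIXELS=", [6000.0, 30000.0]))
    res_range = tuple(config.get("INCLUDE_RESOLUTION_RANGE=", [20.0, 0.0]))
    used = {"VALUE_RANGE_FOR_TRUSTED_DETECTOR_PIXELS=": value_range,
            "INCLUDE_RESOLUTION_RANGE=": res_range}
    bkgpix, abs_img = calib.defpix(bkginit, models.detector, models.beam.wavelength,
                                   value_range, res_range)
    write_cbf(bkgpix.to_cbf(), workdir / "BKGPIX.cbf")
    write_cbf(abs_img.to_cbf(), workdir / "ABS.cbf")
    _log(workdir, "DEFPIX.LP",
         [f"trusted fraction {bkgpix.trusted.mean():.3f}",
          f"median ABS {np.median(abs_img.values[abs_img.trusted]):.0f}"], used)


def _step_xplan(config: KeywordConfig, workdir: Path) -> None:
    models = read_xparm(_require(workdir, "XPARM.XDS", "IDXREF"))
    bkgpix = _table_from_cbf(_require(workdir, "BKGPIX.cbf", "DEFPIX"), "BKGPIX")
    starts = config.get("STARTING_ANGLES_OF_SPINDLE_ROTATION=", [0.0, 90.0, 30.0])
    totals = config.get("TOTAL_SPINDLE_ROTATION_RANGES=", [30.0, 90.0, 30.0])
    res_range = tuple(config.get("INCLUDE_RESOLUTION_RANGE=", [20.0, 2.0]))
    used = {"STARTING_ANGLES_OF_SPINDLE_ROTATION=": starts,
            "TOTAL_SPINDLE_ROTATION_RANGES=": totals,
            "INCLUDE_RESOLUTION_RANGE=": res_range}
    start_grid = np.arange(starts[0], starts[1] + 1e-9, starts[2] or 30.0)
    total_grid = np.arange(totals[0], totals[1] + 1e-9, totals[2] or 30.0)
    table = plan_completeness(models, bkgpix, start_grid, total_grid, res_range)
    lines = ["  start   range   completeness (overlap ignored)"]
    for row in table:
        lines.append(f" {row['start']:7.1f} {row['total']:7.1f} {row['completeness']:10.3f}")
    _log(workdir, "XPLAN.LP", lines, used)


def _step_integrate(config: KeywordConfig, workdir: Path) -> None:
    models = read_xparm(_require(workdir, "XPARM.XDS", "IDXREF"))
    bkgpix = _table_from_cbf(_require(workdir, "BKGPIX.cbf", "DEFPIX"), "BKGPIX")
    gain = _table_from_cbf(_require(workdir, "GAIN.cbf", "INIT"), "GAIN", scale=100.0)
    dr = config.get("DATA_RANGE=")
    if dr is None:
        raise PipelineError("DATA_RANGE= is required for INTEGRATE")
    data_range = (int(dr[0]), int(dr[1]))
    frames = load_frames(config, workdir, data_range)
    res_range = tuple(config.get("INCLUDE_RESOLUTION_RANGE=", [20.0, 2.0]))
    refine_tokens = config.get("REFINE(INTEGRATE)=")
    refine_classes = set(refine_tokens) if refine_tokens is not None else None
    delphi = config.get_scalar("DELPHI=")
    cut = config.get_scalar("CUT=", 2.0)
    minpk = config.get_scalar("MINPK=", 75.0)
    used = {"DATA_RANGE=": data_range, "INCLUDE_RESOLUTION_RANGE=": res_range,
            "REFINE(INTEGRATE)=": sorted(refine_classes) if refine_classes else [],
            "DELPHI=": delphi, "CUT=": cut, "MINPK=": minpk,
            "BEAM_DIVERGENCE_E.S.D.=": models.crystal.sigma_D,
            "REFLECTING_RANGE_E.S.D.=": models.crystal.sigma_M}
    spots = read_spot_file(workdir / "SPOT.XDS") if (workdir / "SPOT.XDS").exists() else None
    result = integrate.integrate_range(
        frames, models, bkgpix, gain, data_range, res_range,
        delphi=delphi, cut=cut, minpk=minpk, refine_classes=refine_classes,
        spots_for_shape=spots,
    )
    hkl = AsciiReflectionFile.new(models.crystal.cell, 1, models.beam.wavelength,
                                  CONTENT="unmerged intensities from profile fitting")
    hkl.records = result.records
    write_reflection_file(hkl, workdir / "INTEGRATE.HKL")
    if result.frame_overlay is not None:
        write_cbf(result.frame_overlay, workdir / "FRAME.cbf")
    _log(workdir, "INTEGRATE.LP",
         [result.log, f"{len(result.records)} reflections integrated, "
          f"{result.n_discarded} discarded"], used)


def _step_correct(config: KeywordConfig, workdir: Path) -> None:
    models = read_xparm(_require(workdir, "XPARM.XDS", "IDXREF"))
    data = read_reflection_file(_require(workdir, "INTEGRATE.HKL", "INTEGRATE"))
    remove = set()
    if (workdir / "REMOVE.HKL").exists():
        remove = {r.hkl for r in read_reflection_file(workdir / "REMOVE.HKL").records}
    cell = data.cell
    minpk = config.get_scalar("MINPK=", 75.0)
    res_range = tuple(config.get("INCLUDE_RESOLUTION_RANGE=", [20.0, 0.0]))
    excl = [tuple(r) for r in config.get_all("EXCLUDE_RESOLUTION_RANGE=")]
    overload = config.get_scalar("OVERLOAD=")
    friedel = (config.get_scalar("FRIEDEL'S_LAW=", "TRUE") != "FALSE")
    strict_abs = (config.get_scalar("STRICT_ABSORPTION_CORRECTION=", "FALSE") == "TRUE")
    wfac1 = config.get_scalar("WFAC1=", 1.5)
    corrections = set(config.get("CORRECTIONS=", ["DECAY", "MODULATION", "ABSORPTION"]))
    user_sg = config.get_scalar("SPACE_GROUP_NUMBER=")
    user_cell = config.get("UNIT_CELL_CONSTANTS=")
    used = {"MINPK=": minpk, "INCLUDE_RESOLUTION_RANGE=": res_range,
            "EXCLUDE_RESOLUTION_RANGE=": excl, "OVERLOAD=": overload,
            "FRIEDEL'S_LAW=": friedel, "WFAC1=": wfac1,
            "CORRECTIONS=": sorted(corrections), "SPACE_GROUP_NUMBER=": user_sg,
            "STRICT_ABSORPTION_CORRECTION=": strict_abs}

    accepted, tally = correct.accept_reflections(
        data.records, cell, minpk, None,
        res_range if res_range[1] > 0 else None, excl, overload, remove
    )
    corrected, _ = correct.physical_corrections(
        accepted, models,
        air_mu=config.get_scalar("AIR=", 0.0),
        sensor_mu=config.get_scalar("SILICON=", 0.0),
        sensor_thickness=config.get_scalar("SENSOR_THICKNESS=", 0.0),
    )
    hypothesis = correct.propose_space_group(
        corrected, cell,
        test_resolution_range=(tuple(config.get("TEST_RESOLUTION_RANGE="))
                               if config.get("TEST_RESOLUTION_RANGE=") else None),
        min_rfl=int(config.get_scalar("MIN_RFL_Rmeas=", 50)),
        max_fac=config.get_scalar("MAX_FAC_Rmeas=", 2.0),
        friedel=friedel,
        user_space_group=int(user_sg) if user_sg else None,
        user_cell=tuple(user_cell) if user_cell else None,
    )
    reindexed = correct._reindexed(corrected, hypothesis.reindex)
    det_shape = (models.detector.ny, models.detector.nx)
    scaled, surfaces = correct.fit_correction_surfaces(
        reindexed, hypothesis.space_group_number, hypothesis.cell,
        keys=corrections,
        nbatch=int(config.get_scalar("NBATCH=", 10)),
        min_i_over_sigma=config.get_scalar("MINIMUM_I/SIGMA=", 3.0),
        refl_per_factor=int(config.get_scalar("REFLECTIONS/CORRECTION_FACTOR=", 30)),
        strict_absorption=strict_abs, friedel=friedel, det_shape=det_shape,
    )
    try:
        scaled, var_model = correct.fit_variance_model(
            scaled, hypothesis.space_group_number, friedel
        )
    except ValueError:
        var_model = correct.VarianceModel()
    flagged = correct.flag_outliers(scaled, hypothesis.space_group_number, wfac1, friedel)
    shells, axial, wilson_outliers = correct.compute_statistics(
        flagged, hypothesis.space_group_number, hypothesis.cell, friedel=friedel
    )

    out = AsciiReflectionFile.new(hypothesis.cell, hypothesis.space_group_number,
                                  models.beam.wavelength,
                                  FRIEDELS_LAW="TRUE" if friedel else "FALSE",
                                  VARIANCE_MODEL=f"{var_model.a:.4f} {var_model.b:.3e}")
    out.records = flagged
    write_reflection_file(out, workdir / "XDS_ASCII.HKL")
    gx = models.copy()
    gx.crystal.rec_basis = (
        np.linalg.inv(np.asarray(hypothesis.reindex, dtype=float)) @ models.crystal.rec_basis
    )
    write_xparm(gx, workdir / "GXPARM.XDS")
    _write_surface_tables(surfaces, det_shape, workdir)

    lines = [f"accepted {len(accepted)} reflections; rejection tally {tally}",
             f"space group proposal: {hypothesis.space_group_number} "
             f"({hypothesis.bravais}, character {hypothesis.character}), "
             f"R_meas {hypothesis.r_meas:.4f}, {hypothesis.n_unique} unique",
             f"cell: " + " ".join(f"{v:.3f}" for v in hypothesis.cell),
             f"variance model: a={var_model.a:.4f} b={var_model.b:.3e}",
             f"misfits: {sum(r.misfit for r in flagged)} (WFAC1={wfac1})",
             "", " d_max  d_min   nobs  nuniq  compl  R_merge  R_meas  I/sig"]
    for s in shells:
        lines.append(f" {s.d_max:6.2f} {s.d_min:6.2f} {s.n_obs:6d} {s.n_unique:6d} "
                     f"{s.completeness:6.3f} {s.r_merge:8.4f} {s.r_meas:7.4f} "
                     f"{s.mean_i_over_sigma:6.1f}")
    lines.append("")
    lines.append(f"axial reflections: {len(axial)}")
    lines.append(f"Wilson-plot outliers suggested for REMOVE.HKL: "
                 + " ".join(str(r.hkl) for r in wilson_outliers[:20]))
    _log(workdir, "CORRECT.LP", lines, used)


def _write_surface_tables(surfaces, det_shape, workdir: Path) -> None:
    """Render the fitted factor families as small CBF tables (x1000)."""
    ny, nx = det_shape
    for name, filename in (("decay", "DECAY.cbf"), ("modulation", "MODPIX.cbf"),
                           ("absorption", "ABSORP.cbf")):
        factors = getattr(surfaces, name)
        if not factors:
            continue
        vals = np.array([factors[k] for k in sorted(factors)])
        img = np.rint(vals * 1000).astype(np.int32).reshape(1, -1)
        write_cbf(CbfImage(img, {"kind": name, "scale": "1000"}), workdir / filename)


_STEP_FUNCS = {
    "XYCORR": _step_xycorr,
    "INIT": _step_init,
    "COLSPOT": _step_colspot,
    "IDXREF": _step_idxref,
    "DEFPIX": _step_defpix,
    "XPLAN": _step_xplan,
    "INTEGRATE": _step_integrate,
    "CORRECT": _step_correct,
}


# ---------------------------------------------------------------------------
# XPLAN

def plan_completeness(
    models: ExperimentModel,
    bkgpix,
    start_angles,
    total_rotations,
    resolution_range=(20.0, 2.0),
    space_group_number: int = 1,
    reference: set | None = None,
    n_shells: int = 4,
):
    """Expected completeness for each (start angle, total rotation) pair.

    Counts the unique reflection classes reached by the rotation interval
    against all classes possible in the resolution range; reflections in
    ``reference`` (a set of symmetry keys) count as already measured.
    Overlap from the finite oscillation range is deliberately ignored.
    """
    from .correct import _group_ops, symmetry_key

    ops = _group_ops(space_group_number)
    gonio = models.gonio
    possible = correct._possible_unique(
        models.crystal.cell, models.crystal.rec_basis, ops, True,
        resolution_range[0], resolution_range[1],
    )
    table = []
    for start in np.atleast_1d(start_angles):
        for total in np.atleast_1d(total_rotations):
            n_frames = max(int(math.ceil(total / gonio.delta_phi)), 1)
            shifted = models.copy()
            shifted.gonio.phi0 = float(start)
            preds = predict_reflections(shifted, (1, n_frames), resolution_range)
            seen = set(reference or ())
            for p in preds:
                if not p.on_detector:
                    continue
                x, y = int(round(p.x)), int(round(p.y))
                if bkgpix is not None and not bkgpix.trusted[y, x]:
                    continue
                seen.add(symmetry_key(p.hkl, ops, True))
            new = seen - (reference or set())
            table.append({
                "start": float(start), "total": float(total),
                "completeness": len(seen & set(possible)) / max(len(possible), 1),
                "new": len(new),
            })
    return table
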