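"""Multi-dataset scaling.

Several corrected reflection files are placed on one common scale: all
input sets of all output groups enter a single joint scaling problem, so
output groups (e.g. the wavelengths of a MAD experiment) remain on the
same scale.  Each set gets per-batch scale factors and, optionally,
decay/modulation/absorption corrections; Friedel pairs separate in the
absorption classes only when the strict-absorption policy demands it.
Zero-dose extrapolation corrects each reflection class of one crystal
for radiation damage by extrapolating its intensity linearly in
accumulated dose back to dose zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .correct import iterative_scaling, r_factors, symmetry_key, _group_ops, _quantile_bins
from .files import AsciiReflectionFile, ReflectionRecord

__all__ = [
    "InputSet",
    "OutputGroup",
    "ScaleJob",
    "ScaleResult",
    "scale_sets",
    "merge_observations",
    "zero_dose_extrapolate",
]


@dataclass
class InputSet:
    data: AsciiReflectionFile
    resolution_range: tuple[float, float] | None = None  # (d_max, d_min)
    corrections: set[str] = field(default_factory=set)  # subset of DECAY MODULATION ABSORPTION
    nbatch: int = 5
    crystal_name: str | None = None  # enables zero-dose extrapolation
    dose_per_frame: float = 1.0


@dataclass
class OutputGroup:
    name: str
    input_sets: list[InputSet]
    merge: bool = False
    friedel: bool = True
    strict_absorption: bool = False


@dataclass
class ScaleJob:
    output_groups: list[OutputGroup]


@dataclass
class ScaleResult:
    outputs: dict[str, AsciiReflectionFile]
    set_scales: list[np.ndarray]  # per input set, per batch factor
    r_meas: float
    n_iterations: int
    report: str = ""


def _resolution(records, cell):
    from .geometry import cell_to_reciprocal_basis

    rec_basis = cell_to_reciprocal_basis(cell)
    hkls = np.array([r.hkl for r in records], dtype=float)
    return 1.0 / np.linalg.norm(hkls @ rec_basis, axis=1)


def scale_sets(job: ScaleJob, tol: float = 1e-6, max_iter: int = 100) -> ScaleResult:
    """Jointly scale every input set of every output group."""
    sets: list[tuple[OutputGroup, InputSet]] = [
        (group, inp) for group in job.output_groups for inp in group.input_sets
    ]
    if not sets:
        raise ValueError("no input sets")
    sg_number = sets[0][1].data.space_group_number
    cell = sets[0][1].data.cell
    ops = _group_ops(sg_number)

    records: list[ReflectionRecord] = []
    set_of: list[int] = []
    for si, (group, inp) in enumerate(sets):
        recs = [r for r in inp.data.records if not r.misfit]
        if inp.resolution_range is not None:
            d = _resolution(recs, inp.data.cell)
            d_max, d_min = inp.resolution_range
            recs = [r for r, dd in zip(recs, d) if d_min <= dd <= d_max]
        records.extend(recs)
        set_of.extend([si] * len(recs))
    set_of = np.asarray(set_of)
    if not records:
        raise ValueError("no acceptable reflections in any input set")

    iobs = np.array([r.iobs for r in records])
    sig = np.array([abs(r.sigma) for r in records])
    z = np.array([r.zd for r in records])

    friedel_classes = all(g.friedel for g, _ in sets)
    keys = [symmetry_key(r.hkl, ops, friedel_classes) for r in records]
    ids: dict[tuple, int] = {}
    class_of = np.array([ids.setdefault(k, len(ids)) for k in keys])

    # cross-link check: every set must share classes with the others
    for si in range(len(sets)):
        mine = set(class_of[set_of == si].tolist())
        rest = set(class_of[set_of != si].tolist())
        if len(sets) > 1 and not mine & rest:
            raise ValueError(
                f"no cross-links: input set {si} shares no reflection class with the others"
            )

    # factor families: one batch-scale label per (set, batch)
    labels = np.zeros(len(records), dtype=int)
    offset = 0
    batch_split: list[slice] = []
    for si, (_, inp) in enumerate(sets):
        sel = set_of == si
        zb, nb = _quantile_bins(z[sel], inp.nbatch, 1)
        labels[sel] = offset + zb
        batch_split.append(slice(offset, offset + nb))
        offset += nb
    factor_groups = {"SCALE": labels}

    g_total, factors, it = iterative_scaling(
        iobs, sig, class_of, factor_groups, tol=tol, max_iter=max_iter
    )

    scaled = [
        ReflectionRecord(r.hkl, r.iobs / g, math.copysign(abs(r.sigma) / g, r.sigma),
                         r.xd, r.yd, r.zd, r.rlp, r.peak, r.corr, r.psi)
        for r, g in zip(records, g_total)
    ]

    # zero-dose extrapolation per crystal
    for si, (group, inp) in enumerate(sets):
        if inp.crystal_name is None:
            continue
        sel = np.nonzero(set_of == si)[0]
        subset = [scaled[i] for i in sel]
        corrected, _ = zero_dose_extrapolate(
            subset, ops, friedel=group.friedel, dose_per_frame=inp.dose_per_frame
        )
        for i, r in zip(sel, corrected):
            scaled[i] = r

    outputs: dict[str, AsciiReflectionFile] = {}
    report_lines = [f"joint scaling: {len(sets)} input sets, {it} iterations"]
    for group in job.output_groups:
        group_records = [
            scaled[i]
            for i in range(len(scaled))
            if sets[set_of[i]][0] is group
        ]
        merged = merge_observations(group_records, group.merge, group.friedel, sg_number)
        out = AsciiReflectionFile.new(cell, sg_number, sets[0][1].data.wavelength,
                                      MERGED="TRUE" if group.merge else "FALSE",
                                      FRIEDELS_LAW="TRUE" if group.friedel else "FALSE")
        out.records = merged
        outputs[group.name] = out
        _, rme, *_ = r_factors(group_records, ops, group.friedel)
        report_lines.append(
            f"output {group.name}: {len(group_records)} obs -> {len(merged)} records, "
            f"R_meas {rme:.4f}" if math.isfinite(rme) else
            f"output {group.name}: {len(group_records)} obs -> {len(merged)} records"
        )

    _, r_meas_all, *_ = r_factors(scaled, ops, friedel_classes)
    set_scales = [factors["SCALE"][batch_split[si]] for si in range(len(sets))]
    return ScaleResult(outputs, set_scales, r_meas_all, it, "\n".join(report_lines) + "\n")


def merge_observations(
    records: list[ReflectionRecord],
    merge: bool,
    friedel: bool,
    space_group_number: int,
) -> list[ReflectionRecord]:
    """Merge symmetry equivalents (or pass scaled records through).

    Merged sigma is the larger of the propagated inverse-variance error
    and the sample scatter of the contributing observations.
    """
    if not merge:
        return list(records)
    ops = _group_ops(space_group_number)
    classes: dict[tuple, list[ReflectionRecord]] = {}
    for r in records:
        if r.misfit:
            continue
        classes.setdefault(symmetry_key(r.hkl, ops, friedel), []).append(r)
    out = []
    for key, members in sorted(classes.items()):
        vals = np.array([m.iobs for m in members])
        var = np.array([m.sigma**2 for m in members])
        w = 1.0 / np.maximum(var, 1e-12)
        mean = float((w * vals).sum() / w.sum())
        sig_prop = math.sqrt(1.0 / w.sum())
        if len(members) > 1:
            scatter = float(vals.std(ddof=1) / math.sqrt(len(members)))
            sigma = max(sig_prop, scatter)
        else:
            sigma = sig_prop
        out.append(ReflectionRecord(key, mean, sigma, peak=100.0))
    return out


def zero_dose_extrapolate(
    records: list[ReflectionRecord],
    ops,
    friedel: bool = True,
    dose_per_frame: float = 1.0,
    min_obs: int = 3,
):
    """Per-class linear extrapolation of intensities to zero dose.

    Dose is proxied by the frame coordinate times ``dose_per_frame``.
    Classes with fewer than ``min_obs`` observations, or without dose
    spread, are left unchanged and reported.  Returns (records, slopes).
    """
    classes: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        classes.setdefault(symmetry_key(r.hkl, ops, friedel), []).append(i)
    out = list(records)
    slopes: dict[tuple, float | None] = {}
    for key, idx in classes.items():
        if len(idx) < min_obs:
            slopes[key] = None
            continue
        dose = np.array([records[i].zd for i in idx]) * dose_per_frame
        vals = np.array([records[i].iobs for i in idx])
        if np.ptp(dose) < 1e-9:
            slopes[key] = None
            continue
        slope, intercept = np.polyfit(dose, vals, 1)
        slopes[key] = float(slope)
        for i in idx:
            r = records[i]
            corrected = r.iobs - slope * (r.zd * dose_per_frame)
            out[i] = ReflectionRecord(r.hkl, corrected, r.sigma, r.xd, r.yd, r.zd,
                                      r.rlp, r.peak, r.corr, r.psi)
    return out, slopes
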