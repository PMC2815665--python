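"""Text file dialects exchanged between pipeline steps.

Three families: spot centroid lists (SPOT.XDS), ASCII reflection files
(INTEGRATE.HKL / XDS_ASCII.HKL) and geometry state files (XPARM.XDS /
GXPARM.XDS).  All numeric output uses fixed-width, scientific-free
formatting so that write -> read -> write is byte-stable.

The reflection-file header vocabulary is our own documented, versioned
set of ``!``-prefixed lines; it carries enough state (cell, space group,
wavelength, column names) to re-interpret the records without the
original keyword file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BeamModel,
    CrystalModel,
    DetectorModel,
    ExperimentModel,
    GoniometerModel,
)

__all__ = [
    "SpotRecord",
    "ReflectionRecord",
    "AsciiReflectionFile",
    "FileFormatError",
    "read_spot_file",
    "write_spot_file",
    "read_reflection_file",
    "write_reflection_file",
    "read_xparm",
    "write_xparm",
]


class FileFormatError(ValueError):
    pass


@dataclass
class SpotRecord:
    x: float  # fast pixel centroid (file numbers are 1-based; in-memory 0-based)
    y: float
    z: float  # continuous frame coordinate
    intensity: float
    hkl: tuple[int, int, int] | None = None

    @property
    def is_alien(self) -> bool:
        """Indexed spots not matching the lattice carry indices 0,0,0."""
        return self.hkl == (0, 0, 0)


REFLECTION_COLUMNS = (
    "H", "K", "L", "IOBS", "SIGMA", "XD", "YD", "ZD", "RLP", "PEAK", "CORR", "PSI",
)


@dataclass
class ReflectionRecord:
    hkl: tuple[int, int, int]
    iobs: float
    sigma: float  # negative sign marks a misfit
    xd: float = 0.0
    yd: float = 0.0
    zd: float = 0.0
    rlp: float = 0.0
    peak: float = 0.0  # recorded percentage of the profile (partiality * 100)
    corr: float = 0.0
    psi: float = 0.0

    @property
    def misfit(self) -> bool:
        return self.sigma < 0


@dataclass
class AsciiReflectionFile:
    header: dict[str, str] = field(default_factory=dict)
    records: list[ReflectionRecord] = field(default_factory=list)

    _MANDATORY = ("FORMAT", "SPACE_GROUP_NUMBER", "UNIT_CELL_CONSTANTS", "X-RAY_WAVELENGTH")

    @classmethod
    def new(cls, cell, space_group_number: int, wavelength: float, **extra) -> "AsciiReflectionFile":
        header = {
            "FORMAT": "ROTRED_ASCII VERSION=1",
            "SPACE_GROUP_NUMBER": str(int(space_group_number)),
            "UNIT_CELL_CONSTANTS": " ".join(f"{v:.4f}" for v in cell),
            "X-RAY_WAVELENGTH": f"{wavelength:.6f}",
        }
        header.update({k: str(v) for k, v in extra.items()})
        return cls(header)

    @property
    def cell(self) -> tuple[float, ...]:
        return tuple(float(v) for v in self.header["UNIT_CELL_CONSTANTS"].split())

    @property
    def space_group_number(self) -> int:
        return int(self.header["SPACE_GROUP_NUMBER"])

    @property
    def wavelength(self) -> float:
        return float(self.header["X-RAY_WAVELENGTH"])


# ---------------------------------------------------------------------------
# SPOT.XDS

def write_spot_file(spots: list[SpotRecord], path) -> None:
    """Columns: x y z intensity [h k l]; positions written 1-based."""
    with open(path, "w") as fh:
        for s in spots:
            line = f"{s.x + 1.0:10.2f}{s.y + 1.0:10.2f}{s.z:10.2f}{s.intensity:12.1f}"
            if s.hkl is not None:
                h, k, l = s.hkl
                line += f"{h:5d}{k:5d}{l:5d}"
            fh.write(line + "\n")


def read_spot_file(path) -> list[SpotRecord]:
    spots: list[SpotRecord] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if ncols is None:
                if len(parts) not in (4, 7):
                    raise FileFormatError(
                        f"line {lineno}: expected 4 or 7 columns, found {len(parts)}"
                    )
                ncols = len(parts)
            elif len(parts) != ncols:
                raise FileFormatError(
                    f"line {lineno}: ragged column count {len(parts)} != {ncols}"
                )
            x, y, z, sig = (float(v) for v in parts[:4])
            hkl = tuple(int(v) for v in parts[4:7]) if ncols == 7 else None
            spots.append(SpotRecord(x - 1.0, y - 1.0, z, sig, hkl))
    return spots


# ---------------------------------------------------------------------------
# reflection files

_REC_FMT = (
    "{h:6d}{k:6d}{l:6d}{iobs:14.3f}{sigma:12.3f}"
    "{xd:9.2f}{yd:9.2f}{zd:9.2f}{rlp:9.4f}{peak:7.1f}{corr:7.1f}{psi:9.2f}"
)


def write_reflection_file(data: AsciiReflectionFile, path) -> None:
    for key in AsciiReflectionFile._MANDATORY:
        if key not in data.header:
            raise FileFormatError(f"missing mandatory header field {key}")
    with open(path, "w") as fh:
        for key, value in data.header.items():
            fh.write(f"!{key}= {value}\n")
        fh.write("!NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD= 12\n")
        fh.write("!ITEMS= " + " ".join(REFLECTION_COLUMNS) + "\n")
        fh.write("!END_OF_HEADER\n")
        for r in data.records:
            fh.write(
                _REC_FMT.format(
                    h=r.hkl[0], k=r.hkl[1], l=r.hkl[2], iobs=r.iobs, sigma=r.sigma,
                    xd=r.xd, yd=r.yd, zd=r.zd, rlp=r.rlp, peak=r.peak, corr=r.corr,
                    psi=r.psi,
                )
                + "\n"
            )
        fh.write("!END_OF_DATA\n")


def read_reflection_file(path) -> AsciiReflectionFile:
    header: dict[str, str] = {}
    records: list[ReflectionRecord] = []
    in_header = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if in_header:
                if not line.startswith("!"):
                    raise FileFormatError(f"line {lineno}: record before !END_OF_HEADER")
                body = line[1:]
                if body == "END_OF_HEADER":
                    in_header = False
                    continue
                if "= " in body:
                    key, value = body.split("= ", 1)
                    header[key] = value
                continue
            if line.startswith("!"):
                if line[1:] == "END_OF_DATA":
                    break
                continue
            parts = line.split()
            if len(parts) != 12:
                raise FileFormatError(f"line {lineno}: expected 12 columns, found {len(parts)}")
            h, k, l = (int(v) for v in parts[:3])
            vals = [float(v) for v in parts[3:]]
            records.append(ReflectionRecord((h, k, l), *vals))
    missing = [k for k in AsciiReflectionFile._MANDATORY if k not in header]
    if missing:
        raise FileFormatError(f"missing mandatory header fields: {missing}")
    drop = ("NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD", "ITEMS")
    header = {k: v for k, v in header.items() if k not in drop}
    return AsciiReflectionFile(header, records)


# ---------------------------------------------------------------------------
# XPARM-style geometry state

def write_xparm(models: ExperimentModel, path) -> None:
    """Exactly the state needed to re-predict reflection positions."""
    b, g, d, c = models.beam, models.gonio, models.detector, models.crystal
    lines = [
        "ROTRED_XPARM VERSION=1",
        f"WAVELENGTH {b.wavelength:.6f}",
        "BEAM_DIRECTION " + _vec(b.direction),
        f"POLARIZATION_FRACTION {b.polarization_fraction:.4f}",
        "POLARIZATION_PLANE_NORMAL " + _vec(b.polarization_plane_normal),
        "ROTATION_AXIS " + _vec(g.axis),
        f"PHI0 {g.phi0:.4f}",
        f"DELTA_PHI {g.delta_phi:.6f}",
        f"NX_NY {d.nx} {d.ny}",
        f"QX_QY {d.qx:.6f} {d.qy:.6f}",
        f"ORGX_ORGY {d.orgx:.4f} {d.orgy:.4f}",
        f"DISTANCE {d.distance:.4f}",
        "D1 " + _vec(d.d1),
        "D2 " + _vec(d.d2),
    ]
    if c is not None:
        lines += [
            "ASTAR " + _vec(c.rec_basis[0]),
            "BSTAR " + _vec(c.rec_basis[1]),
            "CSTAR " + _vec(c.rec_basis[2]),
            f"SIGMA_D {c.sigma_D:.6f}",
            f"SIGMA_M {c.sigma_M:.6f}",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xparm(path) -> ExperimentModel:
    kv: dict[str, list[float]] = {}
    with open(path) as fh:
        first = fh.readline()
        if "ROTRED_XPARM" not in first:
            raise FileFormatError("not a rotred XPARM file")
        for line in fh:
            parts = line.split()
            if parts:
                kv[parts[0]] = [float(v) for v in parts[1:]]
    try:
        beam = BeamModel(
            wavelength=kv["WAVELENGTH"][0],
            direction=np.array(kv["BEAM_DIRECTION"]),
            polarization_fraction=kv["POLARIZATION_FRACTION"][0],
            polarization_plane_normal=np.array(kv["POLARIZATION_PLANE_NORMAL"]),
        )
        gonio = GoniometerModel(
            axis=np.array(kv["ROTATION_AXIS"]), phi0=kv["PHI0"][0], delta_phi=kv["DELTA_PHI"][0]
        )
        det = DetectorModel(
            nx=int(kv["NX_NY"][0]), ny=int(kv["NX_NY"][1]),
            qx=kv["QX_QY"][0], qy=kv["QX_QY"][1],
            orgx=kv["ORGX_ORGY"][0], orgy=kv["ORGX_ORGY"][1],
            distance=kv["DISTANCE"][0],
            d1=np.array(kv["D1"]), d2=np.array(kv["D2"]),
        )
    except KeyError as exc:
        raise FileFormatError(f"missing XPARM field {exc}") from None
    crystal = None
    if "ASTAR" in kv:
        crystal = CrystalModel(
            rec_basis=np.array([kv["ASTAR"], kv["BSTAR"], kv["CSTAR"]]),
            sigma_D=kv.get("SIGMA_D", [0.05])[0],
            sigma_M=kv.get("SIGMA_M", [0.1])[0],
        )
    return ExperimentModel(beam, gonio, det, crystal)


def _vec(v) -> str:
    return " ".join(f"{x:.8f}" for x in v)
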