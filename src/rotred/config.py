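"""Keyword parameter files (XDS.INP dialect).

Parameters are named by keywords whose last character is an equals sign;
``!`` starts a comment; several keywords may share a line.  Keywords are
matched case-sensitively against a static registry that records the value
type and whether repeated occurrences accumulate (``SPOT_RANGE=``,
``INPUT_FILE=`` ...) or overwrite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = ["KeywordConfig", "KeywordParseError", "parse_keyword_file", "ALL_STEPS"]

ALL_STEPS = ("XYCORR", "INIT", "COLSPOT", "IDXREF", "DEFPIX", "XPLAN", "INTEGRATE", "CORRECT")


class KeywordParseError(ValueError):
    pass


# name -> (value type, repeatable?)  type: "int" | "float" | "token"
# Mixed int/float lists are parsed as "float"; tokens stay strings.
_REGISTRY: dict[str, tuple[str, bool]] = {
    "JOB=": ("token", False),
    "NAME_TEMPLATE_OF_DATA_FRAMES=": ("token", False),
    "DATA_RANGE=": ("int", False),
    "SPOT_RANGE=": ("int", True),
    "BACKGROUND_RANGE=": ("int", False),
    "EXCLUDE_DATA_RANGE=": ("int", True),
    "OSCILLATION_RANGE=": ("float", False),
    "STARTING_ANGLE=": ("float", False),
    "STARTING_FRAME=": ("int", False),
    "X-RAY_WAVELENGTH=": ("float", False),
    "INCIDENT_BEAM_DIRECTION=": ("float", False),
    "ROTATION_AXIS=": ("float", False),
    "FRACTION_OF_POLARIZATION=": ("float", False),
    "POLARIZATION_PLANE_NORMAL=": ("float", False),
    "DETECTOR=": ("token", False),
    "NX=": ("int", False),
    "NY=": ("int", False),
    "QX=": ("float", False),
    "QY=": ("float", False),
    "ORGX=": ("float", False),
    "ORGY=": ("float", False),
    "DETECTOR_DISTANCE=": ("float", False),
    "DIRECTION_OF_DETECTOR_X-AXIS=": ("float", False),
    "DIRECTION_OF_DETECTOR_Y-AXIS=": ("float", False),
    "TRUSTED_REGION=": ("float", False),
    "UNTRUSTED_RECTANGLE=": ("int", True),
    "OVERLOAD=": ("int", False),
    "MINIMUM_VALID_PIXEL_VALUE=": ("int", False),
    "SENSOR_THICKNESS=": ("float", False),
    "SILICON=": ("float", False),
    "AIR=": ("float", False),
    "ROFF=": ("float", False),
    "TOFF=": ("float", False),
    "BRASS_PLATE_IMAGE=": ("token", False),
    "HOLE_DISTANCE=": ("float", False),
    "DARK_CURRENT_IMAGE=": ("token", False),
    "NBX=": ("int", False),
    "NBY=": ("int", False),
    "STRONG_PIXEL=": ("float", False),
    "BACKGROUND_PIXEL=": ("float", False),
    "SIGNAL_PIXEL=": ("float", False),
    "MAXIMUM_NUMBER_OF_STRONG_PIXELS=": ("int", False),
    "MINIMUM_NUMBER_OF_PIXELS_IN_A_SPOT=": ("int", False),
    "SPOT_MAXIMUM-CENTROID=": ("float", False),
    "SEPMIN=": ("float", False),
    "CLUSTER_RADIUS=": ("float", False),
    "INDEX_ERROR=": ("float", False),
    "INDEX_MAGNITUDE=": ("float", False),
    "INDEX_QUALITY=": ("float", False),
    "INDEX_ORIGIN=": ("int", False),
    "MAXIMUM_ERROR_OF_SPOT_POSITION=": ("float", False),
    "REFINE(IDXREF)=": ("token", False),
    "REFINE(INTEGRATE)=": ("token", False),
    "REFINE(CORRECT)=": ("token", False),
    "SPACE_GROUP_NUMBER=": ("int", False),
    "UNIT_CELL_CONSTANTS=": ("float", False),
    "UNIT_CELL_A-AXIS=": ("float", False),
    "UNIT_CELL_B-AXIS=": ("float", False),
    "UNIT_CELL_C-AXIS=": ("float", False),
    "REIDX=": ("int", False),
    "INCLUDE_RESOLUTION_RANGE=": ("float", False),
    "EXCLUDE_RESOLUTION_RANGE=": ("float", True),
    "VALUE_RANGE_FOR_TRUSTED_DETECTOR_PIXELS=": ("float", False),
    "BEAM_DIVERGENCE=": ("float", False),
    "BEAM_DIVERGENCE_E.S.D.=": ("float", False),
    "REFLECTING_RANGE=": ("float", False),
    "REFLECTING_RANGE_E.S.D.=": ("float", False),
    "CUT=": ("float", False),
    "DELPHI=": ("float", False),
    "MINPK=": ("float", False),
    "MAX_CELL_AXIS_ERROR=": ("float", False),
    "MAX_CELL_ANGLE_ERROR=": ("float", False),
    "TEST_RESOLUTION_RANGE=": ("float", False),
    "MIN_RFL_Rmeas=": ("int", False),
    "MAX_FAC_Rmeas=": ("float", False),
    "WFAC1=": ("float", False),
    "CORRECTIONS=": ("token", False),
    "MINIMUM_I/SIGMA=": ("float", False),
    "NBATCH=": ("int", False),
    "REFLECTIONS/CORRECTION_FACTOR=": ("int", False),
    "FRIEDEL'S_LAW=": ("token", False),
    "STRICT_ABSORPTION_CORRECTION=": ("token", False),
    "REFERENCE_DATA_SET=": ("token", False),
    "REMOVE=": ("token", False),
    "MERGE=": ("token", False),
    "OUTPUT_FILE=": ("token", True),
    "INPUT_FILE=": ("token", True),
    "CRYSTAL_NAME=": ("token", True),
    "MAXIMUM_NUMBER_OF_JOBS=": ("int", False),
    "MAXIMUM_NUMBER_OF_PROCESSORS=": ("int", False),
    "TOTAL_SPINDLE_ROTATION_RANGES=": ("float", False),
    "STARTING_ANGLES_OF_SPINDLE_ROTATION=": ("float", False),
}


@dataclass
class KeywordConfig:
    """Typed view of a keyword parameter file.

    ``entries`` maps each keyword to the list of its occurrences, every
    occurrence being the list of typed values that followed it.  Repeatable
    keywords accumulate occurrences; others keep only the last one.
    """

    entries: dict[str, list[list]] = field(default_factory=dict)
    unknown: list[str] = field(default_factory=list)

    def get(self, keyword: str, default=None):
        """Last occurrence's values, or ``default``."""
        occ = self.entries.get(keyword)
        return occ[-1] if occ else default

    def get_scalar(self, keyword: str, default=None):
        values = self.get(keyword)
        if not values:
            return default
        return values[0]

    def get_all(self, keyword: str) -> list[list]:
        """All occurrences (for repeatable keywords)."""
        return self.entries.get(keyword, [])

    @property
    def job_list(self) -> list[str]:
        values = self.get("JOB=", [])
        steps: list[str] = []
        for token in values:
            if token == "XDS":
                steps.extend(ALL_STEPS)
            elif token in ALL_STEPS:
                steps.append(token)
            else:
                raise KeywordParseError(f"unknown JOB step {token!r}")
        # canonical execution order regardless of listing order
        return [s for s in ALL_STEPS if s in steps]


def _convert(token: str, kind: str, keyword: str, lineno: int):
    if kind == "token":
        return token
    try:
        if kind == "int":
            return int(token)
        return float(token)
    except ValueError:
        raise KeywordParseError(
            f"line {lineno}: keyword {keyword} expects {kind} values, got {token!r}"
        ) from None


def parse_keyword_file(text: str) -> KeywordConfig:
    """Parse keyword text into a :class:`KeywordConfig`.

    Unknown keywords are collected and warned about, never fatal; a value
    that fails numeric conversion for a registered keyword is an error
    naming the line and keyword.
    """
    config = KeywordConfig()
    current: str | None = None
    current_values: list = []
    current_known = False

    def flush():
        nonlocal current, current_values
        if current is None:
            return
        if current_known:
            repeatable = _REGISTRY[current][1]
            occurrences = config.entries.setdefault(current, [])
            if occurrences and not repeatable:
                warnings.warn(
                    f"keyword {current} repeated; previous value overwritten",
                    stacklevel=3,
                )
                occurrences.clear()
            occurrences.append(current_values)
        current, current_values = None, []

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("!", 1)[0]
        for token in line.split():
            eq = token.find("=")
            if eq >= 0 and not _looks_numeric(token):
                keyword, attached = token[: eq + 1], token[eq + 1 :]
                flush()
                current = keyword
                current_known = keyword in _REGISTRY
                if not current_known:
                    config.unknown.append(keyword)
                    warnings.warn(f"line {lineno}: unknown keyword {keyword}", stacklevel=2)
                if attached:
                    kind = _REGISTRY[keyword][0] if current_known else "token"
                    current_values.append(_convert(attached, kind, keyword, lineno))
            elif current is not None:
                kind = _REGISTRY[current][0] if current_known else "token"
                current_values.append(_convert(token, kind, current, lineno))
            # bare values before any keyword are ignored
        # keywords do not span lines in practice, but values may: keep current open
    flush()
    return config


def _looks_numeric(token: str) -> bool:
    """True for tokens like ``1e=``-free numerics; '=' only marks keywords."""
    try:
        float(token)
        return True
    except ValueError:
        return False
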