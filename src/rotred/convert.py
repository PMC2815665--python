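"""Intensity-to-amplitude conversion and structure-solution output.

Amplitudes are estimated from merged intensities by Bayesian inference
under a Wilson prior (French & Wilson): the prior on the true intensity
J is exponential with mean Sigma for acentric reflections and the
half-normal intensity distribution for centric ones; the likelihood is
Normal(I, sigI).  The posterior mean and standard deviation of F =
sqrt(J) are computed by Gauss-Legendre quadrature on a truncated
support, which keeps F positive and finite even for strongly negative
measured intensities.  Sigma is taken per resolution shell from the data
themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .files import AsciiReflectionFile, ReflectionRecord

__all__ = [
    "AmplitudeRecord",
    "french_wilson",
    "shell_mean_intensities",
    "is_centric",
    "convert_to_amplitudes",
    "assign_free_set",
    "write_structure_format",
]

N_QUAD = 128  # Gauss-Legendre points
N_SHELLS = 20  # equal-count resolution shells for Sigma estimation


@dataclass
class AmplitudeRecord:
    hkl: tuple[int, int, int]
    f: float
    sig_f: float
    centric: bool = False
    free_flag: int = 0


def is_centric(hkl, ops) -> bool:
    """A reflection is centric when some symmetry operation maps h to -h."""
    neg = tuple(-v for v in hkl)
    return any(tuple(op.apply_to_hkl(list(hkl))) == neg for op in ops)


def french_wilson(i_obs: float, sig_i: float, sigma_mean: float, centric: bool = False):
    """Posterior (F, sigF) under the Wilson prior.

    Truncates the quadrature support at 8 likelihood sigmas around the
    measurement (never below zero) and at the prior scale, which bounds
    the quadrature error well below the documented 1e-3 relative level.
    """
    if sig_i <= 0:
        raise ValueError("sig_i must be positive")
    if sigma_mean <= 0:
        raise ValueError("the shell mean intensity must be positive")
    # integrate in F = sqrt(J): the priors are smooth there (acentric
    # 2F/Sigma exp(-F^2/Sigma), centric half-normal) and the posterior is
    # confined to the likelihood support [I - 8 sig, I + 8 sig]
    f_lo = math.sqrt(max(i_obs - 8.0 * sig_i, 0.0))
    f_hi = math.sqrt(max(i_obs + 8.0 * sig_i, 10.0 * sig_i))
    nodes, weights = np.polynomial.legendre.leggauss(N_QUAD)
    f = 0.5 * (f_hi - f_lo) * (nodes + 1.0) + f_lo
    w = 0.5 * (f_hi - f_lo) * weights
    j = f * f
    if centric:
        log_prior = -j / (2.0 * sigma_mean)
    else:
        log_prior = np.log(np.maximum(2.0 * f / sigma_mean, 1e-300)) - j / sigma_mean
    log_like = -0.5 * ((i_obs - j) / sig_i) ** 2
    log_post = log_prior + log_like
    log_post -= log_post.max()
    post = w * np.exp(log_post)
    norm = post.sum()
    if norm <= 0:
        return math.sqrt(max(i_obs, sig_i)), sig_i / (2.0 * math.sqrt(max(i_obs, sig_i)))
    ef = float((post * f).sum() / norm)
    ef2 = float((post * j).sum() / norm)
    var = max(ef2 - ef * ef, 1e-12)
    return ef, math.sqrt(var)


def shell_mean_intensities(records: list[ReflectionRecord], cell, n_shells: int = N_SHELLS):
    """Per-record Sigma from equal-count resolution shells of the data."""
    from .geometry import cell_to_reciprocal_basis

    rec_basis = cell_to_reciprocal_basis(cell)
    hkls = np.array([r.hkl for r in records], dtype=float)
    inv_d3 = np.linalg.norm(hkls @ rec_basis, axis=1) ** 3
    iobs = np.array([r.iobs for r in records])
    order = np.argsort(inv_d3)
    sigma = np.empty(len(records))
    for shell in np.array_split(order, min(n_shells, max(len(order) // 10, 1))):
        if len(shell) == 0:
            continue
        mean = float(np.mean(np.maximum(iobs[shell], 0.0)))
        sigma[shell] = max(mean, 1e-6 + 0.1 * float(np.abs(iobs[shell]).mean()))
    return sigma


def convert_to_amplitudes(data: AsciiReflectionFile) -> list[AmplitudeRecord]:
    """French-Wilson conversion of a merged reflection file."""
    ops = gemmi.SpaceGroup(data.space_group_number).operations().sym_ops
    records = [r for r in data.records if not r.misfit]
    sigmas = shell_mean_intensities(records, data.cell)
    out = []
    for r, sm in zip(records, sigmas):
        centric = is_centric(r.hkl, ops)
        f, sig_f = french_wilson(r.iobs, abs(r.sigma), float(sm), centric)
        out.append(AmplitudeRecord(r.hkl, f, sig_f, centric))
    return out


def assign_free_set(
    records: list[AmplitudeRecord],
    fraction: float | None = None,
    reference: list[AmplitudeRecord] | None = None,
    space_group_number: int = 1,
    reindex: np.ndarray | None = None,
    seed: int = 0,
) -> list[AmplitudeRecord]:
    """Flag a free-R test set (flag 1 = free, 0 = working).

    Fresh mode selects ``ceil(fraction * n)`` unique reflections with a
    seeded generator.  Inherit mode copies flags from ``reference`` by
    symmetry-expanded hkl (optionally across a reindexing transform);
    unmatched reflections are flagged fresh at the reference's free
    fraction.
    """
    ops = gemmi.SpaceGroup(space_group_number).operations().sym_ops

    def key(hkl):
        from .correct import symmetry_key

        return symmetry_key(hkl, ops, True)

    out = [AmplitudeRecord(r.hkl, r.f, r.sig_f, r.centric, 0) for r in records]
    if reference is not None:
        lookup = {}
        for ref in reference:
            hkl = tuple(ref.hkl)
            if reindex is not None:
                hkl = tuple(int(v) for v in np.asarray(hkl) @ np.asarray(reindex))
            lookup[key(hkl)] = ref.free_flag
        ref_fraction = float(np.mean([r.free_flag != 0 for r in reference])) or 0.05
        rng = np.random.default_rng(seed)
        for r in out:
            k = key(r.hkl)
            if k in lookup:
                r.free_flag = lookup[k]
            else:
                r.free_flag = int(rng.random() < ref_fraction)
        return out

    if fraction is None or not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    unique = sorted({key(r.hkl) for r in records})
    rng = np.random.default_rng(seed)
    n_free = math.ceil(fraction * len(unique))
    free = set(map(tuple, rng.permutation(np.array(unique, dtype=int))[:n_free].tolist()))
    for r in out:
        r.free_flag = int(key(r.hkl) in free)
    return out


def write_structure_format(records: list[AmplitudeRecord], path, dialect: str = "plain") -> None:
    """Write amplitudes for structure-solution packages.

    ``plain``: h k l F sigF flag; ``shelx``: HKLF-4-style fixed columns
    (3I4, 2F8.2); ``cns``: INDE/FOBS/SIGMA/TEST lines where TEST=1 marks
    the *working* set (complement convention).  SHELX amplitudes that
    overflow the fixed columns are rescaled with a header note.
    """
    if dialect == "plain":
        with open(path, "w") as fh:
            fh.write("#  h   k   l        F     sigF  free\n")
            for r in records:
                fh.write(
                    f"{r.hkl[0]:4d}{r.hkl[1]:4d}{r.hkl[2]:4d}"
                    f"{r.f:10.3f}{r.sig_f:9.3f}{r.free_flag:4d}\n"
                )
    elif dialect == "shelx":
        scale = 1.0
        fmax = max((r.f for r in records), default=0.0)
        lines = []
        if fmax >= 1e6:
            scale = 9999.99 / fmax
            lines.append(f"! amplitudes scaled by {scale:.6g} to fit HKLF columns\n")
        with open(path, "w") as fh:
            fh.writelines(lines)
            for r in records:
                fh.write(
                    f"{r.hkl[0]:4d}{r.hkl[1]:4d}{r.hkl[2]:4d}"
                    f"{r.f * scale:8.2f}{r.sig_f * scale:8.2f}\n"
                )
            fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")
    elif dialect == "cns":
        with open(path, "w") as fh:
            fh.write(f"NREFlection= {len(records)}\n")
            fh.write("ANOMalous=FALSe\n")
            fh.write("DECLare NAME=FOBS DOMAin=RECIprocal TYPE=REAL END\n")
            fh.write("DECLare NAME=SIGMA DOMAin=RECIprocal TYPE=REAL END\n")
            fh.write("DECLare NAME=TEST DOMAin=RECIprocal TYPE=INTE END\n")
            for r in records:
                test = 0 if r.free_flag else 1  # TEST=1 marks the working set
                fh.write(
                    f"INDE {r.hkl[0]:5d}{r.hkl[1]:5d}{r.hkl[2]:5d} "
                    f"FOBS= {r.f:12.3f} SIGMA= {r.sig_f:10.3f} TEST= {test}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_plain_amplitudes(path) -> list[AmplitudeRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            out.append(
                AmplitudeRecord(
                    (int(parts[0]), int(parts[1]), int(parts[2])),
                    float(parts[3]), float(parts[4]),
                    free_flag=int(parts[5]) if len(parts) > 5 else 0,
                )
            )
    return out
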