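"""Niggli reduction and the 44 lattice characters.

``niggli_reduce`` implements the Křivý–Gruber iteration with
epsilon-comparisons, tracking the integer change of basis.  The lattice
classification evaluates the 44 Niggli characters of International
Tables: each character carries a fixed integer transform from the reduced
basis to a conventional cell of its Bravais type, and its quality is the
magnitude by which that conventional cell violates the metric constraints
of the type (plus the character's sign conditions on the scalar products).
A quality of zero therefore means the metric conditions hold exactly; the
triclinic characters always fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import cell_parameters, cell_to_reciprocal_basis

__all__ = ["LatticeCharacter", "niggli_reduce", "lattice_characters", "CHARACTER_TABLE"]


@dataclass
class LatticeCharacter:
    number: int  # 1..44
    bravais: str  # aP, mP, mC, mI, oP, oC, oF, oI, tP, tI, hP, hR, cP, cF, cI
    transform: np.ndarray  # integer 3x3: conventional basis rows = M @ reduced rows
    quality: float  # non-negative penalty, 0 iff conditions hold exactly
    conventional_cell: tuple[float, float, float, float, float, float]

    @property
    def likelihood(self) -> float:
        """Heuristic monotone [0, 1] score; larger means a better fit."""
        return 1.0 / (1.0 + self.quality)


def _metric(basis: np.ndarray):
    a, b, c = basis
    return (a @ a, b @ b, c @ c, b @ c, a @ c, a @ b)


def niggli_reduce(basis: np.ndarray, eps_rel: float = 1e-5, max_iter: int = 100):
    """Niggli-reduce a direct basis (rows a, b, c).

    Returns (reduced_basis, transform) with ``reduced = transform @ basis``
    and ``|det(transform)| = 1``.  Raises ``RuntimeError`` if the iteration
    cap is exceeded (numerically hostile input).
    """
    basis = np.asarray(basis, dtype=float)
    T = np.eye(3, dtype=int)

    def apply(M):
        nonlocal basis, T
        M = np.asarray(M, dtype=int)
        basis = M @ basis
        T = M @ T

    for _ in range(max_iter):
        A, B, C, D, E, F = _metric(basis)
        # Krivy-Gruber work with doubled scalar products
        xi, eta, zeta = 2 * D, 2 * E, 2 * F
        eps = eps_rel * max(A, B, C)

        # step 1: order A <= B
        if A > B + eps or (abs(A - B) <= eps and abs(xi) > abs(eta) + eps):
            apply([[0, -1, 0], [-1, 0, 0], [0, 0, -1]])
            continue
        # step 2: order B <= C
        if B > C + eps or (abs(B - C) <= eps and abs(eta) > abs(zeta) + eps):
            apply([[-1, 0, 0], [0, 0, -1], [0, -1, 0]])
            continue
        # steps 3/4: fix the signs of xi, eta, zeta.  Flipping one basis
        # vector flips the two scalar products it appears in, so only the
        # four proper sign patterns below are reachable.
        flips = ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))
        n_neg = sum(1 for v in (xi, eta, zeta) if v < -eps)
        n_zero = sum(1 for v in (xi, eta, zeta) if abs(v) <= eps)
        if n_zero == 0 and n_neg % 2 == 0:
            # step 3: make all positive
            if not (xi > -eps and eta > -eps and zeta > -eps):
                best = min(
                    flips,
                    key=lambda f: max(-f[1] * f[2] * xi, 0)
                    + max(-f[0] * f[2] * eta, 0)
                    + max(-f[0] * f[1] * zeta, 0),
                )
                apply(np.diag(best))
                continue
        else:
            # step 4: make all non-positive
            if xi > eps or eta > eps or zeta > eps:
                best = min(
                    flips,
                    key=lambda f: max(f[1] * f[2] * xi, 0)
                    + max(f[0] * f[2] * eta, 0)
                    + max(f[0] * f[1] * zeta, 0),
                )
                if best != (1, 1, 1):
                    apply(np.diag(best))
                    continue
        # step 5
        if abs(xi) > B + eps or (abs(xi - B) <= eps and 2 * eta < zeta - eps) or (
            abs(xi + B) <= eps and zeta < -eps
        ):
            s = 1 if xi > 0 else -1
            apply([[1, 0, 0], [0, 1, 0], [0, -s, 1]])
            continue
        # step 6
        if abs(eta) > A + eps or (abs(eta - A) <= eps and 2 * xi < zeta - eps) or (
            abs(eta + A) <= eps and zeta < -eps
        ):
            s = 1 if eta > 0 else -1
            apply([[1, 0, 0], [0, 1, 0], [-s, 0, 1]])
            continue
        # step 7
        if abs(zeta) > A + eps or (abs(zeta - A) <= eps and 2 * xi < eta - eps) or (
            abs(zeta + A) <= eps and eta < -eps
        ):
            s = 1 if zeta > 0 else -1
            apply([[1, 0, 0], [-s, 1, 0], [0, 0, 1]])
            continue
        # step 8
        total = xi + eta + zeta + A + B
        if total < -eps or (abs(total) <= eps and 2 * (A + eta) + zeta > eps):
            apply([[1, 0, 0], [0, 1, 0], [1, 1, 1]])
            continue
        if round(abs(np.linalg.det(T))) != 1:
            raise RuntimeError("reduction transform lost unimodularity")
        return basis, T
    raise RuntimeError(f"Niggli reduction did not converge in {max_iter} steps")


# ---------------------------------------------------------------------------
# the 44 characters
#
# (number, bravais, transform rows, sign type) in International Tables
# order; type "I" characters require positive scalar products D, E, F of
# the reduced basis, type "II" non-positive ones.

def _m(text: str) -> np.ndarray:
    rows = text.split("/")
    return np.array([[int(v) for v in row.split()] for row in rows], dtype=int)


CHARACTER_TABLE: list[tuple[int, str, np.ndarray, str]] = [
    # A = B = C
    (1, "cF", _m("1 -1 1/1 1 -1/-1 1 1"), "I"),
    (2, "hR", _m("1 -1 0/-1 0 1/-1 -1 -1"), "I"),
    (3, "cP", _m("1 0 0/0 1 0/0 0 1"), "II"),
    (5, "cI", _m("1 0 1/1 1 0/0 1 1"), "II"),
    (4, "hR", _m("1 -1 0/-1 0 1/-1 -1 -1"), "II"),
    (6, "tI", _m("0 1 1/1 0 1/1 1 0"), "II"),
    (7, "tI", _m("1 0 1/1 1 0/0 1 1"), "II"),
    (8, "oI", _m("-1 -1 0/-1 0 -1/0 -1 -1"), "II"),
    # A = B
    (9, "hR", _m("1 0 0/-1 1 0/-1 -1 3"), "I"),
    (10, "mC", _m("1 1 0/1 -1 0/0 0 -1"), "I"),
    (11, "tP", _m("1 0 0/0 1 0/0 0 1"), "II"),
    (12, "hP", _m("1 0 0/0 1 0/0 0 1"), "II"),
    (13, "oC", _m("1 1 0/-1 1 0/0 0 1"), "II"),
    (15, "tI", _m("1 0 0/0 1 0/1 1 2"), "II"),
    (16, "oF", _m("-1 -1 0/1 -1 0/1 1 2"), "II"),
    (14, "mC", _m("1 1 0/-1 1 0/0 0 1"), "II"),
    (17, "mC", _m("1 -1 0/1 1 0/-1 0 -1"), "II"),
    # B = C
    (18, "tI", _m("0 -1 1/1 -1 -1/1 0 0"), "I"),
    (19, "oI", _m("-1 0 0/0 -1 1/-1 1 1"), "I"),
    (20, "mC", _m("0 1 1/0 1 -1/-1 0 0"), "I"),
    (21, "tP", _m("0 1 0/0 0 1/1 0 0"), "II"),
    (22, "hP", _m("0 1 0/0 0 1/1 0 0"), "II"),
    (23, "oC", _m("0 1 1/0 -1 1/1 0 0"), "II"),
    (24, "hR", _m("1 2 1/0 -1 1/1 0 0"), "II"),
    (25, "mC", _m("0 1 1/0 -1 1/1 0 0"), "II"),
    # no length conditions
    (26, "oF", _m("1 0 0/-1 2 0/-1 0 2"), "I"),
    (27, "mC", _m("1 -2 0/-1 0 0/0 -1 1"), "I"),
    (28, "mC", _m("-1 0 0/-1 0 2/0 1 0"), "I"),
    (29, "mC", _m("1 0 0/1 -2 0/0 0 -1"), "I"),
    (30, "mC", _m("0 1 0/0 1 -2/-1 0 0"), "I"),
    (31, "aP", _m("1 0 0/0 1 0/0 0 1"), "I"),
    (32, "oP", _m("1 0 0/0 1 0/0 0 1"), "II"),
    (40, "oC", _m("0 -1 0/0 1 2/-1 0 0"), "II"),
    (35, "mP", _m("0 -1 0/-1 0 0/0 0 -1"), "II"),
    (36, "oC", _m("1 0 0/-1 0 -2/0 1 0"), "II"),
    (33, "mP", _m("1 0 0/0 1 0/0 0 1"), "II"),
    (38, "oC", _m("-1 0 0/1 2 0/0 0 -1"), "II"),
    (34, "mP", _m("-1 0 0/0 0 -1/0 -1 0"), "II"),
    (42, "oI", _m("-1 0 0/0 -1 0/1 1 2"), "II"),
    (41, "mC", _m("0 -1 -2/0 -1 0/-1 0 0"), "II"),
    (37, "mC", _m("1 0 2/1 0 0/0 1 0"), "II"),
    (39, "mC", _m("-1 -2 0/-1 0 0/0 0 -1"), "II"),
    (43, "mI", _m("-1 0 0/-1 -1 -2/0 -1 0"), "II"),
    (44, "aP", _m("1 0 0/0 1 0/0 0 1"), "II"),
]

# metric constraints of each Bravais family on the conventional cell
# (pairs of equal lengths, target angles in degrees)
_FAMILY = {
    "c": ("abc", (90.0, 90.0, 90.0)),
    "t": ("ab", (90.0, 90.0, 90.0)),
    "o": ("", (90.0, 90.0, 90.0)),
    "h": ("ab", (90.0, 90.0, 120.0)),
    "m": ("", (90.0, None, 90.0)),
    "a": ("", (None, None, None)),
}


def _symmetry_penalty(cell, bravais: str) -> float:
    a, b, c, al, be, ga = cell
    equal, angles = _FAMILY[bravais[0]]
    q = 0.0
    pairs = {"abc": [(a, b), (b, c)], "ab": [(a, b)], "": []}[equal]
    for u, v in pairs:
        q += 200.0 * abs(u - v) / (u + v)  # percent deviation
    for actual, target in zip((al, be, ga), angles):
        if target is not None:
            q += abs(actual - target)  # degrees
    return q


def _sign_penalty(A, B, C, D, E, F, sign_type: str) -> float:
    scale = 100.0 / ((A + B + C) / 3.0)
    if sign_type == "I":
        return scale * sum(max(0.0, -v) for v in (D, E, F))
    return scale * sum(max(0.0, v) for v in (D, E, F))


def lattice_characters(reduced_basis: np.ndarray) -> list[LatticeCharacter]:
    """Score all 44 characters of a Niggli-reduced direct basis (rows).

    Returned quality-sorted (stable by character number); the list always
    has 44 entries and the triclinic characters fit exactly.
    """
    reduced_basis = np.asarray(reduced_basis, dtype=float)
    A, B, C, D, E, F = _metric(reduced_basis)
    eps = 1e-9 * max(A, B, C)
    out = []
    for number, bravais, M, sign_type in CHARACTER_TABLE:
        conv = M @ reduced_basis
        cell = cell_parameters(conv)
        q = _symmetry_penalty(cell, bravais) + _sign_penalty(A, B, C, D, E, F, sign_type)
        if q < 1e-6:
            q = 0.0
        out.append(LatticeCharacter(number, bravais, M, q, cell))
    out.sort(key=lambda ch: (ch.quality, ch.number))
    return out


def characters_from_cell(cell) -> list[LatticeCharacter]:
    """Convenience: reduce a raw cell first, then classify."""
    direct = np.linalg.inv(cell_to_reciprocal_basis(cell)).T
    reduced, _ = niggli_reduce(direct)
    return lattice_characters(reduced)
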