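"""Niggli reduction and lattice-character classification."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotred.geometry import cell_parameters, cell_to_reciprocal_basis
from rotred.lattice import lattice_characters, niggli_reduce

CENTRING = {
    "P": np.eye(3),
    "C": np.array([[0.5, 0.5, 0], [-0.5, 0.5, 0], [0, 0, 1.0]]),
    "I": np.array([[-0.5, 0.5, 0.5], [0.5, -0.5, 0.5], [0.5, 0.5, -0.5]]),
    "F": np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
    "R": np.array([[2 / 3, 1 / 3, 1 / 3], [-1 / 3, 1 / 3, 1 / 3], [-1 / 3, -2 / 3, 1 / 3]]),
}

BRAVAIS_CASES = [
    ("aP", (10, 13, 17, 75, 85, 95), "P"),
    ("mP", (10, 13, 17, 90, 105, 90), "P"),
    ("mC", (10, 13, 17, 90, 105, 90), "C"),
    ("oP", (10, 13, 17, 90, 90, 90), "P"),
    ("oC", (10, 13, 17, 90, 90, 90), "C"),
    ("oF", (10, 13, 17, 90, 90, 90), "F"),
    ("oI", (10, 13, 17, 90, 90, 90), "I"),
    ("tP", (10, 10, 17, 90, 90, 90), "P"),
    ("tI", (10, 10, 17, 90, 90, 90), "I"),
    ("hP", (10, 10, 17, 90, 90, 120), "P"),
    ("hR", (10, 10, 17, 90, 90, 120), "R"),
    ("cP", (10, 10, 10, 90, 90, 90), "P"),
    ("cF", (10, 10, 10, 90, 90, 90), "F"),
    ("cI", (10, 10, 10, 90, 90, 90), "I"),
]


def direct_basis(cell):
    return np.linalg.inv(cell_to_reciprocal_basis(cell)).T


def random_unimodular(rng, lim=2):
    while True:
        M = rng.integers(-lim, lim + 1, (3, 3))
        if abs(round(np.linalg.det(M))) == 1:
            return M


def test_already_reduced_cubic_unchanged():
    basis = direct_basis((50, 50, 50, 90, 90, 90))
    reduced, T = niggli_reduce(basis)
    np.testing.assert_allclose(np.abs(T), np.eye(3))
    np.testing.assert_allclose(cell_parameters(reduced), (50, 50, 50, 90, 90, 90), atol=1e-8)


def test_reduction_matches_gemmi_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        cell = (rng.uniform(20, 80), rng.uniform(20, 80), rng.uniform(20, 80),
                rng.uniform(70, 110), rng.uniform(70, 110), rng.uniform(70, 110))
        basis = random_unimodular(rng) @ direct_basis(cell)
        reduced, T = niggli_reduce(basis)
        assert abs(round(np.linalg.det(T))) == 1
        a, b, c = reduced
        mine = sorted(np.abs([a @ a, b @ b, c @ c, 2 * b @ c, 2 * a @ c, 2 * a @ b]))
        gv = gemmi.GruberVector(gemmi.UnitCell(*cell_parameters(basis)), None)
        gv.niggli_reduce()
        assert np.allclose(mine, sorted(np.abs(gv.parameters)), rtol=1e-4)


def test_reduction_vs_brute_force_unimodular_search():
    """Oracle: exhaustive search over small unimodular transforms finds no
    basis with a smaller sorted-length vector than the reduced one."""
    rng = np.random.default_rng(1)
    small = [np.array(m).reshape(3, 3) for m in
             __import__("itertools").product([-1, 0, 1], repeat=9)]
    small = [m for m in small if abs(round(np.linalg.det(m))) == 1]
    for _ in range(3):
        cell = (rng.uniform(10, 20), rng.uniform(10, 20), rng.uniform(10, 20),
                rng.uniform(80, 100), rng.uniform(80, 100), rng.uniform(80, 100))
        basis = direct_basis(cell)
        reduced, _ = niggli_reduce(random_unimodular(rng) @ basis)
        norms_red = sorted(np.linalg.norm(reduced, axis=1))
        best = min(sorted(np.linalg.norm(m @ basis, axis=1)) for m in small)
        assert np.allclose(norms_red, best, rtol=1e-9)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_reduction_invariant_under_unimodular_change(seed):
    rng = np.random.default_rng(seed)
    cell = (rng.uniform(15, 60), rng.uniform(15, 60), rng.uniform(15, 60),
            rng.uniform(75, 105), rng.uniform(75, 105), rng.uniform(75, 105))
    try:
        basis = direct_basis(cell)
    except Exception:
        return
    if abs(np.linalg.det(basis)) < 100:
        return
    r1, _ = niggli_reduce(basis)
    r2, _ = niggli_reduce(random_unimodular(rng) @ basis)
    np.testing.assert_allclose(
        sorted(np.linalg.norm(r1, axis=1)), sorted(np.linalg.norm(r2, axis=1)), rtol=1e-6
    )


def test_always_44_characters():
    rng = np.random.default_rng(3)
    for _ in range(5):
        cell = (rng.uniform(15, 40), rng.uniform(15, 40), rng.uniform(15, 40),
                rng.uniform(75, 105), rng.uniform(75, 105), rng.uniform(75, 105))
        reduced, _ = niggli_reduce(direct_basis(cell))
        chars = lattice_characters(reduced)
        assert len(chars) == 44
        assert all(ch.quality >= 0 for ch in chars)
        # the triclinic character always fits exactly
        assert min(ch.quality for ch in chars if ch.bravais == "aP") == 0.0


def test_exact_cubic_cell_scores_cp_zero():
    reduced, _ = niggli_reduce(direct_basis((30, 30, 30, 90, 90, 90)))
    chars = {ch.number: ch for ch in lattice_characters(reduced)}
    assert chars[3].bravais == "cP"
    assert chars[3].quality == 0.0
    np.testing.assert_allclose(chars[3].conventional_cell, (30, 30, 30, 90, 90, 90), atol=1e-6)


def test_stretched_cubic_prefers_tetragonal():
    reduced, _ = niggli_reduce(direct_basis((30, 30, 30.6, 90, 90, 90)))  # 2% stretch
    chars = {ch.number: ch for ch in lattice_characters(reduced)}
    tP = min(ch.quality for ch in chars.values() if ch.bravais == "tP")
    cP = min(ch.quality for ch in chars.values() if ch.bravais == "cP")
    assert tP < 1e-6
    assert cP > tP


@pytest.mark.parametrize("name,cell,centring", BRAVAIS_CASES)
def test_bravais_roundtrip(name, cell, centring):
    """conventional cell -> primitive basis -> random setting -> reduce ->
    classify recovers a zero-quality character of the right type whose
    transform reproduces the conventional cell."""
    import zlib

    rng = np.random.default_rng(zlib.crc32(name.encode()))
    prim = CENTRING[centring] @ direct_basis(cell)
    for _ in range(3):
        basis = random_unimodular(rng) @ prim
        reduced, _ = niggli_reduce(basis)
        chars = lattice_characters(reduced)
        match = [ch for ch in chars if ch.quality < 1e-5 and ch.bravais == name]
        assert match, f"no exact {name} character found"
        got = sorted(match[0].conventional_cell[:3])
        assert np.allclose(got, sorted(cell[:3]), rtol=1e-6)


def test_quality_ordering_true_type_beats_higher_symmetry():
    # orthorhombic cell distorted from tetragonal: oP must fit better than tP
    reduced, _ = niggli_reduce(direct_basis((10, 10.4, 17, 90, 90, 90)))
    chars = lattice_characters(reduced)
    best_oP = min(ch.quality for ch in chars if ch.bravais == "oP")
    best_tP = min(ch.quality for ch in chars if ch.bravais == "tP")
    best_cP = min(ch.quality for ch in chars if ch.bravais == "cP")
    assert best_oP <= best_tP <= best_cP
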