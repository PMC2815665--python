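"""Autoindexing: clustering, basis selection, local indexing, gates."""

import numpy as np
import pytest

from rotred.files import SpotRecord
from rotred.geometry import cell_to_reciprocal_basis, scattering_vector
from rotred.indexing import (
    CLUSTER_REPORT_LENGTH,
    INDEXED_FRACTION_GATE,
    MAX_LOCAL_INDEX_SPOTS,
    IndexingError,
    IndexingParams,
    difference_clusters,
    idxref_gate,
    local_index,
    origin_search,
    run_idxref,
    select_basis,
)
from rotred.validate import cell_agreement, match_indexed_spots


def _lattice_pstars(rng, n=300, cell=(16, 19, 22, 90, 90, 90)):
    basis = cell_to_reciprocal_basis(cell)
    hkls = rng.integers(-6, 7, (n, 3))
    hkls = hkls[np.any(hkls != 0, axis=1)]
    return hkls @ basis, basis, hkls


def test_clusters_sit_on_basis_lattice():
    rng = np.random.default_rng(0)
    pstars, basis, _ = _lattice_pstars(rng)
    clusters = difference_clusters(pstars)
    top = clusters[:10]
    for c in top:
        idx = np.linalg.solve(basis.T, c.center)
        assert np.abs(idx - np.round(idx)).max() < 0.1


def test_random_vectors_fail_integrality():
    rng = np.random.default_rng(1)
    pstars = rng.uniform(-0.3, 0.3, (200, 3))
    with pytest.raises(IndexingError):
        clusters = difference_clusters(pstars)
        select_basis(clusters)


def test_cluster_report_capped_at_60():
    assert CLUSTER_REPORT_LENGTH == 60


def test_select_basis_reports_near_integer_indices():
    rng = np.random.default_rng(2)
    pstars, basis, _ = _lattice_pstars(rng, 400)
    clusters = difference_clusters(pstars)
    B, mean_dev = select_basis(clusters)
    assert mean_dev < 0.05
    for c in clusters:
        assert c.indices is not None


def test_select_basis_invariant_to_cluster_order():
    rng = np.random.default_rng(3)
    pstars, _, _ = _lattice_pstars(rng, 300)
    clusters = difference_clusters(pstars)
    B1, _ = select_basis(list(clusters))
    rng.shuffle(clusters)
    clusters.sort(key=lambda c: (-c.population, np.linalg.norm(c.center)))
    B2, _ = select_basis(clusters)
    # same lattice up to sign/permutation: volumes agree
    assert abs(abs(np.linalg.det(B1)) - abs(np.linalg.det(B2))) < 1e-12


def test_local_index_pure_lattice():
    rng = np.random.default_rng(4)
    pstars, basis, hkls = _lattice_pstars(rng, 500)
    signals = rng.uniform(100, 1000, len(pstars))
    assigned, sizes, members = local_index(pstars, signals, basis)
    assert sizes[0] >= 0.99 * len(pstars)
    # indices agree with truth up to a common offset
    nonzero = np.any(assigned != 0, axis=1)
    offsets = assigned[members] - hkls[members]
    assert len(np.unique(offsets, axis=0)) == 1


def test_local_index_caps_at_3000():
    rng = np.random.default_rng(5)
    basis = cell_to_reciprocal_basis((16, 19, 22, 90, 90, 90))
    hkls = rng.integers(-8, 9, (5000, 3))
    hkls = hkls[np.any(hkls != 0, axis=1)][:5000]
    pstars = hkls @ basis + rng.normal(0, 1e-5, (len(hkls), 3))
    signals = rng.uniform(1, 100, len(pstars))
    assigned, sizes, members = local_index(pstars, signals, basis)
    assert MAX_LOCAL_INDEX_SPOTS == 3000
    assert sum(sizes) <= 3000
    assert len(members) <= 3000


def test_aliens_land_outside_largest_subtree():
    rng = np.random.default_rng(6)
    pstars, basis, hkls = _lattice_pstars(rng, 400)
    n_alien = len(pstars) // 5
    aliens = rng.uniform(-0.25, 0.25, (n_alien, 3))
    allp = np.vstack([pstars, aliens])
    signals = rng.uniform(100, 1000, len(allp))
    assigned, sizes, members = local_index(allp, signals, basis)
    in_largest = np.zeros(len(allp), bool)
    in_largest[members] = True
    # lattice spots dominate the largest subtree; aliens mostly excluded
    assert in_largest[: len(pstars)].mean() > 0.95
    assert in_largest[len(pstars):].mean() < 0.10


def test_gate_thresholds(baseline_models, found_spots, idxref_result):
    assert INDEXED_FRACTION_GATE == 0.70
    gate = idxref_gate(idxref_result.models, idxref_result.spots)
    assert gate.success and gate.fraction > 0.95


def test_gate_failure_carries_continue_instruction(idxref_result):
    rng = np.random.default_rng(7)
    spots = list(idxref_result.spots)
    # make half the spots unexplainable aliens
    n = len(spots) // 2
    for i in range(n):
        s = spots[i]
        spots[i] = SpotRecord(s.x, s.y, s.z, s.intensity, (0, 0, 0))
    gate = idxref_gate(idxref_result.models, spots)
    assert not gate.success
    assert abs(gate.fraction - 0.5) < 0.1
    assert "JOB=DEFPIX XPLAN INTEGRATE CORRECT" in gate.message


def test_gate_flips_at_70_percent(idxref_result):
    """Bisection over the alien fraction locates the documented constant."""
    spots = idxref_result.spots
    explained = [s for s in spots if s.hkl != (0, 0, 0)]

    def gate_at(frac_alien):
        n_alien = int(round(frac_alien * len(explained)))
        mixed = [SpotRecord(s.x, s.y, s.z, s.intensity, (0, 0, 0)) for s in explained[:n_alien]]
        mixed += explained[n_alien:]
        return idxref_gate(idxref_result.models, mixed).success

    lo, hi = 0.0, 1.0
    for _ in range(12):
        mid = (lo + hi) / 2
        if gate_at(mid):
            lo = mid
        else:
            hi = mid
    threshold_fraction_explained = 1.0 - (lo + hi) / 2
    assert abs(threshold_fraction_explained - 0.70) < 0.02


def test_origin_search_prefers_zero_for_consistent_data(idxref_result):
    table = idxref_result.origin_table
    assert table[0]["origin"] == (0, 0, 0)


def test_origin_search_detects_constructed_misindexing(baseline_models, idxref_result):
    """Shift all indices by one row: the search must rank that offset first."""
    models = idxref_result.models
    spots = [s for s in idxref_result.spots if s.hkl != (0, 0, 0)]
    hkls = np.array([s.hkl for s in spots]) + np.array([0, 1, 0])
    xyz = np.array([[s.x, s.y, s.z] for s in spots])
    table = origin_search(models, hkls, xyz)
    assert table[0]["origin"] == (0, -1, 0)
    zero = next(r for r in table if r["origin"] == (0, 0, 0))
    assert table[0]["score"] < zero["score"]


def test_end_to_end_cell_and_index_recovery(baseline_models, stack, idxref_result):
    _, manifest, _ = stack
    len_err, ang_err = cell_agreement(idxref_result.models.crystal, baseline_models.crystal)
    assert len_err < 0.002
    assert ang_err < 0.1
    ok, n = match_indexed_spots(idxref_result.spots, manifest, idxref_result.models,
                                baseline_models)
    assert ok / n >= 0.99
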