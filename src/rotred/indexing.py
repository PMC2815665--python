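"""Autoindexing from spot centroids.

The observed centroids are mapped to reciprocal-lattice vectors of the
unrotated crystal; pairwise difference vectors accumulate in a 3D
histogram whose clusters reveal the reciprocal basis.  A basis is chosen
so every cluster indexes as nearly integral small multiples, reduced to
the Niggli cell, and used to index the strongest spots by the
local-indexing method: spots are nodes of a graph, edge reliability
measures how nearly a pair's difference indexes to small integers, and
the largest subtree of the maximum-reliability spanning forest defines
the crystal lattice.  Alternative index origins are scored, geometry is
refined, and the run is gated on the fraction of explained spots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .files import SpotRecord
from .geometry import (
    ExperimentModel,
    CrystalModel,
    predict_positions_for_hkls,
    refine_geometry,
    scattering_vector,
)
from .lattice import LatticeCharacter, lattice_characters, niggli_reduce

__all__ = [
    "IndexingParams",
    "DifferenceCluster",
    "IndexingError",
    "difference_clusters",
    "select_basis",
    "local_index",
    "origin_search",
    "idxref_gate",
    "run_idxref",
    "IdxrefResult",
]

MAX_LOCAL_INDEX_SPOTS = 3000  # strongest spots admitted to local indexing
CLUSTER_REPORT_LENGTH = 60  # most-populated clusters listed in the log
INDEXED_FRACTION_GATE = 0.70  # minimum explained-spot fraction for success

CONTINUE_INSTRUCTION = (
    "INSUFFICIENT PERCENTAGE OF INDEXED REFLECTIONS. Alien spots (ice, "
    "satellites) may still allow meaningful processing: continue with "
    "JOB=DEFPIX XPLAN INTEGRATE CORRECT"
)


class IndexingError(RuntimeError):
    pass


def _phase_map(s: float, n: int = 201):
    """Measured vs true centroid phase for rocking width ``s`` (frames).

    A rocking curve integrated frame-wise snaps its count-weighted
    centroid toward the frame centre; this returns the (true offset,
    measured offset) curve for offsets v in (-0.5, 0.5) from the centre.
    """
    from scipy.special import ndtr

    j = np.arange(-4, 6)
    v_true = np.linspace(-0.499, 0.499, n)
    v_meas = np.empty_like(v_true)
    for i, v in enumerate(v_true):
        u = 0.5 + v
        p = ndtr((j + 1 - u) / s) - ndtr((j - u) / s)
        v_meas[i] = float((p * (j + 0.5)).sum()) - u + v
    return v_true, v_meas


def debias_frame_centroids(z: np.ndarray, max_width: float = 1.2) -> np.ndarray:
    """Undo the frame-centre snap of rocking centroids.

    The rocking width (in frames) is first estimated from the spread of
    the measured phases, then each centroid is mapped through the inverse
    of the phase-compression curve.  For widths well above one frame the
    correction vanishes.
    """
    v_obs = (z % 1.0) - 0.5
    spread = float(np.sqrt(np.mean(v_obs**2)))
    # calibration: RMS of measured phase vs rocking width
    widths = np.linspace(0.05, max_width, 40)
    rms = []
    for s in widths:
        _, vm = _phase_map(s, 101)
        rms.append(float(np.sqrt(np.mean(vm**2))))
    s_est = float(np.interp(spread, np.asarray(rms), widths))  # rms grows with s
    v_true, v_meas = _phase_map(s_est)
    order = np.argsort(v_meas)
    corrected = np.interp(v_obs, v_meas[order], v_true[order])
    return np.floor(z) + 0.5 + corrected


@dataclass
class IndexingParams:
    sepmin: float | None = None  # 1/Angstrom; None -> auto from the data
    cluster_radius: float | None = None  # 1/Angstrom; None -> auto
    error_eps: float = 0.05  # half-width of the integrality kernel
    magnitude_phi: float = 8.0  # index-magnitude damping
    quality_lmin: float = 0.2  # minimum edge reliability (INDEX_QUALITY = 1 - l_min)
    origin: tuple[int, int, int] = (0, 0, 0)  # user-supplied index-origin offset
    max_spot_error: float = 3.0  # pixels, the explained-spot gate
    max_z_error: float = 3.0  # frames


@dataclass
class DifferenceCluster:
    center: np.ndarray  # 1/Angstrom
    population: int
    indices: np.ndarray | None = None  # real-valued w.r.t. the current basis


def _hemisphere(diffs: np.ndarray) -> np.ndarray:
    """Canonicalize difference vectors to one hemisphere."""
    flip = (
        (diffs[:, 2] < 0)
        | ((diffs[:, 2] == 0) & (diffs[:, 1] < 0))
        | ((diffs[:, 2] == 0) & (diffs[:, 1] == 0) & (diffs[:, 0] < 0))
    )
    out = diffs.copy()
    out[flip] *= -1
    return out


def difference_clusters(
    pstars: np.ndarray,
    params: IndexingParams | None = None,
    max_vectors: int = 400,
    n_bins: int = 64,
) -> list[DifferenceCluster]:
    """Population-sorted clusters of pairwise reciprocal-vector differences.

    The histogram extent adapts to the shortest difference shell so the
    basis-vector clusters are resolved for any cell size; SEPMIN and the
    smoothing radius default to fractions of that scale.
    """
    params = params or IndexingParams()
    pstars = np.asarray(pstars, dtype=float)
    if len(pstars) < 2:
        raise IndexingError("need at least two reciprocal-lattice vectors")
    if len(pstars) > max_vectors:
        pstars = pstars[:max_vectors]
    diffs = pstars[:, None, :] - pstars[None, :, :]
    iu = np.triu_indices(len(pstars), k=1)
    diffs = _hemisphere(diffs[iu])
    lengths = np.linalg.norm(diffs, axis=1)
    scale = float(np.percentile(lengths[lengths > 0], 2.0))
    sepmin = params.sepmin if params.sepmin is not None else 0.3 * scale
    radius = params.cluster_radius if params.cluster_radius is not None else scale / 10.0
    keep = lengths > sepmin
    diffs, lengths = diffs[keep], lengths[keep]
    if len(diffs) == 0:
        raise IndexingError("no difference vectors above SEPMIN")

    extent = 3.5 * scale
    inside = np.all(np.abs(diffs) < extent, axis=1)
    pts = diffs[inside]
    if len(pts) == 0:
        raise IndexingError("no difference vectors inside the histogram")
    bin_width = 2.0 * extent / n_bins
    hist, edges = np.histogramdd(pts, bins=n_bins, range=[(-extent, extent)] * 3)
    sigma = max(radius / bin_width, 0.5)
    smooth = ndimage.gaussian_filter(hist, sigma=sigma, mode="constant")
    peaks = (ndimage.maximum_filter(smooth, size=3, mode="constant") == smooth) & (smooth > 0)
    pz, py, px = np.nonzero(peaks)

    centers_bin = np.stack(
        [edges[0][pz] + bin_width / 2, edges[1][py] + bin_width / 2, edges[2][px] + bin_width / 2],
        axis=1,
    )
    tree = cKDTree(pts)
    clusters = []
    for cb in centers_bin:
        near = tree.query_ball_point(cb, max(radius, bin_width))
        if not near:
            continue
        members = pts[near]
        center = members.mean(axis=0)
        # one refinement pass with the updated centre
        near = tree.query_ball_point(center, max(radius, bin_width))
        if not near:
            continue
        members = pts[near]
        clusters.append(DifferenceCluster(members.mean(axis=0), len(near)))
    if not clusters:
        raise IndexingError("no clusters found: no lattice")
    clusters.sort(key=lambda c: (-c.population, np.linalg.norm(c.center)))
    # merge near-duplicate maxima
    merged: list[DifferenceCluster] = []
    for c in clusters:
        if all(np.linalg.norm(c.center - m.center) > max(radius, bin_width) for m in merged):
            merged.append(c)
    return merged


def select_basis(clusters: list[DifferenceCluster], max_candidates: int = 20):
    """Reciprocal basis (rows) from the most populated clusters.

    Minimizes the population-weighted integrality deviation of all
    cluster indices, with a mild preference for small index magnitudes
    (guards against sub- and super-lattice bases).  Raises when even the
    best triple leaves the clusters far from integral.
    """
    if len(clusters) < 3:
        raise IndexingError("need at least three clusters to pick a basis")
    cand = clusters[:max_candidates]
    centers = np.array([c.center for c in clusters])
    pops = np.array([float(c.population) for c in clusters])
    best = None
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            for k in range(j + 1, len(cand)):
                B = np.array([cand[i].center, cand[j].center, cand[k].center])
                vol = abs(np.linalg.det(B))
                norms = np.prod(np.linalg.norm(B, axis=1))
                if vol < 0.01 * norms:
                    continue
                idx = np.linalg.solve(B.T, centers.T).T
                dev = np.abs(idx - np.round(idx)).sum(axis=1)
                mag = np.abs(np.round(idx)).sum(axis=1)
                score = float((pops * dev).sum() + 2e-3 * (pops * mag).sum())
                if best is None or score < best[0]:
                    best = (score, B, idx)
    if best is None:
        raise IndexingError("all candidate basis triples are degenerate")
    _, B, idx = best
    for c, row in zip(clusters, idx):
        c.indices = row
    dev = np.abs(idx - np.round(idx)).max(axis=1)
    mean_dev = float((pops * np.minimum(dev, 0.5)).sum() / pops.sum())
    if mean_dev > 0.2:
        raise IndexingError(
            "unable to find a reasonable lattice basis: cluster indices "
            f"deviate from integers by {mean_dev:.2f} on average"
        )
    return B, mean_dev


def local_index(
    pstars: np.ndarray,
    signals: np.ndarray,
    rec_basis: np.ndarray,
    params: IndexingParams | None = None,
    n_neighbours: int = 12,
):
    """Index up to 3000 of the strongest spots by the local method.

    Returns (hkl array over *all* input spots with 0,0,0 for those not in
    the largest subtree, subtree sizes descending, indices of the spots in
    the largest subtree).
    """
    params = params or IndexingParams()
    pstars = np.asarray(pstars, dtype=float)
    signals = np.asarray(signals, dtype=float)
    n_all = len(pstars)
    order = np.argsort(-signals, kind="stable")[:MAX_LOCAL_INDEX_SPOTS]
    sub = pstars[order]
    n = len(sub)
    if n < 2:
        raise IndexingError("too few spots for local indexing")

    tree = cKDTree(sub)
    k = min(n_neighbours + 1, n)
    _, nbrs = tree.query(sub, k=k)
    edges = {}
    Binv_t = np.linalg.inv(rec_basis.T)
    for a in range(n):
        for b in nbrs[a][1:]:
            key = (min(a, b), max(a, b))
            if key in edges:
                continue
            diff = sub[key[1]] - sub[key[0]]
            idx = Binv_t @ diff
            m = np.round(idx)
            dev = np.abs(idx - m)
            tri = np.maximum(0.0, 1.0 - dev / params.error_eps)
            damp = 1.0 / (1.0 + (np.linalg.norm(m) / params.magnitude_phi) ** 2)
            rel = float(np.prod(tri) * damp)
            if rel >= params.quality_lmin:
                edges[key] = rel

    # maximum-reliability spanning forest (Kruskal)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    forest: dict[int, list[int]] = {i: [] for i in range(n)}
    for (a, b), rel in sorted(edges.items(), key=lambda kv: (-kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            forest[a].append(b)
            forest[b].append(a)

    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    sizes = sorted((len(v) for v in comp.values()), reverse=True)
    largest = max(comp.values(), key=len)
    if len(largest) < 10:
        raise IndexingError(f"largest subtree holds only {len(largest)} spots")

    # propagate indices from the strongest spot of the largest subtree
    hkl_sub = np.zeros((n, 3), dtype=int)
    in_largest = np.zeros(n, dtype=bool)
    seed = max(largest, key=lambda i: signals[order[i]])
    hkl_sub[seed] = np.round(Binv_t @ sub[seed]).astype(int)
    in_largest[seed] = True
    stack = [seed]
    while stack:
        a = stack.pop()
        for b in forest[a]:
            if not in_largest[b]:
                step = np.round(Binv_t @ (sub[b] - sub[a])).astype(int)
                hkl_sub[b] = hkl_sub[a] + step
                in_largest[b] = True
                stack.append(b)

    hkl_all = np.zeros((n_all, 3), dtype=int)
    member_rows = order[in_largest]
    hkl_all[member_rows] = hkl_sub[in_largest]
    return hkl_all, sizes[:10], member_rows


def index_with_model(models: ExperimentModel, pstars: np.ndarray, tol: float = 0.2):
    """Nearest-integer indices under the current basis; None rows -> 0,0,0."""
    idx = np.linalg.solve(models.crystal.rec_basis.T, np.asarray(pstars).T).T
    m = np.round(idx).astype(int)
    ok = (np.abs(idx - m).max(axis=1) <= tol) & np.any(m != 0, axis=1)
    m[~ok] = 0
    return m, ok


def origin_search(
    models: ExperimentModel,
    hkls: np.ndarray,
    observed_xyz: np.ndarray,
    extra_origins: list[tuple[int, int, int]] | None = None,
    beam_shift_weight: float = 0.05,
):
    """Rank alternative index origins (h0, k0, l0).

    Each candidate offset is added to all indices, the beam direction and
    detector origin re-refined, and the candidate scored by the positional
    rms plus a penalty on how far the direct-beam position had to move.
    Returns the ranked table; the best entry first.
    """
    candidates = {(h, k, l) for h in (-1, 0, 1) for k in (-1, 0, 1) for l in (-1, 0, 1)}
    for extra in extra_origins or []:
        candidates.add(tuple(int(v) for v in extra))
    det = models.detector
    table = []
    for origin in sorted(candidates):
        shifted = hkls + np.asarray(origin)
        nonzero = np.any(shifted != 0, axis=1)
        if nonzero.sum() < 12:
            continue
        try:
            refined, rms_xy, rms_z = refine_geometry(
                models, shifted[nonzero], observed_xyz[nonzero], {"BEAM", "ORGXY"}
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        shift_px = float(
            np.hypot(refined.detector.orgx - det.orgx, refined.detector.orgy - det.orgy)
        )
        score = float(np.hypot(rms_xy, rms_z)) + beam_shift_weight * shift_px
        table.append({"origin": origin, "score": score, "rms_xy": rms_xy,
                      "rms_z": rms_z, "beam_shift_px": shift_px, "models": refined})
    if not table:
        raise IndexingError("origin search found no refinable candidate")
    table.sort(key=lambda row: (row["score"], row["origin"]))
    return table


@dataclass
class GateResult:
    success: bool
    fraction: float
    message: str = ""


def idxref_gate(
    models: ExperimentModel,
    spots: list[SpotRecord],
    max_spot_error: float = 3.0,
    max_z_error: float = 3.0,
) -> GateResult:
    """Success iff >= 70% of the given spots are explained by the lattice."""
    hkls = np.array([s.hkl if s.hkl is not None else (0, 0, 0) for s in spots])
    xyz = np.array([[s.x, s.y, s.z] for s in spots])
    nonzero = np.any(hkls != 0, axis=1)
    explained = np.zeros(len(spots), dtype=bool)
    if nonzero.any():
        x, y, z = predict_positions_for_hkls(models, hkls[nonzero], xyz[nonzero, 2])
        dxy = np.hypot(x - xyz[nonzero, 0], y - xyz[nonzero, 1])
        dz = np.abs(z - xyz[nonzero, 2])
        explained[nonzero] = (dxy <= max_spot_error) & (dz <= max_z_error)
    fraction = float(explained.mean()) if len(spots) else 0.0
    if fraction >= INDEXED_FRACTION_GATE:
        return GateResult(True, fraction)
    return GateResult(False, fraction, CONTINUE_INSTRUCTION)


@dataclass
class IdxrefResult:
    models: ExperimentModel
    spots: list[SpotRecord]  # same order, hkl filled in (0,0,0 aliens)
    characters: list[LatticeCharacter]
    clusters: list[DifferenceCluster]
    subtree_sizes: list[int]
    origin_table: list[dict]
    gate: GateResult
    rms_xy: float = 0.0
    rms_z: float = 0.0
    log: str = ""


def run_idxref(
    models: ExperimentModel,
    spots: list[SpotRecord],
    params: IndexingParams | None = None,
) -> IdxrefResult:
    """The full IDXREF sequence on observed spot centroids."""
    params = params or IndexingParams()
    work = models.copy()
    order = np.argsort([-s.intensity for s in spots], kind="stable")
    spots_sorted = [spots[i] for i in order]
    xyz = np.array([[s.x, s.y, s.z] for s in spots_sorted])
    xyz[:, 2] = debias_frame_centroids(xyz[:, 2])
    signals = np.array([s.intensity for s in spots_sorted])
    pstars = scattering_vector(work, xyz[:, 0], xyz[:, 1], xyz[:, 2])

    clusters = difference_clusters(pstars, params)
    basis, mean_dev = select_basis(clusters)

    # reduce: reciprocal basis -> direct cell -> Niggli
    direct = np.linalg.inv(basis).T
    reduced, T = niggli_reduce(direct)
    rec_reduced = np.linalg.inv(T).T @ basis

    hkls, subtree_sizes, members = local_index(pstars, signals, rec_reduced, params)
    work.crystal = CrystalModel(
        rec_reduced,
        sigma_M=models.crystal.sigma_M if models.crystal else 0.1,
        sigma_D=models.crystal.sigma_D if models.crystal else 0.05,
    )

    # initial refinement on the largest subtree
    work, _, _ = refine_geometry(work, hkls[members], xyz[members], {"CELL", "ORIENTATION", "BEAM", "ORGXY"})

    # fold in every spot that now indexes, then search the index origin
    hkls, ok = index_with_model(work, pstars)
    if params.origin != (0, 0, 0):
        hkls[ok] = hkls[ok] + np.asarray(params.origin)
    origin_table = origin_search(work, hkls[ok], xyz[ok])
    best = origin_table[0]
    work = best["models"]
    hkls[ok] = hkls[ok] + np.asarray(best["origin"])

    # alternate re-indexing and refinement until the spot set stabilises;
    # refinement uses the brighter half of the indexed spots, whose
    # centroids are free of the threshold-quantisation noise of weak ones
    rms_xy = rms_z = 0.0
    for _ in range(3):
        bright = ok & (signals >= np.median(signals[ok])) if ok.sum() > 100 else ok
        work, rms_xy, rms_z = refine_geometry(
            work, hkls[bright], xyz[bright], {"CELL", "ORIENTATION", "BEAM", "ORGXY"},
            z_weight=0.5,
        )
        new_hkls, new_ok = index_with_model(work, pstars)
        if new_ok.sum() == ok.sum() and np.array_equal(new_hkls, hkls):
            hkls, ok = new_hkls, new_ok
            break
        hkls, ok = new_hkls, new_ok

    indexed_spots = [
        SpotRecord(s.x, s.y, s.z, s.intensity, tuple(int(v) for v in h))
        for s, h in zip(spots_sorted, hkls)
    ]
    gate = idxref_gate(work, indexed_spots, params.max_spot_error, params.max_z_error)
    reduced_now, _ = niggli_reduce(work.crystal.direct_basis)
    characters = lattice_characters(reduced_now)
    log = _idxref_log(clusters, basis, mean_dev, subtree_sizes, origin_table, characters, gate)
    return IdxrefResult(
        work, indexed_spots, characters, clusters, subtree_sizes,
        [{k: v for k, v in row.items() if k != "models"} for row in origin_table],
        gate, rms_xy, rms_z, log,
    )


def _idxref_log(clusters, basis, mean_dev, subtree_sizes, origin_table, characters, gate) -> str:
    lines = ["IDXREF log", "", f"difference clusters found: {len(clusters)}"]
    lines.append(" population  x*          y*          z*          indices")
    for c in clusters[:CLUSTER_REPORT_LENGTH]:
        idx = "" if c.indices is None else " ".join(f"{v:7.2f}" for v in c.indices)
        lines.append(
            f" {c.population:10d}  {c.center[0]:10.6f} {c.center[1]:10.6f} "
            f"{c.center[2]:10.6f}  {idx}"
        )
    lines.append("")
    lines.append(f"mean integrality deviation: {mean_dev:.4f}")
    lines.append("subtree sizes (largest ten): " + " ".join(str(s) for s in subtree_sizes))
    lines.append("")
    lines.append(" origin      score    rms_xy   rms_z   beam shift (px)")
    for row in origin_table[:10]:
        h, k, l = row["origin"]
        lines.append(
            f" {h:3d}{k:3d}{l:3d} {row['score']:9.3f} {row['rms_xy']:8.3f} "
            f"{row['rms_z']:7.3f} {row['beam_shift_px']:9.3f}"
        )
    lines.append("")
    lines.append(" character  bravais  quality  conventional cell")
    for ch in characters:
        cell = " ".join(f"{v:8.2f}" for v in ch.conventional_cell)
        lines.append(f" {ch.number:9d}  {ch.bravais:7s} {ch.quality:8.2f}  {cell}")
    lines.append("")
    status = "OK" if gate.success else gate.message
    lines.append(f"indexed fraction: {gate.fraction:.3f}  -> {status}")
    return "\n".join(lines) + "\n"
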