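"""Window-wise ROI definition.

Five approaches are implemented:

* greedy region growing from ReHo-selected (or explicit) seeds, with
  either the *weighted mean consistency* priority (size-weighted mean ROI
  homogeneity minus a size-distribution regularizer, lambda default 100)
  or the *minimum correlation* priority (lowest correlation between the
  candidate voxel and any voxel already in the ROI), optionally gated by a
  percentile acceptance threshold (N percent, default 30);
* normalized-cut (NCUT) spectral clustering of the 6-neighbor voxel
  correlation graph (edge threshold 0.2, target cluster count 246 by
  default), in the style of Craddock et al.;
* random region-grown parcels (re-exported from the synthetic generator);
* static label-volume atlases, consumed as-is;
* the filtered static baseline: the most consistent atlas ROIs under a
  voxel budget.

Greedy and random parcels are 6-connected by construction; voxels can
remain unassigned when thresholding rejects them.  Single-voxel ROIs are
treated as artifacts and removed by :func:`exclude_single_voxel_rois`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

from .core import Parcellation, VoxelVolume, pearson_matrix
from .metrics import regional_homogeneity, spatial_consistency
from .synthetic import generate_random_parcellation as random_parcellation  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "GreedyConfig",
    "CraddockConfig",
    "PriorityKind",
    "select_reho_seeds",
    "greedy_grow",
    "priority_weighted_mean_consistency",
    "priority_min_correlation",
    "threshold_accept",
    "craddock_cluster",
    "ncut_cost",
    "ncut_bisect",
    "voxel_correlation_graph",
    "exclude_single_voxel_rois",
    "filter_static_parcellation",
    "random_parcellation",
]


class PriorityKind(str, Enum):
    WEIGHTED_MEAN_CONSISTENCY = "weighted_mean_consistency"
    MIN_CORRELATION = "min_correlation"


@dataclass
class GreedyConfig:
    """Greedy grower parameters.

    ``lambda_reg`` is the regularization weight of the size-distribution
    penalty in the weighted-mean-consistency priority (default 100).
    ``threshold_percent`` is N: a candidate is accepted only if its mean
    correlation to the target ROI ranks among the N% highest of the
    current queue (default 30); set ``apply_threshold=False`` to grow
    unconditionally.
    """

    priority_kind: PriorityKind = PriorityKind.WEIGHTED_MEAN_CONSISTENCY
    lambda_reg: float = 100.0
    threshold_percent: float = 30.0
    apply_threshold: bool = True

    def __post_init__(self) -> None:
        self.priority_kind = PriorityKind(self.priority_kind)
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if not 0.0 < self.threshold_percent <= 100.0:
            raise ValueError("threshold_percent must lie in (0, 100]")


@dataclass
class CraddockConfig:
    """NCUT clustering parameters: correlation edge threshold and target
    cluster count (defaults 0.2 and 246)."""

    edge_threshold: float = 0.2
    target_clusters: int = 246

    def __post_init__(self) -> None:
        if not -1.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must lie in [-1, 1]")
        if self.target_clusters < 1:
            raise ValueError("target_clusters must be at least 1")


# ---------------------------------------------------------------------------
# seeds


def select_reho_seeds(
    volume: VoxelVolume, atlas: Parcellation
) -> dict[int, tuple[int, int, int]]:
    """One seed per atlas ROI: the masked voxel with maximal ReHo.

    Because the atlas ROIs tile the brain, the seeds inherit their roughly
    even spatial distribution.  Atlas ROIs containing no masked voxels are
    skipped with a warning.  Ties go to the first voxel in C order, and
    the result is invariant to relabeling the atlas.
    """
    labels = atlas.labels()
    if not labels:
        raise ValueError("atlas is empty")
    seeds: dict[int, tuple[int, int, int]] = {}
    for lab in labels:
        voxels = [v for v in atlas.voxels(lab) if volume.mask[v]]
        if not voxels:
            logger.warning("atlas ROI %d has no masked voxels; skipped", lab)
            continue
        rehos = [regional_homogeneity(volume, v) for v in voxels]
        seeds[lab] = voxels[int(np.argmax(rehos))]
    return seeds


# ---------------------------------------------------------------------------
# greedy growing


def priority_weighted_mean_consistency(
    roi_sizes: dict[int, int],
    roi_consistencies: dict[int, float],
    roi: int,
    candidate_consistency: float,
    lambda_reg: float,
) -> float:
    """Global weighted-mean-consistency priority of one ROI-voxel pair.

    Evaluates, as if the candidate voxel were already assigned to ``roi``,

        PV = sum_I |I| phi(I) / sum_I |I|  -  lambda sum_I |I|^2 / (sum_I |I|)^2

    over all current ROIs, where ``candidate_consistency`` is phi of the
    grown ROI.  Single-voxel ROIs, for which phi is formally undefined,
    contribute phi = 1 (a lone series is trivially homogeneous); this
    convention shifts all priorities equally and never changes candidate
    ranking.
    """
    total = 0
    weighted = 0.0
    squares = 0
    for lab, size in roi_sizes.items():
        if lab == roi:
            size = size + 1
            phi = candidate_consistency
        else:
            phi = roi_consistencies.get(lab, 1.0) if size > 1 else 1.0
        total += size
        weighted += size * phi
        squares += size * size
    return weighted / total - lambda_reg * squares / total**2


def priority_min_correlation(
    volume: VoxelVolume,
    roi_voxels: list[tuple[int, int, int]],
    candidate: tuple[int, int, int],
) -> float:
    """Lowest Pearson correlation between the candidate voxel and any
    voxel already assigned to the ROI."""
    if not roi_voxels:
        raise ValueError("roi_voxels must be non-empty")
    series = np.stack([volume.series(candidate)] + [volume.series(v) for v in roi_voxels])
    corr = pearson_matrix(series)
    return float(corr[0, 1:].min())


def threshold_accept(
    candidate_mean_correlation: float,
    reference_distribution,
    threshold_percent: float,
) -> bool:
    """Accept iff the candidate's mean correlation to its ROI ranks among
    the N% highest of the reference distribution.

    Equivalently: value >= the (100 - N)th percentile (linear
    interpolation).  This is the single policy hook for the acceptance
    threshold; the grower's reference set is the mean-correlation values
    of all ROI-voxel pairs currently queued.
    """
    if not 0.0 < threshold_percent <= 100.0:
        raise ValueError("threshold_percent must lie in (0, 100]")
    if threshold_percent == 100.0:
        return True  # "among the 100% highest" filters nothing
    ref = np.asarray(reference_distribution, dtype=float)
    if ref.size == 0:
        raise ValueError("reference distribution must be non-empty")
    cutoff = np.percentile(ref, 100.0 - threshold_percent)
    return bool(candidate_mean_correlation >= cutoff)


class _GreedyState:
    """Flat-array candidate queue for the greedy grower.

    Stores, per ROI-voxel pair, the sum of correlations between the
    candidate and the ROI's members (for Eq.-style consistency updates and
    the acceptance threshold) and the running minimum correlation (for the
    min-correlation priority).  The full priority vector is recomputed
    vectorized at every pop, so the global terms of the weighted-mean
    priority are always current; assignment updates touch only the
    affected entries.
    """

    def __init__(self, corr: np.ndarray, neighbors: list[np.ndarray], n_vox: int):
        self.corr = corr
        self.neighbors = neighbors
        self.label = np.zeros(n_vox, dtype=np.int64)  # 0 = unassigned
        self.members: dict[int, list[int]] = {}
        self.pair_sum: dict[int, float] = {}  # sum of pairwise corr within ROI
        self.roi_arr = np.zeros(0, dtype=np.int64)
        self.vox_arr = np.zeros(0, dtype=np.int64)
        self.c_arr = np.zeros(0)  # sum of corr(candidate, members)
        self.m_arr = np.zeros(0)  # min of corr(candidate, members)
        self.alive = np.zeros(0, dtype=bool)
        self.index: dict[tuple[int, int], int] = {}
        self.vox_entries: dict[int, list[int]] = {}
        self.roi_entries: dict[int, list[int]] = {}
        self.n = 0

    def _grow_capacity(self, extra: int) -> None:
        cap = self.roi_arr.size
        if self.n + extra <= cap:
            return
        new_cap = max(2 * cap, self.n + extra, 64)
        for name in ("roi_arr", "vox_arr", "c_arr", "m_arr", "alive"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def add_entry(self, roi: int, vox: int) -> None:
        if (roi, vox) in self.index:
            return
        mem = np.asarray(self.members[roi])
        cvals = self.corr[vox, mem]
        self._grow_capacity(1)
        i = self.n
        self.roi_arr[i] = roi
        self.vox_arr[i] = vox
        self.c_arr[i] = cvals.sum()
        self.m_arr[i] = cvals.min()
        self.alive[i] = True
        self.index[(roi, vox)] = i
        self.vox_entries.setdefault(vox, []).append(i)
        self.roi_entries.setdefault(roi, []).append(i)
        self.n += 1

    def assign(self, roi: int, vox: int) -> None:
        entry = self.index[(roi, vox)]
        self.label[vox] = roi
        self.pair_sum[roi] += self.c_arr[entry]
        self.members[roi].append(vox)
        # all queue entries for this voxel are now stale
        for i in self.vox_entries.get(vox, []):
            self.alive[i] = False
        # update entries of the grown ROI
        live = [i for i in self.roi_entries[roi] if self.alive[i]]
        if live:
            live = np.asarray(live)
            cv = self.corr[self.vox_arr[live], vox]
            self.c_arr[live] += cv
            self.m_arr[live] = np.minimum(self.m_arr[live], cv)
        # new candidates: unassigned masked neighbors of the voxel
        for u in self.neighbors[vox]:
            if self.label[u] == 0:
                self.add_entry(roi, int(u))


def greedy_grow(
    volume: VoxelVolume,
    seeds: dict[int, tuple[int, int, int]],
    config: GreedyConfig | None = None,
) -> Parcellation:
    """Grow ROIs from seeds by repeatedly assigning the best-priority
    ROI-voxel pair.

    A priority queue holds every pair of an ROI and one of its unassigned
    face-neighbor voxels.  Each iteration pops the maximal-priority pair
    (ties broken by ascending ROI label, then voxel index); if the
    acceptance threshold passes, the voxel joins the ROI and the queue is
    updated.  The loop ends when every queued candidate has been assigned
    or rejected; rejected voxels may remain unassigned.  ROIs are
    6-connected by construction.
    """
    config = config or GreedyConfig()
    if not seeds:
        raise ValueError("seed set must be non-empty")
    coords = volume.masked_coords()
    n_vox = coords.shape[0]
    coord_to_idx = {tuple(c): i for i, c in enumerate(coords)}
    for lab, v in seeds.items():
        if tuple(v) not in coord_to_idx:
            raise ValueError(f"seed {v} for ROI {lab} is outside the mask")
    if len({tuple(v) for v in seeds.values()}) != len(seeds):
        raise ValueError("seed voxels must be pairwise distinct")

    series = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    corr = pearson_matrix(series)

    # masked-neighbor adjacency in linear-index space
    neighbors: list[np.ndarray] = []
    shape = volume.spatial_shape
    for c in coords:
        nbr = []
        for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            p = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and 0 <= p[2] < shape[2]:
                j = coord_to_idx.get(p)
                if j is not None:
                    nbr.append(j)
        neighbors.append(np.asarray(nbr, dtype=np.int64))

    state = _GreedyState(corr, neighbors, n_vox)
    total_assigned = 0
    sum_contrib = 0.0  # sum over ROIs of |I| * phi(I), phi(singleton) := 1
    sum_squares = 0
    contrib: dict[int, float] = {}
    for lab in sorted(seeds):
        i = coord_to_idx[tuple(seeds[lab])]
        state.label[i] = lab
        state.members[lab] = [i]
        state.pair_sum[lab] = 0.0
        contrib[lab] = 1.0
        sum_contrib += 1.0
        sum_squares += 1
        total_assigned += 1
    sizes = {lab: 1 for lab in sorted(seeds)}
    for lab in sorted(seeds):
        for u in neighbors[state.members[lab][0]]:
            if state.label[u] == 0:
                state.add_entry(lab, int(u))

    wmc = config.priority_kind is PriorityKind.WEIGHTED_MEAN_CONSISTENCY
    while True:
        live = np.flatnonzero(state.alive[: state.n])
        if live.size == 0:
            break
        rois = state.roi_arr[live]
        voxs = state.vox_arr[live]
        csum = state.c_arr[live]
        size_v = np.asarray([sizes[r] for r in rois], dtype=float)
        mean_corr = csum / size_v
        if wmc:
            new_size = size_v + 1
            new_contrib = 2.0 * (np.asarray([state.pair_sum[r] for r in rois]) + csum) / (
                new_size - 1.0
            )
            old_contrib = np.asarray([contrib[r] for r in rois])
            tot = float(total_assigned)
            prio = (sum_contrib - old_contrib + new_contrib) / (tot + 1.0) - (
                config.lambda_reg
                * (sum_squares - size_v**2 + new_size**2)
                / (tot + 1.0) ** 2
            )
        else:
            prio = state.m_arr[live]
        best = prio.max()
        ties = np.flatnonzero(prio == best)
        if ties.size > 1:
            order = np.lexsort((voxs[ties], rois[ties]))
            pick = ties[order[0]]
        else:
            pick = ties[0]
        entry = live[pick]
        roi = int(state.roi_arr[entry])
        vox = int(state.vox_arr[entry])
        if config.apply_threshold and config.threshold_percent < 100.0:
            if not threshold_accept(
                float(mean_corr[pick]), mean_corr, config.threshold_percent
            ):
                state.alive[entry] = False
                continue
        new_c = 2.0 * (state.pair_sum[roi] + state.c_arr[entry]) / sizes[roi]
        sum_contrib += new_c - contrib[roi]
        contrib[roi] = new_c
        sum_squares += 2 * sizes[roi] + 1
        sizes[roi] += 1
        total_assigned += 1
        state.assign(roi, vox)

    label_volume = np.zeros(shape, dtype=np.int32)
    assigned = state.label > 0
    label_volume[coords[assigned, 0], coords[assigned, 1], coords[assigned, 2]] = (
        state.label[assigned]
    )
    return Parcellation(
        label_volume,
        method_tag=f"greedy_{config.priority_kind.value}",
        seeds={lab: tuple(int(x) for x in seeds[lab]) for lab in seeds},
    )


# ---------------------------------------------------------------------------
# NCUT spectral clustering


def voxel_correlation_graph(
    volume: VoxelVolume, edge_threshold: float = 0.2
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Thresholded 6-neighbor voxel correlation graph.

    Nodes are the masked voxels (rows of the returned coordinate array, in
    C order); an edge connects face-sharing voxels whose series correlate
    at or above ``edge_threshold``.  Surviving negative weights (possible
    only for a negative threshold) are clamped to 0, as the NCUT cost
    assumes nonnegative weights.  Raises when no positive-weight edge
    survives.
    """
    coords = volume.masked_coords()
    n_vox = coords.shape[0]
    series = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    corr = pearson_matrix(series)
    coord_to_idx = {tuple(c): i for i, c in enumerate(coords)}
    shape = volume.spatial_shape
    rows, cols, vals = [], [], []
    for i, c in enumerate(coords):
        for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            p = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if p[0] < shape[0] and p[1] < shape[1] and p[2] < shape[2]:
                j = coord_to_idx.get(p)
                if j is None:
                    continue
                w = corr[i, j]
                if w < edge_threshold:
                    continue
                rows.append(i)
                cols.append(j)
                vals.append(max(w, 0.0))
    if not vals or not any(v > 0 for v in vals):
        raise ValueError("degenerate graph: no edges survive the threshold")
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(n_vox, n_vox))
    return (W + W.T).tocsr(), coords


def ncut_cost(adjacency: np.ndarray, set_a, set_b) -> float:
    """Normalized-cut cost of a bipartition of a weighted graph.

    NCUT(A, B) = CUT(A, B) / assoc(A, V) + CUT(A, B) / assoc(B, V), where
    CUT is the total weight of edges between the two sides and assoc the
    total connection weight of a side to the whole graph.
    """
    W = np.asarray(adjacency, dtype=float)
    a = np.asarray(sorted(set_a), dtype=int)
    b = np.asarray(sorted(set_b), dtype=int)
    cut = W[np.ix_(a, b)].sum()
    deg = W.sum(axis=1)
    assoc_a = deg[a].sum()
    assoc_b = deg[b].sum()
    if assoc_a == 0 or assoc_b == 0:
        return np.inf
    return float(cut / assoc_a + cut / assoc_b)


def ncut_bisect(W: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Two-way NCUT spectral bisection: second-smallest generalized
    eigenvector of (D - W) v = lambda D v, followed by a sweep over the
    sorted-vector splits minimizing the NCUT cost.  Returns None when the
    graph cannot be split (no positive edges)."""
    n = W.shape[0]
    if n < 2:
        return None
    deg = W.sum(axis=1)
    if (deg <= 0).any() or W.sum() == 0:
        # zero-degree nodes split off trivially
        idx = np.flatnonzero(deg <= 0)
        if 0 < idx.size < n:
            rest = np.setdiff1d(np.arange(n), idx[:1])
            return idx[:1], rest
        return None
    D = np.diag(deg)
    L = D - W
    vals, vecs = eigh(L, D)
    fiedler = vecs[:, 1]
    order = np.argsort(fiedler, kind="stable")
    Ws = W[np.ix_(order, order)]
    deg_s = deg[order]
    vol = deg.sum()
    best_cost = np.inf
    best_k = None
    vol_a = 0.0
    assoc_aa = 0.0
    for k in range(n - 1):
        vol_a += deg_s[k]
        assoc_aa += 2.0 * Ws[k, :k].sum() + Ws[k, k]
        cut = vol_a - assoc_aa
        vol_b = vol - vol_a
        if vol_a <= 0 or vol_b <= 0:
            continue
        cost = cut / vol_a + cut / vol_b
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_k = k
    if best_k is None:
        return None
    return order[: best_k + 1], order[best_k + 1 :]


def craddock_cluster(
    volume: VoxelVolume, config: CraddockConfig | None = None
) -> Parcellation:
    """NCUT spectral clustering of the thresholded voxel correlation graph.

    Each masked voxel connects to its 6-neighbors with Pearson-correlation
    weight; edges below ``edge_threshold`` are removed (and, for a
    negative threshold, surviving negative weights are clamped to 0, as
    the NCUT cost requires nonnegative weights).  Post-threshold connected
    components are clusters; the largest cluster is repeatedly bisected by
    the normalized cut until the target count is reached or nothing
    remains splittable — which is why the method can return fewer clusters
    than requested.
    """
    config = config or CraddockConfig()
    coords = volume.masked_coords()
    n_vox = coords.shape[0]
    if n_vox < config.target_clusters:
        raise ValueError(
            f"{n_vox} masked voxels cannot form {config.target_clusters} clusters"
        )
    W, coords = voxel_correlation_graph(volume, config.edge_threshold)
    shape = volume.spatial_shape

    n_comp, comp = connected_components(W, directed=False)
    clusters: list[np.ndarray] = [np.flatnonzero(comp == k) for k in range(n_comp)]
    splittable = [True] * len(clusters)
    while len(clusters) < config.target_clusters:
        candidates = [
            (len(clusters[i]), i) for i in range(len(clusters)) if splittable[i]
        ]
        if not candidates:
            break
        _, idx = max(candidates, key=lambda t: (t[0], -t[1]))
        nodes = clusters[idx]
        if len(nodes) < 2:
            splittable[idx] = False
            continue
        sub = W[np.ix_(nodes, nodes)].toarray()
        split = ncut_bisect(sub)
        if split is None:
            splittable[idx] = False
            continue
        a, b = split
        clusters[idx] = nodes[a]
        clusters.append(nodes[b])
        splittable.append(True)

    label_volume = np.zeros(shape, dtype=np.int32)
    # deterministic labeling: order clusters by their smallest voxel index
    clusters.sort(key=lambda nodes: int(nodes.min()))
    for lab, nodes in enumerate(clusters, start=1):
        label_volume[coords[nodes, 0], coords[nodes, 1], coords[nodes, 2]] = lab
    return Parcellation(label_volume, method_tag="craddock")


# ---------------------------------------------------------------------------
# post-processing and baselines


def exclude_single_voxel_rois(
    parcellation: Parcellation,
) -> tuple[Parcellation, int]:
    """Remove size-1 ROIs (set to unassigned) and report how many there were."""
    sizes = parcellation.roi_sizes()
    singles = [lab for lab, s in sizes.items() if s == 1]
    out = parcellation.copy()
    if singles:
        out.label_volume[np.isin(out.label_volume, singles)] = 0
        if out.seeds is not None:
            out.seeds = {k: v for k, v in out.seeds.items() if k not in singles}
    return out, len(singles)


def filter_static_parcellation(
    volume: VoxelVolume, atlas: Parcellation, voxel_budget: int
) -> Parcellation:
    """Most-consistent atlas ROIs under a voxel budget.

    Ranks the atlas ROIs by spatial consistency in this window (descending)
    and keeps the longest top-ranked prefix whose cumulative voxel count
    stays within the budget.  Single-voxel ROIs are excluded first (their
    consistency is undefined).
    """
    atlas, _ = exclude_single_voxel_rois(atlas)
    sizes = atlas.roi_sizes()
    ranked = sorted(
        ((spatial_consistency(volume, atlas.voxels(lab)), lab) for lab in sizes),
        key=lambda t: (-t[0], t[1]),
    )
    kept: list[int] = []
    used = 0
    for phi, lab in ranked:
        if used + sizes[lab] > voxel_budget:
            break
        kept.append(lab)
        used += sizes[lab]
    if not kept:
        logger.warning("voxel budget %d fits no atlas ROI; empty result", voxel_budget)
    out = atlas.copy()
    out.label_volume[~np.isin(out.label_volume, kept)] = 0
    out.method_tag = "filtered_static"
    return out
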