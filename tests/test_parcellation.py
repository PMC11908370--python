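"""ROI-definition tests: greedy grower vs a textbook priority-queue oracle,
NCUT bisection vs exhaustive enumeration, thresholding, and baselines."""

import itertools

import numpy as np
import pytest

from reconparc import (
    CraddockConfig,
    GreedyConfig,
    Parcellation,
    craddock_cluster,
    exclude_single_voxel_rois,
    filter_static_parcellation,
    greedy_grow,
    jaccard,
    ncut_cost,
    select_reho_seeds,
    spatial_consistency,
    threshold_accept,
)
from reconparc.metrics import regional_homogeneity
from reconparc.parcellation import (
    ncut_bisect,
    priority_min_correlation,
    priority_weighted_mean_consistency,
    voxel_correlation_graph,
)
from reconparc.synthetic import grow_parcellation_rounds

from conftest import make_volume


# ---------------------------------------------------------------------------
# seeds


class TestRehoSeeds:
    def _volume_and_atlas(self, rng):
        vol = make_volume(rng.standard_normal((4, 4, 2, 20)))
        labels = grow_parcellation_rounds(vol.mask, {1: (0, 0, 0), 2: (3, 3, 1)})
        return vol, Parcellation(labels)

    def test_one_seed_per_roi(self, rng):
        vol, atlas = self._volume_and_atlas(rng)
        seeds = select_reho_seeds(vol, atlas)
        assert set(seeds) == {1, 2}

    def test_seed_maximizes_reho_within_roi(self, rng):
        vol, atlas = self._volume_and_atlas(rng)
        seeds = select_reho_seeds(vol, atlas)
        for lab, seed in seeds.items():
            rehos = {v: regional_homogeneity(vol, v) for v in atlas.voxels(lab)}
            assert rehos[seed] == max(rehos.values())

    def test_invariant_to_relabeling(self, rng):
        vol, atlas = self._volume_and_atlas(rng)
        relabeled = Parcellation(
            np.where(atlas.label_volume == 1, 7, np.where(atlas.label_volume == 2, 3, 0))
        )
        a = set(select_reho_seeds(vol, atlas).values())
        b = set(select_reho_seeds(vol, relabeled).values())
        assert a == b


# ---------------------------------------------------------------------------
# greedy growing: textbook-queue oracle


def oracle_greedy(volume, seeds, kind, lam):
    """Straightforward priority-queue implementation used as an oracle:
    recompute every queued pair's priority from the global definitions at
    each step, pop the max (ties: lowest ROI label, then voxel index)."""
    coords = [tuple(c) for c in volume.masked_coords()]
    vox_index = {v: i for i, v in enumerate(coords)}

    def neighbors(v):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            p = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if p in vox_index:
                yield p

    members = {lab: [tuple(v)] for lab, v in seeds.items()}
    assigned = {tuple(v): lab for lab, v in seeds.items()}
    queue = {
        (lab, p)
        for lab in members
        for p in neighbors(members[lab][0])
        if p not in assigned
    }
    dead = set()
    while queue:
        scored = []
        for roi, vox in queue:
            if kind == "min_correlation":
                pv = priority_min_correlation(volume, members[roi], vox)
            else:
                sizes = {r: len(m) for r, m in members.items()}
                cons = {
                    r: spatial_consistency(volume, m)
                    for r, m in members.items()
                    if len(m) >= 2
                }
                cand_phi = spatial_consistency(volume, members[roi] + [vox])
                pv = priority_weighted_mean_consistency(sizes, cons, roi, cand_phi, lam)
            scored.append((pv, roi, vox_index[vox], vox))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, roi, _, vox = scored[0]
        members[roi].append(vox)
        assigned[vox] = roi
        queue = {(r, v) for (r, v) in queue if v != vox}
        for p in neighbors(vox):
            if p not in assigned and (roi, p) not in dead:
                queue.add((roi, p))
    labels = np.zeros(volume.spatial_shape, dtype=np.int32)
    for v, lab in assigned.items():
        labels[v] = lab
    return labels


@pytest.mark.parametrize(
    "kind,lam",
    [
        ("weighted_mean_consistency", 0.0),
        ("weighted_mean_consistency", 100.0),
        ("min_correlation", 0.0),  # lambda does not enter this priority
    ],
)
def test_greedy_matches_textbook_queue_oracle(kind, lam, rng):
    vol = make_volume(rng.standard_normal((3, 3, 2, 30)))
    seeds = {1: (0, 0, 0), 2: (2, 2, 1)}
    got = greedy_grow(
        vol, seeds, GreedyConfig(priority_kind=kind, lambda_reg=lam, apply_threshold=False)
    )
    expected = oracle_greedy(vol, seeds, kind, lam)
    assert np.array_equal(got.label_volume, expected)


class TestGreedyGrow:
    def test_uniform_series_assigns_everything(self):
        data = np.zeros((4, 3, 1, 10))
        data[..., :] = np.sin(np.arange(10))
        vol = make_volume(data)
        parc = greedy_grow(
            vol, {1: (0, 0, 0), 2: (3, 2, 0)}, GreedyConfig(apply_threshold=False)
        )
        assert (parc.label_volume > 0).all()
        assert parc.n_rois == 2

    def test_planted_blocks_recovered_exactly(self, rng):
        # two internally identical, mutually orthogonal blocks
        t = rng.standard_normal(40)
        u = rng.standard_normal(40)
        u -= u @ t / (t @ t) * t  # orthogonalize: zero correlation by construction
        data = np.zeros((4, 2, 1, 40))
        data[:2, :, 0, :] = t - t.mean()
        data[2:, :, 0, :] = u - u.mean()
        vol = make_volume(data)
        parc = greedy_grow(
            vol, {1: (0, 0, 0), 2: (3, 1, 0)}, GreedyConfig(apply_threshold=False)
        )
        block1 = {(i, j, 0) for i in range(2) for j in range(2)}
        block2 = {(i, j, 0) for i in range(2, 4) for j in range(2)}
        assert jaccard(parc.voxel_set(1), block1) == 1.0
        assert jaccard(parc.voxel_set(2), block2) == 1.0

    def test_rois_are_connected_and_deterministic(self, planted_dataset):
        vol, parcels = planted_dataset
        win = vol.crop_time(0, 80)
        cfg = GreedyConfig(priority_kind="min_correlation", apply_threshold=False)
        a = greedy_grow(win, parcels[0].seeds, cfg)
        b = greedy_grow(win, parcels[0].seeds, cfg)
        assert np.array_equal(a.label_volume, b.label_volume)
        for lab in a.labels():
            assert a.is_connected(lab)
        assert (a.label_volume > 0).sum() == vol.n_masked

    def test_thresholding_can_leave_voxels_unassigned(self):
        # unit-amplitude private noise: poorly fitting voxels get rejected
        from reconparc import SyntheticConfig, generate_reconfiguring_dataset

        cfg = SyntheticConfig(
            grid_shape=(8, 8, 4), n_rois=6, n_timepoints=160, n_windows=2,
            noise_amplitude=1.0, noise_seed=7,
        )
        vol, parcels = generate_reconfiguring_dataset(cfg)
        win = vol.crop_time(0, 80)
        parc = greedy_grow(
            win,
            parcels[0].seeds,
            GreedyConfig(priority_kind="min_correlation", threshold_percent=30.0),
        )
        assert (parc.label_volume > 0).sum() < vol.n_masked
        for lab in parc.labels():
            assert parc.is_connected(lab)

    def test_empty_seed_set_rejected(self, rng):
        vol = make_volume(rng.standard_normal((2, 2, 1, 10)))
        with pytest.raises(ValueError, match="seed"):
            greedy_grow(vol, {})


class TestPriorities:
    def test_wmc_collapses_to_consistency_without_regularization(self):
        pv = priority_weighted_mean_consistency({1: 3}, {1: 0.5}, 1, 0.42, 0.0)
        assert pv == pytest.approx(0.42)

    def test_wmc_hand_evaluation_two_rois(self):
        # sizes 2 and 2, consistencies 0.8 and 0.5, candidate joins ROI 1
        # with hypothetical consistency 0.7, lambda = 100:
        # term1 = (3*0.7 + 2*0.5)/5 = 0.62; term2 = 100*(9+4)/25 = 52
        pv = priority_weighted_mean_consistency(
            {1: 2, 2: 2}, {1: 0.8, 2: 0.5}, 1, 0.7, 100.0
        )
        assert pv == pytest.approx(0.62 - 52.0)

    def test_min_correlation_identical_singleton(self):
        data = np.zeros((2, 1, 1, 12))
        data[:, 0, 0, :] = np.arange(12.0)
        vol = make_volume(data)
        assert priority_min_correlation(vol, [(0, 0, 0)], (1, 0, 0)) == pytest.approx(1.0)

    def test_min_correlation_picks_lowest_via_cholesky(self, rng):
        # construct three series with corr(c,a)=0.9, corr(c,b)=0.2
        target = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.3], [0.2, 0.3, 1.0]])
        L = np.linalg.cholesky(target)
        z = rng.standard_normal((3, 20000))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        series = L @ z
        data = series.reshape(3, 1, 1, -1)
        vol = make_volume(data)
        pv = priority_min_correlation(vol, [(1, 0, 0), (2, 0, 0)], (0, 0, 0))
        assert pv == pytest.approx(0.2, abs=0.05)

    def test_min_correlation_monotone_in_roi_growth(self, rng):
        vol = make_volume(rng.standard_normal((4, 1, 1, 50)))
        small = priority_min_correlation(vol, [(1, 0, 0)], (0, 0, 0))
        large = priority_min_correlation(vol, [(1, 0, 0), (2, 0, 0), (3, 0, 0)], (0, 0, 0))
        assert large <= small


class TestThresholdAccept:
    def test_n_100_always_accepts(self):
        assert threshold_accept(-0.99, [0.1, 0.5, 0.9], 100.0)

    def test_percentile_by_enumeration(self):
        ref = [round(0.1 * k, 1) for k in range(1, 11)]  # 0.1 .. 1.0
        for value in ref:
            assert threshold_accept(value, ref, 30.0) == (value >= 0.8)

    def test_below_reference_minimum_rejected(self):
        ref = [0.3, 0.5, 0.7]
        assert not threshold_accept(0.1, ref, 99.0)

    def test_invalid_percent(self):
        with pytest.raises(ValueError):
            threshold_accept(0.5, [0.1], 0.0)
        with pytest.raises(ValueError):
            threshold_accept(0.5, [0.1], 101.0)


# ---------------------------------------------------------------------------
# NCUT


def brute_force_best_ncut(W):
    """Enumerate all bipartitions and return the minimum NCUT cost."""
    n = W.shape[0]
    best = np.inf
    for r in range(1, n // 2 + 1):
        for a in itertools.combinations(range(n), r):
            b = [i for i in range(n) if i not in a]
            best = min(best, ncut_cost(W, a, b))
    return best


class TestNcut:
    def _two_triangle_graph(self):
        # two strongly connected triangles joined by one weak bridge
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            W[i, j] = W[j, i] = 1.0
        W[2, 3] = W[3, 2] = 0.1
        return W

    def test_bisection_matches_exhaustive_minimum(self):
        W = self._two_triangle_graph()
        a, b = ncut_bisect(W)
        assert ncut_cost(W, a, b) == pytest.approx(brute_force_best_ncut(W), abs=1e-12)
        assert {frozenset(a.tolist()), frozenset(b.tolist())} == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        }

    def test_bisection_matches_exhaustive_on_random_graphs(self, rng):
        # small random weighted graphs where the sweep should find the optimum
        for _ in range(5):
            n = 7
            W = rng.uniform(0.0, 1.0, (n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            W[W < 0.4] = 0.0  # sparsify
            if W.sum() == 0:
                continue
            a, b = ncut_bisect(W)
            got = ncut_cost(W, a, b)
            best = brute_force_best_ncut(W)
            # spectral sweep is a relaxation: allow it to be near-optimal
            assert got <= best * 1.5 + 1e-9

    def test_cost_of_zero_cut_is_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        assert ncut_cost(W, [0, 1], [2, 3]) == 0.0


class TestCraddock:
    def _two_block_volume(self, rng):
        # two internally identical, mutually orthogonal 2x2x1 blocks
        t = rng.standard_normal(60)
        u = rng.standard_normal(60)
        u -= u @ t / (t @ t) * t
        data = np.zeros((4, 2, 1, 60))
        data[:2, :, 0, :] = t - t.mean()
        data[2:, :, 0, :] = u - u.mean()
        return make_volume(data)

    def test_disconnected_cliques_recovered_with_zero_cut(self, rng):
        vol = self._two_block_volume(rng)
        parc = craddock_cluster(vol, CraddockConfig(edge_threshold=0.2, target_clusters=2))
        sets = [parc.voxel_set(lab) for lab in parc.labels()]
        block1 = frozenset((i, j, 0) for i in range(2) for j in range(2))
        block2 = frozenset((i, j, 0) for i in range(2, 4) for j in range(2))
        assert set(sets) == {block1, block2}

    def test_threshold_removes_exactly_subthreshold_edges(self):
        # chain 0-1-2-3 with neighbor correlations +1, -1, +1
        base = np.array([1.0, -2.0, 3.0, -1.0, 2.0])
        data = np.zeros((4, 1, 1, 5))
        data[0, 0, 0] = base
        data[1, 0, 0] = 2 * base
        data[2, 0, 0] = -base
        data[3, 0, 0] = -3 * base
        vol = make_volume(data)
        W, _ = voxel_correlation_graph(vol, edge_threshold=0.2)
        assert W.nnz // 2 == 2  # the two +1 edges survive, the -1 edge is cut
        assert np.allclose(W.toarray()[0, 1], 1.0)
        assert W.toarray()[1, 2] == 0.0

    def test_partitions_mask_and_is_deterministic(self, planted_dataset):
        vol, _ = planted_dataset
        win = vol.crop_time(0, 80)
        cfg = CraddockConfig(edge_threshold=0.2, target_clusters=6)
        parc = craddock_cluster(win, cfg)
        # every masked voxel ends up in exactly one cluster
        assert (parc.label_volume > 0).sum() == vol.n_masked
        assert parc.n_rois >= 6  # bisection continues until the target
        again = craddock_cluster(win, cfg)
        assert np.array_equal(parc.label_volume, again.label_volume)

    def test_improves_consistency_over_shuffled_labels(self, planted_dataset, rng):
        vol, _ = planted_dataset
        win = vol.crop_time(0, 80)
        parc = craddock_cluster(win, CraddockConfig(edge_threshold=0.2, target_clusters=6))
        parc, _ = exclude_single_voxel_rois(parc)
        mean_phi = np.mean(
            [spatial_consistency(win, parc.voxels(lab)) for lab in parc.labels()]
        )
        shuffled = parc.copy()
        coords = np.argwhere(shuffled.label_volume > 0)
        vals = shuffled.label_volume[tuple(coords.T)]
        shuffled.label_volume[tuple(coords.T)] = rng.permutation(vals)
        shuf_phi = np.mean(
            [
                spatial_consistency(win, shuffled.voxels(lab))
                for lab in shuffled.labels()
                if len(shuffled.voxels(lab)) >= 2
            ]
        )
        assert mean_phi > shuf_phi

    def test_too_few_voxels_rejected(self, rng):
        vol = make_volume(rng.standard_normal((2, 1, 1, 10)))
        with pytest.raises(ValueError, match="cluster"):
            craddock_cluster(vol, CraddockConfig(target_clusters=5))

    def test_degenerate_graph_rejected(self, rng):
        vol = make_volume(rng.standard_normal((3, 1, 1, 10)))
        with pytest.raises(ValueError, match="degenerate"):
            voxel_correlation_graph(vol, edge_threshold=1.0)


# ---------------------------------------------------------------------------
# post-processing


class TestExcludeSingleVoxelRois:
    def test_identity_when_no_singletons(self):
        labels = np.array([[[1, 1], [2, 2]]])
        parc, n = exclude_single_voxel_rois(Parcellation(labels))
        assert n == 0
        assert np.array_equal(parc.label_volume, labels)

    def test_all_singletons_empty_result(self):
        labels = np.array([[[1, 2], [3, 4]]])
        parc, n = exclude_single_voxel_rois(Parcellation(labels))
        assert n == 4
        assert parc.n_rois == 0

    def test_mixed_keeps_only_multivoxel(self):
        labels = np.array([[[1, 1], [2, 3]]])
        parc, n = exclude_single_voxel_rois(Parcellation(labels))
        assert n == 2
        assert parc.labels() == [1]


class TestFilterStaticParcellation:
    def _volume_with_ranked_rois(self, rng):
        # ROI 1: identical series (phi = 1); ROI 2: correlated; ROI 3: independent
        data = np.zeros((15, 1, 1, 60))
        base = rng.standard_normal(60)
        for i in range(5):
            data[i, 0, 0] = base
        for i in range(5, 10):
            data[i, 0, 0] = base + 0.8 * rng.standard_normal(60)
        for i in range(10, 15):
            data[i, 0, 0] = rng.standard_normal(60)
        labels = np.zeros((15, 1, 1), dtype=int)
        labels[:5] = 1
        labels[5:10] = 2
        labels[10:] = 3
        return make_volume(data), Parcellation(labels)

    def test_unconstrained_budget_keeps_whole_atlas(self, rng):
        vol, atlas = self._volume_with_ranked_rois(rng)
        out = filter_static_parcellation(vol, atlas, voxel_budget=15)
        assert out.labels() == [1, 2, 3]

    def test_greedy_rank_fill(self, rng):
        vol, atlas = self._volume_with_ranked_rois(rng)
        out = filter_static_parcellation(vol, atlas, voxel_budget=10)
        assert out.labels() == [1, 2]

    def test_retained_mean_consistency_not_below_atlas_mean(self, rng):
        vol, atlas = self._volume_with_ranked_rois(rng)
        out = filter_static_parcellation(vol, atlas, voxel_budget=10)
        phi = lambda p: np.mean(
            [spatial_consistency(vol, p.voxels(lab)) for lab in p.labels()]
        )
        assert phi(out) >= phi(atlas)

    def test_budget_below_smallest_roi_gives_empty(self, rng):
        vol, atlas = self._volume_with_ranked_rois(rng)
        out = filter_static_parcellation(vol, atlas, voxel_budget=3)
        assert out.n_rois == 0
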