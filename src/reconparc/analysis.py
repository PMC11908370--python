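"""Stability and interaction analytics on a multilayer network.

The *stability score* of an ROI is the weight of its heaviest interlayer
edge to the next layer: 1 for an ROI that persists unchanged, 0 for one
whose voxels disperse entirely.  A *trajectory* extends this beyond the
next layer: the best Jaccard overlap of a reference ROI against every
later layer, which can reveal ROIs that shatter and later return to their
original configuration.  The intra-/interlayer interaction analyses
(mean intralayer correlation and ROI edge weight versus stability,
reported as 0.1-wide binned curves) probe whether the best-connected ROIs
are the stable or the reconfiguring ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Parcellation, VoxelVolume
from .metrics import spatial_consistency
from .multilayer import MultilayerNetwork, Window, jaccard

__all__ = [
    "Trajectory",
    "BinnedCurve",
    "CarryoverResult",
    "stability_score",
    "all_stability_scores",
    "trajectory",
    "pairwise_stability",
    "mean_intralayer_correlation",
    "binned_curve",
    "interlayer_weight_cdf",
    "stability_score_cdf",
    "empirical_cdf",
    "consistency_carryover",
]


@dataclass
class Trajectory:
    """Best-overlap series of one reference ROI against later layers.

    ``values[k]`` is the maximum Jaccard index of the reference voxel set
    against all ROIs ``k + 1`` layers later; each value lies in [0, 1].
    """

    reference: tuple[int, int]
    values: np.ndarray


@dataclass
class BinnedCurve:
    """x-binned means of a y-quantity on [0, 1].

    Bin convention: first bin is the closed interval [0, 0.1], subsequent
    bins are half-open (0.1, 0.2], (0.2, 0.3], ...  Means are NaN for
    empty bins.
    """

    bin_edges: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mean": self.bin_means,
                "count": self.bin_counts,
            }
        )


@dataclass
class CarryoverResult:
    """Per-ROI spatial consistencies under window-t boundaries in windows
    t and t+1, with summary changes (negative mean change = consistency
    was higher in the window the ROIs were defined in)."""

    per_roi: dict[int, tuple[float, float]]
    mean_change: float
    mean_relative_change: float


def stability_score(network: MultilayerNetwork, node: tuple[int, int]) -> float:
    """Maximum interlayer edge weight from the node to the next layer.

    0 when no interlayer edge exists (the ROI disappears completely);
    1 iff an identical ROI exists on the next layer.  Undefined for
    last-layer nodes.
    """
    layer, label = node
    if node not in network.nodes:
        raise KeyError(f"no node {node} in the network")
    if layer >= network.n_layers - 1:
        raise ValueError("stability score is undefined for last-layer nodes")
    edges = network.out_edges(layer, label)
    return max(edges.values()) if edges else 0.0


def all_stability_scores(network: MultilayerNetwork) -> dict[tuple[int, int], float]:
    """Stability scores of every node not on the final layer."""
    return {
        node: stability_score(network, node)
        for node in sorted(network.nodes)
        if node[0] < network.n_layers - 1
    }


def trajectory(
    source: MultilayerNetwork | list[Parcellation],
    node: tuple[int, int],
    min_size: int = 5,
) -> Trajectory:
    """Best Jaccard overlap of a reference ROI against each later layer.

    Works from the network's stored voxel sets or directly from a
    parcellation sequence.  ROIs smaller than ``min_size`` voxels
    (default 5) are refused — tiny ROIs produce noisy overlap series.
    A reference on the last layer yields an empty trajectory.
    """
    layer, label = node
    if isinstance(source, MultilayerNetwork):
        voxel_sets = [
            {lab: source.nodes[(l, lab)] for lab in source.layer_labels(l)}
            for l in range(source.n_layers)
        ]
    else:
        voxel_sets = [
            {lab: p.voxel_set(lab) for lab in p.labels()} for p in source
        ]
    if layer >= len(voxel_sets) or label not in voxel_sets[layer]:
        raise KeyError(f"no ROI {label} on layer {layer}")
    ref = voxel_sets[layer][label]
    if len(ref) < min_size:
        raise ValueError(
            f"reference ROI has {len(ref)} voxels; minimum is {min_size}"
        )
    values = [
        max((jaccard(ref, s) for s in voxel_sets[later].values()), default=0.0)
        for later in range(layer + 1, len(voxel_sets))
    ]
    return Trajectory(reference=node, values=np.asarray(values, dtype=float))


def pairwise_stability(
    network: MultilayerNetwork, node_a: tuple[int, int], node_b: tuple[int, int]
) -> float:
    """Mean of the stability scores of two same-layer ROIs."""
    if node_a[0] != node_b[0]:
        raise ValueError("pairwise stability is defined for same-layer nodes")
    return 0.5 * (stability_score(network, node_a) + stability_score(network, node_b))


def mean_intralayer_correlation(
    network: MultilayerNetwork, node: tuple[int, int]
) -> float:
    """Mean intralayer edge weight of the node within its layer."""
    layer, label = node
    if node not in network.nodes:
        raise KeyError(f"no node {node} in the network")
    others = [lab for lab in network.layer_labels(layer) if lab != label]
    if not others:
        raise ValueError("mean intralayer correlation is undefined on a singleton layer")
    return float(
        np.mean([network.intralayer_weight(layer, label, o) for o in others])
    )


def binned_curve(x_values, y_values, bin_width: float = 0.1) -> BinnedCurve:
    """Bin y by x over [0, 1] with a closed first bin.

    The first bin is [0, 0.1]; each later bin is half-open on the left,
    (0.1, 0.2], (0.2, 0.3], ...  so x = 0.1 falls in the first bin and
    x = 0.1001 in the second.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(bin_width * np.arange(n_bins + 1), 1.0)
    # right-closed bins; values exactly at 0 belong to the first bin.
    # The tiny slack keeps values sitting exactly on an edge (e.g. 0.2,
    # whose float ratio 0.2/0.1 exceeds 2) in their closed-right bin.
    idx = np.ceil(x / bin_width - 1e-12).astype(int) - 1
    idx[x <= 0] = 0
    idx = np.clip(idx, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(y[sel].mean())
    return BinnedCurve(edges, means, counts)


def empirical_cdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and their empirical CDF heights i/n."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return v, v
    return v, np.arange(1, v.size + 1) / v.size


def interlayer_weight_cdf(network: MultilayerNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF over all interlayer edge weights, pooled across layers."""
    weights = list(network.interlayer.values())
    if not weights:
        raise ValueError("network has no interlayer edges")
    return empirical_cdf(weights)


def stability_score_cdf(network: MultilayerNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF over the stability scores of all non-final-layer nodes."""
    scores = list(all_stability_scores(network).values())
    if not scores:
        raise ValueError("network has no scorable nodes")
    return empirical_cdf(scores)


def consistency_carryover(
    volume: VoxelVolume,
    parc_t: Parcellation,
    window_t: Window,
    window_t1: Window,
) -> CarryoverResult:
    """Spatial consistency of window-t ROIs evaluated in windows t and t+1.

    Applies the *same* ROI boundaries (those found in window t) to both
    windows' data.  A negative mean change means consistency was higher in
    the window the ROIs were optimized on; the relative change is the mean
    change divided by the mean window-t consistency.  Single-voxel ROIs
    are excluded.
    """
    if not (window_t.stop <= window_t1.start or window_t1.stop <= window_t.start):
        raise ValueError("windows must not overlap")
    sizes = parc_t.roi_sizes()
    labels = [lab for lab, s in sizes.items() if s >= 2]
    if not labels:
        raise ValueError("parcellation has no multi-voxel ROIs")
    vol_t = volume.crop_time(window_t.start, window_t.stop)
    vol_t1 = volume.crop_time(window_t1.start, window_t1.stop)
    per_roi: dict[int, tuple[float, float]] = {}
    for lab in labels:
        voxels = parc_t.voxels(lab)
        per_roi[lab] = (
            spatial_consistency(vol_t, voxels),
            spatial_consistency(vol_t1, voxels),
        )
    phi_t = np.asarray([v[0] for v in per_roi.values()])
    phi_t1 = np.asarray([v[1] for v in per_roi.values()])
    mean_change = float((phi_t1 - phi_t).mean())
    mean_phi_t = float(phi_t.mean())
    rel = mean_change / mean_phi_t if mean_phi_t != 0 else np.nan
    return CarryoverResult(per_roi, mean_change, float(rel))
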