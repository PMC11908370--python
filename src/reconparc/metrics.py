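"""Functional-homogeneity and concordance metrics.

Spatial consistency phi(I) of an ROI is the mean Pearson correlation over
all distinct voxel pairs inside it — the quantity the window-wise ROI
optimization maximizes.  Regional homogeneity (ReHo) is Kendall's
coefficient of concordance W of a voxel's time series with those of its
face-sharing neighbors (K = 7 for a full interior neighborhood).  The
within-/between-ROI correlation distributions and their excess area
quantify how much better than chance a parcellation groups correlated
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import Parcellation, VoxelVolume, face_neighbors, pearson_matrix

__all__ = [
    "ConsistencyReport",
    "spatial_consistency",
    "regional_homogeneity",
    "correlation_distributions",
    "excess_area",
]


@dataclass
class ConsistencyReport:
    """Per-ROI consistency plus pooled voxel-pair correlation distributions."""

    per_roi_consistency: dict[int, float]
    within_distribution: np.ndarray
    between_distribution: np.ndarray
    excess_area: float = field(default=0.0)

    def to_frame(self):
        """Per-ROI consistencies as a tidy DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "roi": list(self.per_roi_consistency),
                "consistency": list(self.per_roi_consistency.values()),
            }
        )


def spatial_consistency(
    volume: VoxelVolume, roi_voxels: list[tuple[int, int, int]]
) -> float:
    """Mean pairwise Pearson correlation of the ROI's voxel time series.

    Defined over all distinct voxel pairs; requires at least two voxels
    (a single series has no pairs).  Constant series contribute
    correlation 0 under the shared zero-variance policy.
    """
    roi_voxels = list(roi_voxels)
    if len(roi_voxels) < 2:
        raise ValueError("spatial consistency is undefined for ROIs of size < 2")
    for v in roi_voxels:
        if not volume.mask[v]:
            raise ValueError(f"voxel {v} is outside the mask")
    series = np.stack([volume.series(v) for v in roi_voxels])
    corr = pearson_matrix(series)
    n = len(roi_voxels)
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def regional_homogeneity(volume: VoxelVolume, voxel: tuple[int, int, int]) -> float:
    """Kendall's W over the voxel and its masked face-neighbors.

    W = 12 * sum_i (R_i - Rbar)^2 / (K^2 (n^3 - n)), where R_i is the sum
    across the K series of the rank of time point i within each series
    (midranks for ties, no tie correction).  W lies in [0, 1]; 1 means the
    neighborhood's series are rank-identical.
    """
    if not volume.mask[voxel]:
        raise ValueError(f"voxel {voxel} is outside the mask")
    neighborhood = [voxel] + [
        p for p in face_neighbors(voxel, volume.spatial_shape) if volume.mask[p]
    ]
    series = np.stack([volume.series(v) for v in neighborhood])
    return kendalls_w(series)


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series of length n."""
    series = np.asarray(series, dtype=float)
    K, n = series.shape
    if K < 1 or n < 2:
        raise ValueError("need at least one series of length >= 2")
    ranks = np.apply_along_axis(rankdata, 1, series)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    return 12.0 * S / (K**2 * (n**3 - n))


def excess_area(
    within, between, bin_width: float = 0.01
) -> float:
    """Area where the within-ROI correlation density exceeds the between-ROI one.

    Both samples are histogrammed on a shared grid over [-1, 1] with the
    given bin width and density normalization; the statistic is
    sum_bins max(0, f_within - f_between) * bin_width.  It is 0 when the
    distributions coincide and 1 when their supports are disjoint.
    """
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    if within.size == 0 or between.size == 0:
        raise ValueError("both distributions must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    f_within, _ = np.histogram(within, bins=edges, density=True)
    f_between, _ = np.histogram(between, bins=edges, density=True)
    return float(np.sum(np.clip(f_within - f_between, 0.0, None)) * bin_width)


def correlation_distributions(
    volume: VoxelVolume,
    parcellation: Parcellation,
    max_pairs: int = 100_000,
    seed: int | np.random.Generator = 0,
    bin_width: float = 0.01,
) -> ConsistencyReport:
    """Within- vs between-ROI voxel-pair correlation distributions.

    Single-voxel ROIs are excluded first.  Within-ROI pairs are enumerated
    exhaustively; between-ROI pairs (quadratic in voxel count) are
    subsampled uniformly to ``max_pairs`` when necessary.  Also reports
    per-ROI spatial consistency and the excess-area statistic.
    """
    rng = np.random.default_rng(seed)
    sizes = parcellation.roi_sizes()
    multi = [lab for lab, s in sizes.items() if s >= 2]
    if not multi:
        raise ValueError("parcellation has no multi-voxel ROIs")

    keep = np.isin(parcellation.label_volume, multi)
    coords = np.argwhere(keep)
    labels = parcellation.label_volume[keep]
    series = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], :]
    corr = pearson_matrix(series)

    per_roi: dict[int, float] = {}
    within_parts = []
    for lab in multi:
        idx = np.flatnonzero(labels == lab)
        block = corr[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = block[iu]
        within_parts.append(vals)
        per_roi[int(lab)] = float(vals.mean())
    within = np.concatenate(within_parts)

    iu = np.triu_indices(len(labels), k=1)
    cross = labels[iu[0]] != labels[iu[1]]
    between = corr[iu][cross]
    if between.size > max_pairs:
        between = rng.choice(between, size=max_pairs, replace=False)

    area = (
        excess_area(within, between, bin_width=bin_width) if between.size else 0.0
    )
    return ConsistencyReport(per_roi, within, between, area)
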