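"""Core data containers shared across the pipeline.

A :class:`VoxelVolume` holds a masked 4D scalar field (three spatial axes
plus time) of BOLD-like voxel time series.  A :class:`Parcellation` assigns
masked voxels to ROI labels for one time window; label 0 means unassigned.
All voxel coordinates are 0-based ``(i, j, k)`` indices in the volume's
native axis order, and "neighborhood" always means face-sharing
6-connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: structuring element for face-sharing (6-) connectivity
FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

#: the six face-neighbor offsets
NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class VoxelVolume:
    """Masked 4D voxel time-series volume.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz, nt)``.
    mask:
        Boolean array of shape ``(nx, ny, nz)``; True marks in-brain voxels.
    sample_interval:
        Seconds per time point.  Defaults to 0.1 s (a 100-ms repetition
        time, typical of ultrafast inverse-imaging acquisitions).
    affine:
        Voxel-to-world affine retained for NIfTI write-back.
    """

    data: np.ndarray
    mask: np.ndarray
    sample_interval: float = 0.1
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t); got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("volume must hold at least 2 time points")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("masked voxel series contain non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def series(self, voxel: tuple[int, int, int]) -> np.ndarray:
        """Time series of one voxel."""
        return self.data[voxel[0], voxel[1], voxel[2], :]

    def masked_coords(self) -> np.ndarray:
        """``(n_masked, 3)`` integer coordinates of masked voxels, in C order."""
        return np.argwhere(self.mask)

    def crop_time(self, start: int, stop: int) -> "VoxelVolume":
        """Volume restricted to samples ``[start, stop)``."""
        if not (0 <= start < stop <= self.n_timepoints):
            raise ValueError(f"invalid time range [{start}, {stop})")
        return VoxelVolume(
            self.data[..., start:stop], self.mask, self.sample_interval, self.affine
        )


@dataclass
class Parcellation:
    """Assignment of masked voxels to ROI labels for one time window.

    ``label_volume`` is an integer 3D array: 0 = unassigned, positive
    values are ROI labels.  ``seeds`` optionally records the seed voxel of
    each ROI (used by the synthetic generator and the greedy grower).
    """

    label_volume: np.ndarray
    window_index: int = 0
    method_tag: str = ""
    seeds: dict[int, tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label_volume must be 3D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            self.label_volume = self.label_volume.astype(np.int32)
        if (self.label_volume < 0).any():
            raise ValueError("labels must be nonnegative (0 = unassigned)")

    def labels(self) -> list[int]:
        """Sorted positive ROI labels present."""
        u = np.unique(self.label_volume)
        return [int(x) for x in u if x > 0]

    def voxels(self, label: int) -> list[tuple[int, int, int]]:
        """Coordinates of the voxels carrying ``label``."""
        return [
            (int(c[0]), int(c[1]), int(c[2]))
            for c in np.argwhere(self.label_volume == label)
        ]

    def voxel_set(self, label: int) -> frozenset[tuple[int, int, int]]:
        return frozenset(self.voxels(label))

    def roi_sizes(self) -> dict[int, int]:
        lab, cnt = np.unique(self.label_volume[self.label_volume > 0], return_counts=True)
        return {int(l): int(c) for l, c in zip(lab, cnt)}

    @property
    def n_rois(self) -> int:
        return len(self.labels())

    def assigned_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def is_connected(self, label: int) -> bool:
        """True iff the ROI is a single 6-connected component."""
        roi = self.label_volume == label
        _, n = ndimage.label(roi, structure=FACE_STRUCT)
        return n == 1

    def copy(self) -> "Parcellation":
        return Parcellation(
            self.label_volume.copy(),
            self.window_index,
            self.method_tag,
            dict(self.seeds) if self.seeds is not None else None,
        )


def pearson_matrix(series: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of rows, with a zero-variance policy.

    Rows with zero variance (constant series) get correlation 0 against
    everything, including themselves, instead of NaN; a warning is logged
    once per call.  This keeps downstream means and priorities finite.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a 2D array (n_series, n_timepoints)")
    std = series.std(axis=1)
    degenerate = std == 0
    if degenerate.any():
        logger.warning(
            "%d constant time series; their correlations are set to 0",
            int(degenerate.sum()),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(series)
    corr = np.atleast_2d(corr)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, np.where(degenerate, 0.0, 1.0))
    return corr


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two series under the zero-variance policy."""
    return float(pearson_matrix(np.vstack([x, y]))[0, 1])


def face_neighbors(
    voxel: tuple[int, int, int], shape: tuple[int, int, int]
) -> list[tuple[int, int, int]]:
    """In-bounds face-sharing neighbors of a voxel."""
    out = []
    for off in NEIGHBOR_OFFSETS:
        p = (voxel[0] + off[0], voxel[1] + off[1], voxel[2] + off[2])
        if 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and 0 <= p[2] < shape[2]:
            out.append(p)
    return out
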