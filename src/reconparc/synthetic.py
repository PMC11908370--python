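"""Synthetic voxel time-series generator with planted parcellations.

The generator emulates the simulation used to motivate window-wise ROI
optimization: random seed voxels are grown into approximately spherical,
6-connected parcels covering the mask; each seed carries an independent
white-noise signal; every other voxel mixes its seed's signal with private
noise according to a distance-decaying Gaussian weight,

    y(t) = (G(d)/G(0)) x(t) + (1 - G(d)/G(0)) n(t),

where ``G`` is the zero-mean Gaussian density with the configured variance
(default 5), ``d`` the Euclidean distance to the parcel's seed, ``x`` the
seed signal, and ``n`` voxel-specific white noise.  Multi-window datasets
relocate a configurable fraction of seeds between consecutive windows and
regrow the parcels, giving ground truth for reconfiguration analytics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Parcellation, VoxelVolume

__all__ = [
    "SyntheticConfig",
    "generate_random_parcellation",
    "generate_voxel_timeseries",
    "generate_reconfiguring_dataset",
    "grow_parcellation_rounds",
    "save_dataset",
]


@dataclass
class SyntheticConfig:
    """Parameters of the reconfiguring synthetic dataset.

    ``gaussian_variance`` is the variance of the mixing kernel G (default
    5, in squared voxel units).  ``reconfigure_fraction`` is the fraction
    of ROI seeds relocated between consecutive windows; 0 reproduces a
    static parcellation on every window.  ``noise_amplitude`` scales the
    private white noise relative to the unit-variance seed signals.
    """

    grid_shape: tuple[int, int, int] = (10, 10, 10)
    n_rois: int = 10
    n_timepoints: int = 240
    gaussian_variance: float = 5.0
    noise_seed: int = 0
    reconfigure_fraction: float = 0.3
    n_windows: int = 3
    noise_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_variance <= 0:
            raise ValueError("gaussian_variance must be positive")
        if not 0.0 <= self.reconfigure_fraction <= 1.0:
            raise ValueError("reconfigure_fraction must lie in [0, 1]")
        if self.n_rois > int(np.prod(self.grid_shape)):
            raise ValueError("n_rois exceeds the number of voxels in the grid")
        if self.n_windows < 1:
            raise ValueError("need at least one window")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be nonnegative")


def _neighbor_min_label(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """For each voxel, the minimum positive label among its face neighbors
    (0 where no assigned neighbor exists)."""
    big = np.iinfo(np.int64).max
    best = np.full(labels.shape, big, dtype=np.int64)
    padded = np.where(labels > 0, labels.astype(np.int64), big)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(padded, shift, axis=axis)
            # zero out the wrapped slice
            idx = [slice(None)] * 3
            idx[axis] = 0 if shift == 1 else -1
            rolled[tuple(idx)] = big
            best = np.minimum(best, rolled)
    best[~mask] = big
    return np.where(best == big, 0, best).astype(labels.dtype)


def grow_parcellation_rounds(
    mask: np.ndarray, seeds: dict[int, tuple[int, int, int]]
) -> np.ndarray:
    """Grow 6-connected parcels from seeds in synchronous rounds.

    Each round, every parcel absorbs all of its currently unassigned
    masked face-neighbors; a voxel claimed by several parcels in the same
    round goes to the lowest label.  Terminates when no unassigned masked
    voxel borders a parcel (covering the whole mask when the mask is
    6-connected).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    for lab, (i, j, k) in seeds.items():
        if not mask[i, j, k]:
            raise ValueError(f"seed {(i, j, k)} for ROI {lab} lies outside the mask")
        if labels[i, j, k] != 0:
            raise ValueError(f"duplicate seed voxel {(i, j, k)}")
        labels[i, j, k] = lab
    while True:
        claim = _neighbor_min_label(labels, mask)
        frontier = (labels == 0) & mask & (claim > 0)
        if not frontier.any():
            break
        labels[frontier] = claim[frontier]
    return labels


def generate_random_parcellation(
    mask: np.ndarray, n_rois: int, seed: int | np.random.Generator
) -> Parcellation:
    """Random seeds grown into approximately spherical parcels.

    Seeds are drawn uniformly without replacement over masked voxels;
    growth proceeds in synchronous rounds (see
    :func:`grow_parcellation_rounds`).
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("mask contains no voxels")
    if n_rois > coords.shape[0]:
        raise ValueError(
            f"n_rois={n_rois} exceeds number of masked voxels {coords.shape[0]}"
        )
    if n_rois < 1:
        raise ValueError("n_rois must be at least 1")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(coords.shape[0], size=n_rois, replace=False)
    seeds = {lab + 1: tuple(int(x) for x in coords[c]) for lab, c in enumerate(chosen)}
    labels = grow_parcellation_rounds(mask, seeds)
    return Parcellation(labels, method_tag="random", seeds=seeds)


def generate_voxel_timeseries(
    parcellation: Parcellation,
    n_timepoints: int,
    gaussian_variance: float = 5.0,
    seed: int | np.random.Generator = 0,
    noise_amplitude: float = 1.0,
) -> VoxelVolume:
    """Planted voxel signals: Gaussian-weighted seed/noise mixtures.

    Each seed voxel carries an independent standard white-noise series
    x(t); every other voxel of the parcel carries
    ``y(t) = w x(t) + (1 - w) n(t)`` with ``w = G(d)/G(0) =
    exp(-d^2 / (2 var))`` and voxel-specific white noise ``n``.
    """
    if parcellation.seeds is None:
        raise ValueError("parcellation carries no seed records")
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if gaussian_variance <= 0:
        raise ValueError("gaussian_variance must be positive")
    rng = np.random.default_rng(seed)
    labels = parcellation.label_volume
    mask = labels > 0
    data = np.zeros(labels.shape + (n_timepoints,), dtype=float)
    for lab in parcellation.labels():
        if lab not in parcellation.seeds:
            raise ValueError(f"missing seed record for ROI {lab}")
        seed_vox = parcellation.seeds[lab]
        x = rng.standard_normal(n_timepoints)
        coords = np.argwhere(labels == lab)
        d = np.linalg.norm(coords - np.asarray(seed_vox), axis=1)
        w = np.exp(-(d**2) / (2.0 * gaussian_variance))
        noise = noise_amplitude * rng.standard_normal((coords.shape[0], n_timepoints))
        series = w[:, None] * x[None, :] + (1.0 - w[:, None]) * noise
        data[coords[:, 0], coords[:, 1], coords[:, 2], :] = series
    return VoxelVolume(data, mask)


def generate_reconfiguring_dataset(
    config: SyntheticConfig,
) -> tuple[VoxelVolume, list[Parcellation]]:
    """Multi-window dataset with planted, partially relocating parcels.

    Per-window volumes are generated independently from per-window planted
    parcellations and concatenated in time; between consecutive windows a
    ``reconfigure_fraction`` of seeds is relocated to random masked voxels
    and the parcels regrown.  Returns the volume and the ground-truth
    parcellation sequence (one per window).
    """
    if config.n_timepoints % config.n_windows != 0:
        raise ValueError(
            f"n_timepoints={config.n_timepoints} is not a multiple of "
            f"n_windows={config.n_windows}"
        )
    window_len = config.n_timepoints // config.n_windows
    if window_len < 2:
        raise ValueError("windows must hold at least 2 time points")
    mask = np.ones(config.grid_shape, dtype=bool)
    rng = np.random.default_rng(config.noise_seed)

    parcels: list[Parcellation] = []
    first = generate_random_parcellation(mask, config.n_rois, rng)
    first.window_index = 0
    first.method_tag = "planted"
    parcels.append(first)
    coords = np.argwhere(mask)
    n_move = int(round(config.reconfigure_fraction * config.n_rois))
    for w in range(1, config.n_windows):
        prev = parcels[-1]
        seeds = dict(prev.seeds)  # type: ignore[arg-type]
        if n_move > 0:
            moved = rng.choice(sorted(seeds), size=n_move, replace=False)
            for lab in moved:
                occupied = set(seeds.values())
                while True:
                    c = tuple(int(x) for x in coords[rng.integers(coords.shape[0])])
                    if c not in occupied:
                        break
                seeds[int(lab)] = c
        labels = grow_parcellation_rounds(mask, seeds)
        parcels.append(
            Parcellation(labels, window_index=w, method_tag="planted", seeds=seeds)
        )

    volumes = [
        generate_voxel_timeseries(
            p,
            window_len,
            config.gaussian_variance,
            rng,
            config.noise_amplitude,
        )
        for p in parcels
    ]
    data = np.concatenate([v.data for v in volumes], axis=3)
    return VoxelVolume(data, mask), parcels


def save_dataset(
    volume: VoxelVolume, parcellations: list[Parcellation], outdir: str | Path
) -> Path:
    """Write the volume, per-window label volumes, and a JSON sidecar
    mapping window index to label-volume filename."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(volume.data, volume.affine), outdir / "volume.nii")
    nib.save(
        nib.Nifti1Image(volume.mask.astype(np.uint8), volume.affine),
        outdir / "mask.nii",
    )
    sidecar: dict[str, str] = {}
    for p in parcellations:
        fname = f"parcellation_w{p.window_index:03d}.nii"
        nib.save(
            nib.Nifti1Image(p.label_volume.astype(np.int32), volume.affine),
            outdir / fname,
        )
        sidecar[str(p.window_index)] = fname
    (outdir / "parcellations.json").write_text(json.dumps(sidecar, indent=2))
    return outdir
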