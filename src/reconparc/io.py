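"""NIfTI readers/writers, run configuration, and the end-to-end pipeline.

The pipeline executes, in order: window splitting → per-window ROI
definition → single-voxel-ROI exclusion → multilayer network assembly →
stability/interaction analytics, and writes every artifact with a JSON
manifest recording the configuration and seeds.  Identical configuration
and seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import analysis
from .core import Parcellation, VoxelVolume
from .multilayer import build_network, split_windows
from .parcellation import (
    CraddockConfig,
    GreedyConfig,
    PriorityKind,
    craddock_cluster,
    exclude_single_voxel_rois,
    filter_static_parcellation,
    greedy_grow,
    random_parcellation,
    select_reho_seeds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_volume",
    "read_parcellation",
    "write_volume",
    "write_parcellation",
    "parcellate_window",
    "run_pipeline",
]

METHODS = (
    "greedy_wmc",
    "greedy_minc",
    "craddock",
    "random",
    "static",
    "filtered_static",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run over one input volume."""

    volume_path: str | Path
    output_dir: str | Path
    mask_path: str | Path | None = None
    atlas_path: str | Path | None = None
    method: str = "greedy_wmc"
    n_rois: int = 20
    window_length: int = 80
    rng_seed: int = 0
    greedy: GreedyConfig = field(default_factory=GreedyConfig)
    craddock: CraddockConfig = field(default_factory=CraddockConfig)
    voxel_budget: int | None = None  # for filtered_static; defaults to all voxels

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method in ("static", "filtered_static") and self.atlas_path is None:
            raise ValueError(f"method {self.method!r} requires an atlas label volume")


def read_volume(
    path: str | Path, mask_path: str | Path | None = None
) -> VoxelVolume:
    """Read a 4D NIfTI volume, with the mask from a companion file or a
    nonzero-variance heuristic."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mdata = np.asarray(mimg.dataobj)
        if mdata.ndim != 3:
            raise ValueError(f"{mask_path}: expected a 3D mask, got shape {mdata.shape}")
        if mdata.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mdata.shape} does not match volume spatial shape "
                f"{data.shape[:3]}"
            )
        mask = mdata > 0
    else:
        mask = data.std(axis=3) > 0
        logger.info("no mask given; derived %d-voxel nonzero-variance mask", mask.sum())
    if not np.all(np.isfinite(data[mask])):
        raise ValueError(f"{path}: masked data contain non-finite values")
    return VoxelVolume(data, mask, affine=img.affine)


def read_parcellation(path: str | Path, window_index: int = 0) -> Parcellation:
    """Read an integer label volume (0 = unassigned)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got shape {data.shape}")
    return Parcellation(
        np.rint(data).astype(np.int32), window_index=window_index, method_tag="static"
    )


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.data, volume.affine), str(path))


def write_parcellation(
    parcellation: Parcellation, path: str | Path, affine: np.ndarray | None = None
) -> None:
    nib.save(
        nib.Nifti1Image(
            parcellation.label_volume.astype(np.int32),
            np.eye(4) if affine is None else affine,
        ),
        str(path),
    )


def parcellate_window(
    windowed: VoxelVolume,
    method: str,
    n_rois: int,
    rng: np.random.Generator,
    atlas: Parcellation | None = None,
    greedy_config: GreedyConfig | None = None,
    craddock_config: CraddockConfig | None = None,
    voxel_budget: int | None = None,
) -> Parcellation:
    """Run one ROI-definition method on one window's data.

    Greedy methods take their seeds from the atlas by ReHo when an atlas
    is available, otherwise from a random region-grown parcellation of
    the same window (uniform seeds, one per requested ROI).
    """
    if method in ("greedy_wmc", "greedy_minc"):
        cfg = greedy_config or GreedyConfig()
        cfg.priority_kind = (
            PriorityKind.WEIGHTED_MEAN_CONSISTENCY
            if method == "greedy_wmc"
            else PriorityKind.MIN_CORRELATION
        )
        if atlas is not None:
            seeds = select_reho_seeds(windowed, atlas)
        else:
            seeds = random_parcellation(windowed.mask, n_rois, rng).seeds or {}
        return greedy_grow(windowed, seeds, cfg)
    if method == "craddock":
        cfg = craddock_config or CraddockConfig()
        return craddock_cluster(windowed, cfg)
    if method == "random":
        return random_parcellation(windowed.mask, n_rois, rng)
    if method == "static":
        assert atlas is not None
        return atlas.copy()
    if method == "filtered_static":
        assert atlas is not None
        budget = voxel_budget if voxel_budget is not None else int(windowed.n_masked)
        return filter_static_parcellation(windowed, atlas, budget)
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the output dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "volume": str(config.volume_path),
            "mask": str(config.mask_path) if config.mask_path else None,
            "atlas": str(config.atlas_path) if config.atlas_path else None,
            "method": config.method,
            "n_rois": config.n_rois,
            "window_length": config.window_length,
            "rng_seed": config.rng_seed,
            "voxel_indexing": "0-based (i, j, k), native axis order",
        },
        "outputs": [],
        "stage": None,
    }

    def _record(name: str) -> None:
        manifest["outputs"].append(name)

    def _fail(stage: str, err: Exception) -> None:
        manifest["stage"] = stage
        manifest["error"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        manifest["stage"] = "read"
        volume = read_volume(config.volume_path, config.mask_path)
        atlas = (
            read_parcellation(config.atlas_path) if config.atlas_path else None
        )

        manifest["stage"] = "windows"
        windows = split_windows(volume, config.window_length)
        if not windows:
            raise ValueError("volume is shorter than one window")

        manifest["stage"] = "parcellation"
        rng = np.random.default_rng(config.rng_seed)
        parcels: list[Parcellation] = []
        excluded_counts: list[int] = []
        for i, win in enumerate(windows):
            windowed = volume.crop_time(win.start, win.stop)
            parc = parcellate_window(
                windowed,
                config.method,
                config.n_rois,
                rng,
                atlas=atlas,
                greedy_config=config.greedy,
                craddock_config=config.craddock,
                voxel_budget=config.voxel_budget,
            )
            parc, n_excluded = exclude_single_voxel_rois(parc)
            parc.window_index = i
            excluded_counts.append(n_excluded)
            parcels.append(parc)
            fname = f"parcellation_w{i:03d}.nii"
            write_parcellation(parc, outdir / fname, volume.affine)
            _record(fname)
        manifest["n_single_voxel_rois_excluded"] = excluded_counts

        manifest["stage"] = "network"
        net = build_network(volume, parcels, config.window_length)
        net.save_json(outdir / "network.json")
        _record("network.json")
        net.edge_table().to_csv(outdir / "edges.tsv", sep="\t", index=False)
        _record("edges.tsv")

        manifest["stage"] = "analysis"
        import pandas as pd

        scores = analysis.all_stability_scores(net)
        pd.DataFrame(
            [{"layer": l, "roi": lab, "stability": s} for (l, lab), s in scores.items()]
        ).to_csv(outdir / "stability.csv", index=False)
        _record("stability.csv")

        if net.interlayer:
            v, cdf = analysis.interlayer_weight_cdf(net)
            np.savetxt(
                outdir / "interlayer_weight_cdf.txt",
                np.column_stack([v, cdf]),
                header="weight cdf",
            )
            _record("interlayer_weight_cdf.txt")
        if scores:
            mic = []
            for node, s in scores.items():
                try:
                    mic.append((s, analysis.mean_intralayer_correlation(net, node)))
                except ValueError:
                    continue
            if mic:
                curve = analysis.binned_curve(
                    [m[0] for m in mic], [m[1] for m in mic]
                )
                curve.to_frame().to_csv(
                    outdir / "mean_intralayer_correlation_vs_stability.csv", index=False
                )
                _record("mean_intralayer_correlation_vs_stability.csv")
        if len(windows) >= 2:
            carry = analysis.consistency_carryover(
                volume, parcels[0], windows[0], windows[1]
            )
            pd.DataFrame(
                [
                    {"roi": lab, "phi_t": a, "phi_t1": b}
                    for lab, (a, b) in carry.per_roi.items()
                ]
            ).to_csv(outdir / "carryover.csv", index=False)
            _record("carryover.csv")
            manifest["carryover_mean_change"] = carry.mean_change
            manifest["carryover_mean_relative_change"] = carry.mean_relative_change

        manifest["multiplex"] = bool(net.is_multiplex()) if net.interlayer else None
        manifest["stage"] = "done"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir
    except Exception as err:  # record the failing stage, then re-raise
        _fail(manifest["stage"], err)
        raise
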