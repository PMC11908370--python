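"""Node-reconfiguring multilayer network assembly.

Layers are consecutive non-overlapping time windows (80 samples by
default).  Nodes are the ROIs of that window's parcellation, identified
by ``(layer index, ROI label)``; labels carry no identity across layers.
Intralayer edges form a complete weighted graph per layer, weighted by
the Pearson correlation of the ROI mean time series.  Interlayer edges
connect ROIs on *consecutive* layers only and are weighted by the Jaccard
index of their voxel sets; ROI pairs that share no voxel have no edge.
With a static parcellation replicated across windows the network
degenerates to a multiplex: each node has exactly one unit-weight
interlayer edge to its successor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Parcellation, VoxelVolume, pearson_matrix

__all__ = [
    "Window",
    "MultilayerNetwork",
    "split_windows",
    "roi_mean_timeseries",
    "intralayer_edges",
    "interlayer_edges",
    "jaccard",
    "build_network",
]

DEFAULT_WINDOW_LENGTH = 80


@dataclass(frozen=True)
class Window:
    """Half-open sample window ``[start, start + length)``."""

    start: int
    length: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be at least 2")
        if self.start < 0:
            raise ValueError("window start must be nonnegative")

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class MultilayerNetwork:
    """Ordered layers of ROI nodes with correlation intralayer edges and
    Jaccard interlayer edges.

    ``nodes`` maps ``(layer, label)`` to the ROI's frozen voxel set;
    ``mean_series`` holds the windowed ROI mean time series;
    ``intralayer`` maps ``(layer, label_a, label_b)`` (a < b) to the
    Pearson weight; ``interlayer`` maps ``(layer, label_t, label_t1)`` to
    the Jaccard weight of the ROI on ``layer`` against the ROI on
    ``layer + 1``.
    """

    layers: list[Window]
    nodes: dict[tuple[int, int], frozenset] = field(default_factory=dict)
    mean_series: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    intralayer: dict[tuple[int, int, int], float] = field(default_factory=dict)
    interlayer: dict[tuple[int, int, int], float] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_labels(self, layer: int) -> list[int]:
        return sorted(lab for (l, lab) in self.nodes if l == layer)

    def intralayer_weight(self, layer: int, a: int, b: int) -> float:
        if a == b:
            raise ValueError("no self-edges in the intralayer graph")
        key = (layer, min(a, b), max(a, b))
        return self.intralayer[key]

    def interlayer_weight(self, layer: int, label_t: int, label_t1: int) -> float:
        """Jaccard weight between (layer, label_t) and (layer+1, label_t1);
        0 when the edge does not exist."""
        return self.interlayer.get((layer, label_t, label_t1), 0.0)

    def out_edges(self, layer: int, label: int) -> dict[int, float]:
        """Interlayer edges from a node to the next layer."""
        return {
            lab1: w
            for (l, lab, lab1), w in self.interlayer.items()
            if l == layer and lab == label
        }

    def is_multiplex(self) -> bool:
        """True iff every node's interlayer edges form a unit-weight
        perfect matching with the next layer."""
        for layer in range(self.n_layers - 1):
            labels_t = self.layer_labels(layer)
            labels_t1 = set(self.layer_labels(layer + 1))
            matched = set()
            for lab in labels_t:
                edges = self.out_edges(layer, lab)
                if len(edges) != 1:
                    return False
                (succ, w), = edges.items()
                if w != 1.0 or succ in matched:
                    return False
                matched.add(succ)
            if matched != labels_t1:
                return False
        return True

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "layers": [{"start": w.start, "length": w.length} for w in self.layers],
            "nodes": [
                {
                    "layer": layer,
                    "label": lab,
                    "voxels": sorted(map(list, self.nodes[(layer, lab)])),
                    "mean_series": self.mean_series[(layer, lab)].tolist(),
                }
                for (layer, lab) in sorted(self.nodes)
            ],
            "intralayer_edges": [
                {"layer": l, "a": a, "b": b, "weight": w}
                for (l, a, b), w in sorted(self.intralayer.items())
            ],
            "interlayer_edges": [
                {"layer": l, "label_t": a, "label_t1": b, "weight": w}
                for (l, a, b), w in sorted(self.interlayer.items())
            ],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def from_json_dict(cls, d: dict) -> "MultilayerNetwork":
        net = cls([Window(w["start"], w["length"]) for w in d["layers"]])
        for nd in d["nodes"]:
            key = (nd["layer"], nd["label"])
            net.nodes[key] = frozenset(tuple(v) for v in nd["voxels"])
            net.mean_series[key] = np.asarray(nd["mean_series"])
        for e in d["intralayer_edges"]:
            net.intralayer[(e["layer"], e["a"], e["b"])] = e["weight"]
        for e in d["interlayer_edges"]:
            net.interlayer[(e["layer"], e["label_t"], e["label_t1"])] = e["weight"]
        return net

    @classmethod
    def load_json(cls, path: str | Path) -> "MultilayerNetwork":
        return cls.from_json_dict(json.loads(Path(path).read_text()))

    def edge_table(self):
        """Flat edge list (both kinds) as a tidy DataFrame."""
        import pandas as pd

        rows = [
            {"layer_a": l, "roi_a": a, "layer_b": l, "roi_b": b, "weight": w,
             "edge_type": "intralayer"}
            for (l, a, b), w in sorted(self.intralayer.items())
        ] + [
            {"layer_a": l, "roi_a": a, "layer_b": l + 1, "roi_b": b, "weight": w,
             "edge_type": "interlayer"}
            for (l, a, b), w in sorted(self.interlayer.items())
        ]
        return pd.DataFrame(
            rows, columns=["layer_a", "roi_a", "layer_b", "roi_b", "weight", "edge_type"]
        )


def split_windows(
    volume_or_length: VoxelVolume | int, window_length: int = DEFAULT_WINDOW_LENGTH
) -> list[Window]:
    """Consecutive non-overlapping windows [0, L), [L, 2L), ...; trailing
    samples that do not fill a whole window are discarded."""
    if window_length < 2:
        raise ValueError("window_length must be at least 2")
    n = (
        volume_or_length.n_timepoints
        if isinstance(volume_or_length, VoxelVolume)
        else int(volume_or_length)
    )
    return [Window(s, window_length) for s in range(0, n - window_length + 1, window_length)]


def roi_mean_timeseries(
    volume: VoxelVolume, roi_voxels, window: Window
) -> np.ndarray:
    """Element-wise mean of the ROI's voxel series over the window's samples."""
    roi_voxels = list(roi_voxels)
    if not roi_voxels:
        raise ValueError("roi_voxels must be non-empty")
    if window.stop > volume.n_timepoints:
        raise ValueError("window extends past the end of the volume")
    for v in roi_voxels:
        if not volume.mask[v]:
            raise ValueError(f"voxel {v} is outside the mask")
    coords = np.asarray(roi_voxels)
    series = volume.data[coords[:, 0], coords[:, 1], coords[:, 2], window.start : window.stop]
    return series.mean(axis=0)


def intralayer_edges(roi_series: dict[int, np.ndarray]) -> dict[tuple[int, int], float]:
    """Complete symmetric Pearson weight map over ROI mean series.

    Keys are label pairs (a, b) with a < b; n ROIs yield n(n-1)/2 weights.
    Constant series get weight 0 under the shared zero-variance policy.
    """
    labels = sorted(roi_series)
    if len(labels) < 2:
        raise ValueError("need at least two ROIs for intralayer edges")
    corr = pearson_matrix(np.stack([roi_series[lab] for lab in labels]))
    return {
        (labels[i], labels[j]): float(corr[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two voxel sets."""
    if not a and not b:
        return 0.0
    inter = len(set(a) & set(b))
    if inter == 0:
        return 0.0
    return inter / len(set(a) | set(b))


def interlayer_edges(
    parc_t: Parcellation, parc_t1: Parcellation
) -> dict[tuple[int, int], float]:
    """Jaccard weights between ROIs of two consecutive-window parcellations.

    Only ROI pairs with non-empty voxel intersection yield an edge; the
    map is keyed by (label on t, label on t+1).
    """
    if parc_t.label_volume.shape != parc_t1.label_volume.shape:
        raise ValueError("parcellations live on different voxel grids")
    edges: dict[tuple[int, int], float] = {}
    sets_t1 = {lab: parc_t1.voxel_set(lab) for lab in parc_t1.labels()}
    for lab_t in parc_t.labels():
        s_t = parc_t.voxel_set(lab_t)
        for lab_t1, s_t1 in sets_t1.items():
            w = jaccard(s_t, s_t1)
            if w > 0.0:
                edges[(lab_t, lab_t1)] = w
    return edges


def build_network(
    volume: VoxelVolume,
    parcellations: list[Parcellation],
    window_length: int = DEFAULT_WINDOW_LENGTH,
) -> MultilayerNetwork:
    """Assemble the multilayer network from per-window parcellations.

    Expects one parcellation per window (single-voxel ROIs already
    excluded upstream).  Layers with fewer than two ROIs contribute no
    intralayer edges.
    """
    windows = split_windows(volume, window_length)
    if len(parcellations) != len(windows):
        raise ValueError(
            f"{len(parcellations)} parcellations for {len(windows)} windows"
        )
    net = MultilayerNetwork(windows)
    for layer, (win, parc) in enumerate(zip(windows, parcellations)):
        series_map: dict[int, np.ndarray] = {}
        for lab in parc.labels():
            voxels = parc.voxel_set(lab)
            net.nodes[(layer, lab)] = voxels
            s = roi_mean_timeseries(volume, voxels, win)
            net.mean_series[(layer, lab)] = s
            series_map[lab] = s
        if len(series_map) >= 2:
            for (a, b), w in intralayer_edges(series_map).items():
                net.intralayer[(layer, a, b)] = w
    for layer in range(len(windows) - 1):
        for (a, b), w in interlayer_edges(
            parcellations[layer], parcellations[layer + 1]
        ).items():
            net.interlayer[(layer, a, b)] = w
    return net
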