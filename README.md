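# reconparc

Node-reconfiguring multilayer networks of brain function: per-time-window
parcellation of voxel time series into functionally homogeneous ROIs, and
network analytics that track how those ROIs reorganize over time.

## The problem

Functional brain networks usually take Regions of Interest (ROIs) — fixed
collections of fMRI voxels — as their nodes. Using an ROI as a node assumes
*functional homogeneity*: the voxel time series inside it should be highly
correlated, so that averaging them loses little information. Static atlases
routinely violate this assumption, and the violation is not just a matter of
badly drawn boundaries — the underlying groups of correlated voxels
reorganize at time scales of seconds, so *no* fixed parcellation can track
them.

`reconparc` implements the node-reconfiguring multilayer network model: the
recording is split into non-overlapping time windows (80 samples by
default), ROIs are re-optimized for homogeneity inside every window, and the
windows become the layers of a multilayer network in which

- **nodes** are the per-window ROIs, identified as `(layer, label)` — labels
  carry no identity across layers;
- **intralayer edges** connect every ROI pair within a layer, weighted by
  the Pearson correlation of the ROI mean time series;
- **interlayer edges** connect ROIs on *consecutive* layers, weighted by the
  Jaccard index of their voxel sets, `|I_t ∩ I'_{t+1}| / |I_t ∪ I'_{t+1}|`;
  ROIs sharing no voxel get no edge.

With a static parcellation the model degenerates to a multiplex network
(unit-weight diagonal interlayer edges only), so the classical construction
is contained as a special case.

## What is inside

- **ROI definition** (`reconparc.parcellation`) — greedy region growing from
  ReHo-selected or explicit seeds with two priority functions: *weighted
  mean consistency* (size-weighted mean ROI homogeneity minus a
  `λ Σ|I|²/(Σ|I|)²` size regularizer, λ = 100 by default) and *minimum
  correlation* (lowest correlation between candidate voxel and ROI members),
  optionally gated by an N% percentile acceptance threshold (N = 30);
  normalized-cut (NCUT) spectral clustering of the thresholded 6-neighbor
  voxel correlation graph (threshold 0.2, target 246 clusters); random
  region-grown parcels; static label volumes; and a filtered-static baseline
  that keeps the most consistent atlas ROIs under a voxel budget.
  Single-voxel ROIs are treated as artifacts and excluded.
- **Homogeneity metrics** (`reconparc.metrics`) — spatial consistency
  `ϕ(I)` (mean pairwise Pearson correlation inside an ROI), regional
  homogeneity (Kendall's W over a voxel's face-neighborhood, K = 7 in the
  interior), within-/between-ROI correlation distributions and their
  excess-area summary.
- **Network assembly** (`reconparc.multilayer`) and **analytics**
  (`reconparc.analysis`) — stability scores (max interlayer weight to the
  next layer), multi-layer trajectories, pairwise stability, mean intralayer
  correlation, binned interaction curves (bins `[0,0.1]`, `(0.1,0.2]`, …),
  empirical CDFs, and the consistency-carryover comparison that applies
  window-t ROI boundaries to window t+1.
- **Synthetic generator** (`reconparc.synthetic`) — planted, reconfiguring
  parcellations with distance-decaying signal mixtures
  `y(t) = G(d)/G(0)·x(t) + (1 − G(d)/G(0))·n(t)` (Gaussian kernel variance
  5), so the whole pipeline is testable without any data download.
- **I/O and CLI** (`reconparc.io`, `reconparc.cli`) — NIfTI volumes, masks
  and label volumes; JSON networks; tidy CSV/TSV analytics; subcommands
  `simulate`, `parcellate`, `build-net`, `analyze`, `run-all`.

## Worked example

Generate a two-window planted dataset, re-optimize ROIs per window with the
min-correlation greedy grower, and read off the stability scores:

```python
import numpy as np
from reconparc import (
    SyntheticConfig, generate_reconfiguring_dataset, greedy_grow, GreedyConfig,
    exclude_single_voxel_rois, build_network, spatial_consistency,
)
from reconparc.analysis import all_stability_scores

cfg = SyntheticConfig(grid_shape=(8, 8, 4), n_rois=6, n_timepoints=160,
                      n_windows=2, noise_amplitude=0.1, noise_seed=7)
volume, planted = generate_reconfiguring_dataset(cfg)

parcels = []
for i in range(2):
    window = volume.crop_time(80 * i, 80 * (i + 1))
    parc = greedy_grow(window, planted[i].seeds,
                       GreedyConfig(priority_kind="min_correlation",
                                    apply_threshold=False))
    parc, n_single = exclude_single_voxel_rois(parc)
    parc.window_index = i
    parcels.append(parc)
    phis = [spatial_consistency(window, parc.voxels(l)) for l in parc.labels()]
    print(f"window {i}: {parc.n_rois} ROIs, mean consistency {np.mean(phis):.3f}")

net = build_network(volume, parcels, window_length=80)
print(f"network: {len(net.nodes)} nodes, {len(net.interlayer)} interlayer edges")
for node, score in all_stability_scores(net).items():
    print(f"  ROI {node[1]} on layer {node[0]}: stability {score:.3f}")
```

This prints:

```
window 0: 6 ROIs, mean consistency 0.866
window 1: 6 ROIs, mean consistency 0.910
network: 12 nodes, 18 interlayer edges
  ROI 1 on layer 0: stability 0.649
  ROI 2 on layer 0: stability 0.806
  ROI 3 on layer 0: stability 0.462
  ROI 4 on layer 0: stability 0.750
  ROI 5 on layer 0: stability 0.537
  ROI 6 on layer 0: stability 0.371
```

The recovered ROIs are highly homogeneous (mean consistency ≈ 0.9, since the
generator plants strongly correlated parcels), and the stability scores are
spread well below 1: 30% of the planted seeds were relocated between the two
windows, so the optimized ROIs genuinely reconfigure — exactly the behavior
the multiplex model cannot represent.

The same pipeline from the shell:

```bash
reconparc simulate --out data --grid 8 8 4 --n-rois 6 --n-timepoints 160 \
    --n-windows 2 --seed 7
reconparc run-all --volume data/volume.nii --mask data/mask.nii \
    --method greedy_minc --n-rois 6 --window-length 80 --out results
```

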