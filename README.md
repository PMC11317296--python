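# lynsu

Two-stage neuropil segmentation for 3D fluorescence brain stacks, with
bilateral volume asymmetry morphometry and a synthetic phantom generator.

**Stage 1** collapses a stack into max/mean Z-projections and locates
region-of-interest (ROI) boxes for three classes (`AL`, `MB_CAL`, `CX`)
with a compact trainable detector, scored by mAP@0.5:0.95 and a strict
coverage-success criterion (a detection succeeds only if the box contains
the entire structure).

**Stage 2** extrudes each box through Z, standardizes the region to a
fixed 124x168x168 grid (Z zero-padding, XY resampling), tiles it into
overlapping 64x128x128 cubes at stride 20 (with Z-mirrored copies for
training augmentation), and segments it with a residual 3D
encoder-decoder trained under a weighted-Dice (0.4 background / 0.6
neuropil) + categorical-focal composite loss. Cube predictions are fused
by probability averaging and restored to the original stack geometry.

**Morphometry** filters segmented cohorts to masks with exactly two
26-connected components (largest at most twice the second), measures
left/right volumes against an annotated midline column, and summarizes
signed percent volume differences, including cross-model consistency
regression.

Everything trains and evaluates on **synthetic phantoms**: textured
stacks containing bilateral and midline ellipsoid-composite structures
with exact masks, tight boxes, a known midline, and a controllable planted
left/right volume asymmetry.

The neural models run on a small numpy/numba backend (hand-written
convolutions and backprop) so the whole pipeline is CPU-trainable and has
no deep-learning-framework dependency.

## CLI

```sh
lynsu synth --n 8 --seed 0 --asymmetry 0.1 --out data/        # phantoms
lynsu project data/stacks/phantom-000123.tif --out proj/      # Z-projections
lynsu detect-train --data data/ --epochs 30 --out det.npz     # stage 1
lynsu detect --model det.npz --in stack.tif --out boxes.txt
lynsu cubes --structure MB_CAL --data data/ --out cubes/      # augmentation
lynsu seg-train --structure MB_CAL --data data/ --out seg.npz # stage 2
lynsu segment --model seg.npz --stack stack.tif --boxes boxes.txt \
      --structure MB_CAL --out mask.tif
lynsu eval --gt gt_masks/ --pred pred_masks/ --out metrics.csv
lynsu cohort --masks masks/ --manifest data/manifest.csv --out summary.csv
```

`lynsu convert`/`lynsu inspect` handle 8-bit multi-page TIFF stacks
(`--rescale` min-max maps wider bit depths). Box files use the
normalized-centre text dialect (`class cx cy w h [conf]`).

## Layout

| module | contents |
| --- | --- |
| `lynsu.io_formats` | `VolumeStack` / `LabelVolume` / `BoundingBox2D`, TIFF + box-file I/O, coordinate conventions |
| `lynsu.phantoms` | phantom specs, generator, cohort sampling |
| `lynsu.projection` | max/mean Z-projections |
| `lynsu.detection` | detector config/model/training, NMS, mAP, coverage success |
| `lynsu.roi` | box→3D region, standardization, sliding windows, stitching, restore |
| `lynsu.segmentation` | loss formulas, 3D encoder-decoder, training protocol, per-ROI prediction |
| `lynsu.evaluation` | confusion counts, recall/precision/F1/3D-IoU, annotator consistency |
| `lynsu.morphometry` | component filter, bilateral volumes, hemisphere difference, cohort summaries |
| `lynsu._nn` | numpy/numba conv layers, pooling, Adam |
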