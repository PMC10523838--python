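# somaswin

Automated 2D detection and segmentation of fluorescent neuronal cell
bodies (somas) in two-photon images of thick acute brain slices, built
around a hierarchical shifted-window (Swin) transformer.

Measuring somatic areas matters for quantifying neuronal swelling under
physiological and pathological conditions (e.g. NMDA-induced cytotoxic
edema), but manual tracing is slow, biased and incomplete — especially
for calcium indicators such as GCaMP6s whose brightness fluctuates with
activity, and in thick slices where the neuropil produces dense
low-contrast background.  `somaswin` provides the full pipeline:

* **simulate** — copy-paste synthetic training data: neuropil background
  tiles shuffled and feather-blended into full backgrounds, annotated (or
  parametrically rendered) soma crops pasted with feathered alpha
  compositing and per-instance ground-truth masks, plus salt-and-pepper
  corruption; byte-reproducible from `(config, seed)`.
* **preprocess** — rolling-ball-style background subtraction, radius-2
  median filter, maximum-intensity projection every 10 slices (20 µm at
  2 µm steps), and CLAHE.
* **backbone / detector** — a from-scratch Swin transformer (4×4 patch
  tokens, linear embedding to C = 96, W-MSA/SW-MSA block pairs with
  windowed multi-head attention and cyclic shifts, 2×2 patch merging;
  stages at H/4 … H/32 with channels C, 2C, 4C, 8C) feeding a
  proposal-free segmentation head; instances carry confidence scores and
  are kept above a configurable threshold (default 0.05, favouring
  recall).  Runs — and trains — on plain NumPy via a built-in autograd
  engine, one CPU is enough for the small configurations.
* **metrics** — Dice = 2|X∩Y|/(|X|+|Y|), IOU = |X∩Y|/|X∪Y|, per-ground-
  truth highest-Dice matching with TP at IOU > 0.5, FP sub-typing
  (wrong boundary / background / doublet), precision, recall, yield
  rate, somatic areas in µm², OLS area agreement, and confidence
  threshold sweeps.

The training interface is scikit-learn style: `SomaSwinSegmenter` is a
`BaseEstimator` with `fit(images, instance_masks)` and
`predict(images)`, so it composes with sklearn model-selection tooling.

## Worked example

```python
import numpy as np
from somaswin import (GeneratorConfig, SomaSwinSegmenter,
                      match_instances, recall)
from somaswin.simulate import (build_cell_bank, build_tile_bank,
                               synthesize_image)

cfg = GeneratorConfig(n_images=16, image_size=(64, 64),
                      cells_per_image=(2, 4), max_pairwise_overlap_iou=0.0,
                      min_separation_px=3, condition_mix=(0.0, 0.6, 0.4),
                      seed=11)
rng = np.random.default_rng(1)
cells = build_cell_bank(24, rng, condition_mix=(0.0, 0.6, 0.4),
                        radius_range=(4.0, 7.0))
tiles = build_tile_bank(12, (32, 32), rng)
images, gt = [], []
for i in range(16):
    syn = synthesize_image(cfg, cells, tiles, 1000 + i)
    images.append(syn.pixels)
    gt.append(syn.instances)

est = SomaSwinSegmenter(embed_dim=32, depths=(1, 1, 1, 1),
                        num_heads=(2, 4, 8, 16), window_size=4,
                        fuse_dim=32, epochs=300, batch_size=4,
                        lr=3e-3, seed=0)
est.fit(images, gt)
preds = est.predict(images, threshold=0.05)
tp = fn = 0
for masks, ps in zip(gt, preds):
    res = match_instances(masks, [p.mask for p in ps], iou_threshold=0.5)
    tp, fn = tp + res.tp, fn + res.fn
print(f"loss {est.loss_history_[0]:.3f} -> {est.loss_history_[-1]:.3f}, "
      f"recall {recall(tp, fn):.2f} on {tp + fn} somas")
```

Output on one CPU (a few minutes):

```
loss 0.816 -> 0.037, recall 1.00 on 52 somas
```

meaning the pixel-wise training loss fell from chance level to near
convergence and every ground-truth soma in the fixture was recovered
with mask IOU above 0.5 at the 0.05 confidence threshold.

The same flow is available from the shell:

```sh
somaswin simulate  --config run.yaml --out data/ --seed 5
somaswin preprocess --in stack.tif --window 10 --out mips/
somaswin train     --config run.yaml --data data/manifest.json --out model.npz
somaswin predict   --ckpt model.npz --in mips/mip_0000.tif --threshold 0.05 --out pred.json
somaswin evaluate  --pred pred.json --gt data/annotations.json \
                   --iou-threshold 0.5 --thresholds 0.05,0.1,0.2,0.4
```

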