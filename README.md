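# papillae

Automatic detection and counting of **fungiform papillae** (FPs) — the
mushroom-shaped, taste-bud-bearing structures of the anterior tongue — in
photographs of blue-dye-stained tongue regions. FP density is a standard
proxy for taste function, and counting FPs by eye is slow and
observer-dependent; this package automates it with convolutional
heatmap regression.

## Method

Given a stained-tongue photograph, the pipeline:

1. segments the stained region, fits an ellipse to it, crops a square
   around the ellipse, resizes to 250 × 250, and applies CLAHE contrast
   normalization;
2. converts point annotations of FP centers into continuous ground-truth
   maps by placing a unit-peak Gaussian `G(x) = exp(-‖x − c‖² / 2σ²)` at
   each center `c` (σ = 3 px by default), combined pixelwise by maximum;
3. trains encoder–decoder networks — **Classic U-Net**, **MultiResUNet**,
   and an **Optimized U-Net** (slimmer filter plan 64/64/128/256 with
   middle 512, BatchNorm, Dropout) — to regress these maps with MSE loss,
   a linear final activation, Adam (lr 1e-3), batch size 2, and 5-fold
   cross-validation;
4. extracts predicted FP coordinates by local peak detection and matches
   them one-to-one to the annotations within a radius `r` (default 5 px),
   yielding true positives (TP), spurious detections (UP) and missed
   papillae (UN), and the rates

   ```
   TP rate           = TP / |ground truth| · 100 %
   accurate count    = TP / (TP + UP)      · 100 %
   complete accuracy = TP / (TP + UP + UN) · 100 %
   ```

   alongside MAE, SSIM and Dice between predicted and ground-truth maps,
   aggregated as mean ± SD across folds.

The networks run on a compact NumPy computation-graph engine (im2col
convolutions over BLAS, explicit backpropagation, Adam), so the whole
pipeline is a pure scientific-Python stack. A synthetic scene generator
renders stained-region images with known FP coordinates — blue stain
ellipse, darker filiform speckle, lighter soft-edged spots — so every
stage is testable end to end without clinical data.

## Worked example

```python
import dataclasses
from papillae import (desk_profile, generate_samples, make_training_pairs,
                      optimized_unet_spec, train_model, evaluate_fold)

prof = desk_profile(seed=1)                      # 128x128 scenes, 50 epochs
scenes = generate_samples(40, prof.scene)
pairs = make_training_pairs(scenes, prof.heatmap)
ids = [s.sample_id for s in scenes]
spec = prof.scaled(optimized_unet_spec())        # width-scaled for CPU
cfg = dataclasses.replace(prof.training, seed=1)
model, hist = train_model(spec, [pairs[i] for i in ids[:32]],
                          [pairs[i] for i in ids[32:]], cfg)
by_id = {s.sample_id: s for s in scenes}
val = [(i, by_id[i].image.pixels, by_id[i].annotations) for i in ids[32:]]
rep = evaluate_fold(model, val, prof.heatmap, radius=prof.match_radius)
print(f"epoch-1 MSE {hist.train_mse[0]:.3f} -> epoch-50 MSE {hist.train_mse[-1]:.4f}")
r = rep.rates
print(f"TP {r.tp_rate_pct:.1f}%  UP {r.up_rate_pct:.1f}%  UN {r.un_rate_pct:.1f}%")
print(f"MAE {rep.aggregates['mae'][0]:.4f}  SSIM {rep.aggregates['ssim'][0]:.3f}  "
      f"Dice {rep.aggregates['dice'][0]:.3f}")
```

prints

```
epoch-1 MSE 0.527 -> epoch-50 MSE 0.0046
TP 98.4%  UP 0.5%  UN 1.6%
MAE 0.0180  SSIM 0.829  Dice 0.672
```

i.e. after 50 epochs on 32 synthetic scenes the model recovers 98.4 % of
the held-out papillae with 0.5 % spurious detections; MAE/SSIM/Dice
measure the pixel-level agreement between predicted and ground-truth
heatmaps. The same pipeline is available from the shell:

```bash
papillae simulate --n 40 --out data/ --seed 1
papillae make-gt  --annotations data/ --shape 128 --sigma 2 --out gt/
papillae train    --data data/ --arch optimized_unet --out runs/ --seed 1
papillae evaluate --run runs/ --data data/ --out report/
```

See `docs/methods.md` for the model, parameter, and preset details.

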