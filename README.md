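# holocount

Label-free cell detection and counting **directly from raw off-axis
digital-holographic-microscopy (DHM) diffraction patterns**, using a fully
convolutional encoder–decoder and a morphological counting chain.

## The problem

DHM records the interference between light that has passed a semi-transparent
specimen (such as red blood cells) and a tilted reference beam.  Counting
cells normally requires first reconstructing a quantitative phase image from
the hologram — spatial filtering, demodulation, sometimes unwrapping and
numerical propagation — before any segmentation can run.  This package
implements the alternative: a UNet-style network is trained to segment cells
in the *raw hologram itself*, where cell edges are buried in carrier fringes,
so the reconstruction step disappears from the analysis path entirely.  It is
aimed at people building high-throughput label-free cytometry pipelines and
at anyone who wants a self-contained, CPU-trainable reference implementation
of the hologram-to-count approach.

## The method

- **Network**: encoder–decoder FCN (UNet) with (3×3 conv + ReLU)×2 blocks,
  2×2 max-pooling, 2×2 stride-2 up-convolutions with skip concatenations, and
  a 1×1 conv + sigmoid head producing a per-pixel foreground probability map
  ỹ the same size as the input.  Implemented in numpy with hand-written
  backpropagation (finite-difference verified), so training needs nothing
  beyond the scientific Python stack.
- **Loss**: soft Dice plus binary cross entropy,
  `L = (1 − 2Σyỹ/Σ(y+ỹ)) − (1/N)Σ[y·log ỹ + (1−y)·log(1−ỹ)]`,
  optimized with SGD (momentum 0.9, lr 0.01 decayed 10× every 30 epochs,
  weight decay 1e-4, batch 4).
- **Counting**: threshold 0.5 (strict) → morphological opening with a
  radius-3 disk → connected-component labeling → removal of border-touching
  components smaller than 40 px (applied to ground truth too) → the maximum
  label is the cell count.
- **Evaluation**: pixel sensitivity/accuracy/Dice, (95th-percentile)
  Hausdorff boundary distance, and a centroid matching rule that classifies
  each predicted component as correctly counted or over-counted.
- **Simulator**: because real labeled DHM recordings are not distributed,
  `sim_dhm` generates off-axis holograms of cosine-taper phase discs
  (λ = 682 nm, tunable carrier, angular-spectrum defocus, additive intensity
  noise) with exact ground-truth masks, plus the classical Fourier-sideband
  phase reconstruction as a round-trip oracle.

See `docs/methods.md` for the full model description, parameter defaults and
design rationale.

## Worked example

Train the desk-scale model on 200 simulated holograms and count cells on 30
held-out images (about five minutes on one CPU):

```python
import numpy as np
from holocount import sim_dhm, training, metrics
from holocount.fcn_model import build_model
from holocount.data_pipeline import normalize

prof = training.desk_profile(seed=1)          # 128x128 scenes, 5-15 cells
rng = np.random.default_rng(1)
train_set = [sim_dhm.generate_sample(prof["sim"], rng=rng)[:2] for _ in range(200)]
test_set  = [sim_dhm.generate_sample(prof["sim"], rng=rng)[:2] for _ in range(30)]

model = build_model(prof["model"], seed=1)
model, curve = training.train(model, train_set, test_set,
                              prof["train"], prof["augment"])

probs = [model.forward(normalize(img, model.norm_stats)[None, None])[0, 0]
         for img, _ in test_set]
table, _ = metrics.evaluate_set(probs, [m for _, m in test_set])
gt = table["gt_total"].sum()
print(f"mean DSC            {table['dsc'].mean():.4f}")
print(f"counting accuracy   {table['correct'].sum() / gt:.4f}")
print(f"over-counted rate   {table['over'].sum() / gt:.4f}")
```

Output:

```
mean DSC            0.9780
counting accuracy   0.9789
over-counted rate   0.0000
```

The mean Dice says that 97.8% of predicted foreground overlaps the true cell
supports; of the 284 cells present in the 30 test holograms, 97.9% are
matched one-to-one by a predicted component whose centroid falls inside them,
and no component is an over-count.

The same pipeline is available from the shell:

```sh
holocount simulate --config run.yaml      # hologram/mask pairs + manifest
holocount train    --config run.yaml      # checkpoint + learning curve
holocount count    --config run.yaml model.npz holo_0001.tif
holocount evaluate --config run.yaml --pred-dir preds/ --truth-dir truth/
```

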