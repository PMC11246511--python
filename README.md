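# spinerecon

3D vertebra shape reconstruction from orthogonal bi-planar radiographs.

Clinically, the 3D arrangement of vertebrae under natural, upright weight
bearing matters for spine diagnosis and surgical planning, but volumetric
modalities (CT/MRI) image patients lying down, while standing radiographs
are only 2D projections. `spinerecon` implements an adversarially trained
reconstruction pipeline that recovers the 3D binary occupancy of an
*individual* vertebra from a pair of orthogonal radiograph patches (coronal
+ sagittal), each annotated with a centroid mask marking the target
vertebra, and reassembles per-vertebra reconstructions into a labelled
spine. It is aimed at researchers in medical image analysis who want a
fully testable, CPU-reproducible reference implementation of this class of
model, including the data machinery around it.

## What is inside

* **Generator** `G`: per-view *centroid fusion* (channel-concatenate patch
  and centroid mask → conv stem → non-local self-attention block
  `y = x + W_o(softmax(θ(x)ᵀφ(x))σ(x)ᵀ)`), *2D–3D lifting* (each S×S view
  duplicated S times along its projection axis into a shared S³ frame), and
  a 3D residual U-Net with batch norm and skip connections ending in a
  sigmoid occupancy head.
* **Discriminator** `D`: PatchGAN-style stack of stride-2 3D convolutions
  producing a spatial real/fake score map.
* **Integrated loss** `L = λ·L_Dice + α·L_Hausdorff + β·L_Focal + γ·L_GAN`
  with defaults (10, 1e-4, 10, 0.1); focal α_t = 0.2, γ_f = 5; least-squares
  adversarial objectives; the Hausdorff term is the distance-transform
  surrogate `mean((p−q)²·(d_p² + d_q²))`.
* **Data machinery**: synthetic spine phantoms with labels and centroids,
  parallel-beam DRR projection, patch/centroid-mask construction,
  VerSe-style NIfTI + centroid-JSON ingestion, the whole-spine cohort
  exclusion rules, and patient-level 4:1 splitting.
* **Evaluation**: Dice, HD95 and normalized surface distance (NSD), all
  cross-checked against brute-force oracles in the test suite.

The networks, their backward passes and the Adam training loop are written
directly in NumPy (`spinerecon.nn`) — deterministic, single-threaded and
validated by finite-difference gradient checks — so every result in the
package is reproducible bit-for-bit from a seed on any CPU.

## Worked example

```python
import numpy as np
from spinerecon import (PhantomSpec, make_spine_phantom, build_pairs,
                        ReconstructionModel)
from spinerecon.network import desk_generator_config, desk_discriminator_config
from spinerecon.train import desk_train_config

# 10 synthetic training spines and 3 held-out spines, 4 vertebrae each
records = [make_spine_phantom(PhantomSpec(seed=i)) for i in range(13)]
train = [p for r in records[:10] for p in build_pairs(r, size=32, radius=2)]
held = [p for r in records[10:] for p in build_pairs(r, size=32, radius=2)]

model = ReconstructionModel(train,
                            desk_train_config(seed=0),
                            desk_generator_config(),
                            desk_discriminator_config())
results = model.fit()
print(results.summary(eval_pairs=held))
```

```
Bi-planar vertebra reconstruction — fit summary
================================================
training pairs:        40
patch size S:          32
generator parameters:  109421
steps run:             200 (epochs 10, batch 2)
final losses:          dice=0.1143 hausdorff=0.0342 focal=0.0003 adv=1.0160 (integrated 1.2471)
final learning rate:   0.002
held-out (n=12):   dice=0.8935 hd95=1.4274 mm nsd=0.8995
```

The held-out block is the part to read: Dice is volume overlap (1 = perfect),
HD95 the 95th-percentile surface distance in mm (lower is better), NSD the
fraction of surface within 1 mm of the reference (1 = perfect). An untrained
generator scores Dice ≈ 0.15 on the same pairs, so the fit recovers most of
the vertebral shape from the two projections. A full-scale configuration
(S = 120, 100 epochs, batch 8, lr 1e-4 decaying ×0.1 every 20 epochs) is the
package default for `TrainConfig`/`GeneratorConfig` but needs GPU-class
compute; the desk preset exists so that everything can be exercised in
minutes on one CPU.

The same pipeline is scriptable from the shell:

```bash
spinerecon phantom --out cases/ --n-cases 13 --n-vertebrae 4 --seed 0
spinerecon build --case-dir cases/ --out pairs.npz --size 32 --radius 2
spinerecon train --pairs pairs.npz --out run/ --desk --seed 0
spinerecon evaluate --weights run/generator.npz --pairs pairs.npz --out metrics.csv
spinerecon assemble --weights run/generator.npz --pairs pairs.npz \
    --canvas 64 64 96 --out spine.nii.gz
```

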