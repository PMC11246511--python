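# Methods

## Problem and model

`spinerecon` reconstructs the 3D binary shape of a single vertebra from two
orthogonal 2D radiograph patches — one coronal (anterior–posterior) and one
sagittal (left–right) — each annotated with a centroid mask that marks which
vertebra in the patch is to be reconstructed. Upright bi-planar radiographs
are often the only imaging available for weight-bearing spinal analysis;
recovering per-vertebra 3D occupancy from them is posed here as a
conditional generative task trained adversarially against ground-truth CT
segmentations.

The generator has three stages:

1. **Centroid fusion.** Per view, the patch and its centroid mask are
   channel-concatenated, passed through a convolutional stem, and then a
   *non-local* self-attention block:

   `y = x + W_o ( softmax(θ(x)ᵀ φ(x)) σ(x)ᵀ )`

   where θ, φ, σ are 1×1 convolutions to C/2 channels, the softmax runs over
   all N = H·W key positions for each query position, and `W_o` is a 1×1
   output projection back to C channels, added residually. Attention lets
   the single centroid disk modulate every pixel, disambiguating the target
   vertebra from neighbours visible in the same patch.

2. **2D–3D lifting.** With exactly orthogonal parallel-beam views, the
   coronal feature map (axes: sagittal × axial) is duplicated S times along
   the anterior–posterior axis and the sagittal feature map (coronal ×
   axial) S times along the left–right axis; both land in a shared
   (sagittal, coronal, axial) frame and are channel-concatenated. This is an
   exact adjoint-friendly operation: the backward pass is a sum over the
   duplicated axis.

3. **3D residual U-Net.** Encoder–decoder with residual conv blocks, batch
   normalisation, stride-2 convolution downsampling, nearest-neighbour ×2
   upsampling + convolution, channel-concatenated skip connections, and a
   1-channel sigmoid head producing a soft occupancy volume in (0,1).
   Nearest-neighbour upsampling (rather than trilinear) was chosen because
   its adjoint is an exact 2×2×2 block sum, keeping the hand-written
   backward pass simple and bit-reproducible; at these scales the
   interpolation scheme is immaterial to accuracy.

The discriminator is a PatchGAN-style fully convolutional stack of four
stride-2 3D convolutions (leaky ReLU, batch norm except on the first layer)
emitting a spatial map of real/fake scores — no global pooling — so the
adversarial signal is local and shape-detail oriented. It is unconditional:
it scores occupancy volumes alone.

## Objective

The generator minimises

`L = λ·L_Dice + α_w·L_Hausdorff + β·L_Focal + γ·L_GAN(G)`

with defaults λ=10, α_w=1e-4, β=10, γ=0.1.

* **Dice**: `1 − 2⟨p,q⟩/(Σp + Σq + ε)`, ε=1e-6 — region overlap, robust to
  the extreme foreground/background imbalance of a vertebra in a 120³ box.
* **Hausdorff (distance-transform surrogate)**: mean over the voxel domain
  of `(p−q)² · (d_p^a + d_q^a)` where `d_q` is the Euclidean distance
  transform to the ground-truth boundary, `d_p` the same for the prediction
  thresholded at 0.5, and a=2 (the exponent is configurable;
  2 follows the established distance-transform Hausdorff-loss form). The
  distance maps are recomputed each step and treated as constants in the
  gradient — differentiating through a distance transform is ill-defined.
  Boundary = foreground voxel with a background 6-neighbour, volume border
  counting as background; an empty mask contributes a zero distance map, so
  the term degrades to a plain squared error.
* **Focal**: mean of `−α_t (1−p_t)^γ_f log(p_t)` with α_t=0.2 on foreground,
  1−α_t on background, γ_f=5; predictions clamped to [1e-7, 1−1e-7].
* **Adversarial (least squares)**: `G` minimises mean `(D(G(x))−1)²`; `D`
  minimises `(D(y)−1)² + D(G(x))²`, unweighted. 1:1 alternation, no gradient
  penalty or label smoothing.

## Implementation of the networks

All layers, their backward passes, and the Adam loop are written directly in
NumPy (`spinerecon.nn`): convolutions as sums of k³ shifted einsum
contractions (whose adjoint is the same shifts transposed), explicit
batch-norm and softmax-attention Jacobians, and a deterministic Adam with
betas (0.5, 0.9) — the usual GAN setting; the published configuration names
only the optimiser. Everything is single-threaded, seeded, and
bit-reproducible, which is what makes the training-determinism tests
possible. Every layer's gradient is validated against central finite
differences in float64 (tolerance 1e-6); the composite generator is checked
end-to-end with a bulk criterion because ReLU kinks make isolated finite
differences unreliable.

Weight init: conv weights ~ N(0, 0.02²), batch-norm γ=1/β=0, all from one
`numpy.random.Generator` seeded by the run seed.

## Data

**Phantoms.** Each synthetic vertebra is an elliptic-cylinder body (radii
and height drawn per vertebra) with a posterior spinous-process bar and two
lateral transverse-process bars, stacked along the axial axis with a
configurable minimum gap; labels are consecutive integers with anatomical
position codes (alphabet C1–C7, T1–T13, L1–L6, exposed as configuration
since the thoracolumbar count varies anatomically). Intensity is two-level
(bone 1000, background 50) plus additive Gaussian noise (σ=20) clipped at 0.
What the phantom reproduces: per-vertebra connected shapes with processes,
inter-vertebra proximity, bone/soft-tissue contrast, annotation geometry.
What it does not: realistic vertebral anatomy (endplates, pedicles, cortical
vs trabecular bone), ribs and other occluding structures, scanner physics.
Passing the recovery experiment therefore demonstrates that the pipeline and
optimisation work end-to-end, not clinical-grade accuracy on real
radiographs.

**DRRs.** Orthographic parallel-beam line integrals (axis sums), per-patch
min–max normalised to [0,1]. No Beer–Lambert log transform, divergent-beam
geometry, scatter or beam hardening: the lifting stage duplicates features
uniformly along the ray axis, which is only geometrically consistent with
parallel rays, and the input conditioning a network needs is the min–max
range, not radiometric calibration. Views are assumed exactly orthogonal
(90°); no view-angle parameter is exposed.

**Patches.** 120×120 crops centred on the projected vertebra centroid (the
training-scale setting; the centre pixel of an even-sized crop sits at index
size/2, and off-image regions are zero-filled). The centroid annotation is a
binary disk, default radius 4 px, carried as a second input channel — the
simplest annotation an attention block can exploit. The supervised target is
the axis-aligned size³ window of the annotated vertebra's binary mask only,
never a union with neighbours.

**VerSe-style cases.** NIfTI CT + label volumes with a JSON centroid file
(integer anatomical codes: 1–7 cervical, 8–19 thoracic, 20–25 lumbar, 28 =
T13). The small-cohort filter excludes whole spines containing T13/L6/any
cervical vertebra, spines with ≤ 2 annotated thoracic vertebrae, and spines
flagged for metal occlusion (a sidecar flag — no image-based detection).
Rules are applied in that order and only the first matching rule is
recorded; membership is order-independent. Train/test splitting is by
patient at a 4:1 ratio.

## Evaluation

Dice coefficient, HD95 and normalized surface distance (NSD), computed on
surface voxels (foreground with a background 6-neighbour, border counting as
background). Directed nearest-surface distances are pooled over both
directions before taking the 95th percentile (linear interpolation) for
HD95 or the within-tolerance fraction for NSD. Conventions that the
literature leaves open and that change absolute values — pooled vs per-
direction percentiles, voxel-centre surfaces, and the NSD tolerance
(default 1.0 mm, CLI-exposed) — are fixed as stated here. Empty masks yield
NaN sentinels excluded from aggregation; Dice of an empty prediction
against a nonempty target is 0. Both metrics are verified against all-pairs
brute-force oracles on small random masks.

## Desk-scale experiment and problem sizes

Full-scale training (120³ outputs, 100 epochs, batch 8) needs GPU hardware;
the package's reference experiment is deliberately CPU-sized: 13 phantom
spines × 4 vertebrae (10 subjects → 40 training pairs, 3 subjects → 12
held-out pairs), S = 32 patches, generator depth 3 / base 8 / fusion 4,
discriminator base 4, batch 2, 200 steps at lr 2e-3 (the desk preset's
learning rate was set by a pilot run; the full-scale default remains 1e-4
with ×0.1 decay every 20 epochs). A run takes a few minutes on one CPU
and reliably reaches held-out Dice well above the untrained baseline
(~0.14, i.e. thresholding a random sigmoid field).

## Numerical choices and degenerate inputs

* Binarisation threshold 0.5 for reconstruction (monotone: raising it never
  adds voxels); empty predictions are valid and flagged.
* Spine assembly pastes each vertebra at its crop offset; overlapping claims
  resolve to the higher generator probability, exact ties to the
  later-indexed vertebra.
* Min–max normalising a constant image returns all zeros (declared
  convention).
* Dice of two empty masks is defined as 1; ε-smoothing keeps the loss finite
  when either side is empty.
* Checkpoints round-trip bit-exactly (named parameter arrays + architecture
  config in one `.npz`).

## Known limitations

Hand-written NumPy training is orders of magnitude slower than GPU
frameworks and is intended for correctness, testing and small studies, not
full-scale benchmarking. The phantom's anatomical realism is minimal (see
above). Absolute HD95/NSD values depend on the stated surface conventions
and tolerance; comparisons across implementations should align those first.
The discriminator is unconditional; a conditional variant (scoring the
input–output pair) is a possible extension the current loss definitions do
not require.
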