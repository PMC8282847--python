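# Methods

`emrestore` implements a learned post-processing operation for cryo-EM
density maps: a 3D U-net regression model that, given a raw (unsharpened,
unmasked) map, produces a map resembling a tightly masked, locally
sharpened reference — performing masking-like and sharpening-like
operations in a single step.  This note documents the model, the
surrounding pipeline, the synthetic data the package trains and validates
on, and the numerical and design choices made where the design was open.

## Pipeline

Maps are 3D scalar grids (`DensityMap`) carrying an isotropic voxel size
(Å/voxel) and a physical origin, held internally in `(z, y, x)` axis order;
MRC/CCP4 files are read and written through gemmi, with MAPC/MAPR/MAPS axis
permutations normalized on read.  Processing a map runs:

1. **Half-map averaging** (when two half maps are given): the full map is
   the voxel-wise mean; independent half-map noise variance halves.
2. **Resampling to the 1 Å/voxel working grid**, so molecular features span
   a fixed number of voxels regardless of deposited sampling.  The resize
   is a Fourier-space zero-pad/crop of the centred spectrum: exactly
   band-limited, linear and deterministic (a real-space cubic-spline
   alternative is available behind a flag).  Output shape per axis is
   `round(n · voxel/target)` (round-half-away-from-zero); a
   `ResampleRecord` stores the originals so the inverse is unambiguous.
3. **Noise-statistics normalization**: the map is affinely rescaled so its
   noise (solvent) region has mean 0 and standard deviation 0.1.  The noise
   region, when no explicit mask is given, is the set of voxels outside the
   centred sphere of radius `0.9 · min(shape)/2` *and* within the outer 15%
   shell of the box — deposited particles are centred and boxed with
   margin, so these voxels are overwhelmingly solvent.  The standard
   deviation is computed after discarding values beyond 4 MADs from the
   noise median, so stray signal in the shell cannot inflate it.  All
   normalization parameters are recorded in run metadata.
4. **Chunking**: the volume is covered with cubes (64 voxels at inference,
   stride 16).  Per axis of length `N`, cube origins are `0, s, 2s, …`
   capped at `N − c`, with the final origin clamped to exactly `N − c`;
   clamping (rather than discarding partial windows or reflect-padding)
   guarantees full coverage with at most one irregular step per axis.
   Volumes smaller than the cube are padded with the post-normalization
   noise mean (≈0) and cropped again after reassembly.
5. **Cube-wise inference** through the network, then **overlap-averaged
   reassembly**: each voxel is the arithmetic mean over all cubes covering
   it.  Extraction∘assembly is the identity for any valid grid.
6. **Resize to the original grid** via the recorded `ResampleRecord`.

The chain is deterministic end to end: same input + checkpoint ⇒ identical
output.  By default the output stays on the network's target scale (the
masked-sharpened convention); `denormalize=True` maps intensities back
through the recorded normalization.

## Network

A 3-level volumetric U-net:

* encoder: per level, three convolutions (kernel 3, same padding) each
  followed by group normalization and channel-wise PReLU; stride-2 strided
  convolution between levels (doubling channels);
* channel widths 32/64/128 (a reduced 8/16/32 variant is used for
  CPU-scale experiments; any widths divisible by the group count are
  constructible through the same code path);
* decoder: kernel-2 stride-2 transposed convolution (each output voxel
  receives exactly one kernel tap, avoiding checkerboard artifacts),
  concatenation with the matching encoder output, then three conv blocks;
* final 1×1×1 linear convolution to one channel, no output activation
  (negative outputs are kept; clipping is a display concern).

Choices the architecture description leaves open and how they were fixed:
kernel size 3 with same padding (standard U-net practice; keeps 64³→64³);
`norm_groups = 8` (divides 32/64/128; configurable); skips are
concatenation, not addition; PReLU has one learnable slope per channel
(init 0.25).  The final projection's He initialization is down-scaled by
0.1 (`final_init_scale`): group normalization pins internal activations at
O(1) while the masked targets are much smaller, so a full-scale final layer
starts training far from the data; the down-scaled init starts near the
zero map (the better constant predictor for tightly masked targets)
without zeroing the layer, which would cut off backpropagation entirely.

The layers — convolution, transposed convolution, group norm, PReLU — are
implemented directly on NumPy with hand-written backward passes;
convolutions are evaluated as BLAS GEMMs over shifted views of the padded
input.  Every backward pass is pinned by finite-difference gradient checks
in the test suite (in float64, to two or more significant digits per
sampled parameter).  Group-norm statistics never mix samples, so the
forward pass is independent of batch composition and identical in train
and eval mode; with fixed weights it is bitwise reproducible.

## Training

Stochastic gradient descent with batches of 8 cubes, mean-absolute-error
loss, initial learning rate 1e-3, halved whenever the best validation loss
fails to improve (by ≥1e-5 relative) for 5 consecutive epochs; the
patience counter resets on improvement and after each decay.  An epoch is
one seeded shuffle-pass over the training cubes; the returned model
carries the best-validation-epoch weights.  Heavy-ball momentum is
available (`TrainConfig.momentum`, default 0) and is used in the
CPU-scale benchmark (0.98): at a step budget of ~10³ updates rather than
the ~10⁵–10⁶ of a full-scale run, plain lr-1e-3 SGD cannot move the
network appreciably, and momentum raises the effective step size without
touching the prescribed learning rate.  Gradient clipping is available but
off by default — MAE gradients are bounded by construction (sign/N), and a
global-norm clip would uniformly rescale (slow) every update rather than
guard against rare spikes.

Augmentation, applied per pair at sampling time: one of the 24
axis-aligned cube orientations (applied identically to input and target);
Gaussian blurring of the input only (σ ~ U(0.3, 1.5) voxels); replacement
of a random sub-box of the input with N(0, 0.1) noise.  Blur and
corruption never touch the target: it is the clean supervision signal.
Default probabilities are 0.3 each.

Training pairs are built by `prepare.make_training_pairs`: inputs
noise-normalized, targets scaled so their in-mask 95th percentile is 1
(masked targets have no noise region, so noise-statistics normalization is
undefined for them; a fixed percentile gives every target a common scale),
both chunked with a shared grid (stride 32, i.e. 50% overlap, by default).
Cubes with ≥1% in-mask voxels count as *signal*; noise-only cubes are
retained but subsampled to ≤20% of the set — the network must see solvent
to learn to suppress it, but solvent must not dominate the loss.

## Synthetic data

The generator emulates the statistical structure of a (map, target) pair:

* **Pseudo-model**: a self-avoiding random walk with 3.8 Å steps (protein
  backbone Cα spacing), uniform amplitudes in [0.8, 1.2] and atomic
  B-factors in [5, 30] Ų.
* **Sharp reference map**: a sum of isotropic Gaussians, width
  σ² = B/(8π²) + σ₀² with σ₀ = 0.8 Å, each peaking at its atom's
  amplitude.
* **Degradation**: Fourier amplitudes attenuated by exp(−B·s²/4)
  (crystallographic amplitude convention — stated explicitly because B
  conventions differ by factors of 4), optionally blended position-wise
  between two attenuation levels using a smooth random weight field to
  mimic spatially varying local quality.  Two half maps add independent
  noise draws (white by default; optionally band-limited); the full map is
  their mean.  The Guinier slope of the degraded map recovers the imposed
  B, and half-map FSC resolution degrades monotonically with noise — both
  are tested.
* **Mask and target**: the sharp map thresholded at 5% of its maximum,
  dilated by a 2-voxel ball; the target is the sharp map times the mask.
* **Default study conditions**: 96³ boxes at 1 Å/voxel, 60–200 atoms,
  global B ∈ [50, 200] Ų, per-half-map noise set by a peak
  signal-to-noise ratio drawn from [2, 6].

Not emulated: electron scattering factors, CTF effects, reconstruction
artifacts, solvent/lipid density, map-to-map alignment errors.  Passing
tests on this generator show the pipeline machinery and training dynamics
behave as designed; they do not certify performance on experimental maps.

## Evaluation

FSC between maps A and B per spherical shell (one Fourier voxel wide;
anisotropic boxes use per-axis normalized frequency):
`FSC(s) = Re Σ F_A conj(F_B) / sqrt(Σ|F_A|² Σ|F_B|²)`.  The FFT shell sums
are checked against a direct-DFT brute force on 8³ maps.  Threshold
resolution takes the *first* crossing (DC shell excluded), linearly
interpolated in frequency; a curve that never drops below the threshold
reports the Nyquist resolution (2·voxel) with a `reached_nyquist` flag,
and a curve below threshold from the first shell reports infinity with a
`below_from_start` flag.  Masked FSC multiplies both maps by the mask
softened with a 3-voxel cosine edge (width configurable; 0 = hard mask) to
limit mask-correlation artifacts.  Real-space similarity is the Pearson
correlation over (optionally masked) voxels.

## Desk-scale benchmark

`benchmark.run_benchmark` runs the whole method end to end on one CPU
core: 40 synthetic 96³ maps (30 train / 10 held out), the reduced 8/16/32
U-net, batch 8, MAE, lr 1e-3 with plateau halving, momentum 0.98, 20
epochs.  Problem sizes were chosen so a single run completes in roughly a
quarter hour of one core; three of them matter scientifically and were
settled by controlled comparisons:

* **Training crops are 16³, with a deliberate composition**: per map, the
  8 most molecule-dense crops (from a stride-8 candidate grid), 8 more
  signal crops drawn at random, and ≤20% noise-only cubes.  The dense
  anchors are essential at this step budget — with tightly masked targets
  ~90% of voxels are zero, and the MAE objective otherwise drives the
  network into the zero-map constant predictor before any feature
  learning happens.  The random crops are equally essential: a network
  trained on dense crops alone emits a spatially structured solvent
  background at whole-map inference, which destroys the box-scale FSC
  shell against the (exactly zero-solvent) targets.
* **Rotation-only augmentation** (p = 0.3): the 24 axis-aligned cube
  orientations multiply the effective data and close most of the
  memorization gap at 30 training maps; input blurring and patch
  corruption remove too much local information at this crop size.
* **Inference uses the full 64³ cube at stride 32**: group-norm
  statistics stabilize with cube volume, and the 8-fold overlap averaging
  cancels cube-level artifacts.  In a sweep at fixed weights, held-out
  median FSC@0.5 resolution went from worse-than-input at 16³ inference
  cubes to best at 64³ — large-cube inference is part of why the
  full-scale pipeline chunks at 64³.

Reported quantities mirror the full-scale assessment: best validation MAE
against the input-as-prediction baseline, and median real-space CC and
median FSC@0.5 resolution of inputs vs predictions against the reference
targets on the held-out maps.

## Known limitations

* A from-scratch NumPy implementation on one CPU core supports ~10³
  optimizer steps in a practical budget, versus the ~10⁵–10⁶ steps of the
  a full-scale GPU training campaign; the desk-scale benchmark therefore probes
  the training *machinery* at the edge of what that step budget can learn,
  not the quality attainable by the method at scale (see the benchmark
  discussion above).
* The noise-region heuristic assumes a centred, margin-boxed particle;
  off-centre particles need an explicit noise mask.
* Group normalization ties cube statistics into the learned function, so
  predictions depend (mildly) on the inference cube size; large cubes
  (64³) with overlap averaging are the stable regime and the default.
* Anisotropic voxel sizes are rejected by default; an override resamples
  each axis independently.
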