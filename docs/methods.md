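# Methods

`mvseg` implements a one-step, six-class voxel classifier for co-registered
multi-sequence eye MRI — background, sclera, vitreous humour, lens, retinal
detachment (retina plus sub-retinal fluid) and tumor — together with the
preprocessing, synthetic phantoms and evaluation statistics needed to
exercise it end to end without clinical data. This note records the model,
its assumptions, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## The classifier

Each voxel is classified from 2D patches taken in the three orthogonal
anatomical planes through it (a "2.5D" multi-view design), at three pyramid
scales λ ∈ {0, 1, 2}. The scale-0 patch is the unaltered 32×32 in-plane
crop with the query voxel inside patch pixel (16, 16); the scale-λ patch
covers a (32·2^λ)² field of view reduced back to 32×32 by non-overlapping
2^λ×2^λ average pooling. MR sequences (a high-resolution steady-state
sequence, a T2-weighted and a contrast-enhanced T1-weighted sequence) enter
as channels, so `ch` = 2 or 3.

Each (view, scale) pair feeds one branch:
[conv 3×3 → BN → ReLU] ×2 → max-pool 2×2 → dropout (p = 0.25) →
dense(32) → BN → ReLU. Batch normalization always precedes the activation.
Branch outputs are concatenated per scale and across scales, then pass
through dense(32) → BN → ReLU → dropout (0.25) → dense(6) → softmax. The
best configuration uses all three views, all three scales and all three
sequences (9 branches); the ablations keep every other hyperparameter and
replace the input structure with a single axial view (3 branches) or a
single 3D view with 32³ patches and 3×3×3 kernels.

Decisions the architecture description leaves open, resolved here:

- **Convolution filter counts** are not fixed by the topology; the default
  is (32, 64), configurable. The desk profile (below) uses (2, 4).
- **Padding** is `same` for all convolutions, so two convolutions plus one
  pool map 32 → 16 and the dense input width is deterministic.
- **Dropout placement** follows the listed sequence exactly: after pooling
  inside each branch and after the post-concatenation dense layer; it is
  *not* repeated after the per-branch dense(32), whose position in the
  prose is ambiguous.
- **Pooling lattice for context scales** is anchored to the volume grid
  (block edges at multiples of 2^λ). This makes a context patch exactly a
  32×32 crop of the once-pooled image, satisfies the identity "a volume
  constant within each 2^λ-block yields the scale-0 patch of the block-mean
  image" at every voxel (a crop-anchored lattice violates it at odd
  coordinates), and lets inference share each context-branch evaluation
  among the voxels of one block.
- **Mirroring semantics**: left–right augmentation flips axial and coronal
  patches in-plane; the sagittal patch content is unchanged (a left–right
  flip relocates the sagittal plane itself). The 3D patch flips along the
  left–right axis. The operation is involutive and never alters labels.

## Training

Unweighted categorical cross-entropy H(p, q) = −Σ_c Σ_a p(a,c) log q(a,c)
(q clipped to [1e-7, 1]), minimized with Adam at batch size 64 for a fixed
number of epochs — no early stopping or validation split. A random subset
of the eligible training voxels is drawn once per fold (5% at clinical
scale) and reshuffled every epoch; with mirroring enabled each presentation
is flipped with probability 0.5. Dropout is active only during training.
The eligible pool is configurable (`roi` = the 25 mm registration mask,
`roi5` = the 5 mm mask, `inference` = the region classified at test time,
`volume` = everything); the region classified at inference is the detected
eye sphere dilated by a configurable margin (default 5 mm, matching the
normalization support).

## Preprocessing

The eye is localized on the steady-state volume with a 3D Hough sphere
transform: voxels above the 98th gradient-magnitude percentile vote along
±gradient for centres at each candidate radius (0.5 mm steps); per-radius
accumulators are surface-normalized, Gaussian-smoothed (σ = 1 mm) and
peak-picked, the radius refined by parabolic interpolation, and a second
detection suppressed within 1.5× the first radius. A detection must be
*supported*: the fraction of edge voxels lying on the candidate shell
(±max(1 mm, 1.5 voxels)) with radially aligned gradients (within 30°) must
exceed 0.08 — pure noise scores below 0.01, real globes near 0.6. Each
sequence is then rescaled to zero mean, unit variance within the union of
the detected 5 mm masks. Rigid inter-sequence registration is out of
scope: inputs are assumed co-registered on one grid.

## Synthetic phantoms

A phantom is a scleral shell (default thickness 1 mm) around a vitreous
cavity, an ellipsoidal lens apposed to the inner wall at the anterior pole,
optional tumor blobs (default one, 5.2 mm radius ≈ 0.6 mL, in the range of
clinical tumor volumes) strictly inside the cavity, and a retinal-
detachment wedge hugging the inner wall. Default grid 128×128×118 at
0.27×0.27×0.30 mm with an 11 mm globe (~5.6 mL eye). Class boundaries are
assigned by a voxel-centre-in-solid test with fixed overlap priority
lens > detachment > tumor > vitreous, so ground truth is unambiguous for
metric oracles. Per-sequence class mean intensities are configurable; the
defaults make the vitreous bright on the steady-state and T2-like
sequences, the tumor enhancing on the contrast-T1-like sequence and dark on
T2, and the globe bright against background on the steady-state sequence
(so its outer edge dominates sphere detection). Gaussian noise
(σ = 0.08 against ~1.0 contrast, SNR ≈ 12) is added i.i.d.; there is no
bias field, partial volume or motion, and no multi-scanner variability —
so passing the synthetic experiments demonstrates the pipeline's
correctness and trainability, not clinical performance. Cohorts jitter
geometry and contrast per subject (±10% globe radius, ±15% tumor radius,
±5% intensities, millimetre-scale centre shifts), with jittered blobs
clamped to stay inside the cavity.

## Desk-scale profile

All shipped experiments run on one CPU, so they use a reduced profile
(`desk_spec`, `desk_params`, `desk_network`), chosen a priori and fixed:

- Phantom: 48³ grid at 0.9 mm isotropic, 9.5 mm globe, 1.2 mm sclera,
  4.1 mm tumor (~12% of the globe, as in the clinical size range). At this
  size the vitreous keeps an interior-to-surface ratio (effective radius
  ≈ 8.5 voxels) at which overlap metrics are not dominated by single-voxel
  boundary effects — the regime the method occupies at clinical
  resolution, where structures are 25× larger in voxel count.
- Network: filter counts (2, 4); topology, dense width 32 and dropout 0.25
  unchanged.
- Training: 2 epochs at learning rate 6e-3 cosine-decayed to 1e-3
  (β₂ = 0.99), sampling 3.5% of the pool per subject; the pool and the
  classified region are the detected sphere + 2 mm. The raised, decayed
  learning rate replaces the long fixed-rate schedule of the full-scale
  regime, whose epoch budget does not transfer to a ~75 ms/step CPU
  backend; the 5% clinical-scale sampling fraction likewise assumes pools
  ~25× larger.
- Hough search range 6.5–13 mm (clinical default 8–14 mm).

With this profile one leave-one-subject-out run over a 10-subject cohort
takes ~80 s (multi-view) or ~30 s (axial ablation); the test suite runs the
full 10-seed ensembles within its budget. Typical medians: vitreous DSC
≈ 0.92, tumor DSC ≈ 0.88, whole-eye DSC ≈ 0.96, with the axial ablation's
tumor DSC consistently lower (≈ 0.83) — the same ordering reported for the
clinical data, though the absolute values are not comparable.

## Evaluation

Spatial agreement is DSC = 2|A∩B|/(|A|+|B|); a comparison where both masks
are empty is *undefined* and excluded from summaries (with its count
logged), whereas a structure present in the reference but missed entirely
scores a defined 0. The whole-eye mask is the union of the five
non-background classes. Volumetric agreement is ICC(A,1) — two-way model,
absolute agreement, single measure — computed from the ANOVA mean squares;
it is undefined (None) without between-subject variance. Paired DSC
comparisons use the two-sided Wilcoxon signed-rank test (zeros discarded,
exact null for n ≤ 25, normal approximation with continuity correction
above) with Bonferroni correction, m defaulting to the 6 classes. Tumor
sizes are stratified at the 33⅓ and 66⅔ linear-interpolation percentiles;
values equal to a cut fall in the lower group, so all-equal inputs land in
one group.

## Numerical and implementation notes

- The network is implemented in NumPy with numba-compiled kernels for the
  2D branch stems (direct channels-first convolution, fused BN+ReLU,
  max-pool with stored argmax) and hand-written backpropagation; the
  generic layer objects implement the same mathematics and the test suite
  asserts agreement of forward passes and all gradients to float32
  precision. The 3D-view branch uses the generic im2col path.
- Patch block means are accumulated in float64 in a fixed order and
  rounded to float32, so the reference extractor, the batched extractor
  and the test oracle agree bit-for-bit, including zero-padded borders.
- Max-pool gradients split evenly among exactly tied inputs (ties occur
  only among identical, e.g. zero-padded, values); inference argmax ties
  break toward the lowest class index.
- Batch norm uses biased batch variance, ε = 1e-5, running-moment momentum
  0.9; evaluation mode uses the running moments.
- Weight initialization is He-normal, seeded; a single seed drives
  sampling, shuffling, mirroring, dropout and initialization, so folds are
  reproducible bit-for-bit up to BLAS rounding.
- Shared-context inference evaluates each context branch once per pooled
  block; it matches plain per-voxel evaluation to ~1e-7 (BLAS batch
  blocking), and predicted label maps are deterministic for a fixed batch
  size.

## Known limitations

- Phantom realism (no partial volume, bias field, or anatomical
  variability beyond parameter jitter) bounds what the synthetic results
  can claim; clinical performance requires clinical data.
- At desk scale the sclera is proportionally thicker than anatomy
  (1–2 voxels) and its DSC (~0.78) is limited by the 2×2 pooling in the
  architecture relative to structure thickness; the same softness is
  visible in the clinical-scale published figures for thin structures.
- The single-subject phantom has one eye; two-eye layouts are supported by
  the detector (non-maximum suppression) but not generated by default.
- Training on CPU is memory-bandwidth-bound; the desk profile exists
  because of that, and its absolute DSC values are specific to the profile.
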