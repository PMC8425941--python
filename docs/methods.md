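# Methods

## Problem and approach

Rectal tumors are hyperintense on high-b-value diffusion-weighted MR images
(DWI), but DWI volumes are noisy and low-resolution, so manual delineation
is slow and subjective. `dwiseg` implements two segmentation routes over the
same volume containers:

1. a **volumetric U-Net** that maps a DWI volume to a same-shaped per-voxel
   tumor-probability map, trained with the soft-Dice objective 1 − DSC; and
2. a **semi-automatic baseline**: a manually chosen lower gray-level bound,
   an inclusive threshold, and largest-connected-region selection.

Both are scored by the Dice similarity coefficient
DSC(A, B) = 2|A∩B| / (|A|+|B|) and the exact symmetric Hausdorff distance
HD(A, B) = max(max_a min_b d(a,b), max_b min_a d(b,a)).

Since clinical DWI with expert ground truth cannot ship with the package, a
phantom module generates DWI-like volumes with exact ground-truth masks, and
every claim the test suite makes is made on phantoms.

## The network

The U-Net is the classic symmetric encoder–decoder: at each of `levels`
resolution stages, a block of 3×3×3 "same"-padded convolutions with ReLU;
2×2×2 max-pooling between encoder stages; 2×2×2 stride-2 transposed
convolutions between decoder stages; skip concatenation at matching
resolution; and a per-voxel probability head (sigmoid for one output
channel, channel softmax for two). Input shapes must be divisible by
`2**(levels-1)` per axis; the native working grid is 256×256×32, which a
5-level net reduces to a 16×16×2 bottleneck.

The reference architecture is pinned by two published facts: a layer census
of **21** 3×3×3 convolutions, **4** poolings, **4** transposed convolutions
and **4** concatenations, and a total of **6,832,321** trainable parameters.
A plain 2-convs-per-block 5-level U-Net with a convolutional head has 19
convolutions, so two extra convolutions must sit somewhere; the default
configuration places one extra convolution after each of the first two
concatenations in decoding order (decoder levels 3 and 2).

Forward pass, backpropagation and Adam are implemented directly on NumPy
arrays (float32, channels-first), with convolutions evaluated as
slab-chunked im2col matrix products so large grids stay within memory.
Gradients of every layer were verified against central differences (in
double precision the agreement is ~1e-9; apparent discrepancies at larger
step sizes trace to ReLU/max-pool kink crossings of the finite-difference
stencil, not to the analytic gradients).

### Width-configuration search

Per-level channel widths are not published. `find_width_config` closes the
gap: given a layer census and an exact parameter target, it enumerates a
documented family of candidate configurations — monotone width ladders on a
step-4 grid with per-level growth ≤ 4×, conv-per-block counts, placements of
the extra convolutions, head kernel (1×1×1 / 3×3×3) and channel count (1/2),
transpose-channel convention ('halve' to the skip width or 'keep'), and
bias/normalization toggles — scoring each candidate with the closed-form
per-layer parameter formula (27·c_in·c_out + c_out for a biased 3×3×3 conv,
8·c_in·c_out + c_out for a 2×2×2 transpose, 2·c per normalized channel).
The parameter total is exactly quadratic in the bottleneck width, so that
width is solved per candidate rather than enumerated, and integer roots are
verified exactly.

A parity observation shapes the space: with bias terms, a convolution
contributes c_out·(27·c_in + 1), which is even whenever c_out is even. An
odd target such as 6,832,321 therefore forces a single-channel output head
even though a softmax is described — the head is the only layer allowed an
odd channel count in conventional ladders.

Exact matches are ranked deterministically (prefer 'halve' transposes, a
3×3×3 single-channel head, doubling steps, small widths, then
lexicographic). For the published census and total the search returns
widths **(40, 60, 76, 152, 180)** with extra decoder convolutions at levels
3 and 0, whose built network counts to 6,832,321 exactly. No fully
geometric (doubling) ladder hits the target, so this is a consistent
reconstruction, not a claim about the original model's widths; if a target
is unreachable the search raises an error reporting the nearest candidates
and their deltas instead of guessing.

## Training

* **Objective**: soft Dice, `1 − (2Σp·a + ε)/(Σp + Σa + ε)` with ε = 1e-6,
  averaged over cases; on binary predictions it equals 1 − DSC up to ε.
* **Accuracy**: mean DSC of predictions binarized at 0.5 (inclusive ≥),
  the quantity learning curves plot.
* **Optimizer**: Adam, default learning rate 1e-4 and decay 1e-5 — the two
  published scalars. `decay` follows the legacy-Keras learning-rate decay
  convention `lr_t = lr/(1 + decay·t)` (the framework generation the
  original hyperparameters come from); a weight-decay reading is available
  via `decay_mode="weight"`. Batch size defaults to 1 volume (3D memory
  pressure); gradients are averaged when larger.
* **Model selection**: the epoch with the highest validation accuracy,
  earliest epoch on ties; with `keep_best` the weights of that epoch are
  restored after training ("train long, keep the peak").
* **Seeding**: one master seed fans out through `numpy.random.SeedSequence`
  to cohort generation, the split, He-style weight initialization, and
  epoch shuffling, so an experiment is reproducible from one integer.
* **No augmentation** is applied, and network output is *not*
  post-processed by largest-component selection by default (the volumetric
  context makes thresholded output a single region in practice).

## Phantoms

A phantom is a voxelized ellipsoid tumor {x : Σ((x−c)/a)² ≤ 1} painted at
`tumor_intensity` over a darker background, with optional bright specks
(point-like false-positive candidates) and an optional larger, equally
bright *confounder* ellipsoid, then corrupted by Rician noise (magnitude of
complex Gaussian — the physically appropriate model for magnitude MR). The
ground-truth mask is the exact ellipsoid, untouched by noise.

Default grid conventions mirror a typical high-b-value acquisition:
256×256 in-plane matrix at 340 mm FOV (1.328 mm pixels), 4 mm slices +
1 mm gap (5 mm spacing). The default working grid is **64×64×16** — a 4×
in-plane / 2× through-plane downscale of 256×256×32 — chosen so a full
train–select–evaluate cycle is a desk-scale computation; native-resolution
phantoms are available by passing the native shape. Default intensities
(background ≈ 100, tumor 400–600, σ = 25) keep the tumor/background
separation comfortably above the noise floor, which is what makes the
threshold baseline succeed on clean phantoms and makes its failure on
confounder phantoms a statement about structure, not noise.

What phantoms do **not** model: anatomy and anatomical texture, EPI
distortion/ghosting, partial-volume boundaries, multi-b-value signal decay,
and inter-scanner intensity variation. Passing tests therefore demonstrate
the correctness of the algorithms and the qualitative behaviors (learning
with 1 − DSC generalizes on this family; threshold + largest-component
fails when a brighter-adjacent structure outgrows the tumor), not clinical
accuracy on real DWI.

## Scaled experiment defaults

The packaged end-to-end experiment scales the 300-case protocol
(180/60/60 split) down to 25 phantoms split 15/5/5 at 64×64×16, with a
reduced-width U-Net (levels 3, widths (4, 8, 16)) and learning rate 1e-3
(decay 1e-5) — a larger step suited to the much smaller network and
cohort; 25 epochs reach a validation plateau. Under these conditions the
held-out mean DSC exceeds 0.98 and the validation curve rises to a peak
before the final epoch.

## Numerical conventions and edge cases

* Crop/pad centering: odd margins put the extra voxel on the high-index
  side; 0-based indices throughout.
* DSC of two empty masks is 1; empty-versus-nonempty is 0.
* HD is exact (no percentile), Euclidean on voxel indices by default, with
  an mm option scaling by header spacing; HD with an empty operand is
  undefined and recorded as missing, never a sentinel value.
* Group standard deviations are sample (n−1) deviations.
* Thresholds (gray-level and probability) are inclusive: foreground iff
  value ≥ bound.
* Connected components default to 26-connectivity; size ties are broken by
  the component containing the smallest linearized voxel index.
* Z-score normalization maps constant volumes to all-zero rather than
  dividing by zero.
* Volumes are processed on the stored voxel lattice; RAS reorientation is
  opt-in at read time.

## Known limitations

* CPU-only NumPy training: practical for reduced grids and widths; the
  full 256×256×32 cohort-scale experiment is out of desk-scale reach.
* The recovered width configuration is one exact solution among several
  hundred in the search family; the published facts do not identify the
  original uniquely.
* Rician noise is applied independently per voxel; no noise correlation or
  coil-profile structure is modeled.
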