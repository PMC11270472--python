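# Methods

## The quantification model

EAT quantification treats the segmentation masks as the region of interest
and derives two scalars per patient.

**Volume.** Each slice contributes an area `A_i = n_i·s_x·s_y` (foreground
pixel count times pixel area, mm²).  Consecutive mask-bearing slices, sorted
by their z positions, contribute an inter-slice volume
`v_i = (A_i + A_{i+1})/2 · Δz_i` — the trapezoidal rule over the *true*
inter-slice distances, which in clinical acquisitions vary between roughly
2.2 and 4.5 mm.  The sum is converted mm³ → mL.  Volume uses every mask
pixel with no HU filtering: the segmentation output is taken as-is, with no
post-processing.  A single mask-bearing slice has no gap to integrate over;
it falls back to `A·t` with `t` the series' median z gap (or a configured
nominal thickness) and is flagged in the result's warnings.  Gaps larger
than 10 mm between selected slices are flagged but never capped — a gap is
information about the scan, not an error.

**Attenuation.** EATd is the mean HU over all mask pixels whose value lies
in the conventional adipose window [−190, −30] HU.  Pixels outside the
window are excluded from both the numerator and the pixel count M, so EATd
is always inside the window when defined; M = 0 yields an explicit
"undefined" (NaN + warning), never a silent zero.  The asymmetry — windowed
attenuation but unfiltered volume — is deliberate and configurable
(`QuantConfig`).

## Slice classifier

A small residual CNN maps a normalized slice to an EAT-presence posterior.
The loss is the class-weighted binary cross-entropy with inverse-frequency
weights `λ_i = (1/k_i)(N/C)`, which satisfy `Σ k_i λ_i = N`; with the
reference training composition (20,234 absent / 15,449 present of 35,683)
they evaluate to 0.882 and 1.155, weighting EAT-present slices up.  A slice
is labeled positive iff its mask has ≥ 1 foreground pixel (no minimum-area
rule).  Training uses RMSProp, initial lr 1e-4 halved every 20 epochs (step
decay; the halving period is a package choice, configurable), batch 128,
±15° rotation augmentation, 60 epochs, inputs resized to 224×224 — these
full-scale defaults are in `ClassifierConfig`.  Intensity normalization is
per-slice min-max to [0, 1] after clipping HU to [−1000, 1000]; the
preprocessing travels with the model handle so inference always matches
training.  Posteriors are ε-clipped at 1e-7 to keep the loss finite.

## Segmenter

A UNet-style encoder–decoder (configurable depth and base filter count,
batch normalization after each convolution, dropout 0.5 in the bottleneck)
ends in a **two-channel per-pixel softmax** trained with sparse categorical
cross-entropy.  A single sigmoid channel would be mathematically
equivalent for two classes; the two-channel convention matches the "sparse
categorical" formulation and generalizes to more tissue classes.  Training:
Adam, batch 64, initial lr 1e-4 constant for 5 epochs then decaying as
`lr·exp(−0.05·(e−5))`; rotation, random 90–100% cropping, and intensity
normalization as augmentation.  Only EAT-containing slices are used for
training — the classifier screens the rest at inference.

Predicted posteriors live on the model grid and are upscaled to the native
CT grid by area interpolation (bilinear for enlargement) **before**
binarization at 0.5: interpolating the probability field and thresholding
once gives smooth boundaries, whereas binarize-then-upscale (available as
`binarize_first=True` for ablation) produces blocky masks.

## Network engine

Both models run on a small numpy engine written for this package:
convolutions are lowered to GEMM via im2col, and the input-gradient pass is
itself a convolution with the flipped, channel-transposed kernel, so no
scatter operations are needed.  Gradients of every layer are verified
against central finite differences in the test suite.  Training is
deterministic for a fixed seed under single-threaded execution (the
documented contract; BLAS reduction order is fixed per environment).

## Phantom generator

The phantom emulates what the quantification pathway is sensitive to, not
scanner physics.  Each synthetic patient is an axial stack (native grid 512,
pixel spacing ~0.6–0.8 mm, inter-slice gaps drawn uniformly from
2.2–4.5 mm) containing a soft-tissue body ellipse (~40 HU), two lung
ellipses (−800 HU), a heart disc (~45 HU) and, on a contiguous slice block,
the EAT ring: a sector (default 80% of the circle) of the annulus between
the heart disc and a pericardium circle.  Ring radii follow a smooth
`taper + (1−taper)·sin(πu)` axial profile so per-slice areas differ —
exercising the trapezoid nontrivially.  EAT voxels are drawn at
`eat_hu_mean ± eat_hu_sd` (default −90 ± 12 HU, a typical fat attenuation),
global Gaussian noise (default 5 HU) is added, and labeled voxels are
clamped into [−190, −30] HU *after* noise so the adipose window always
holds.  Optional fat-valued distractor blobs outside the pericardium make
segmentation non-trivial (off by default).

The analytic ground truth applies the same trapezoidal rule to the
parametric sector areas, so the rasterized and analytic volume paths differ
only by pixelization.  The ring center carries an irrational offset from
the grid center so circle boundaries do not align with the pixel lattice;
with the default radii (≈80–135 px at grid 512) the measured per-slice
rasterization error is below 0.1% and the volume error ~0.02%.  Ground-truth
EATd is the noiseless mean (noise is zero-mean; recovery error scales as
`noise_sd/√M`), and cohort HU means are quantized to 1/8 HU so they are
float32-exact — a noiseless phantom then recovers its attenuation
bit-for-bit.

What the phantom does **not** emulate: anatomical shape variability,
contrast agents, beam hardening, ECG gating, partial-volume texture.
Passing the learning tests therefore shows the training loop, losses and
mask pathway work end-to-end on geometry of controlled difficulty — not
that the desk-scale networks would reach clinical accuracy on real scans.

## Dataset split

The holdout pool is `floor(n·fraction)` rounded **down to the nearest even
integer**, halved into validation and test; the remainder trains.  This is
the only rule consistent with both reference splits
(41,979 → 35,683/3,148/3,148 and 23,771 → 20,207/1,782/1,782).  Membership
is random under a seed (the reference protocol does not say random or
sequential; random-with-seed is the package's choice).  Splits are
per-slice to match that protocol; a per-patient grouped split is available
(`groups=`) because slice-level splits leak patients across sets.  The same
grouping option exists for k-fold cross-validation.

## Evaluation conventions

* Dice of two empty masks is 1.0 (perfect agreement on absence);
  configurable to NaN for strictness.
* Bland–Altman: differences are `pred − label`; limits of agreement are
  `mean ± 1.96·SD` with the sample (n−1) SD.
* Pearson p-values use the t-transform; they are reported, never used as a
  gate.  Constant inputs yield a flagged NaN, not an error.
* Confusion-matrix metrics are one-vs-rest for a stated positive class;
  note that transposing the matrix (swapping the actual/predicted axes)
  exchanges precision and recall — the likely source of inconsistent
  labeling in reported tables.

## Desk-scale experiment sizes

The test suite trains on 12 phantom patients (grid 96, ~160 slices;
classifier at 48×48 input, width 8; UNet at 64×64, 8 base filters) and
evaluates on 30 held-out phantom patients.  Desk-scale runs raise the
learning rate to 1e-3 — tiny networks on tiny datasets need it to converge
within tens of epochs, whereas the full-scale defaults keep 1e-4.  Under
these conditions the classifier reaches 100% hold-out slice accuracy, the
segmenter a mean Dice around 0.9, and the end-to-end pipeline a cohort EATv
Pearson r above 0.99 with mean |EATd error| ≈ 0.1 HU; the acceptance tests
assert the looser bounds 0.9 / 0.8 / 0.95 / 2 HU.

## Known limitations

* The exact layer tables of the original full-scale backbones are not
  public; architectures here are configurable reimplementations of the same
  families (residual classifier, UNet), which is sufficient for the
  framework but not for weight-level reproduction.
* The numpy engine is CPU-bound and single-threaded-deterministic; it is a
  reference implementation, not a performance target.
* NIfTI headers carry only a uniform slice spacing, so variable z grids are
  restored from the cohort manifest on load; DICOM series keep their true
  per-slice positions.
* Real-data headline figures (mean Dice 0.844, cohort r ≈ 0.97) belong to a
  private clinical cohort and are out of scope; the phantom analogues above
  are what this package's tests compute.
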