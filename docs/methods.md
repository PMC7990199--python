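# Methods

`atquant` quantifies air trapping (AT) on paired inspiratory/expiratory chest
CT three ways — a fixed attenuation threshold, a personalized threshold, and a
dense convolutional network trained from the personalized threshold's own
output — and characterizes how each responds to incomplete expiratory effort
using a Jacobian-based deflation simulator. Because suitable paired clinical
CT is rarely shareable, every component is exercised on a synthetic paired
phantom with mechanistic ground truth. This note records the models, the
defaults, and the design decisions that were genuinely open.

## Threshold-based quantification

Both scans of a pair are passed through a 3×3×3 median filter (nearest-edge
replication at borders) before any classification. Lung fields come either
from a supplied mask or from the built-in segmenter: low-attenuation
thresholding at −300 HU, removal of exterior air by discarding components that
touch the volume border, retention of the up-to-two largest components above
50 mL, morphological closing (radius 2), and a final exclusion of any voxel
with HU > 0 so that dense tissue re-admitted by the closing can never count as
parenchyma. Large airways are not pruned; lobar splitting is out of scope.

* **Static threshold.** A voxel is trapped if its expiratory attenuation is
  strictly below −856 HU, the conventional gas-trapping cutoff.
* **Personalized threshold method (PTM).** From the filtered inspiratory lung
  histogram take X = 90th and Y = 50th percentile (linear interpolation
  between order statistics), and let D be the deflation response of the 90th
  percentile. The subject-specific threshold is

      T = X − (1 − D/343) · (X − Y) / 3 .

  343 HU acts as a full-deflation normalizer: as the expiratory histogram
  shifts up by 343 HU the correction vanishes and T → X. The wording
  "difference in the 90th percentiles of the inspiratory and expiratory
  scans" is ambiguous in sign; the default convention is
  D = P90(exp) − P90(insp), which is positive under adequate deflation and
  drives (1 − D/343) toward 0 — consistent with the normalizer reading. The
  literal opposite sign is available as `d_convention="insp_minus_exp"`.
  D is not clamped to [0, 343]; out-of-range values log a warning and
  extrapolate T. Ties at T are not trapped (strict `<`).

QAT is reported as 100·|AT map|/|lung| (% of whole-lung voxels).

## Dense network (DN)

The DN is a 2D dense encoder–decoder: an initial 3×3 convolution, two
[dense block → transition down] stages, a bottleneck dense block, two
[transition up → skip concatenation → dense block] stages, and a 1×1
convolution with per-pixel two-class softmax. A dense-block layer is
BN → ReLU → 3×3 convolution emitting `growth_rate` channels concatenated onto
the stack; a transition down is BN → ReLU → 1×1 convolution → 2×2 max pool; a
transition up is a stride-2 3×3 transposed convolution. Two decisions were
open and resolved as follows:

* **Skip wiring.** Concatenative skips from each pre-pooling dense-block
  stack to the matching-resolution decoder stage (the standard dense
  encoder–decoder reading).
* **Transition-up width.** The transposed convolution upsamples only the new
  feature maps of the preceding dense block (growth × layers channels), the
  FC-DenseNet convention. Upsampling the full concatenated stack would make
  the decoder's transposed convolutions dominate the network's cost at full
  resolution for no accuracy benefit at this problem scale.

Training minimizes the soft Dice loss 1 − (2Σpy + 1)/(Σp + Σy + 1),
aggregated over the whole mini-batch, with plain SGD-momentum
(γ = 0.9), mini-batches of 16 slices, He-style zero-mean normal weights
(variance 2/fan-in), zero biases. Labels are PTM AT maps — weak labels — cut
into 2D slices; the loss is computed over the whole slice, and the lung mask
is applied only at prediction time. Inputs are median-filtered slices
normalized from the HU window [−1000, 200] to [0, 1] — the same
representation the threshold methods see, so train- and simulation-time
inputs match. Prediction runs slice-wise, reassembles a 3D probability map,
and binarizes at 0.5 within the lung mask.

The reference configuration uses growth rate 8, initial width 16, and
learning rate 0.001 — the regime reported for cohort-scale 512×512 training.
The CPU-scale preset used by the tests and the acceptance study
(`DNConfig.desk()`) halves the width (growth 4, initial 8) and raises the
learning rate to 0.03 over 32 epochs: with mini-batch-aggregated Dice loss
the per-weight gradient scale shrinks with slice count and pixel count, so
the reference rate is far below the stable-and-fast band at 96×96 desk scale.
Two safeguards address a known failure mode of Dice-loss training with plain
momentum — intermittent collapse into a saturated all-foreground or
all-background state with vanishing gradients: (i) validation soft-Dice is
monitored each epoch and the best-validation epoch's weights are kept, and
(ii) a collapse guard rolls back to the best weights, halves the learning
rate, and clears the momentum buffer whenever the epoch loss jumps more than
0.2 above the best seen. Both are deterministic, so training remains
bit-reproducible given the seed (single-threaded NumPy); a numerical
gradient check of the full backward pass is part of the test suite.

Subject-level generalization uses nested 2-fold cross-validation: eight
repetitions, each an equal random bipartition of subjects; all timepoints of
a subject stay on one side.

## Deflation simulation

A deformable registration of inspiration onto expiration yields a per-voxel
Jacobian determinant J, taken here as the local inspiration→expiration
volume-contraction factor (≥ 1 in normally deflating lung). Intermediate
deflation is simulated by linear scaling, J* = 1 + β(J − 1), with β = 1 full
deflation and β = 0 none. The scaled factor is applied to the
registration-warped inspiratory scan in air-referenced density space,

    HU* = J*·(HU_warped + 1000) − 1000 ,

which preserves tissue mass exactly (the operation is multiplicative in
density) and is self-consistent at both endpoints: β = 0 returns the warped
inspiration, β = 1 reproduces the expiratory scan up to registration
residual. The published expression multiplies the expiratory scan by J*
directly, which would alter the original scan at β = 1; that literal form is
retained as `mode="literal"`. Outputs are clamped to [−1024, 3071] HU with a
logged clamp count.

Registration itself is an external-provider contract: the module consumes
displacement fields (millimetres, expiratory geometry) or Jacobian maps from
any source and ships no optimizer. `jacobian_from_field` computes
det(I + ∇u) by central differences w.r.t. physical coordinates and raises on
folding (det ≤ 0). Deflation curves re-derive the PTM threshold per β by
default (the threshold is personalized per scan); a switch freezes the β = 1
threshold instead. The DN model is applied unchanged across β, as a fixed
trained observer.

## Synthetic phantom

The phantom emulates the paired-CT regime the methods target: a soft-tissue
body (30 HU) in exterior air, two ellipsoidal lungs (default grid 96×96×40 at
2 mm), inspiratory parenchyma at −850 ± 40 HU, and additive scanner noise
(σ = 15 HU). AT regions are drawn by thresholding a correlated Gaussian
random field inside the lung at the exact in-lung quantile for the target
fraction (default 15%). The contraction field takes J_n = 1.6 in normal lung
and J_at = 1.05 inside AT patches; expiratory density is J times inspiratory
density (mass-preserving by construction), so trapped lung retains
near-inspiratory attenuation while normal lung densifies — the mosaic
pattern. AT is thus defined mechanistically (failure to contract), keeping
ground truth independent of any threshold method.

Free parameters not pinned by the emulated regime were chosen once, from
realism arguments, and frozen:

* **Parenchymal texture correlation 2.6 mm** — fine heterogeneity that
  partially survives the median filter, leaving a filtered inspiratory
  spread of ~25–30 HU (X − Y ≈ 30–40 HU), in the range of real inspiratory
  lung histograms.
* **AT patch correlation 28 mm** — cm-scale mosaic patches, as seen
  radiologically; much smaller patches are disproportionately eroded by the
  3×3×3 median filter and are not the regime the methods are read against.
* **Contraction blend 0.5 mm** — mosaic borders are sharply marginated at CT
  resolution; the blend only prevents voxel-exact staircasing.
* **Registration residual σ = 3 HU** — the expiratory scan is generated from
  the warped inspiratory scan plus this residual, representing the error of a
  good deformable registration; scan noise itself is carried by each scan.

The displacement field is axial: u_z is the cumulative integral of
(J − 1) dz, so det(I + ∇u) = 1 + ∂u_z/∂z holds exactly whatever the in-plane
variation of J. The stored Jacobian is defined through the same [1, 2, 1]/4
central-difference stencil the numerical operator uses, so
`jacobian_from_field` recovers it to float rounding — deliberate discrete
consistency, keeping truncation error out of correctness checks. The suite
generator varies baseline AT fraction (~5–15%), per-interval progression
(+1.5–4 points per timepoint, nested patches that grow over time), noise
(±20%) and lung size across subjects.

What the phantom does not emulate: airways, vessels, fissures, gravity
gradients, beam hardening, scanner noise spectra, or geometric lung
deformation (the simulator modulates densities only, matching the
mass-preservation model). Passing tests therefore show that the methods are
implemented correctly and behave as designed under the mosaic-attenuation
model — not that clinical performance figures transfer.

## Problem sizes and numerical choices

The bundled studies use 8 subjects × 4 timepoints (32 pairs) at 96×96×40,
training on 160 slices from the 4-subject training pool for 32 epochs; these
sizes keep a full train–evaluate–simulate cycle practical on one CPU core
while preserving 3D structure and subject-level splits. 512×512 slices are
supported but not exercised by the tests. HU are clamped to the 12-bit CT
range [−1024, 3071] on every ingest. Percentiles interpolate linearly between
order statistics. Empty∩empty Dice is defined as 1.0 (two methods agreeing on
"no AT" is agreement). Sample (n−1) standard deviations throughout.

## Known limitations

* The deflation-sensitivity *ordering* among methods depends on where the
  expiratory attenuation distribution sits relative to each threshold. With
  the phantom's defaults (inspiratory lung −850 HU, J_n = 1.6), normally
  deflating lung stays ≥ 50 HU above −856 HU at every β ≥ 0.5, so the static
  threshold intercepts less of the downward-shifting attenuation mass than
  the personalized threshold (T ≈ −830 HU) and shows the *smallest* |ΔQAT| —
  see the sensitivity tests for the measured ordering. Real cohorts, whose
  expiratory histograms have substantial mass near −856 HU, can show the
  opposite ranking.
* Weak-label training cannot out-perform its labels where label errors are
  systematic (patch rims eroded by the median filter), so DN-vs-truth
  overlap is bounded near PTM-vs-truth overlap on this phantom.
* The statistical layer stops at tables; Wilcoxon/mixed-effects analyses of
  clinical endpoints are out of scope.
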