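# Methods

## The cascade

The segmenter treats whole-tumor delineation as per-pixel binary
classification and couples two classifiers of complementary character in
series. The CNN sees raw spatial context (a multimodal intensity patch) and
produces a presegmentation plus per-pixel class probabilities. The SVM
ensemble sees compact per-pixel statistics — grayscale, windowed mean,
windowed median per modality — *augmented with the current label guess*, and
is trained against the ground truth with the CNN's presegmentation in that
label column. This detail matters: the ensemble is fitted to the CNN's
actual mistakes, not to an oracle labeling, which is what makes the
refinement pass informative (a test asserts the two trainings genuinely
differ).

At segmentation time the two are iterated inside a region of interest
(ROI): the current foreground dilated by a disc (2-D) or ball (3-D) of
radius `roi_dilation`. Within the ROI the ensemble's labels overwrite the
current map first; the CNN then re-scores the ROI and its argmax overwrites
the ensemble wherever its maximum class probability reaches
`cnn_veto_threshold` — a confidence-gated veto. No published fusion rule
exists for this step, so the package uses this explicit, configurable one:
the SVM is free to rewrite uncertain territory while the CNN retains
authority where it is confident. Pixels outside the ROI are never touched,
and convergence is measured as the changed-pixel fraction over the whole
image. The loop stops when that fraction drops below `convergence_tol`
(checked after each pass, so a tolerance of 1.0 runs exactly one pass) or
after `max_iterations` passes; every intermediate map and change fraction is
retained on the result for inspection.

3-D volumes are processed slice-wise along the last axis and restacked; the
processing unit is deliberately the 2-D slice, the common desk-scale
baseline.

Whether the ensemble should be retrained per test image was genuinely open;
the package trains it once on the training set, which keeps segmentation
O(prediction) per case and makes the train/test separation clean.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `feature.window` | 5 px | neighborhood for mean/median features |
| `svm.sigma` | 0.1 | RBF kernel width; exponent scale 1/(2σ²) |
| `svm.C` | 1000 | SVM penalty |
| `svm.n_members` | 5 | bagged ensemble size |
| `svm.subsample` | 0.5 | bootstrap fraction per member |
| `svm.max_train_pixels` | 5000 | per-member cap (kernel cost is quadratic) |
| `cnn.patch_size` | 17 px | CNN input patch |
| `cnn.conv_channels` | (8, 16) | conv stack, 3×3 kernels, 2×2 max pool |
| `cnn.max_train_pixels` | 8000 | class-balanced training-pixel cap |
| `roi_dilation` | 3 px | ROI dilation radius |
| `cnn_veto_threshold` | 0.9 | CNN confidence needed to override the SVM |
| `max_iterations` | 2 | refinement passes |
| `convergence_tol` | 0.001 | changed-pixel fraction to stop early |

Window size, σ and C are the published operating point of the method; the
CNN architecture, loss and optimizer are this package's own choices (the
published description fixes only the layer *types* — conv/pool alternation,
fully connected, Softmax), sized so a full training run takes seconds on
one CPU. The σ parameterization is the conventional bandwidth reading; it
is configurable for anyone who prefers γ directly.

The CNN consumes raw patches rather than the 3-feature vector: convolving a
per-pixel scalar triplet would be vacuous, while the windowed statistics are
exactly the right granularity for the kernel SVM. The two stages therefore
see genuinely different views of the data.

"Integrated"/"aggregated" SVM is implemented as bagging with mean-decision
aggregation — the minimal reading that is well-defined, permutation
invariant in the members, and keeps σ = 0.1 / C = 1000 kernel fits
tractable on subsampled pixel sets. With one member and full subsampling it
degenerates exactly to a single SVM, which is how the implementation is
cross-checked against an independent scikit-learn fit.

## Synthetic phantoms

The generator emulates what the cascade needs from BraTS-style data, and
only that: four nested elliptical tumor subregions (NCR ⊂ ET ⊂ NET ⊂ ED,
BraTS codes 1/4/1/2) inside an elliptical brain on a zero background;
modality-dependent tissue means in normalized units reproducing the
clinical contrast orderings (edema bright on FLAIR/T2, enhancing core
bright on T1CE, necrosis dark on T1/T1CE); one shared smooth multiplicative
bias field per case (a broad Gaussian bump rescaled to peak relative
deviation `bias_amplitude`) — the simplest smooth confounder of the kind
offset correction targets; and independent additive Gaussian pixel noise.
Cohorts jitter tumor center (±12 % of each axis) and subregion radii
(±15 %), resampling any draw that breaks nesting.

Default study conditions: 64×64 grids, `noise_sd` 0.4, `bias_amplitude`
0.2 — a low-SNR regime in which single-modality thresholding fails and the
multimodal patch context is genuinely needed, while an 8-case experiment
still runs in ~25 s.

What the phantoms do **not** model: real anatomy and partial-volume
boundaries, Rician noise statistics, tumor mass effect, inter-rater
ground-truth ambiguity, and registration/skull-stripping artifacts. Passing
the synthetic-recovery suite therefore demonstrates that the cascade's
machinery works and that refinement does not degrade the presegmentation
under noise and bias — it does not certify clinical-grade accuracy on real
MRI.

## Numerical choices and edge cases

- Intensity standardization is a z-score over nonzero pixels (zero
  background preserved, as in skull-stripped MRI); a constant nonzero image
  is centered only, with a logged warning.
- Windowed features use reflect padding (avoids artificial zeros inflating
  border statistics) and are computed by sliding-window reductions over a
  contiguous copy, making them bit-identical to a per-window oracle.
- Softplus is evaluated as `log1p`-style `logaddexp(0, x)`; no overflow at
  |x| = 1000.
- Argmax label ties break toward the lower class index; an exactly zero
  mean SVM decision value maps to the tumor class. Both rules are asserted.
- DSC on an empty truth *and* empty prediction is defined as 1.0;
  sensitivity/specificity with an empty positive/negative class are
  reported as missing and excluded (with a logged count) from cohort means.
- Every stochastic step — phantom synthesis, cohort jitter, pixel
  subsampling, weight init, minibatch order, bootstrap draws, fold
  assignment — flows from one integer seed per run; two identical runs are
  bitwise identical.
- The determinism test exercises the full fit+segment round trip at reduced
  size (4 cases, 48×48, 3 epochs); the recovery suite runs the full study
  conditions. Problem sizes were chosen so the whole default suite completes
  in about a minute.

## Known limitations

- The CNN is a compact pure-numpy network; it is not meant to compete with
  modern encoder–decoder architectures on real BraTS data, and no attempt
  is made to reproduce absolute published index values (gated/private
  datasets, unspecified training details). Those values ship as reference
  inputs in `cascadeseg.benchmarks` for the improvement computations only.
- Multiclass (subregion) support exists in the classifiers but the cascade
  and its validation target the single whole-tumor foreground.
- Slice-wise 3-D processing ignores through-plane context.
- The ROI restriction means a tumor entirely missed by the presegmentation
  cannot be recovered by refinement; that is inherent to the cascade design.
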