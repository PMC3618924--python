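# Methods

This note documents the models and procedures implemented in `mammica`, the
parameter choices that matter, and the limits of what the synthetic study
shows.

## Synthetic data model

**Background.** Each image is a clustered-lumpy texture: blob centres follow
a homogeneous Poisson process with rate λ (blobs per px², configured per
10⁴ px²), each contributing an isotropic Gaussian bump `a·exp(−r²/2s²)`, on a
constant base intensity (default 0.08) with additive white noise (σ = 0.02).
Centres are drawn over a domain extended 3s beyond the image so the texture
is stationary up to the borders; by Campbell's theorem the blob field then
has mean `λ·a·2πs²` and variance `λ·a²·πs²` per pixel, which the tests check
against the empirical moments. The per-grade defaults

| grade | blobs / 10⁴ px² | amplitude | scale (px) |
|------:|----------------:|----------:|-----------:|
| 1 | 4 | 0.05 | 6 |
| 2 | 9 | 0.20 | 9 |
| 3 | 13 | 0.29 | 11 |
| 4 | 16 | 0.38 | 12 |

make blob rate and amplitude non-decreasing in the grade (a validated config
invariant), so mean intensity, variance and high-frequency content rise from
mainly-fatty to extremely dense. The scales approach typical mass radii at
high grades — that overlap, not noise, is what makes grade 4 hard. The
values were fixed once by a pilot run of the full pipeline so that the
difficulty ordering (grade 1 easiest, grade 4 hardest) is realised with
comfortable margins; they are configuration, not code.

**Masses.** A mass is an additive bright lesion `c·(1 − (r/R(θ))²)^1.5`
inside an irregular margin `R(θ) = R·(1 + Σ_k a_k cos(kθ + φ_k))` with 3–8
random low-order harmonics (orders from 2, amplitudes ∝ 1/k, total
perturbation ≲ 25 %). Default contrast c = 0.32 and radii 14–26 px. The
analytic margin is rasterized into a closed 8-connected pixel loop and
stored as a chain-code region, so generated ground truth round-trips through
the overlay parser with zero geometry loss. Lesions that would cross the
border raise; callers place centres with a safety margin.

**What the generator does not emulate:** X-ray physics, skin line and
pectoral muscle, digitizer characteristics, spiculation, architectural
distortion, calcifications, and the malignant/benign texture distinction
(both mass labels share one lesion model — the classification task is
mass vs normal tissue). Consequently the study's *absolute* AUCs carry no
clinical meaning; only the *ordering* across density grades, and the
pipeline's statistical machinery, are the testable contract.

## ROI conventions

- Chain-code dialect: digits 0–7 clockwise from north in (row, col)
  coordinates, row increasing downward; overlays are plain text
  (`IMAGE H W`, then `REGION/START/CODES/END` blocks). The writer and parser
  share this single definition.
- Smallest square: side = max bounding-box extent; aligned with the box
  along the longer axis, centred along the shorter (integer centring pads
  one pixel less on the low side when the padding is odd). If the centred
  square leaves the image the region is **discarded** — no shift-and-crop
  rescue — matching how border masses are dropped from prototype pools.
- Resizing: bilinear with a corner-aligned grid (source corners map to
  target corners), so constants are preserved, outputs stay inside the
  source intensity range, and same-size resizing is the identity.
- Normal-tissue sampling: sides uniform on the observed range of mass square
  sides, positions uniform over valid placements; patches with mean
  intensity below 0.05 are redrawn (up to 100 attempts) to avoid empty
  background in archives with large dark borders.

## ICA feature extraction

Centre by the mean patch, PCA-whiten to exactly the component count n
(square-mixing regime; the retained dimension equalling n is the standard
FastICA setup), then iterate the symmetric fixed-point update with
g(u) = tanh(u), the derivative of log cosh, with symmetric (parallel)
orthogonalization `W ← (WWᵀ)^{−1/2}W`. Convergence is
`max_j |1 − |⟨w_j^new, w_j^old⟩|| < 10⁻⁴`.

Numerical choices: up to 1000 iterations and 5 seeded restarts. With only
~100–150 training patches the finite-sample fixed point can take several
hundred iterations and occasionally limit-cycles on some initialisations;
1000 iterations with restarts absorbs this. On exhausted restarts the
default is an error carrying the per-restart iteration log (the expected
outcome for Gaussian sources, where the rotation is unidentifiable); the
experiment runner instead takes the lowest-residual rotation flagged
`converged: False`, since a near-fixed-point basis is still a valid linear
feature map and a single stubborn fold should not abort a fifty-run study.

Determinism: after fitting, components are ordered by descending log-cosh
non-Gaussianity and signs fixed so each basis image's largest-magnitude
pixel is positive; fits are bit-reproducible under a fixed seed. The basis
is fitted on each fold's training patches only — validation and test
patches never touch it — which is the leakage-free reading of the two-stage
design; a `shared_basis` option provides the cheaper single-basis variant
for comparison.

## Classifiers

**MLP.** One sigmoid hidden layer, one sigmoid output unit, binary
cross-entropy loss, batch Rprop (the Rprop⁻ variant: no weight backtracking)
with the original constants η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1, Δmax = 50,
Δmin = 10⁻⁶; on a gradient sign flip the step shrinks and the stored
gradient is zeroed. Early stopping on validation loss (patience 30, cap
2000 epochs) returns the best-validation-epoch weights. Grid: hidden sizes
50–650 step 50, four random restarts each; selection by validation AUC,
ties to the smaller width then the lower restart index.

**SVM.** Soft-margin RBF SVM solved by scikit-learn's libsvm binding (the
standard solver for this model); grids γ = 2^−5…2^3, C = 2^−5…2^10, both in
half steps of the exponent, endpoints included. ROC scores are raw decision
values, never calibrated probabilities. Ties break to smaller C, then
smaller γ.

Features are standardized per dimension with training-set statistics before
either classifier (RBF kernels and Rprop are scale-sensitive). Selection
functions accept only train and validation sets — test data cannot
influence selection by construction.

## Evaluation design

Unstratified random partition into 30 near-equal test folds (fold selection
ignores labels; class balance emerges statistically). Per fold the non-test
prototypes are split 80/20 train/validation to within one prototype. ROC
curves sweep thresholds at the unique score values — tied scores collapse
to one sweep point, equivalent to half-credit for ties in the Mann–Whitney
rank form, which the tests assert exactly — and AUC is the trapezoidal
integral. Fold AUCs are summarized as mean ± t₀.₉₇₅,ₙ₋₁·s/√n (Student-t
rather than normal, since n = 30). Folds whose test set is single-class are
skipped with a warning and counted in the result. Per-stratum experiments
draw fresh fold plans. Relative comparisons use
`100·(AUC_to − AUC_from)/AUC_from` reported to two decimals, and the
class-imbalance figure is `100·(N − (M + B))/N` rounded to an integer.

## Study configurations

The shipped presets fix the problem sizes: `desk` (the reduced study:
~150 patches per grade at 64 px, 10 components, 10-fold CV, reduced grids —
hidden {50, 100} × 2 restarts, γ ∈ {2⁻³, 2⁻¹, 2¹}, C ∈ {1, 4, 16}) runs in
about half a minute on one CPU; `smoke` is a minimal wiring check;
`paper-nn` / `paper-svm` carry the full-grid optimal extractor shapes
(64 px with 10 components for the MLP, 15 for the SVM, 30-fold CV) for
larger runs. The `ddsm-mix` class-mix preset reproduces the per-grade
mass:normal proportions characteristic of DDSM-style prototype pools, under
which grade 4 is ~57 % imbalanced toward normal tissue.

## Known limitations

- The synthetic difficulty ladder is calibrated, not emergent: passing the
  ordering check shows the pipeline orders strata by task difficulty, not
  that real dense breasts would yield these numbers.
- A cross-validation fold is not a patient split; source images are
  synthetic and one mass never yields two patches, but normal patches from
  the same image can land in different subsets.
- The MLP loss and output activation (cross-entropy, sigmoid) are one
  reasonable instantiation of a "single hidden layer + Rprop" description;
  alternatives (squared error, tanh output) were not explored.
- Grade-4 backgrounds clip noticeably at intensity 1.0, so their effective
  texture variance is slightly below the Campbell prediction; the variance
  test therefore pins grade 2, where clipping is negligible.
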