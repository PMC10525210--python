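# Methods

## The pipeline

The package implements a fixed-architecture "feature engineering" classifier
for two-class image datasets. No network is trained: three ImageNet-pretrained
CNNs are used as frozen feature extractors, and all learning happens in a
shallow stack of filter feature selection + 1-nearest-neighbor classification,
wrapped in an ensemble-voting loop that picks its own best output. The design
assumes a binary diagnosis task in which one class carries localized
hyperintensity (bone-marrow edema adjacent to the sacroiliac joint in the
motivating application) and the other does not.

### Feature extraction

Six layer taps are registered, in fixed order:

| # | backbone | tap | width |
|---|----------|-----|-------|
| F1 | DenseNet201 | final affine (`fc1000`), pre-softmax | 1000 |
| F2 | DenseNet201 | global average pool (`avg_pool`) | 1920 |
| F3 | ResNet50 | final affine (`fc1000`), pre-softmax | 1000 |
| F4 | ResNet50 | global average pool (`avg_pool`) | 2048 |
| F5 | ShuffleNet | `node_200` → registered as the last global-pool output | 1024 |
| F6 | ShuffleNet | `node_202` → registered as the final fully-connected output | 1000 |

The ShuffleNet tap names are export-graph node labels rather than canonical
layer names; the registry maps them to the pooled and fully-connected outputs
of `shufflenet_v2_x1_0` and the mapping is overridable. Inputs are resized
to 224×224 by bilinear interpolation (no aspect preservation), grayscale is
replicated to three channels, intensities are scaled to [0, 1] and normalized
with the standard ImageNet channel constants. All backbones run in eval mode
with frozen weights, so extraction is deterministic and batch-size invariant.

The **toy extractor** replaces a backbone with a seeded Gaussian random
projection of a 36-dimensional hand-crafted statistics vector (global
moments, 16-bin histogram, 4×4 block means and block gradient energies).
It is Lipschitz in pixel intensities, so class-dependent intensity/texture
differences survive projection, and it is the extractor used by the whole
test suite. The six toy stand-ins have distinct widths (300…400), all above
the retained-feature count so top-k selection stays non-trivial.

### Feature selection

Each of three selectors scores every column of every feature matrix; the
top **k = 272** columns are kept (ties broken by ascending column index;
k clamps to d when d < 272). Defaults:

- **chi2** — each feature is discretized into 10 equal-width bins over its
  observed range (a constant feature falls in one bin and scores exactly 0);
  the score is the Pearson chi-square statistic of the bins×classes table
  with zero-count bins dropped. The binning makes a categorical test
  applicable to continuous deep features; 10 bins is a fixed, documented
  choice.
- **ReliefF** — deterministic pass over *all* instances (no random
  subsampling, so results are single-valued): k_hits = 10 nearest same-class
  neighbors and 10 nearest neighbors per other class, Manhattan distance on
  min-max-scaled features, neighbor ties broken by ascending index; the
  weight update subtracts the mean hit difference and adds the
  prior-weighted mean miss difference, normalized by n. Scaled weights lie
  in [−1, 1]. The pipeline clamps k_hits to (smallest class size − 1) when
  a fixture class is small.
- **NCA** — diagonal-weight neighborhood component analysis: weights w
  maximize Σᵢ pᵢ − λ‖w‖², where pᵢⱼ is a softmax over −Σᵣ wᵣ²|xᵢᵣ−xⱼᵣ|
  and pᵢ sums pᵢⱼ over same-class j. Features are z-scored internally;
  optimization is full-batch gradient ascent from the all-ones vector for
  100 iterations with step `learn_rate/n` (learn_rate 0.2, λ = 1/n by
  default). The step is capped at 0.9/(2λ) so strongly regularized runs
  contract monotonically instead of oscillating. Scores are the squared
  final weights; zero-variance columns are assigned score 0 (they enter no
  distance and carry no information). The implementation stores only the
  i<j half of the pairwise |difference| tensor in float32 and accumulates
  distances/gradients by matrix-vector products; the ~1e−7 relative error
  of float32 accumulation is far below ranking resolution. Instances too
  large for the pair tensor fall back to per-row chunking in float64.

Selection is computed **once on the full dataset** before cross-validation
(the protocol default, mirroring the upstream pipeline's step order). This
optimistically biases CV accuracy whenever d exceeds k and features are
noisy, because the selected columns have seen the held-out labels. The bias
is real and measurable: on a pure-noise fixture (n = 200, d = 600) the
best-candidate accuracy under full-dataset selection is ≈ 0.69 versus ≈ 0.52
under the leakage-safe alternative. The package therefore also provides
`selection_scope="nested"`, which recomputes ranking and selection inside
every training fold; the test suite asserts both behaviors explicitly.

### Classification

1-nearest neighbor, Euclidean distance, uniform weighting. For every fold of
a stratified 10-fold cross-validation (seeded shuffle within class, then
round-robin), features are z-scored with the *training-fold* mean and
population standard deviation (zero-variance columns map to 0), the held-out
fold is transformed with those parameters, and each query takes the label of
its nearest training row (distance ties go to the lowest training index).
The concatenated held-out predictions in original sample order form the
out-of-fold prediction vector; its accuracy is the fraction of samples
predicted correctly while held out.

Per-fold standardization is the default because it is the leakage-free
reading; a `standardize_mode="global"` flag reproduces whole-dataset
z-scoring for strict replication. Grouped CV (all images of one patient in
one fold) is available but off by default, matching an image-level protocol.
Holdout splits (0.2/0.25/0.3) are supported as alternate validation schemes.

### Voting and selection

Prediction vectors are sorted by accuracy (stable sort; ties keep the
F-index × selector order). For each r in [3, 18] the per-sample mode of the
top r vectors forms a voted outcome; mode ties resolve to the smallest class
code. With 18 inputs this yields 16 voted outcomes. The final output is the
argmax-accuracy candidate over all 34 outcomes (ties prefer voted over
classifier-wise, then smaller r, then earlier classifier index); a config
switch restricts the pool to the 16 voted outcomes. When fewer matrices are
available (e.g., a single feature table), the loop's upper bound clamps to
the number of prediction vectors and all counts generalize accordingly.

Majority voting is not guaranteed to beat the best single vector; the only
guaranteed dominance is best-of-all-candidates ≥ best classifier-wise, since
the selector scans both pools.

### Metrics

Confusion matrices use rows = truth, columns = predicted, axes in the fixed
class-name order; classes are encoded 1..C in that order (control = 1,
disease = 2 in the fixtures). The panel reports overall accuracy
(trace/total) and per-class recall, precision, and F1 (harmonic mean), with
0/0 conventions mapping to 0. Report percentages round half-up to two
decimals via the value's shortest decimal representation, so printed-digit
identities (e.g., recall 80.72 and precision 94.24 giving F1 86.96) are
reproduced exactly.

## Synthetic fixtures

`gen_feature_dataset` draws two-class Gaussian features: a fraction
(default 10%) of columns are shifted between classes by delta × noise_sd
(defaults delta = 6, noise_sd = 1, d = 600, 100 samples per class); the rest
are pure noise. `gen_image_dataset` writes grayscale phantoms sharing a
bright vertical "joint line" on a dark background; the disease-like class
adds 1–3 Gaussian blobs beside the line with contrast delta × the pixel
noise scale. delta = 0 makes the classes statistically identical.

These fixtures emulate only the statistical task (localized hyperintensity
vs. none, or mean-shifted feature columns) — not MRI physics, scanner noise
correlations, patient-level repeated imaging, or class imbalance. Passing
tests on them demonstrates that the pipeline's machinery is correct and
recovers separable signal; it says nothing about clinical performance on
real MRIs, which depends on data that is not distributed with the package.

Test and acceptance problem sizes — 40-sample phantom runs for structural
checks, n = 200 / d = 600 feature fixtures for signal-recovery checks, 10
seeds for the null average — were chosen as the smallest sizes at which the
checked properties are statistically stable.

## Numerical and design choices

- Population (not sample) standard deviation in all z-scores; fixed for
  bit-stability across runs.
- All tie-breaks are deterministic and documented: lowest training index
  (1-NN), ascending column index (selection), input order (accuracy sort),
  smallest class code (mode).
- One global seed fans out to per-stage seeds by fixed offsets, so stages
  are individually reproducible.
- DICOM pixels are rescaled with slope/intercept when present; no windowing
  is applied (no windowing protocol is assumed; raw rescaled intensities
  are a deterministic default). Multi-frame DICOM and NIfTI are out of
  scope.
- The duplicate-sample behavior of deterministic ReliefF is intentional:
  a duplicated instance becomes its own zero-distance nearest hit, which
  changes weights relative to the unduplicated data. The test suite pins
  this behavior against an independent brute-force enumeration rather than
  asserting a (false) invariance.

## Known limitations

- The pretrained path needs `torch`/`torchvision` and downloaded weights;
  it is exercised in toy mode only by the test suite. The exact activations
  of the original (MATLAB-exported) backbones are not bit-reproducible from
  any other framework, so pretrained-mode results are expected to differ in
  detail from any previously published numbers even on identical images.
- Full-dataset selection (the protocol default) should not be used to report
  honest generalization accuracy when d ≫ k; use `selection_scope="nested"`.
- The retained-feature count 272 is treated as a fixed constant of the
  architecture; no tuning interface is offered.
- The best-of-34 selection step itself optimizes over out-of-fold accuracy
  and therefore carries a mild winner's-curse optimism on small datasets.
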