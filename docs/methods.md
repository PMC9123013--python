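# Methods

This note documents the models, numerical choices and limitations behind
`phenotrack`, in the spirit of a software methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic videos as study conditions

No public dataset pairs label-free videos with per-cell phenotype ground
truth at the scale needed here, so the package ships a first-class generator
(`phenotrack.simulate`) whose defaults define the study conditions used by
the tests and the acceptance script:

* **Geometry/optics.** 512 × 512 px field at 0.33 µm/px, 60 frames at
  1 frame/min (full 720-frame, 12 h acquisitions remain configurable). Cells
  are dark, soft-edged discs (graylevel depth 0.28 below a 0.44 background)
  with radius ~N(5.9, 0.5) µm — matching the detector's physical radius
  range. Additive Gaussian camera noise, sd 0.008 graylevels, then clamping
  to [0, 1]. The background/depth/noise budget keeps the whole image within
  [0, 1] at ±3 sd and leaves ≥ 0.5 graylevel of headroom above the brightest
  pixel, so bias-injection experiments up to +0.5 run without clipping.
* **Morphodynamics.** The phenotype signal is a radial boundary perturbation
  `r(θ,t) = r₀ (1 + a Σ_k w_k sin(kθ + φ_k(t)))` over harmonics k = 2–5 with
  decreasing weights; `a` is the class's `fluctuation_amplitude` and the
  phases φ_k random-walk at `fluctuation_rate` (default 0.15 min⁻¹, i.e. the
  shape decorrelates within a few frames). Setting the rate to 0 freezes a
  deformed shape — used to construct classes whose *instantaneous* shape
  statistics are identical while their *temporal* statistics differ (the
  single-time-point control).
* **Motion and clustering.** Cells sit on rings around cluster anchors laid
  out on a grid (default pitch 84.5 µm, ring radius 18 µm ⇒ ≥ 3 radii
  between neighbours) and move as an Ornstein–Uhlenbeck walk tethered to the
  anchor (speed 0.1 µm/min, reversion 0.05 min⁻¹), so clusters persist for
  the whole video. Classes are assigned to clusters in a checkerboard
  pattern so each lateral half of every field contains every class — a
  requirement of the left/right cross-validation protocol.
* **Not modelled:** division, apoptosis, optical PSF, illumination
  gradients, focus drift, fluorescence. Passing tests therefore demonstrate
  the pipeline's mechanics and its luminance-robustness guarantee, not
  performance on real microscope data.

## Detection and tracking

Canny edges (σ = 2 px) feed a Circular Hough Transform over radii 13–23 px
(step 2). Accumulator peaks above 0.30 × the per-frame maximum, separated by
at least 1.5 × the minimum radius, become detections; centers are refined to
sub-pixel precision as the dark-mass centroid inside the detected circle.
Linking solves the exact rectangular assignment problem per frame on squared
centroid distances, padded with virtual birth/death nodes priced at the
gating cost (gate = 2 × mean search radius), so "no link" competes fairly
with every pairing; gaps up to 2 frames are bridged by linear interpolation
and flagged; tracks shorter than 10 frames are discarded, since temporal
statistics on very short signals are meaningless. Clusters are connected
components of the graph joining tracks whose time-averaged centroids lie
within 4 × the mean radius; the rule is order-invariant (components
relabelled by smallest member id) and the threshold configurable.

## Bit-exact luminance-bias invariance

Background suppression subtracts the frame's mean luminance and clips at
zero, which cancels any constant offset *algebraically*; in floating point
the cancellation would survive only to ~1e−16, while the robustness claim is
tested bit-for-bit. The implementation therefore quantizes graylevels to a
1e−4 grid inside the suppression step and evaluates
`max(n·v − Σv, 0) / (n·q)` with exactly representable integer-valued floats
(63² pixels × 10⁴ levels ≪ 2⁵³). Any offset that is a whole number of grid
steps (0.3 and 0.5 are) then shifts `v` uniformly and cancels exactly, so
biased and unbiased pipelines emit *identical* bits — descriptors,
selections, predictions and accuracies included. The 1e−4 grid is far below
the generator's noise floor and camera bit depths, and is a configuration
parameter (`quant_levels`).

Two further conventions: pixels exactly at the mean map to 0 (the strict/
non-strict branch choice is immaterial, `I − m_I = 0` either way), and the
Gaussian window uses peak value 1 — "normalization factor" chosen so the
cell-centre intensity is preserved; unit-integral normalization is exposed
as an option and only rescales all features by a constant.

Contrast enhancement stretches the first frame between its 1st/99th
percentile graylevels (linear-interpolation quantiles) and histogram-matches
later frames to it through a 256-bin CDF inversion. A degenerate first frame
(l₁ ≈ l₂) maps to zeros rather than dividing by zero. The
"no-preprocessing" comparison arm keeps the inversion (so object polarity is
constant for the backbone) and nothing else; whether enhancement belongs in
that arm was an open design choice — here it does not, keeping the arm
maximally naive.

## Feature backbones

The named CNN backbones are declared with their published transfer-learning
contract (pooling layer, input size, feature count: alexnet pool5/227/9216,
googlenet pool5/224/1024, resnet101 pool5/224/2048, nasnetlarge
average_pooling/331/4032) and require torchvision at runtime; requesting one
without it raises with a remediation message rather than silently
substituting.

The built-in `fallback` backbone is a deterministic hand-designed feature
extractor, not a pretrained network: nine multi-scale maps
(Gaussian-smoothed intensity at two scales, two difference-of-Gaussian
band-passes, gradient magnitude, four oriented derivatives), pooled over a
3 × 3 grid (mean + max), then mixed by a seeded random affine map with ReLU
(default 256 units). Half of each unit's L1 weight mass lies positively on
the intensity channels, so — like rectified CNN units trained on
natural-range images — a global graylevel shift drives units across their
activation thresholds instead of cancelling. This property is what makes the
no-preprocessing arm of the bias protocol degrade, and it is itself under
test. The random mixing is fixed by the backbone seed; identical inputs give
identical outputs.

Track descriptors use the sample (n−1) standard deviation of each feature
signal over time; the coefficient-of-variation variant ("relative" standard
deviation) is exposed as an option since both readings of the descriptor are
defensible. Features identically zero over the whole sequence are dropped as
inactive; when several preprocessing conditions must share a feature basis
(the bias protocol), the full dimensionality is kept and inactive features
contribute 0.

The traditional benchmark branch segments each crop (Otsu threshold,
morphological closing, hole filling, small-object removal, centre-most
component; any mask provider with the same signature can be plugged in,
e.g. a trained semantic-segmentation model) and computes per frame the
perimeter, area, eccentricity and solidity plus 13 classical Haralick
co-occurrence statistics (64 gray levels within the masked intensity range,
distance 1, averaged over 4 directions; out-of-mask pixels are excluded via
a reserved co-occurrence level). Each feature's trajectory is summarized by
mean, sample std, skewness, kurtosis (0 by convention when the signal is
degenerate) and the Shannon entropy of a 32-bin histogram of its values.

## Selection, classifiers, protocol

Feature AUC is the Mann–Whitney statistic computed by midranks (exact under
ties; verified against exhaustive pair counting). Selection keeps features
whose AUC is *strictly* below the 0.1-quantile or above the 0.9-quantile of
the training fold's AUC distribution. Two degeneracies get defined
behaviour: when a threshold quantile coincides with the distribution extreme
(e.g. many features at AUC 1.0 on an easy fold) boundary ties join the
selection, otherwise the strict rule would keep only the uninformative
opposite tail; and when all scores are equal the selector falls back to the
top-k (default 10) by |AUC − 0.5| and flags it. Multi-class problems score
each feature by its maximum one-vs-rest |AUC − 0.5| and keep the upper tail
at the same total retained fraction — the "keep the extremes" intent carried
to more than two classes.

Classifiers: linear SVM (C = 1; any convergent linear-SVM optimizer defines
the same decision function, so the solver is sklearn's); a boosted tree
ensemble whose grid (ensemble cycles, maximum leaf nodes, shrinkage learning
rate) is tuned by inner 5-fold CV on the training partition, with a
classical random forest as an alternative variant; LDA with a shared
*diagonal* covariance (hand-implemented, since sklearn's LDA is full-
covariance); KNN with K = 9 on the top 2.5 % of features ranked by
|AUC − 0.5| on the training fold. Features are z-scored with training-fold
statistics for all model families, and likewise before PCA.

Half-experiment-out CV assigns each cluster a side by the sign of its
time-averaged centroid x minus the frame midline; fold 0 tests all left
clusters (training on all right clusters pooled over videos), fold 1 swaps.
The implementation asserts the train/test cluster intersection is empty, and
a video whose clusters all fall on one side is rejected with a diagnostic.
Reported mean ± std spans the two folds (a spread over 2 values is
indicative only; repeated seeded replicates can be pooled on top). Cluster
votes are modal track labels; ties resolve by the larger summed classifier
decision score, then lexicographically, and are flagged.

## Problem sizes

The default test and acceptance workloads use 512 × 512 px, 60-frame videos
with 4 clusters × 5 cells each: 4 videos (≈80 tracks, 40 per class) for the
end-to-end recovery experiment, 2 for the bias and single-time-point
protocols, 1 for the bit-exactness checks. These sizes were chosen as the
smallest at which cluster-level voting and the two-fold protocol are
meaningful; all of them scale up through configuration.

## Known limitations

* The built-in backbone is not a pretrained CNN; absolute accuracies on real
  videos will differ from any published transfer-learning results, and no
  claim is made that filter-bank features match CNN features beyond the
  interface and the qualitative luminance behaviour.
* Detection assumes quasi-circular cells; strongly deformed cells are found
  (the Hough peak survives ±30 % boundary modulation) but with centre errors
  of several pixels, which the tracking gate absorbs and ROI windowing
  tolerates.
* The bit-exact bias guarantee holds for offsets on the quantization grid
  and without clipping; arbitrary offsets cancel to within one grid step.
* Cluster membership is static (assigned from whole-track centroids); cells
  migrating between clusters are not re-assigned over time.
* No lineage handling: a division event would appear as a track birth.
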