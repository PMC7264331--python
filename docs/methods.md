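# Methods

This note records the models implemented in `hrvnet`, the conventions and
numerical choices behind them, and what the synthetic cohorts do and do not
establish.

## Data model

RR intervals are stored in seconds (milliseconds accepted on input via a
flag), strictly positive and finite, at least two per series.  Beat times
are anchored at t₁ = 0.  BPM series count the RR intervals whose end time
falls in successive non-overlapping 60 s windows; the trailing partial
minute is discarded.  Box-plot summaries use linearly interpolated
quartiles and standard Tukey fences [Q₁ − 1.5·IQR, Q₃ + 1.5·IQR]; a
one-sided fence centred twice on Q₃ is sometimes quoted in the HRV
literature but is degenerate for symmetric data, so the symmetric
convention is used throughout.

## Synthetic cohort generator

No per-class marker statistics are published for real cohorts of this
composition, so the generator is property-driven: its defaults are fixed
once from clinical expectations and then used as the study conditions for
every test.

Each series is built as

1. an AR(1) core xₙ = φ·xₙ₋₁ + ηₙ around the class mean RR, with the
   innovation variance chosen so the stationary SD equals the class SDNN
   target;
2. additive sinusoids at 0.25 Hz (respiratory, HF band) and 0.10 Hz
   (baroreflex, LF band) evaluated at the cumulative beat times of the
   core, with uniformly random phases;
3. log-normal heavy-tail contamination: with per-beat probability
   `tail_mix` the beat is replaced by mean_rr·exp(N(0, tail_sigma²)),
   reproducing the right-tailed RR distributions of real recordings;
4. clipping to the physiological range [0.2 s, 3.0 s].

Class defaults (mean RR s / SDNN s / φ): H 0.85/0.050/0.90 with strong
HF+LF modulation; AF 0.75/0.150/0.05 — near-uncorrelated and dispersed, as
the AF ventricular response is close to random; CD 0.90/0.015/0.97 — low
variability, strong persistence; DIAB/TIR/TENS are jittered healthy
variants with reduced autonomic modulation; O is an intermediate profile.
Default class counts are 600 H, 560 AF, 232 CD, 217 TIR, 161 DIAB,
113 TENS and 946 unspecified (O), 2829 in total, so folding all non-target
classes together yields 1669 "other" patients against AF and 1997 against
CD.  Per-patient seeds fan out deterministically from the master seed and
a stable per-class hash, so adding a class never perturbs another.

These choices make the two properties the analysis depends on emerge
rather than being hard-coded: AF separates from H+O by ≈7 pooled SDs in
the (RPL mean, ApEn) marker plane, and AF sample skewness and lag-1
autocorrelation order correctly in ≥95 % of seeded runs.  What passing
tests on this cohort do *not* show: performance on real Holter data, with
its artifacts, ectopic beats, circadian structure and label noise, none of
which the generator emulates.

## Marker battery

Conventions, chosen once and frozen so golden values are stable:

- per-series SDs (SDNN, STDHR) use the sample estimator (ddof = 1);
- NN50 threshold 50 ms; pNN50 = 100·NN50/(L−1);
- RR histogram bin width 1/128 s for the triangular index and TINN; TINN
  is the baseline width of the least-squares triangular fit, optimised
  independently on each side of the histogram mode (the squared error
  separates at the peak);
- SDNN-index / SDANN over complete 300 s windows anchored at the first
  beat, requiring ≥ 10 min of data (two complete windows);
- spectra: cubic-spline resampling of RR(t) (in ms, attached to interval
  end times) at 4 Hz; FFT route = Welch periodogram with 300 s Hann
  segments at 50 % overlap, DC bin dropped; AR route = Burg model of order
  16 (coefficients via statsmodels), parametric one-sided PSD on a 2048
  point grid.  Bands: VLF ≤ 0.04 Hz, LF (0.04, 0.15], HF (0.15, 0.4];
  band powers by rectangular rule, total power = VLF+LF+HF so relative
  powers sum to 100 exactly; normalized LF/HF are percentages of LF+HF,
  which forces their perfect anti-correlation across any cohort;
- Poincaré SD1/SD2 as RMS dispersions of the lag-1 return map orthogonal
  to / along the identity line (SD1 ≡ RMSSD/√2 algebraically);
- RQA: embedding m = 10, delay 1, Euclidean radius √m × SD, minimum line
  length 2; REC excludes the main diagonal; DET/line statistics from the
  upper-triangle diagonals (the plot is symmetric);
- ApEn/SampEn: m = 2, r = 0.2·SDNN, Chebyshev distance; self-matches
  included for ApEn, excluded (and templates restricted to the common
  N−m set) for SampEn;
- DFA: integrated mean-centred series, linear detrending per
  non-overlapping window, α₁ over 4–16 beats and α₂ over 16–64 beats
  (10 log-spaced sizes each);
- D₂: Grassberger–Procaccia on the m = 10 embedding; the log–log slope is
  fit over radii spanning the 2nd–25th percentile of inter-point
  distances.  This scaling region recovers D₂ = 1 for a noise-free closed
  curve while staying below the saturation regime; it is a pragmatic
  default, not an adaptive plateau search.

Markers whose preconditions a series fails (5-min statistics under 10 min
of data; DFA under 256 beats; D₂ under 500; spectra under 5 min) are
recorded as absent (NaN), never zero; imputation with training-split means
happens at the cohort level.

Exact numeric parity with commercial HRV tools is not attainable — the
resampling rate, windowing and AR order they use are only partially
documented — but all analytically forced identities hold to machine
precision, and every non-trivial marker is checked against an independent
brute-force oracle or closed form in the test suite.

## Redundancy reduction

Pearson correlations use the population (1/M) convention.  Pairs with
|Cᵢⱼ| ≥ 0.990 are redundant; the fixed default drop list is
{22, 27, 29, 31, 33, 34, 35, 38}.  The first six are the documented
normalized/relative-power and SD1 redundancies; #33 and #34 complete the
list to eight because the absolute/relative HF powers of the AR route
duplicate their FFT counterparts — the unique completion consistent with
both the stated count of eight and the 41-input classifier.  A greedy mode
(drop the marker in the most surviving pairs, ties to the higher index)
derives a list from the data instead.

## Augmentation

PCA is fit on standardized matrices (correlation PCA); component signs are
fixed by making each component's largest-magnitude loading positive, so
rotations are reproducible across BLAS builds.  Soiling multiplies each
row's pc₁ score by an independent α ~ U(1−ε/2, 1+ε/2) per copy and
back-rotates; the output contains only the copies (20 copies of 2300 rows
give exactly 46 000 points).  Since E[α] = 1 and ε = 0.1 is small, the
per-marker Kolmogorov–Smirnov distance between source and augmented sets
stays below 0.05.  Augmented data are used exclusively for classifier
pre-training, never for validation.

## Classifier

Each block: 41 inputs → 256 → 512 → 1024 ELU units, multiplicative
Gaussian dropout before each hidden layer with rate 0.2 (noise SD
√(0.2/0.8), the Keras convention), batch normalization (momentum 0.99,
ε = 10⁻³) on the last hidden layer, two softmax outputs.  Loss is the
categorical cross-entropy with probabilities floored at 10⁻¹²; optimizer
is SGD with Nesterov momentum (lr 0.01, momentum 0.9 — conventional
defaults, exposed in the schedule, since no canonical values exist for
this architecture).  Pre-training takes one gradient step per epoch on a
freshly sampled batch of 2000 augmented examples (50 epochs); training
iterates mini-batches of 300 over the real training split (700 epochs at
full scale; 200 in the reduced desk schedule).  Batch-norm statistics
carry over from pre-training and keep updating.  Argmax ties predict the
negative class.  He-normal initialization, float32, fully seeded; runs are
bit-reproducible single-threaded.

Splits are stratified 80/20; imputation means, standardization constants,
the PCA rotation and the augmentation are all fit on the training split
only.  (Standardizing on the whole cohort before splitting would leak
validation information; the package deliberately avoids it even though
cohort-level standardization is the natural reading of the original
workflow.)  The three-block combiner maps one-positive patterns to the
block's class, all-negative to O, and multi-positive patterns — for which
no canonical rule exists — to the positive block with the highest
positive-class probability, flagged `consistent=False`.  A cross-database
audit counts patients called AF by the combiner while the CD block also
votes positive, and vice versa.

## Similarity graphs

Classic DTW (absolute-difference cost, unit steps, Sakoe–Chiba band of
half-width 0.1 × the longer length by default, widened to cover any length
difference) is the default distance; a literal closest-point matching
variant (sum over each series of minimum pointwise distances to the other,
both directions added) is provided because it is sometimes described as
"DTW" in applied work — the two disagree whenever alignment order matters.
Series are truncated to their first 2000 beats: the distance cost is
O(L₁·L₂) and the early beats carry the same rhythm structure as the rest
of a stationary series.  Similarity is w = 1/(1+d); any strictly
decreasing transform yields the same kNN sets, this one is bounded and
dimensionless.  Ties in the k-nearest selection break toward the lower
node index, for bit-reproducibility.

Directed global clustering is trace(A³)/Σᵢ≠ⱼ(A²)ᵢⱼ — closed directed
triangles over directed 2-paths, the three-node reading of "paths of
length three", which is the only reading that yields a triangle-based
coefficient.  Reciprocity is the fraction of directed edges whose reverse
exists.  Clique percolation (default clique size 3) runs on the
mutual-link symmetrization A ∧ Aᵀ, since the community method is defined
for undirected graphs; community clustering averages the directed GC of
each community's induced subgraph, skipping communities without a
2-path.  Ensembles draw seeded node samples per class and cache pairwise
distances across realizations.

## Problem sizes

Desk-scale defaults keep a full run of the test suite and the acceptance
script in the minutes range on one CPU: cohorts of 100–2829 patients at
1000 beats, graph ensembles of 8–50 nodes with 2–100 realizations, and
the reduced 50 + 200 epoch schedule.  The acceptance script trains the
AF/NAF block on the full 2829-patient default cohort.

## Known limitations

- The generator has no circadian structure, artifacts or ectopy; marker
  distributions are narrower than clinical ones, which inflates classifier
  accuracy relative to real data (validation accuracy reaches 1.0 on the
  default cohort, against ~0.8–0.9 reported on comparable private data).
- TINN's triangular fit is evaluated on histogram bin centres; very sparse
  histograms make it coarse.
- The D₂ scaling region is fixed, not adaptive; for high-dimensional noise
  it returns an effective (finite-sample) dimension rather than a
  converged invariant.
- AR-route band powers integrate a sampled parametric spectrum; with
  near-noiseless sinusoids the spectral peak can be narrower than the
  frequency grid and band fractions become grid-limited.
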