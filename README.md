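# hrvnet

Detection of cardiac pathologies from heart-rate-variability (HRV) data by
two complementary routes, exercised end to end on a synthetic RR-interval
cohort generator.

A Holter recording reduces to a *tachogram*: the sequence of beat-to-beat
(RR) intervals RRₙ = tₙ₊₁ − tₙ.  Patients carry a class label — healthy
(H), atrial fibrillation (AF), congestive heart failure (CD), diabetes,
thyroid dysfunction, hypertension, or unspecified other (O).  The package
implements:

**Route A — marker-based classification.**  Each patient is coarse-grained
into a vector **x** ∈ ℝ⁴⁹ of standard ESC/NASPE HRV markers: time-domain
(mean RR, SDNN, RMSSD, NN50/pNN50, triangular index, TINN, SDNN-index,
SDANN, …), frequency-domain via both Welch periodogram and Burg
autoregressive spectra of the 4 Hz-resampled tachogram (band peaks and
absolute/relative/normalized powers in VLF ≤ 0.04 Hz, LF 0.04–0.15 Hz,
HF 0.15–0.4 Hz), and non-linear (Poincaré SD1/SD2, recurrence
quantification, approximate/sample entropy, DFA α₁/α₂, correlation
dimension D₂).  Pearson correlation Cᵢⱼ = Cov(x⁽ⁱ⁾,x⁽ʲ⁾)/σ⁽ⁱ⁾σ⁽ʲ⁾ across
the cohort exposes redundant pairs (|Cᵢⱼ| ≥ 0.990) — several of them exact
by construction (SD1 ≡ RMSSD/√2; normalized LF + HF ≡ 100) — and eight
markers (#22, 27, 29, 31, 33, 34, 35, 38) are dropped, leaving 41
classifier inputs.  The training pool is enlarged by *PCA soiling*: each
row's first principal-component score is multiplied by α ~ U(1−ε/2, 1+ε/2)
(ε = 0.1, 20 copies per row) and back-rotated, preserving the per-marker
distributions.  Three binary feed-forward blocks (H/NH, AF/NAF, CD/NCD;
hidden layers of 256/512/1024 ELUs with Gaussian dropout 0.2, batch
normalization, two softmax outputs) minimize the categorical cross-entropy
ℒ = −Σᵢ tᵢ ln f(sᵢ) by Nesterov-momentum SGD in two stages — 50
pre-training epochs on the augmented pool, then mini-batch training on the
real examples — and a consistency combiner maps the three outcomes to a
four-way H/AF/CD/O call.

**Route B — similarity networks.**  Samples of N patients per class become
digraph nodes; dynamic time warping between truncated tachograms gives
weights wᵢⱼ = 1/(1 + DTW(rᵢ, rⱼ)), and each node points to its k most
similar peers.  Out-degree is k everywhere and mean in-degree is k by
construction, while the in-degree spread, the directed global clustering
GC = (# closed directed 2-paths)/(# directed 2-paths), the reciprocity
GR = (# mutual links)/(# links), and clique-percolation communities of the
mutual-link skeleton discriminate the classes: AF graphs are markedly less
reciprocal and less clustered.

Because real labelled Holter cohorts of this kind are private, the package
ships a seeded generator of class-conditional synthetic tachograms (AR(1)
core with class-specific variance and persistence, respiratory/baroreflex
sinusoidal modulation, log-normal heavy-tail contamination) that reproduces
the qualitative structure both routes rely on.

## Worked example

```python
from hrvnet import (table_cohort_config, generate_cohort, marker_table,
                    impute_missing, pearson_matrix, find_redundant_pairs,
                    reduce_markers, prepare_task_data, BlockClassifier,
                    ensemble_metrics)

cohort = generate_cohort(table_cohort_config(seed=7, series_length=1000, scale=0.1))
markers = marker_table(cohort)                      # 283 patients x 49 markers
imputed, _ = impute_missing(markers)
pairs = find_redundant_pairs(pearson_matrix(imputed))
# -> [(5, 38, 1.0), (6, 7, 1.0), (18, 22, -1.0), (31, 35, -1.0), (8, 9, 0.998)]
reduced = reduce_markers(imputed)                   # 41 marker columns remain

data = prepare_task_data(markers, "AF/NAF", seed=7)
clf = BlockClassifier(pretrain_epochs=50, train_epochs=200, seed=7)
clf.fit(data.x_train, data.y_train, pretrain=(data.x_aug, data.y_aug),
        validation=(data.x_val, data.y_val))
clf.history_.val_accuracy[-1]                       # -> 1.000

ensemble_metrics(cohort, "AF", n_nodes=20, k=5, realizations=10, seed=7)
# AF graphs: gc 0.240+/-0.019  gr 0.384+/-0.045
# H  graphs: gc 0.274+/-0.028  gr 0.502+/-0.035
```

The redundant-pair list shows the analytically forced correlations (SD1 vs
RMSSD at +1, normalized LF vs HF at −1) surfacing from data alone; the
AF/NAF block separates atrial fibrillation perfectly on this synthetic
cohort; and the AF similarity graphs are visibly less clustered and less
reciprocal than the healthy ones.

A `hrvnet` console script exposes the same steps
(`simulate`, `markers`, `reduce`, `augment`, `train`, `graph`,
`run-route-a`, `run-route-b`); see `hrvnet --help`.

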