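# Methods

## Signal model and preprocessing

The package treats an ECG record as a uniformly sampled single-lead
voltage series (mV) with beat annotations: a 0-based R-peak sample index
plus a class symbol per beat. Annotations are taken as given; no R-peak
detection or correction is performed.

Baseline wander is removed by subtracting a two-stage median-filter
estimate: the signal is median-filtered with a short window `w1`
(default 0.2 s), then that output with a longer window `w2` (default
0.6 s), and the result — the baseline — is subtracted. The window
defaults follow the physiological wave durations (the 0.2 s window spans
the P wave and QRS complex, the 0.6 s window the T wave); both are
configurable and are converted to odd sample counts at the record's
sampling rate (rounded, bumped up by one if even, so the median is
centred). Edges use replicate padding so length is preserved. On a unit
0.2 Hz sinusoid the cascade leaves a residual below 2% of the amplitude,
comfortably under the 10% bound the tests assert. Filtering the signal
versus subtracting a baseline estimate is an arbitrary choice at this
point in the pipeline; subtraction is used because it leaves in-band beat
morphology untouched.

## Segmentation

Each beat is the half-open window `[r − pre, r + post)` with
`pre = round(0.25·fs)` and `post = round(0.40·fs)` samples — at 360 Hz,
90 + 144 = 234 samples (0.65 s). The half-open convention makes the
segment length exactly `pre + post` with the R peak at local index
`pre`. Beats whose window crosses a record boundary are dropped rather
than padded: padding would distort the wavelet coefficients, and
boundary beats also lack the RR neighbours the features need.

## Features

**RR-interval features** (seconds), for an interior beat *i*:

| feature    | definition                                                         | default |
|------------|--------------------------------------------------------------------|---------|
| `rr_prev`  | (r_i − r_{i−1}) / fs                                               | —       |
| `rr_post`  | (r_{i+1} − r_i) / fs                                               | —       |
| `rr_short` | mean of the up-to-*l* most recent previous intervals, incl. rr_prev | l = 10  |
| `rr_long`  | mean of previous intervals fully inside the last *d* minutes        | d = 5   |

Two conventions were genuinely open and are fixed as follows.
`rr_short` *includes* the interval ending at beat *i* (so with l = 1 it
equals `rr_prev` exactly — a tested identity). `rr_long` admits an
interval when both of its defining R peaks lie within *d* minutes before
the current peak, again including the interval ending at *i*; if no
interval qualifies (only possible within the first seconds of a record)
it falls back to `rr_short`, logged. First and last beats of a record
are excluded from the dataset rather than imputed.

**Wavelet time-frequency features.** Each 234-sample segment is run
through the Mallat cascade (low/high-pass filtering with dyadic
downsampling) to depth `level`, and the final-level approximation (cA)
and detail (cD) coefficients are the features, cA first, each in time
order. Signal extension is symmetric (half-sample), giving per-level
length `floor((n + f − 1)/2)` for filter length `f` — the convention
under which the closed-form `coefficient_count` reproduces the
decomposition lengths of all four supported families (db1, bior1.3,
rbio3.1, sym2) at every admissible depth; the unit suite pins the full
count table for n = 234. Depth admissibility follows the standard
`floor(log2(n/(f − 1)))` rule, which is why bior1.3 stops at level 5 on
234 samples. Defaults are db1 at level 5: 8 + 8 = 16 coefficients, hence
20 features in total with the RR block. The transform itself is
delegated to PyWavelets; a brute-force pad–convolve–downsample oracle
and a Parseval energy check (periodized mode on power-of-two lengths)
verify the convention in the tests.

One numerical quirk worth knowing: with db1 at level 5 on 234 samples
the last detail coefficient is structurally zero (odd-length levels
mirror their final sample, and the Haar high-pass of a mirrored pair
vanishes). The standardizer's zero-variance guard handles it.

**Standardization** is the z-score with per-column training-set mean and
*population* (divide-by-N) standard deviation, so the transformed
training matrix has exactly zero mean and unit variance. Zero-variance
columns pass through centred (sigma replaced by 1, logged). The scaler
is always fitted on training rows only — per training split during grid
search — and travels with a serialized model.

## Classifier

The ELM hidden layer has `L` logistic-sigmoid nodes whose input weights
and biases are drawn i.i.d. uniform on [−1, 1] from a seeded PCG64
generator; the draw is frozen thereafter, so (seed, data, C, L) fully
determine the model. Labels are encoded as ±1 rows (+1 at the true
class; class order is first appearance unless given). The output weights
solve the ridge problem `min ½‖β‖² + ½C‖T − Hβ‖²` in closed form. Note
the convention: C multiplies the *error* term, so the normal equations
carry `I/C` on the Gram matrix and larger C means *less* regularization
(‖β‖ is non-decreasing in C, and β tends to the min-norm pseudoinverse
solution H†T as C → ∞ — both tested).

The primal system `(I/C + HᵀH)β = HᵀT` is L×L; at the grid's upper end
(L = 5000) that is needlessly large when only N ≪ L samples are in play,
so for N < L the identity `(I/C + HᵀH)⁻¹Hᵀ = Hᵀ(I/C + HHᵀ)⁻¹` switches
to the N×N dual. Both are symmetric positive definite for C > 0 and are
solved by Cholesky factorization (no explicit inverse), with a logged
least-squares fallback if factorization fails. Argmax ties in decoding
go to the lowest class index — an arbitrary but deterministic rule.

## Model selection

The train/validation split (default 70/30) is stratified per class,
because realistic beat-class frequencies are skewed enough that a plain
random split can lose rare classes entirely; classes with a single
sample stay in training, logged. The wavelet/depth grid is searched
first at fixed C and L, then (C, L) on the chosen features, each cell
scored by validation accuracy. One fixed split (from the grid seed) is
shared by all cells of a run, while each cell draws its own hidden layer
from a seed derived from (grid seed, cell index) — making every number
in the result table bit-reproducible. Ties prefer the smaller L, then
the smaller C (parsimony); for wavelets, the shallower level. Default
grids: C ∈ {10⁻⁴, …, 10⁵} by decades, L ∈ {200, 400, …, 5000}.

A one-against-one SVM harness (scikit-learn) is included purely as a
baseline comparator; for m classes it fits m(m−1)/2 binary problems
(120 for the 16 MIT-BIH beat classes).

## Metrics

Per class, sensitivity Se = TP/(TP+FN) and positive predictivity
Pp = TP/(TP+FP), as percentages, from a confusion matrix with true
classes as rows. Overall accuracy is trace/total — the micro-average,
which is the only summary for which total Se, total Pp and accuracy
coincide (a tested identity on random matrices). A per-class binary
accuracy (TP+TN)/total is also exposed. 0/0 cells report 0% with a
degeneracy flag instead of NaN, so summary tables stay printable for
classes that were never predicted.

## Synthetic data

The generator produces what the method consumes and nothing more
elaborate: beats are sums of five Gaussian bumps (P, Q, R, S, T at fixed
offsets −0.20, −0.03, 0, +0.03, +0.25 s relative to R) with
class-specific amplitudes and widths; per-beat classes are drawn from a
mixing distribution; the interval preceding a beat is drawn from the
class's N(rr_mean, rr_sd), scaled by a prematurity factor (< 1 for
premature-type classes), with a 0.3 s floor applied to the final
interval so beats cannot collide at the default segmentation settings.
R times are snapped to the sample grid, so annotations are exact and
coincide with the noiseless template's local maxima. Sinusoidal baseline
wander (default 0.25 Hz — below respiratory-band drift and squarely in
what the median cascade must remove) and white noise are added last.

The frozen 3-class benchmark (300 s, ~380 beats, seed 2024) has a
normal-like class, a premature class (prematurity 0.65) separable almost
purely by rhythm, and a wide-QRS class (σ = 0.035 s, absent P,
discordant T, symmetric Q/S so the rendered peak stays on the annotated
R sample) separable by its wavelet signature. Its previous-RR class
means are pairwise > 3 pooled standard deviations apart by construction.

What the generator does *not* emulate: beat-to-beat morphological
variability within a class, non-stationary rhythms, electrode artefacts,
muscle noise, or the near-identical morphologies that make several real
beat classes (e.g. junctional vs normal) hard. Passing the end-to-end
tests therefore demonstrates that the pipeline's stages compose
correctly and that the features separate what they are designed to
separate — not that comparable accuracy transfers to clinical
recordings.

## Problem sizes and defaults in the tests

The test suite and acceptance script run entirely on simulated records
of 1–5 minutes (up to ~500 beats) and ELMs up to L = 500 — sizes chosen
so the full suite completes in seconds while still exercising both the
primal and dual training paths, all four wavelet families, and the
complete CLI. The package itself has no such limits; the defaults
(L = 3000, C = 0.1 for the wavelet search) mirror sensible settings for
half-hour ambulatory records.

## Known limitations

- No R-peak detection: annotation files are required inputs.
- No multi-lead fusion, resampling, or streaming ingestion.
- The WFDB reader needs the optional `wfdb` dependency and leaves
  record-specific channel conventions (e.g. MIT-BIH record 114's swapped
  leads) to the caller via the `channel` argument.
- The classifier is the plain regularized ELM; no ensembling, online
  updates, kernelization or class weighting.
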