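# Methods

## Signal model and assumptions

An epoched trial is e = g + n: a stereotyped evoked waveform g (present
only in target trials) plus zero-mean background EEG n, uncorrelated with
g. Coherent averaging of K time-locked trials leaves g and shrinks the
background by ~√K; the method further assumes that a subject's P300
waveshape is stable enough for an averaged **template** to represent it,
and that template-to-curve shape distances are smaller for P300 trials
than for background. Amplitude and latency vary across electrodes (the
farther from the generating cortex, the smaller the deflection), which is
why every stage operates per electrode.

## Chain codec

A curve of T samples is rediscretized to S segments by keeping the S+1
existing samples nearest 1 + mΔ (m = 0..S, Δ = T/(S+1), round half up,
clipped to [1, T]); no interpolation is performed, so segment endpoints
are always acquired samples, and S = T−1 keeps every sample. x and y are
then independently min–max scaled to [0, 1]; a flat axis maps to zeros so
a zero-amplitude epoch encodes to the all-zero chain. Each segment's
symbol is its inclination angle relative to the horizontal divided by 90°,
rounded half-away-from-zero to two decimals — values on the 0.01 grid
strictly inside (−1, 1), i.e. 199 realizable symbols (symbols that would
round to ±1.00 are clipped to ±0.99 to keep the interval open). An
alternative codec convention (`mode="dy"`, the signed normalized rise of
each segment with unit segment width) is provided because the magnitudes
of the published example chains are difficult to reconcile with the
angle reading; all published worked-example quantities are plain
arithmetic on printed chains and are identical under either convention.

Chain distance is the ℓ₁ norm of the symbol difference; tortuosity is the
sum of |bₛ| over **all S symbols** — the published worked example (0.64)
matches the S-term sum and not an S−1-term sum (0.60), so the former is
implemented.

## Shape features

Each curve (template and candidate), normalized on its own min–max range,
contributes S trapezoid areas over its consecutive point pairs; the
template-minus-candidate differences of the first S−1 areas are kept
signed (direction matters to the classifier), and their absolute sum T̆
serves as a scalar dissimilarity. The feature vector
[a₁..a_{S−1}, T̆, d, Υ, b₁..b_S] has 2S+2 components; the chain distance d
sits at position S+1, which the calibration stage reads directly.

## Calibration wrapper

For each stimulation count k (from K downward) and each electrode:
O templates are built (coherent average of A random P300 trials, encoded
to a chain), and each is scored by U = ⌊(P−A)/k⌋ cross-validation folds.
Every fold averages k P300 trials (disjoint from the template's trials and
from previous folds of the same template) and k non-P300 trials,
featurizes both against the template, and the AUROC of the two distance
samples — oriented so smaller P300 distance scores toward 1, ties counted
half, computed from pooled ranks — fills the O×C matrix Z. φ_c is the
column mean. Electrodes with φ ≥ 0.8 are accepted; if none passes at the
first k, electrodes with φ > 0.6 are selected once and iteration stops
(or the subject is declared unsuitable). While the accept criterion holds
the wrapper decrements k; K′ is recorded as the smallest passing k, and
the profile carries the full φ-vs-k trace so the alternative "last k
before failure + 1" reading is recoverable. Per electrode the template
with the highest Z entry (ties toward the lowest index) supplies the
stored chain, feature mask and regression weights.

Feature reduction is forward-entry/backward-removal stepwise least-squares
regression of +1/−1 class labels on the 2U×(2S+2) per-electrode feature
block: the candidate with the smallest two-sided t-test p-value enters
while p < 0.1, retained columns with p > 0.15 leave (worst first);
constant or collinear columns are skipped. It is run per (electrode,
template), and the mask of the winning template is returned — the
alternative (one fit per electrode on pooled templates) is not used
because the returned per-electrode mask must correspond to the returned
template. The original description also mentions a 38-component maximum
per electrode where the vector has 34; no 38th component is derivable and
the discrepancy is documented here rather than emulated.

## Parameters

| name | default | meaning |
|---|---|---|
| S (`segments`) | 16 | segments per curve; ⌊800 ms × 20 Hz⌋ from the ~10 Hz ERP bandwidth and Nyquist |
| A (`trials_per_template`) | 180 | P300 trials averaged into a template (inflection of the φ-vs-A curve) |
| K (`max_stimulations`) | 15 | acquisition maximum per symbol in the speller protocol |
| O (`templates_per_electrode`) | 10 | candidate templates banked per electrode; bounds runtime at U·O·C extractions per k |
| `auroc_accept` / `auroc_fallback` | 0.8 / 0.6 | electrode screening thresholds |
| `p_enter` / `p_remove` | 0.1 / 0.15 | stepwise regression criteria |
| `max_folds` | 20 | cap on U when k is small (U = 20 uncapped at the K = 15 regime); bounds runtime |
| `master_seed` | 0 | all randomness derives from it via per-(k, electrode, template) seed sequences |

`calibrate` is bit-reproducible for a fixed master seed.

## Preprocessing

Conditioning order is band-pass → DC removal → linear detrend, per trial
and electrode. The band-pass realizes the designed 4th-order Butterworth
(0.1–12 Hz) with zero phase by multiplying each epoch's DFT by the
filter's squared magnitude response (the forward-backward convention).
A time-domain forward-backward pass is not used because the 0.1 Hz edge's
impulse response (~10 s) exceeds an 800 ms epoch, leaving edge transients
larger than the attenuated signal; on the DFT grid the realized
attenuation matches the designed response to within spectral leakage
(≈1.5 % residual RMS for a 30 Hz tone on 204 samples, against 0.04 %
designed). Zero phase is chosen so the P300 latency is not shifted; the
acquisition-side notch/anti-alias filters act before data reach this
package and are not modeled.

## Synthetic subjects

The simulator emulates the post-conditioning acquisition regime: 10
electrodes (Fz, C4, Cz, C3, P4, Pz, P3, PO8, Oz, PO7), 256 Hz, 800 ms
epochs (204 samples), 480 P300 + 2,400 non-P300 training trials and
150 + 750 validation trials. A P300 trial is background noise plus a
Gaussian deflection: latency 350 ms with 20 ms SD jitter (latency
variability is a documented property of the component), width 80 ms,
amplitude 10 µV scaled per electrode by a profile defaulting to three
full-amplitude, four half-amplitude and three silent channels — a known
answer for recovery tests that mimics amplitude decay with distance from
the generator. Background is Gaussian noise band-limited to 0.1–12 Hz
(the post-filter band) with 10 µV SD, i.e. single-trial SNR ≈ 1, a
realistic speller regime. An optional two-bump mode adds a second
deflection 125 ms later (the interstimulus interval implies ~2 target
responses per 800 ms epoch); the default is a single bump.

What the simulator deliberately omits: 1/f and alpha spectral structure,
eye/muscle artifacts, inter-trial amplitude drift, and spatial correlation
between electrodes. Passing recovery tests therefore show that the
pipeline's inference is correct under its own signal model, not that the
published population-level numbers (mean AUROC 0.87 ± 0.10 over 21
subjects, SWLDA accuracy 93.15 % ± 7.17) transfer to real EEG — those
require the original database and are out of scope.

## Numerical choices and degenerate inputs

- Symbol quantization rounds half away from zero (symmetric in sign).
- Chain distance re-rounds at 10 decimals to remove float dust from sums
  of exact 0.01 multiples.
- Min–max normalization of a flat axis maps to zeros instead of dividing
  by zero.
- The AUROC is the normalized Mann–Whitney statistic from pooled ranks;
  ties contribute ½.
- Stepwise regression guards: candidates numerically in the span of the
  current design (residual norm < 1e−8·‖x‖) are skipped; an all-constant
  matrix yields an empty selection; entry stops when residual degrees of
  freedom run out.
- SWLDA's decision threshold is the midpoint of the projected class-mean
  scores (the intercept is otherwise unidentified); profile-based
  validation uses threshold 0 on the +1/−1 coding, equivalent for
  balanced training folds.
- Validation groups are disjoint K-trial blocks of a seeded permutation:
  all ⌊P′/K⌋·K P300 trials are used, and the same number of non-P300
  trials.
- Per-electrode validation is the default; concatenated-electrode feature
  vectors are available (`mode="concat"`) but require an explicitly
  trained model, since the calibration profile stores per-electrode
  weights.

## Problem sizes used by the test suite

The full-scale recovery test runs the complete wrapper once at the
reference regime (C=10, P=480, N=2,400, A=180, K=15, O=10, U=20) — about
a minute of CPU — shared across tests via a session fixture; all other
tests use miniature subjects (tens of trials, 2–3 electrodes, O ≤ 3)
that exercise the same code paths. Oracle cross-checks (exhaustive
pairwise AUROC, statsmodels stepwise-path replay) run at small n where
enumeration is exact.

## Known limitations

- The published chains' small symbol magnitudes cannot be reproduced from
  the angle convention and unit-square normalization; absent the raw
  curves the convention cannot be settled, hence the dual codec modes.
- Electrode screening at φ thresholds is a hard cut; near-threshold
  electrodes flip with sampling noise (a t-test-based selection would be
  a natural extension).
- The stepwise p-values are ordinary OLS t-tests, not selection-adjusted;
  this matches standard SWLDA practice but overstates significance.
- Online (real-time) operation, vendor EEG formats, and the reference
  system's decimated-voltage feature vector are out of scope.
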