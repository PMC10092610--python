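# Methods

## The analysis model

The pipeline treats a session as a continuous multi-channel signal plus a
stimulus train, and reduces it to per-trial quantities in two 500 ms windows:
**baseline** (−0.5–0 s relative to each stimulus onset) and **late**
(0.2–0.7 s). Samples are 0-based, windows half-open, and time t maps to
sample `round(t·fs)`; both windows therefore contain the same number of
samples at any sampling rate, making their spectra bin-compatible. Epoching
never resamples or detrends: concatenating epochs back reproduces the
original samples.

Five bands are analysed: delta 1–4, theta 5–9, sigma 10–16, beta 17–29 and
gamma 30–80 Hz. Band filtering is a 4th-order Butterworth applied
forward–backward (zero phase; effective 8th-order magnitude). Zero phase
matters because the late-window boundaries carry meaning; a causal filter
would shift energy across them.

**Spectra.** Each 500 ms epoch is analysed as a single Hamming-tapered
segment — no overlap, no averaging — which yields exactly 2 Hz resolution.
Spectra are one-sided with doubling at all bins except DC/Nyquist and scaled
so the bin sum equals the windowed signal's energy (Parseval holds to
rounding error; this is tested). Epoch means are removed by default before
tapering to stop DC leakage. Band power sums bins with
`low ≤ f ≤ high`, both edges inclusive; on the 2 Hz grid the odd-Hz band
boundaries never produce a shared bin between adjacent bands.

**Normalised power** is the mean of per-trial ratios `P_e[i]/P_b[i]`, never
the ratio of means. Note a small-sample property of this estimator: when the
numerator contains power independent of the denominator, `E[X/Y] >
E[X]/E[Y]` (Jensen), and the bias grows as the effective number of spectral
bins shrinks. Recovery tests therefore use a broadband configuration where
the statistic concentrates.

**Evoked/induced decomposition.** The evoked component is the band power of
the spectrum of the time-domain average of the *same* late epochs being
decomposed; induced power per trial is `total − evoked − baseline`
("methods" definition, the default). A documented alternative
(`induced_definition="figure3"`, also exposed as `--induced-def` on the CLI)
omits the evoked term — the source material states both variants, and the
package exposes the discrepancy rather than resolving it silently. Because
the synthetic evoked kernel lives entirely inside 0–200 ms, the two variants
differ only by the (small) residual background surviving the 40-trial
average.

**Multiscale entropy.** Sample entropy is `−ln(A/B)` with B the number of
unordered pairs of m-length templates within Chebyshev distance r
(self-matches excluded) and A the same for m+1; only the first N−m templates
enter both counts so every template has an extension. Parameters follow the
conventions of the literature this analysis descends from: m = 2,
r = 0.2 × SD, scales 1–20, all configurable. r is computed once from the
scale-1 band-filtered epoch and held fixed across scales (recomputing per
scale is available behind a flag). MSE is computed per trial and averaged
across trials — never on concatenated trials. A scale where A or B is zero
is flagged undefined and that trial is excluded at that scale with a logged
count, rather than imputed; a zero-variance epoch yields an all-undefined
curve. The optimized counting (thresholded distance matrix, diagonal-shift
AND) is exactly equal to brute-force template counting, which the test suite
asserts count-for-count against an independent oracle.

**Coherence.** Magnitude-squared coherence uses Welch cross/auto spectra
with the classic default segmentation — 8 Hamming segments, 50 % overlap —
applied per 500 ms epoch (nperseg = ⌊N/4.5⌋). At this epoch length the
estimator's grid (~9 Hz) is coarser than the 2 Hz analysis grid; band
averaging deliberately uses the estimator's own grid since interpolating
coherence onto a finer grid would fabricate resolution. Coherence is
estimated per trial and averaged over the 40 trials; a pooled estimator
(spectra averaged across trials before the ratio) exists behind a flag.
Welch coherence of independent signals has a positive bias that decreases
with the number of (effectively independent) segments; the tests pin this
bias against a hand-rolled Monte-Carlo oracle. The bias is slightly larger
for narrowband signals, whose overlapping segments are more correlated — a
second-order effect that shows up as a small (~0.01) apparent coherence
change when one channel's spectrum whitens between conditions.

**Statistics.** Paired t (two-sided, df = n−1); Wilcoxon matched-pairs
signed-rank with zero differences dropped before ranking (their count is
logged) and an exact null for ≤ 25 untied nonzero differences, normal
approximation with tie correction above; one-way ANOVA with optional
Holm–Šidák-adjusted pairwise post-hocs; balanced two-way ANOVA
(time × condition) by the standard sum-of-squares decomposition, the
interaction being the test of interest for induced power. Holm–Šidák:
sorted ascending, `adj_(i) = 1 − (1 − p_(i))^(m−i+1)`, running maximum,
unsorted. Degenerate inputs (zero-variance differences, zero within-group
variance) are flagged, never silently NaN. All tests are calibrated: under
their own nulls the 10,000-replicate type-I error sits inside the 95 %
binomial interval of α = 0.05.

The two-way ANOVA is applied to **log** band power by default
(`anova_log_power=True`): band powers are approximately chi-square and
heavy-tailed, the conditions differ several-fold in variance, and on the log
scale the interaction directly tests the late/baseline power-*ratio*
contrast, which is the scientific question. Trials are treated as
independent units, mirroring the pooled 40-trial design being emulated; a
rat-level mixed model would be the statistically stricter choice and is a
documented non-goal.

**Multiple-comparison families** are defined per figure-panel analog: the
four channels form one Holm–Šidák family per band for the baseline, induced
and MSE analyses; the three channel pairs form the family per band for
coherence.

## The synthetic session generator

The generator is phenomenological — it reproduces the statistical structure
the analyses assume, not thalamocortical biophysics (no TRN bursting, no
membrane dynamics). Each channel is a sum of:

| component | default | role |
|---|---|---|
| pink (1/f) background | gain 0.4 | broadband LFP floor |
| delta sinusoid, 2 Hz | gain 2.0 | slow-wave sleep |
| theta band noise 5–9 Hz | gain 0.5 | background |
| sigma spindles, 11–15 Hz core | gain 0.5 | intermittent 0.75 s Hann bursts every 2.5–5.5 s |
| beta rhythm, 20–26 Hz core | gain 1.5 | ongoing beta |
| gamma rhythm, 42–62 Hz core | gain 1.0 | ongoing gamma |
| white noise | gain 0.3 | entropy dial |
| evoked kernel | amplitude 5 | 40 Hz damped sinusoid, ~4 cycles, confined to 0–100 ms |
| induced bursts | power gains: beta 6, gamma 2.5 | random-phase core-band bursts confined to 200–700 ms |

Ongoing rhythms and induced bursts are white noise filtered into a narrow
"oscillation core" *inside* the analysis band rather than spanning it:
physiological rhythms are rhythmic (narrowband), and this is what gives the
entropy measure a meaningful predictability contrast against broadband
noise — a full-band "rhythm" is statistically indistinguishable from
filtered noise. An induced gain g produces a burst whose expected band power
is g times that of a unit-amplitude core noise, independent of the
background gain.

The gamma rhythm of L6 and VPm is a unit-variance linear mix of a shared and
a private source, `(w·shared + (1−w)·private)/√(w²+(1−w)²)` with
`w = shared_gamma_mix` (default 0.8), giving the core component the closed-form
expected coherence `w²/(w² + (1−w)²)` used as a test oracle. The late-window
induced gamma bursts of L6/VPm are mixed from a shared burst source with the
same weight — the induced gamma itself is coherent across the
thalamocortical pair, which is precisely the connectivity the late-window
coherence analysis measures. EEG/PoM gamma, and all beta bursts, are
private.

The design constants follow the emulated protocol: 10 trials per rat ×
4 rats = 40 paired trials, one stimulus per 15 s, 20 kHz sampling. "Rat" is
simulated only as trial grouping (no rat-level random effect). Since no
analysed band exceeds 80 Hz, tests and shipped examples run at 1 kHz —
lossless for the analyses and 20× faster; 20 kHz remains supported. All
randomness flows from the config seed through one `numpy` generator with a
fixed draw order, so sessions are bit-reproducible.

The **ketamine condition** (`ketamine_variant`) multiplies ongoing beta/gamma
power by 2, halves both induced burst powers, lowers the shared gamma mix
0.8 → 0.4, and triples the broadband noise in L6 and VPm only, with a
distinct derived seed. The saline/ketamine defaults were fixed once, as the
canonical synthetic experiment, by two requirements: each headline effect
should be detectable at the emulated 40-trial design size, and the untouched
channels/pairs should stay statistically quiet. Two couplings constrain
them: (i) raising a channel's gamma gain while holding its noise fixed
*lowers* band-limited entropy, so the ketamine PoM parameters keep the
narrowband late-window power constant (background ×2, burst ×½ with
saline gain 2.5 ↔ ketamine 1.25 nearly swap); (ii) whitening a channel's
spectrum slightly lowers its coherence bias with *any* channel (the
narrowband-segment-correlation effect above), so the saline noise floor is
kept high enough (0.3) that this drift stays well under the decision
thresholds.

## The signature evaluation

`evaluate_signature` makes compound directional calls at α = 0.05 on
Holm–Šidák-adjusted p-values:

- **baseline_up** — ketamine/saline baseline power ratio > 1 at all four
  sites in both bands, adjusted-significant at all sites in gamma;
- **induced_down** — aggregate induced %-change (ratio of means, robust to
  trials with near-zero baselines) lower under ketamine at all sites in both
  bands, interaction adjusted-significant at all sites in gamma;
- **entropy_up_L6_VPm** — gamma MSE adjusted-significantly higher in both L6
  and VPm (PoM's non-change is reported separately);
- **coherence_down_L6_VPm** — L6–VPm gamma coherence adjusted-significantly
  lower *and* by at least 30 % relative; the other pairs count as changed
  only under the same joint significance + ≥30 % criterion.

Direction is required in both bands but significance only in gamma because
the beta-band interaction and baseline contrasts are underpowered at 40
trials under realistic trial-to-trial variability (spindle and 1/f leakage
into the 17–29 Hz band); gamma is the primary endpoint of the emulated
study. The 30 % effect-size margin in the coherence calls mirrors the
emulated finding that a ~25 % drop was reported as non-significant while a
~40 % drop was the headline effect, and it keeps the second-order bias drift
(≈5–10 % relative) from masquerading as connectivity change. Under a
saline-vs-saline null every positive call needs several adjusted tests to
fire simultaneously in the right direction, so false signatures are rare
(measured: none in 20 null seeds).

## What the generator does and does not show

Passing tests demonstrate that the estimators are implemented correctly
(oracle equality, closed forms, Parseval, calibrated error rates) and that
the pipeline recovers a known ground-truth contrast of the stated shape at
the stated design size. They do not validate the biological claims: real
LFPs have nonstationary rhythms, cross-frequency coupling, volume
conduction, rat-level random effects and artifacts, none of which are
modelled. Two known artifacts of the synthetic world are documented above:
the beta-band MSE also rises in L6/VPm under the ketamine configuration
(white noise is broadband, so the entropy dial is not band-selective), and
whitening changes coherence bias slightly. Analyses at 20 kHz are supported
but all shipped numbers use 1 kHz.

## Numerical and degenerate-input choices

- Butterworth order 4, `sosfiltfilt`; series shorter than the pad length are
  rejected, as are bands reaching Nyquist.
- Epochs must be exactly 500 ms for spectra (2 Hz grid); anything else is an
  error, and an onset whose window leaves the recording rejects the whole
  run — no silent trial dropping anywhere.
- Sample entropy requires r > 0 and N > m+1; undefined values are flagged,
  and comparisons exclude (and count) flagged trials.
- Coherence requires ≥ 2 segments (single-segment coherence is identically
  1 and is rejected).
- Wilcoxon with no nonzero differences, t tests with zero-variance
  differences (detected with a relative float tolerance), and ANOVAs with
  zero within-cell variance all return explicit degenerate flags.
- TSV outputs are written with fixed float formatting and a header carrying
  the package version and config hash; identical inputs produce
  byte-identical outputs.
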