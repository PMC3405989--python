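# Methods

## The detection problem

A circadian time-course experiment measures one expression value per gene
per time point — here 24 points, every 2 h for 48 h of constant darkness —
in each of three conditions: wildtype animals, animals whose circadian
clock is rescued only in the brain, and clock-mutant animals.  The
questions the package answers are (i) which genes cycle, with what period,
peak time and amplitude, in each condition, and (ii) how each gene's
rhythm changes across conditions: restored by the brain rescue, lost
without a local clock, or converted from a 12-h ("harmonic") rhythm to a
24-h rhythm.

## Rank-based rhythm test

For a candidate period `T` and peak time `φ` the reference waveform is
`cos(2π(t−φ)/T)` evaluated at the sampling times and converted to average
ranks (values within 1e−9 are tied).  The statistic is Kendall's
`S = #concordant − #discordant` pairs between the data ranks and the
reference ranks; pairs tied in the reference contribute zero.  The
normalised concordance is `τ = S / S_max`, where `S_max` is the number of
reference-untied pairs.

The scan evaluates every reference on a period grid (default 10–40 h in
1-h steps — deliberately finer than the sampling interval, since real
analyses report non-integer periods) and a phase grid at half the sampling
interval (1 h here), and keeps the reference with maximal `|τ|`.
Normalising by `S_max` before comparing references matters: reference tie
patterns differ across periods (a 24-h cosine sampled over two days ties
each value with its repeat and mirror; a 23-h cosine is tie-free), and the
raw `|S|` would systematically favour tie-free references.  Ties among
equally scoring references break deterministically to the smallest period,
then the smallest phase.  If the winning concordance is negative the
reported phase is flipped by half a period (the anti-phase reference has
reversed ranks), so results always carry a non-negative `τ`.

### Exact null distribution

Under the null the gene's ordering is exchangeable, so `S` depends on a
random permutation only through the number of between-group inversions `k`
with respect to the reference's tie groups: `S = S_max − 2k`.  The number
of orderings with exactly `k` inversions is the coefficient of `q^k` in
the Gaussian (q-analog) multinomial coefficient over the tie-group sizes,
which the package evaluates with exact integer arithmetic (polynomial
convolution of Gaussian binomials).  Tail probabilities are therefore
exact and attainable: the reported p-value `P(|S| ≥ s)` is always a point
of the winning reference's discrete tail set, which is why p-values appear
"quantized" across genes.  The implementation is verified value-by-value
against brute-force enumeration of all `n!` orderings for every tie
pattern arising on grids of up to 8 points.

The reported p-value is the minimum single-reference tail over the scan,
**without** a multiplicity correction (a Bonferroni-over-references flag
exists but is off by default, matching how published JTK-family p-values
are quoted).  This choice has a measurable cost, quantified below under
*Known limitations*.

### Data ties and missing values

Data ties receive average ranks.  The exact null assumes tie-free data, so
when more than 10% of data pairs are tied the p-value switches to a seeded
Monte-Carlo permutation tail (2 000 permutations, flagged
`method="permutation"`).  Missing time points are dropped from both the
series and the reference family; fewer than 6 remaining points is an
error.  A constant series has no ordering signal and is reported with
`S = 0`, `p = 1` and undefined period/phase.

## Multiple testing

q-values are Benjamini–Hochberg step-up adjustments of the per-gene
p-values, computed per condition over all genes tested in that condition
(delegated to `statsmodels`; an independent hand-rolled step-up oracle
checks it in the tests).  The default significance threshold, `p < 0.0011`,
is the p-value that corresponded to `q < 0.05` in the wildtype condition
of the emulated study.

## Amplitude and phase

The half peak-to-trough amplitude `A` is the least-absolute-error
coefficient of a cosine at the detected `(T, φ)` — an LP solved exactly by
HiGHS; LAD rather than least squares so a single corrupted time point
cannot dominate.  A negative fit (anti-phase) is clipped to zero with a
warning.  The fold amplitude (peak:trough ratio) is
`(p10 + 2A) / p10`, where `p10` is the 10th percentile of the series
(linear interpolation between order statistics — percentile dialects
differ, so this is pinned down deliberately) used as a robust trough
estimate; it requires strictly positive expression.

Phases are circular quantities.  Differences are wrapped into
`(−m/2, m/2]` with modulus `m = 24` h for circadian rhythms and `m = 12` h
for harmonics (a 12-h rhythm's peak time is only defined modulo 12).  The
sign convention: `circular_phase_difference(wildtype, rescue) > 0` means
the rescue peaks earlier (a phase advance).

## Cross-condition classification

Per condition, a significant gene is `circadian_24` when its period is
≥ 20 h, `harmonic_12` when its period lies in [10, 14] h, and
`long_period` otherwise; non-significant genes are `arrhythmic`.  Across
conditions: `rescued_24h` requires a significant circadian call in both
wildtype and rescue; `harmonic_reverted` requires a wildtype harmonic call
(either significant, or — for genes on a user-supplied known-harmonics
list — a harmonic-band period at a relaxed `p < 0.1`, the convention used
for re-assessing previously described 12-h genes) together with a
circadian rescue call; `wildtype_only`, `non_wildtype_cycler` and
`arrhythmic_everywhere` cover the remainder.  Rescued genes whose
rescue/wildtype fold-amplitude ratio is at least 0.75 are flagged as
system-driven candidates — genes whose amplitude barely depends on the
local clock; the flag is reported alongside, never as a separate class.

Harmonic-panel phase similarity is assessed against the panel's cluster:
a gene is phase-similar when both its wildtype and its rescue peak time
(mod 12) lie within 3 h of the respective group circular mean.  A
pairwise wildtype-vs-rescue comparison would not isolate outliers whose
phase is internally consistent but offset from the rest of the panel,
which is exactly the observed outlier pattern in the published 11-gene
panel (10 of 11 cluster; Samd8 does not).

Amplitude-reduction counts support strict (`rescue < wildtype`) and
tie-inclusive comparisons.  On tables printed at one-decimal precision the
two bracket the count computed from unrounded values; the strict count is
the default.

## Synthetic data generator

Expression is `B · (1 + Σ_k a_k w_k(t)) · ε` with per-gene baseline `B`
log-normal (median 100, log-sd 0.5) and multiplicative log-normal noise
`ε` of unit mean and CV `noise_cv` (default 0.1) — multiplicative so that
fold amplitudes are scale-free.  Relative amplitudes `a` are uniform on
[0.3, 0.6], giving noiseless fold amplitudes of roughly 1.8–2.8, the range
where the bulk of detected cyclers sit in real liver data.  Component
structure per class:

* **arrhythmic** — no components anywhere.
* **local_only** — one 24-h cosine in wildtype only.
* **rescued** — the same 24-h cosine in wildtype and rescue.  The rescue
  amplitude is attenuated on the *fold* scale: the generator solves
  per gene for the rescue amplitude whose noiseless peak:trough fold is
  `rescue_amplitude_factor` (default 0.8) times the wildtype fold, since
  the published amplitude comparison is a peak:trough statement.  In the
  mutant the component runs at a long free-running period drawn from
  `Normal(27.6, 4.5)` h (clipped to the 10–40 h scan window) at 0.3× the
  wildtype relative amplitude — residual rhythmicity of a hypomorphic,
  not null, clock.
* **harmonic** — the wildtype 12-h rhythm is the sum of two equal circular
  peaks 12 h apart, `exp(κ(cos−1))` (von Mises shape): a systemic peak
  that persists in rescue and a local peak lost outside wildtype; flat in
  the mutant.  Two pure anti-phase cosines would cancel identically, so a
  peaked waveform is the *only* way to realise a two-peaks-per-day rhythm
  in this additive form.  The sharpness default κ = 2.45 is the root of
  `2·I₂(κ) = I₁(κ)`, at which the 12-h Fourier fundamental of the
  two-peak waveform equals the 24-h fundamental of the single peak — the
  generator thereby embodies, structurally, the observation that harmonics
  revert to 24-h rhythms with no loss of amplitude.

Phases are uniform on [0, 24) in every class (rescued rhythms peak at all
times of day).  All randomness flows from the mandatory seed; identical
configurations are bit-identical.  The default class sizes
(200/100/100/60) keep every class large enough for recovery scoring while
the full three-condition analysis still runs in a few seconds.

What the generator does **not** emulate: probe-level array noise, batch
and hybridisation effects, RNA degradation, inter-animal variability and
pooling structure (a `replicates` option averages noise draws but defaults
to 1, matching the one-array-per-time-point design), non-sinusoidal
circadian waveforms beyond the harmonic class, and correlated noise across
genes.  Passing recovery tests therefore demonstrates correctness of the
analysis chain under the declared generative model, not performance on
real arrays.

## Numerical choices

* Reference tie tolerance 1e−9 on cosine values; transitive grouping
  along the sorted order.
* Winner tie-breaks: smallest period, then smallest phase; `|τ|`
  comparisons use a 1e−12 slack so exact rational ties are not split by
  float noise.
* Exact-null masses are ratios of exact integers, converted to float at
  the end; masses sum to 1 within 1e−12 and the whole-support tail is
  returned as exactly 1.
* LAD amplitude fits: HiGHS LP, variables (baseline, amplitude,
  residuals); noiseless cosines are recovered to ~1e−9.
* Degenerate inputs: constant series → zero amplitude and undefined
  period; non-positive 10th percentile → error naming the gene; empty
  phase-pair lists and empty gene tables → errors.

## Problem sizes used by the test suite

Property tests use the defaults above (460 genes × 3 conditions), 5 000
arrhythmic genes for the false-positive-rate measurement, full `n!`
enumeration up to `n = 8` for the null-distribution cross-check, and
1 000 random vectors for the BH cross-check.  These sizes make the whole
suite run in well under a minute while keeping Monte-Carlo standard errors
small relative to the asserted tolerances.

## Known limitations

* **The min-over-references p-value is anti-conservative.**  Per
  reference, the exact p-values are calibrated (measured
  `P(p ≤ α) ≤ α`).  But the default scan reports the minimum tail over
  ~775 correlated references, and on pure-noise genes the measured rate of
  `p < α` is ~27× α at α = 0.01 and ~42–46× α at α = 0.0011.  This is the
  long-documented behaviour of this family of scan statistics when the
  per-reference p is quoted uncorrected; the package measures it honestly
  in its test suite rather than hiding it.  Consequences: the arrhythmic
  background contributes false positives at well above the nominal rate,
  which also caps the achievable recall of the `arrhythmic_everywhere`
  class (~0.87 at defaults).  Users who need strict type-I control should
  enable `bonferroni=True` (conservative) or rely on the BH q-values
  computed across genes.
* **Period resolution.**  Two days of 2-h sampling cannot distinguish
  24 h from 23/25 h reliably; noiseless signals are recovered exactly, but
  noisy 24-h genes occasionally report 22 or 26 h.  Recovery claims are
  therefore stated to within one sampling interval (2 h).
* **Per-gene amplitude jitter.**  A 12-h rhythm leaves only 6 samples per
  cycle, so LAD cosine amplitudes of individual harmonic genes jitter by
  ~±10%; amplitude-preservation statements are panel-level (medians), as
  is the corresponding published comparison.
* Harmonics below the scan window (8-h rhythms) are out of scope, as are
  raw-array preprocessing, enrichment analysis and behavioural-record
  analysis.
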