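# Methods

## The amortised lethality score

Heat mortality of stored-grain insects behaves like a dose: published
lethal-time tables for the rice weevil shrink roughly geometrically with
temperature (hours near 42 °C, minutes near 50 °C). The score models this
with an explicit halving law: the exposure needed for one lethal dose at
binned level *t* is `D · 2^{-(t-T)}` minutes, with threshold `T = 40 °C` and
normaliser `D = 1440` min (one day). An episode — a maximal run of readings
at or above `T` — accumulates `g_t / required(t)` over its temperature bins;
the floored sum `Ŝ` labels it effective when ≥ 1. Dropping below `T` resets
the sum: partially accrued doses do not carry across interruptions, which
understates rather than overstates lethality.

Numerical choices:

- **Binning.** Readings are binned downward (`floor` relative to `T`,
  1 °C bins by default), again the conservative direction; bin width is
  configurable.
- **Time credit.** Each reading contributes its full cadence (15 min by
  default) to its bin; no interpolation between readings, matching logger
  granularity.
- **Flooring tolerance.** `Ŝ = ⌊raw + 10⁻⁹⌋`, so an exposure that reaches a
  dose exactly is not lost to float round-off.
- **Per-reading labels.** The paper-style dataset labels single readings.
  In the default `running` mode a reading is positive once its episode's
  cumulative raw score reaches 1 (the reset wording implies a running
  quantity); `end_of_episode` mode instead back-labels the whole episode by
  its final verdict. Episodes are defined by threshold crossings only —
  calendar days play no role beyond the normaliser `D`.

The test suite checks the score against an independent per-minute simulator
(expanding every reading into one-minute ticks) and its structural laws:
monotonicity in duration and temperature, the exact doubling law
`raw(T+1, m) = raw(T, 2m)`, and the reset inequality.

## Synthetic field campaign

The generator emulates the implied study: an 11-day Canadian-prairie summer
campaign (a 5-day part with nightly mixing/stacking, then a 6-day part
without), four bag treatments logged at 15-minute cadence, and a
weather station. It is a statistical stand-in, not a physical model — no
calibrated heat-transfer model of grain bulks is attempted.

**Weather.** Ambient temperature is a diurnal sinusoid (mean 23 °C,
amplitude 8 °C, peak 15:00) plus day-level heat-wave offsets (σ = 1 °C,
standardised within the campaign so every campaign has a comparable hottest
spell) and short-memory noise. RH is anti-correlated with the diurnal cycle
with substantial measurement noise; solar flux is a clear-sky bell (900 kJ/m²
per 15 min at noon) attenuated by day-level cloud and rain (P = 0.15/day);
radiation is the day-cumulative integral with measurement noise; wind,
direction and pressure are nuisance series with no causal path to the label.
A deliberate design rule: *persistent* within-day noise is kept minimal,
because slowly varying station noise would act as a day fingerprint that
lets row-level cross-validation memorise episodes through their neighbours
rather than learn the planted structure.

**Bag thermal response.** The bag-bottom temperature relaxes towards
`T_eq = ambient + solar_gain · flux + mixing_boost · mix` with a
mass-dependent time constant (110/150/215 min for 16/21/25 kg — grain
insulates, so thicker bulks lag more), explicit-Euler integrated at the
cadence, plus a slowly varying unobserved disturbance (AR(1), σ = 2.6 °C,
~5 h memory) standing for substrate, handling and sensor-placement effects
the weather record cannot explain. Solar gain rises with mass (a larger
absorber) while the lag also rises, so the *peak* response has an interior
maximum at the 21 kg boxed bag — the planted headline effect; the boxless
bag's gain is reduced to 42 %. The calibration (gains 0.0100/0.0198/0.0115
°C per kJ/m² for 16/21/25 kg in box) was chosen so that, across campaigns:
positive prevalence falls in the 0.5–3 % band around the benchmark's implied
~1.27 %; the 21 kg boxed bag dominates time above 40 °C; most lethal episodes
occur in that treatment; and whether a given warm afternoon actually labels
is decided largely by the unobserved disturbance, so instantaneous weather
alone cannot resolve it.

What the generator does *not* reproduce: row-level fidelity to the deposited
table, spatial temperature gradients within bags, multi-sensor structure,
autocorrelated weather fronts, or sensor dropout. Passing tests therefore
demonstrate correctness of the pipeline's machinery and recoverability of
planted structure, not performance on real field data.

## Class imbalance study

The four experiments run each model family on the original table and on
three rebalanced variants (random oversampling, SMOTE, random
under-sampling), under stratified 10-fold CV. The default
`resample_before_cv` placement applies the transform to the whole table
before splitting — this is the published protocol and is leakage-prone,
since replicated or interpolated minority rows straddle fold boundaries; the
near-perfect scores it produces are characteristic of that leakage. The
`resample_within_fold` mode is the methodologically sound alternative and is
exposed with equal prominence; a test asserts that the leaky mode reports
strictly higher minority recall. Because an 11-day campaign carries only a
few dozen positive rows, single-campaign CV metrics are noisy; the
acceptance surfaces therefore aggregate the protocol over three replicate
campaigns (fixed seeds) and assert the qualitative pattern on the replicate
means.

SMOTE follows the original algorithm: synthetic minority points interpolate
between a minority row and one of its k = 5 nearest minority neighbours
(Euclidean distance on z-scored continuous features); binary and one-hot
features are copied from the seed row, which preserves the treatment
invariant — interpolation would create fractional flags. Metrics use the
0/0 → 0 convention, so an all-negative predictor reports zero
precision/recall/F1 next to ~99 % accuracy, the canonical imbalance trap.
Both positive-class conventions are supported and every report names its
positive class, because the published per-class tables are only jointly
consistent when the majority class is read as positive.

## Shapley explanation

Attributions target the class-1 probability (the forest's vote fraction)
under the interventional value function
`v(S) = E_r~background f(x_S, r_!S)`, which guarantees the dummy property
(a feature no tree splits on gets zero credit) and exact additivity
`base + Σφ = f(x)` with `base = E_r f(r)`. Three routes:

- `tree_path` — exact and fast for the tree and forest. For each
  (target, reference) pair, each leaf's path constraints split the features
  into a set only the target satisfies (size *a*) and a set only the
  reference satisfies (size *b*); all other features are free. The Shapley
  weight of such a leaf has the closed form
  `w⁺(a,b) = Σ_k C(m,k)(a-1+k)!(p-a-k)!/p!` for each required feature and
  the symmetric `w⁻` for each blocking feature (m = p − a − b free
  features), precomputed for all (a, b). Zero-valued leaves are skipped.
- `exact_subsets` — brute-force enumeration of all 2^p coalitions
  (p ≤ 12), the independent oracle used in tests; the tree route matches it
  to < 10⁻⁹ on stumps and small forests.
- `sampling` — permutation Monte Carlo for any model (the only route for
  gradient boosting, whose logistic link breaks tree-additivity in
  probability space); additivity then holds to Monte-Carlo tolerance.

The default background is the model's training table (for the balanced
under-sampled table, its mean vote fraction — the base value — sits near
0.5); a `max_background` option subsamples large backgrounds, seeded.
Conditional-expectation flavour is recorded in each attribution's metadata.
Global importance ranks features by mean |φ| (ties alphabetical) with a sign
flag from the mean signed φ; force decompositions order positive and
negative pushes by magnitude.

## Field statistics

Daily summaries per treatment: time above 40 °C (strictly above, per the
field convention) and degree-minutes with base 40 °C — the base is not
spelled out in the source literature's text, and 40 °C keeps the dose scale
aligned with the lethality threshold; both are configurable. Group
comparisons use classical (mean-centred) Levene, one-way ANOVA, and
Tukey-Kramer HSD via the studentised-range distribution with the unequal-n
correction. Compact letters assign one letter per maximal clique of the
"not significantly different" graph, which guarantees the display invariant
(significant pairs never share a letter; non-significant pairs always do).
All are verified against hand-computed sum-of-squares oracles. The published
field ANOVA values themselves require the unpublished per-replicate field
data and are not reproduction targets; the degrees-of-freedom structure
(4 treatments × 3 replicates → F₃,₈) is reproduced on synthetic replicates.

## Scale of the shipped experiments

Tests and the acceptance script run the default 11-day, 4 224-row campaign;
the four-experiment study uses three replicate campaigns and the explanation
study ten, sizes at which the full suite completes in a few minutes while
every stochastic assertion retains a comfortable margin.

## Known limitations

- The thermal stand-in is first-order and lumped; it cannot express
  inversion layers, wind-driven convective loss or within-bag gradients.
- Episode rows are temporally autocorrelated, and row-level CV is therefore
  optimistic on original data even without resampling leakage; the package
  exposes but does not default to grouped splitting.
- SMOTE's copied-flag rule keeps one-hot validity but slightly sharpens the
  treatment marginals of the synthetic minority.
- `exact_subsets` is exponential by construction and refuses more than 12
  features.
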