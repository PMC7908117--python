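# Methods

## The model family

Grey relational analysis treats association as geometric similarity of
curves. One reference sequence x₀ and n comparison sequences x₁…xₙ are
observed at m aligned points k = 1…m; each model first normalizes every
sequence with an *image operator*, then condenses the pointwise or
integral closeness of the normalized curves into a degree in (0, 1].

Image operators (`greyrank.sequence`):

* **mean image** x′(k) = x(k)/x̄ — removes units/scale; mean of the image
  is 1. Undefined for zero-mean series (rejected with `ZeroMeanError`).
* **initial-value image** x(k)/x(1) — removes scale relative to the start;
  undefined when x(1) = 0.
* **zero-start image** x(k) − x(1) — removes location.

Degrees (`greyrank.models`, `greyrank.synthesis`):

* **Deng's degree**: coefficients γᵢ(k) = (Δmin + εΔmax)/(Δᵢ(k) + εΔmax)
  on mean-image deviations Δᵢ(k), with Δmin/Δmax taken *jointly* over all
  comparators and all points, and the degree the arithmetic mean of a
  comparator's coefficients over all m points. Because the extremes are
  global, the model couples the whole panel: adding a comparator changes
  every coefficient.
* **Absolute degree**: signed-area statistic s = Σₖ₌₂^{m−1} z(k) + ½z(m)
  of each zero-start image z, combined as
  (1+|s₀|+|sᵢ|)/(1+|s₀|+|sᵢ|+|s₀−sᵢ|). Equal to 1 iff the areas agree;
  invariant under additive shifts of either series.
* **Relative degree**: the same statistic on zero-start images of
  initial-value images; invariant under positive scaling of either series.
* **First synthetic degree (SDGRA)** θ·absolute + (1−θ)·relative and
  **second synthetic degree (SSGRA)** θ·Deng + (1−θ)·absolute, θ ∈ [0, 1].
  θ always weights the first argument; at the conventional θ = 0.5 the
  orientation is immaterial.

Ranking is by descending degree with competition ranks: a comparator's
rank is 1 plus the number of strictly larger degrees, so exact ties share
the smaller rank number (1, 1, 3) and are flagged on the
`RankTable`.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| ε | resolution coefficient damping the global-maximum deviation in Deng's coefficient | 0.5 | conventional choice; any value in (0, 1] accepted |
| θ | blend weight of the synthetic degrees | 0.5 | convex combination, [0, 1] |
| decimals | display rounding of degree rows | 4 (5 for SSGRA) | half-up on the shortest decimal repr; display only, never fed back into computation |

## Numerical and design choices

* **Averaging Deng coefficients.** The degree divides by the number of
  observation points m (the only reading under which the degree is the
  mean of a comparator's coefficients over k), not by the number of
  comparators.
* **Degenerate Deng panel.** If every comparator equals the reference
  after mean normalization, Δmax = 0 and the coefficient formula is 0/0;
  all coefficients are then defined as 1, the limiting value as the
  deviations vanish.
* **Zero-start operator.** Defined as x(k) − x(1), the standard
  grey-systems convention; it makes the absolute degree exactly
  shift-invariant.
* **Relative-degree normalization.** The initial-value image x(k)/x(1) is
  the default. A mean-anchored variant (divide by the series mean) is
  exposed as `relative_degree(..., image=ImageKind.MEAN)` for users who
  prefer comparing deviations from the average level; it is an
  alternative, not the default semantics.
* **Length-2 sequences.** Allowed — the middle sum of the area statistic
  is empty and s reduces to half the end point — but a warning is issued
  because the integral degrees are degenerate at m = 2.
* **Missing values** are rejected, not imputed: every bundled and
  generated panel is complete, and imputation policy belongs upstream of
  the analysis.
* **Observation order** is preserved exactly as given. Deng-type degrees
  are permutation-insensitive in the degree value, but the per-point
  coefficient matrix is only reproducible if order is stable.
* **Input dialect.** One wide CSV format (rows = observations, columns =
  series, optional leading label column; UTF-8, comma delimiter, period
  decimal mark). Long format is deliberately unsupported to keep parsing
  unambiguous.

## Bundled data and the verification harness

`greyrank.data` ships the region-level healthcare panel (mean satisfaction
score plus five resource indicators over eight regions — the four economic
regions and four municipalities of mainland China — for pooled 2013&2015,
2013, and 2015) and the published degree/rank tables of all five models
for those periods plus per-region Deng rows. Values are embedded as
text-exact decimals; an SHA-256 checksum over the panel values is frozen
in the test suite. The aggregate "total" row is excluded from the panel:
it is a weighted aggregate of the regional rows, not an observation.

Two checks are *asserting* because they depend only on the published
numbers themselves:

1. every published synthetic cell equals the θ = 0.5 blend of its two
   base-model cells within 5e-5 (the published values are printed at 4–5
   decimals, so rounding can contribute up to half a unit in the last
   place, i.e. 5e-5);
2. re-ranking every published degree row reproduces the published rank
   row exactly (23 rows).

The synthetic-degree component pairing — SDGRA = blend(absolute,
relative), SSGRA = blend(Deng, absolute) — is verified numerically by
check 1 across all 30 cells.

A third operation recomputes all five models from the bundled regional
panel and reports the comparison (degree differences, rank agreement,
Kendall's τ). It is informational only: the published degree values were
produced from sequences whose construction (what k indexed; how individual
survey scores were paired with province-level resources) is not stated, so
they are not reproducible from the printed regional means alone. On the
pooled panel the recomputed Deng ranks happen to match the published Deng
rank vector exactly; the integral-model degrees do not, as expected.

## Synthetic panels and what they show

`greyrank.simulate` plants a known similarity ordering: comparator j is
(1−λⱼ)·x₀ + λⱼ·u + N(0, noise_sd²), with x₀ and the distractor u drawn
i.i.d. uniform on [1, 10] — the magnitude of per-thousand-population
resource indicators — and values clipped at 1e-3 so every panel satisfies
all model preconditions. Strictly increasing λ's make the intended rank
vector simply 1…n; λ = 0 plants an exact copy of the reference, which every
model must score 1. Defaults (m = 8, n = 5, λ = 0, 0.1, 0.3, 0.6, 0.9)
mirror the scale of the bundled eight-region, five-factor panel.

The recovery experiment runs seeded replicates (seeds seed, seed+1, …) and
reports, per model, the frequency of exact recovery of the λ order, the
frequency with which the λ = 0 comparator is ranked first, and the mean
Kendall distance to the planted order. With no noise, recovery is exact
for all five models across the seeded replicates used in the tests; with
additive noise it degrades monotonically over the tested grid
(0, 0.1, 0.5).

The mixture family is a deliberately clean target: it produces smooth,
positive, complete panels whose true ordering is monotone in λ for every
model. It does not emulate survey-score distributions, spatial correlation
between resource indicators, measurement error that scales with level, or
missing data — so passing recovery tests demonstrates correctness of the
degree computations and ranking logic, not robustness of GRA on real
survey panels.

## Problem sizes

The bundled analyses are tiny (m = 8, n = 5) and run in milliseconds. The
test suite cross-checks the vectorized degrees against naive loop-based
transcriptions on 1,000 random panels (m ≤ 5, n ≤ 4) at 1e-12, exercises
the invariances on 500 random panels, and runs the recovery experiment at
100 replicates per noise level; the whole suite completes in a few
seconds.

## Limitations

* Deng's model weights all observation points equally; no per-point
  weighting is offered.
* Degrees quantify curve similarity, not causation or statistical
  significance; no inference on rank differences is provided.
* The θ ≠ 0.5 behavior of other software that prints synthetic degrees is
  not emulated; this package defines θ as weighting the first blend
  component and documents it.
* Panels must be complete and aligned; no resampling, alignment, or
  missing-data handling.
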