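# Methods

## Model

The red phase of tomato pericarp colour development is modelled as

a\*(x) = α / (1 + e^(βx)) + γ,

with x the storage period in days since harvest, α > 0 the amplitude (a\*
units), β < 0 the rate (1/day), and γ < 0 the offset (a\* units). The curve
rises from the lower asymptote γ to the equilibrium (fully-ripe) plateau
α + γ, typically 24–36 a\* units for the packaged parameter sets. The model
deliberately describes only the red phase (a\* > 0): evaluated at small x it
produces large negative values (e.g. −288 at day 0 for Miracle at 12 °C)
that have no physical meaning, which is why trajectory data are partitioned
at a\* = 0 before fitting and why pattern queries before the lag return a
`PRE_BREAKER` marker instead of a number.

Breaker is defined as a\* = 0, so the onset of red colour development — the
*time lag* — follows analytically:

lag = ln[(α + γ)/(−γ)] / β.

The generalised inversion for any target a\* strictly inside (γ, α + γ) is
x = ln(α/(a\* − γ) − 1)/β; at a\* = 0 it reduces algebraically to the lag
formula, and the two implementations agree to ~10⁻¹² relative (they differ
only in floating-point association).

### Identifiability

Only the upper limb of the logistic is observed (measurements start well
after the inflection at x = 0), so α and γ are strongly anti-correlated:
very different (α, γ) pairs with similar α + γ and similar lag produce
nearly identical curves over the observed range — the packaged Momotaro
York 25 °C set (α = 4671.1, γ = −4645.22) next to its 30 °C neighbour
(α = 186.7, γ = −161.8) illustrates the spread. All recovery claims in the
tests are therefore about the *predicted curve* over the observed day range
and the *derived lag*, never about raw parameter values.

## Fitting

Per fruit, points with a\* ≥ 0 (exact zeros belong to the red phase by the
breaker definition) are fitted by `scipy.optimize.least_squares` (trust
region reflective) with bounds α ∈ (0, 10⁵], β ∈ [−5, 0), γ ∈ [−10⁵, 0)
that enforce the valid-curve region without constraining realistic
magnitudes. Initialisation uses the observed upper-limb geometry:
γ₀ = −2·max(a\*), α₀ = 3·max(a\*) (so α₀ + γ₀ equals the observed maximum),
β₀ = −0.2/day; on non-convergence a multi-start over β₀ ∈ {−0.05, −0.2,
−0.6} is tried and the best solution kept. Convergence tolerances are
ftol = 10⁻¹⁰ and xtol = 10⁻¹², max 10⁴ evaluations — cheap at ~10–60 points
per fruit. A fit needs at least 4 points on 3 distinct days; persistent
optimiser failure is reported as `converged=False`, not an exception, so a
cohort run always completes.

Goodness of fit reports R² = 1 − SSE/SStot about the observed mean, RMSE,
and %RMSE = RMSE / √(Σ a\*obs²) × 100. Note the %RMSE denominator is the
root of the raw *sum* of squares (not the mean), so the statistic depends
on n for a fixed signal level; it is kept in that form for comparability
with the convention it comes from.

Universal curves are arithmetic means of per-fruit (α, β, γ) within one
cultivar × temperature group (temperatures matched to 0.01 °C). Because of
the α–γ anti-correlation the mean of parameters is not exactly the mean of
curves, but at the cohort sizes and noise levels modelled here the lag of
the averaged parameters tracks the generating lag well (median absolute
error ≈ 0.3–0.4 day over 100 five-fruit cohorts; see the acceptance suite).
Averaging uses converged fits only by default; `require_converged=False`
includes everything.

## Lag versus storage temperature

Per cultivar, the analytic lags of the temperature-wise average parameter
sets form knots (T, lag) to which a cubic c₀ + c₁T + c₂T² + c₃T³ is fitted
by least squares (`numpy.polynomial`). With exactly four distinct knots the
cubic interpolates them; with the default five it smooths. Predictions
outside the experimental span 12–30 °C raise an error unless extrapolation
is explicitly enabled, because ripening above ~30 °C is physiologically
abnormal (lycopene synthesis is repressed) and the cubic carries no
information there.

**Known limitation — non-monotonicity inside 12–25 °C.** The knot lags
themselves shorten strictly from 12 to 25 °C for all three cultivars, and
lengthen again at 30 °C (markedly for Momotaro York: 8.45 d at 25 °C vs
9.70 d at 30 °C; mildly for Rei-getsu; not for Miracle). Fitting a single
cubic through all five knots lets that 30 °C upturn pull the polynomial's
local minimum *below* 25 °C: the fitted cubics stop decreasing at ≈ 23.2 °C
(Miracle), ≈ 24.7 °C (Rei-getsu) and ≈ 21.4 °C (Momotaro York), with rises
of 0.003–0.72 day between the minimum and 25 °C. The intuitive property
"warmer storage up to 25 °C always shortens the lag" therefore holds for
the knots but not for the continuous cubic, and the acceptance test that
asserts it on a fine grid fails by design rather than being weakened. Users
interpolating near 21–25 °C should expect the cubic to be locally flat and
up to ~0.7 day above the 25 °C knot for Momotaro York.

## Stage tables

Storage periods to named USDA stages are continuous inversions of the
universal curve at per-stage a\* thresholds, rounded to whole days.
Rounding is nearest-day with halves up by default (ceil/floor/none
selectable), and is applied only at reporting — every internal computation
keeps the fractional day. Breaker (a\* = 0) is definitional; the shipped
thresholds for turning (5), pink (10), light red (16) and red (22) are
illustrative waypoints on the a\* scale, clearly not a published
calibration, since the USDA stages are defined by percentage of red
surface. Thresholds must be strictly increasing; stages whose threshold
meets or exceeds a curve's equilibrium are dropped from the table with a
warning (a plateau of 24.9 can never reach 26).

## Synthetic cohorts

The generator emulates a constant-temperature storage trial:

- **Initial colour**: per fruit, a latent harvest a\* is drawn from a
  normal(−5.5, 0.3) truncated to [−6, −5] — the band observed for
  mature-green fruit at harvest.
- **Green phase**: an exponential relaxation a₀·e^(−kd) toward 0, with k
  calibrated so the baseline passes a\* = −1 one day before the (shifted)
  breaker. This branch is illustrative plumbing: the red-phase model says
  nothing about the green phase, and the generator's green branch exists so
  the partition logic and skip paths are exercised; it is never fitted.
- **Onset variability (the metachronous property)**: each fruit's sigmoid
  is shifted horizontally by s ~ N(0, 1 day). The shift leaves (α, β, γ)
  shared within a cohort, isolating onset variation as a single knob. A
  shifted sigmoid is not exactly representable in the unshifted three-
  parameter family, which mimics how real per-fruit fits absorb onset
  differences into large compensating α/γ values.
- **Composition**: latent(d) = max(green(d), sigmoid(d − s)). The maximum of
  two increasing functions is increasing, hands over exactly where the
  sigmoid overtakes the baseline, and equals the sigmoid at every day at or
  after the shifted lag. (A branch rule switching on the sigmoid exceeding
  the initial a\* would jump discontinuously at the switch; the max avoids
  that.)
- **Measurement**: daily sampling for 1.5 × lag + 20 days (covering the
  plateau), plus additive homoscedastic Gaussian noise, sd 0.5 a\*. At that
  noise level simulated per-fruit fits score R² ≈ 0.99 and RMSE ≈ 0.4–0.6,
  inside the ranges real fits produce.
- **Determinism**: every draw for fruit i derives from (master seed, i), so
  cohorts are bit-reproducible and fruit i's trajectory is invariant under
  cohort subsetting.

What the generator does *not* emulate: heteroscedastic or autocorrelated
measurement error, per-fruit curve-shape variation (only onset varies by
default), plateau drift, mixed or speckled colouration at 30 °C, and
dynamic storage temperatures. Passing tests on synthetic cohorts therefore
demonstrate correctness of the estimation machinery under the stated
statistical structure, not robustness to every feature of real trials.

## Problem sizes in the test suite

The Monte-Carlo recovery check runs 100 five-fruit cohorts per cultivar
(temperatures cycled across the five available), ~1500 per-fruit fits in
total, and asserts the median absolute lag error < 0.5 day with every
per-fruit R² ≥ 0.90. The bisection-oracle check covers 100 random valid
parameter sets with amplitude 50–5000, rate −1 to −0.05/day and equilibrium
15–35.

## Numerical notes

- The exponent βx is clipped to ±700 before `exp` to avoid overflow at
  extreme arguments; in the physical range (0–60 days, |β| ≤ 5) the clip is
  never active and results are unchanged.
- Whole-day rounding uses floor(x + 0.5) (half up) rather than banker's
  rounding, so 4.5 → 5.
- Strict-inequality properties (monotonicity, open-interval bounds) are
  asserted where double precision can resolve them; at saturation
  (|βx| ≳ 35) the sigmoid is numerically equal to its asymptote.
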