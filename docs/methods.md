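# Methods

## Scope and data model

The package analyzes two kinds of raw data: (1) intermittent-flow
respirometry traces — oxygen concentration (mg O2 l-1) sampled in a
sealed chamber that alternates flush (re-oxygenation) and measure
phases — and (2) cardiac heating-ramp tables — maximum heart rate
(f_Hmax, bpm) per stabilized 1 °C step under pharmacological vagal
blockade and β-adrenergic stimulation, optionally derived from beat
timestamps. Raw timestamps are in seconds; rates are reported in
mg O2 kg-1 min-1, and the per-second-to-per-minute conversion happens
exactly once, inside the slope fit.

## Oxygen uptake from slopes

Each measurement window is fit by ordinary least squares of
concentration on time (minutes); r2 is the squared Pearson
correlation, defined as 0 for a flat trace (a rateless window must
fail every validity gate). Mass-specific uptake is
`MO2 = |slope| * (v_R − v_F) / m`, with the fish volume assumed equal
to its mass (1 kg ≈ 1 l). Chamber volumes are carried in liters
(e.g. 0.566 l for a 13 × 8.7 × 5.5 cm chamber; vendor-style "total"
volumes quoted in the hundreds are read as milliliters, since a box
of those dimensions holds ~0.6 l).

Microbial background respiration is modeled as a first-order
exponential `B(t) = b0 e^{kt}` anchored at the mean blank-chamber
slope magnitudes before (t = 0) and after (t = span) the trial, and
`B(t_mid)` is subtracted from each window's slope before conversion.
Degenerate anchors fall back gracefully: a nonpositive initial blank
gives linear growth from zero (the exponential form is undefined
there); both nonpositive give a zero model; nonphysical positive
blank slopes are clamped to zero magnitude with a warning. A
corrected slope below zero yields MO2 = 0 and a flag; gates and flags
are pure filters and never alter stored values.

## Traits

**MMR** is the steepest decline over all windows of length
≥ 120 s starting at 1-s increments within the post-chase measurement
phase (5–7 min), gated at r2 > 0.9, implemented with prefix sums so
the exhaustive search is exact; ties break to the earliest start,
then the shortest window (verified against a naive per-window
polyfit oracle). **SMR** is the mean of the lowest decile of all
validated (r2 > 0.95) measurements after exercise and after feeding
(outside the handling mask); the alternative reading — the 10th
percentile value itself — is available as `smr_method="quantile"`.
`AAS = MMR − SMR` and `FAS = MMR / SMR` follow exactly.

Whole-animal rates may scale allometrically: log10(whole-animal rate)
is regressed on log10(mass) with the exponent free, fixed at 1.0
(isometric) or fixed at 0.89 (the universal fish exponent), compared
by BIC (`n ln(RSS/n) + p ln n`); models within ΔBIC < 7 of the best
are reported as statistically equivalent. Because experimental
cohorts of near-identical juveniles often cannot identify the
exponent from data, the standardization applied downstream is
configured explicitly (default: isometric SMR, 0.89 for MMR, 5-g
common mass), with the data-driven selection reported alongside.
`scale_to_common_mass` multiplies by `(m/m_common)^{1−b}` and is an
exact identity at b = 1 or m = m_common.

## Recovery

Post-exercise recovery is summarized three ways. (1) A biexponential
`A1 e^{−k1 t} + A2 e^{−k2 t} + c` fitted by variable projection: the
two decay rates are optimized on a log scale (Nelder–Mead from a
small multistart grid) with the amplitudes and asymptote profiled out
by linear least squares — robust to starting values and exact to
~1e-11 on noise-free data; a monoexponential is fitted the same way
and both BICs are reported. (2) Time to an available factorial scope
of 2 (`MMR/MO2(t)`), with samples pooled into 10-min blocks (the
block width is configurable; a single default keeps results
deterministic) and the midpoint of the first qualifying block
returned. (3) Percent of aerobic scope recovered,
`100 (MMR − MO2)/AAS`, clipped to [0, 105]; a logarithmic growth
curve `a + b ln t` (t > 0; the t = 0 MMR point is excluded because
ln 0 is undefined) is fitted by least squares and inverted for the
75% and 100% crossing times, reported as undefined when the curve
does not reach the threshold within the 180-min observation window.
Threshold crossings are evaluated on the fitted curve rather than raw
samples so that per-group times are well defined; group fits pool the
raw per-fish samples. Among-fish variability is the coefficient of
variation of %AAS across fish per timepoint, averaged over timepoints
with positive mean.

## Specific dynamic action

Sham-feeding trials show anesthesia and gavage handling inflate MO2
for 2–3 h, so SDA analysis starts 3 h post-feeding (configurable
mask). The baseline SMR_SDA is the lowest-decile summary of the
postprandial pool itself (empirically equivalent to overnight SMR).
The integration curve starts at (0 h, SMR_SDA), runs straight to the
first node of the hourly-minimum polyline (lowest MO2 of each hour,
at its own timestamp — this suppresses spontaneous-activity spikes),
then follows the polyline; SDA is the trapezoidal integral of the
excess above SMR_SDA over **minutes** (units mg O2 kg-1), up to
SDA_dur, the time of the first node back at or below baseline
(truncated with a flag if the series ends first; zero if the curve
never rises above baseline). SDA_peak is the maximum *raw* masked
value (ties to the earliest), deliberately not hourly-pooled.

Energy bookkeeping: `E_SDA = (SDA/1000) × 13.6 kJ per g O2`;
`E_meal` per kg fish = 10 × ration(% body mass) × 3.87 kJ g-1 × 0.8
digestibility; `SDA_coeff = 100 E_SDA/E_meal`. The scope partition at
peak digestion uses group means:
`scope_used = 100 (SDA_peak − SMR)/AAS`, its complement, the absolute
remaining scope, and `SDA_peak/SMR` beside FAS. Note that published
SDA tables in this literature sometimes carry integrals whose
magnitude implies per-minute rates integrated over hours; this
package integrates over minutes, consistent with the stated unit, and
the energy coefficient is computed from whatever integral it is
given.

## Cardiac thermal limits

Per step, f_Hmax from beat timestamps is `60 × n_intervals / span`.
T_ARR is the first step flagged arrhythmic, or — absent flags — the
first step whose rate falls below 70% of the running maximum
(`drop_frac = 0.3` operationalizes "precipitous decline"; the
original calls were made by visual ECG inspection, so the fraction is
configurable and documented rather than asserted). Peak f_Hmax and
T_PEAK are taken over rhythmic steps before T_ARR, ties to the lowest
temperature; TSM is `T_ARR − T_env` for configurable reference
temperatures (defaults 31 and 33 °C), so TSM differences across
references are exact identities. Assays with fewer than three
rhythmic steps are flagged and excluded from group summaries.
Group thermal performance curves are polynomials of order 1–4 fitted
by least squares to pooled pre-arrhythmia points (all fish), centered
in temperature for conditioning, either one pooled curve or
group-specific curves; BIC over the pooled residuals selects among
all (order, structure) pairs, and a grouped winner constitutes
evidence that acclimation shapes the curve. Arrhenius breakpoint
analysis is deliberately not implemented (too few pre-peak steps at
warm acclimation to identify a breakpoint).

## The synthetic-data generator

The generator emulates one trial end to end. Fish MO2 starts at MMR
(the chase ends at t = 0), decays biexponentially to SMR (default
half-lives 6 and 45 min, 60% fast amplitude — values that put the
available-scope-of-2 and 75%-recovery times in the tens of minutes
typical of small reef fish at ambient temperature), and, if a meal is
configured, rises linearly from feeding to a peak and relaxes
exponentially toward a slight undershoot chosen so the curve first
crosses SMR exactly at the configured duration (peak, time-to-peak,
duration and the closed-form integral are therefore all analytically
known). Background grows as a first-order exponential between
configured fractions of the SMR-driven slope (defaults 0.1 → 0.6,
i.e. ~10% of the resting signal at the start growing to ~60% by the
end); blank cycles bracketing the trial carry exactly the endpoint
magnitudes, so the analysis-side correction is exact in noise-free
tests. Activity spikes are Poisson-timed transient MO2 additions
(default 0.5 h-1, +2 mg O2 kg-1 min-1 for 5 min) included precisely
to exercise the hourly-minimum baseline's robustness.

Within each measure window the fish rate is sampled at the window
start and held, so concentration declines linearly and the
slope-implied rate equals the held rate exactly — the "conservation"
invariant the test suite checks at 1e-9. Flushes restore
concentration exactly to a configurable air-saturation constant
(default 6.8 mg l-1, seawater near 28 °C). Gaussian concentration
noise defaults to 0.01 mg l-1, typical optode precision and the level
at which resting-rate windows of a 5-g fish retain r2 ≈ 0.97 —
consistent with protocols that validate nearly all windows at
r2 > 0.95. Among-fish variation is exposed as per-parameter lognormal
CVs plus a mass CV and a whole-animal scaling exponent tying
mass-specific rates to mass; no particular between-fish distribution
is asserted beyond that. Cardiac ramps follow a Gaussian-bump
performance curve (peak 415 bpm near 37 °C, width 8 °C, 1 °C / 6 min
steps); at the first step at or above the configured arrhythmia
temperature the rate collapses to 40% of the running maximum and the
step is flagged. All generators are bit-reproducible from their seed.

What the generator does *not* emulate: chamber mixing dynamics,
temperature-dependent oxygen solubility (inputs are already mg l-1),
diel or tidal rhythms, regurgitation, or drifting optode calibration.
Passing parameter-recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every
field artifact.

## Problem sizes and numerical choices

Simulation-backed tests use overnight trials of 18–64 h at 2–3-s
sampling, cohorts of 3–4 fish per group, 100-seed recovery sweeps for
SMR and T_ARR, 100 cohorts for scaling-exponent selection and 50 runs
for polynomial-order selection — sizes at which every stochastic
check is stable across seeds while the full suite runs in a few
minutes. Tie-breaks on the sliding-window search use a 1e-12
relative slope tolerance so that exactly collinear data resolve to
the earliest, shortest window. BIC uses the Gaussian profile form
`n ln(RSS/n) + p ln n` throughout, with RSS floored at 1e-300.

## Known limitations

- Group recovery times are computed from pooled per-group samples;
  per-fish curve fitting with group averaging would weight fish
  differently and is not implemented.
- The SMR pool size gate (≥ 10 validated values) makes short or very
  noisy trials fail loudly rather than return unstable quantiles.
- Energy coefficients for rations other than the default assume the
  ration actually retained; regurgitation accounting is the caller's
  responsibility.
- TSM is a difference of point estimates; no uncertainty propagation
  beyond group SEM tables is attempted, and inferential statistics
  (ANOVA families) are intentionally out of scope — the pipeline
  reports mean ± SEM per group.
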