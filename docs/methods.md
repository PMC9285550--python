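# Methods

## Model

A growth reference describes BMI at each age and sex by the LMS triplet
(L, M, S); the z-score of a measurement x is

    z = ((x/M)^L - 1)/(L*S)     (|L| > 1e-7)
    z = ln(x/M)/S               (otherwise)

and the inverse is x = M*(1 + L*S*z)^(1/L) (or M*exp(S*z)). The switch at
|L| < 1e-7 avoids catastrophic cancellation near L = 0; at L = 1e-5 the two
branches differ by ~L*ln(x/M)^2/(2S), i.e. well under 1e-6 anywhere near the
median. The inverse raises an out-of-support error when 1 + L*S*z <= 0 (the
Box-Cox support boundary). L, M and S are interpolated linearly in age,
separately per curve: published tables are tabulated monthly or half-yearly,
where higher-order interpolation changes nothing material, and linearity is
exactly testable.

A category cut-off is a fixed z-score on one reference. Its distance from a
cut-off on another reference is measured symmetrically: each cut-off's BMI
value is scored on both references and the two mean z-scores are subtracted,

    dz = zbar_B - zbar_A = ((z_B - z_A) + (z_B_onA - z_A_onB)) / 2 ,

which is antisymmetric in A and B by construction. The subscript convention
follows the operational ground truth of the published worked example
(boys aged 8, WHO +1 vs IOTF 25: zbar_A = (1.00 + 0.91)/2, zbar_B =
(1.31 + 1.47)/2, dz = 0.435).

Prevalence conversion assumes the target population's BMI distribution
differs from both references only by a shift on the z-score scale. Then with
the probit Z = -sign(z) * PHI^-1(p),

    p_B = PHI(-sign(z_B) * (Z_A + b*dz)),

b = 1 by default. The reverse conversion uses -dz, making the round trip
exact to floating precision. The bias-adjusted preset b = 0.84 (the
equal-weight mean of the five source-by-category validation slopes) shrinks
the shift for target populations whose tails are heavier than the
references'. Conversions are only defined within a category family: the
overweight category must include obesity (cut-offs define tail areas), and a
helper adds net overweight and obesity prevalences.

## Parameters that matter

- **b (slope multiplier, unitless, default 1).** 1 = the pure-shift
  algorithm, fully generalizable and reversible; 0.84 = the bias-adjusted
  preset, better fitting but estimated from two datasets only.
- **Look-up grid (ages 2-18 y by 0.5 y).** dz varies smoothly with age; a
  group's conversion uses the grid age nearest its mean age, exact-midpoint
  ties rounding to the younger age (deterministic and documented).
- **Boundary prevalences.** p = 0 or 1 has an infinite probit; with a known
  denominator n they are continuity-corrected to 1/(2n) and 1 - 1/(2n),
  without one they raise. (The sources are silent here; this is the package's
  choice.)
- **Generic 'IOTF thinness'** resolves to grade 2 (BMI 17 at age 18), the
  grade closest to the WHO and CDC thinness cut-offs, with a warning naming
  grade 1.
- **WHO under-5 band.** BMI-for-age LMS with cut-offs +/-2/+3 is used for
  ages 2-5; the weight-for-height definition used below age 5 by the original
  standard is approximated, not implemented.

## Validation regression

Paired records (one group, two cut-offs) are stacked one row per
group x pair, oriented so dz > 0 to avoid double counting; retaining both
orientations doubles the points. The fit is a no-intercept probit model with
the observed Z_A as offset and b*dz as the only term, maximising a
beta-binomial likelihood for the B-side counts y_B = round(p_B * n):

    y_B ~ BetaBinomial(n, pi, rho),  pi = PHI(-sign*(Z_A + b*dz)),
    rho = c * |dz|,  c >= 0 estimated,

so records with dz = 0 (or c = 0) collapse to plain binomial and the
extrapolation error grows with the cut-off distance. "Dispersion proportional
to |dz|" admits several parameterizations; intra-class correlation is the
simplest faithful one and is flagged in the fit output. Three mean models are
available: b fixed at 1, one common b, or one b per source x category cell
(the grouped model; its equal-weight cell average is the bias-adjustment
constant). Optimization is bounded L-BFGS-B from fixed starting values
(b = 1, c = 0.1) with tolerance 1e-12 on the objective, for determinism; 95%
CIs are Wald intervals from a central-difference observed-information matrix
(when c sits at its zero boundary it is dropped from the Hessian, the
curvature there being one-sided). BIC is k*ln(N) - 2*logL with N the record
count; absolute BIC values are not comparable with other software's
bookkeeping, only orderings are used.

The likelihood weights records by their denominators; a count-weighted and an
equal-weight summary of the grouped slopes are therefore both reported, since
"the overall slope" depends on that choice.

Residual summaries work on the prevalence scale: each record contributes both
prediction directions, the RSD is the root-mean-square residual, the baseline
is the RMS of +/-(p_A - p_B) (predicting each rate by the other unchanged),
and variance explained = 100*(1 - (RSD/baseline)^2). RMS rather than
mean-centred SD is used because both pools are symmetric around zero by
construction. Bland-Altman preparation emits (mean, difference) pairs for the
algorithm's predictions and for the baseline pairs.

## Synthetic data

The generator stands in for real surveillance datasets, which are not
redistributable. Stand-in references use smooth polynomial L/M/S curves with
realistic shapes (median BMI dipping to ~15 kg/m^2 at ages 5-6 and rising to
~21 at 18, S growing 0.08 -> 0.13, negative Box-Cox power), and the three
default stand-ins differ by small median shifts and S scalings chosen so that
the WHO+1 vs IOTF25 distance is of the size seen between the real references
(~0.4-0.6 z) — they are synthetic, and no numeric output computed on them
reproduces tables computed on the real references.

Populations are defined in the base reference's z-metric: a child's z-score
is Normal(z_shift, s_inflation^2). This makes every simulated prevalence
analytic — p = PHI(-sign*(z_cut - z_shift)/s_inflation) with z_cut the
cut-off re-expressed on the base reference — so the pure-shift assumption is
exactly satisfiable (s_inflation = 1) or controllably violated
(s_inflation > 1 fattens both tails, the documented mechanism that biases the
fitted slope below 1). Counts are binomial by default; a beta-binomial option
(rho = c*|dz| on the B side) supports dispersion-recovery experiments. Seeds
are mandatory; identical seeds give byte-identical CSVs.

Two ready-made designs:

- `paper_shaped_design`: two sources mimicking the shape of the published
  validation data — 52 school-survey groups x 2 IOTF/WHO pairs plus 22
  cohort groups x 9 pairs across all three references, 302 records (604 with
  both orientations), group denominators ~1300 and ~930.
- `zshift_setup`: two log-normal (L = 0, equal S) references that are an
  exact z-shift of one another, so slope-recovery experiments have zero
  approximation error: the fitted b estimates exactly 1/s_inflation.

Slope-recovery benchmarks use 300 groups of n = 1300 and two upper-tail
pairs (600 records), a size at which the slope's 95% CI is ~ +/-0.01 and the
full benchmark suite runs in seconds.

What passing these benchmarks does *not* show: real populations are not exact
z-shifts of any reference, real references differ in skewness as well as
spread, survey groups carry design effects beyond binomial or |dz|-linked
dispersion, and the bias constant 0.84 was estimated from two datasets only.
The synthetic results validate the algorithm's mathematics and the
estimator's behaviour under its own assumptions, not its field accuracy.

## Numerical choices and degenerate inputs

- Probit and tail areas via scipy's normal distribution; no approximations.
- Cross-scoring a cut-off on its own reference short-circuits to the stored
  z, so same-reference distances are machine exact.
- Probabilities inside the likelihood are clipped to [1e-12, 1 - 1e-12];
  rho is capped at 0.999; simulated true prevalences at machine 0/1 are
  clamped with a warning.
- A fit with all dz ~ 0 raises (the slope is unidentifiable); fewer than two
  records likewise.
- CSV presentation rounds prevalences to 1 dp and z-scores to 2 dp (dz to
  3 dp in look-up tables); full precision is kept internally. A CLI round
  trip through printed output is therefore exact only to one unit in the
  last printed digit, while the library round trip is exact to 1e-9.

## Known limitations

- Published IOTF/WHO/CDC LMS tables are not bundled; users supply their own
  CSVs for real-data work, and the default registry stores the published
  two-decimal IOTF z-values (an exact BMI-at-18 variant is available when a
  table covering age 18 is loaded).
- No confidence intervals for converted prevalences.
- No individual-level modelling: only grouped prevalences in, grouped
  prevalences out.
- The dispersion model is one reading of "error proportional to |dz|";
  fitted dispersion and BIC values are not comparable with GAMLSS output.
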