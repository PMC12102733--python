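# Methods

## Kinetic model and mechanism taxonomy

Velocities are specific activities (pmol min⁻¹ μg⁻¹); concentrations are
μM throughout the internal computation. The general inhibitor model

v = Vmax·S / ( KM·(1 + I/Ki) + S·(1 + I/Ki′) )

treats Ki (EI complex) and Ki′ (ESI complex) as dissociation-scale
constants; an infinite constant is represented explicitly (`math.inf`)
and the corresponding I/K term is exactly zero, never a large-number
sentinel — this keeps the mechanism taxonomy (none / competitive /
uncompetitive / noncompetitive / mixed as the finiteness pattern of the
two constants) checkable and avoids cancellation. At fixed I the model is
Michaelis–Menten in the apparent constants
KM,app = KM(1+I/Ki)/(1+I/Ki′), Vmax,app = Vmax/(1+I/Ki′); for an
uncompetitive inhibitor KM,app/Vmax,app is independent of I, which is the
structural basis of the consistency check below.

## Unit conventions

One deliberately asymmetric convention: in the substrate-over-velocity
secondary plot, S enters the ordinate in nM while v stays in
pmol min⁻¹ μg⁻¹, so S/v carries "min μg". This is the convention under
which KM = 93.9 μM, Vmax = 33.02 pmol min⁻¹ μg⁻¹ gives
KM/Vmax = 2843.73 min μg, the scale on which the reference crossing
ordinate (3116.68 min μg) is quoted. Everything else is μM.

## Synthetic assay generator

The generator emulates a fluorogenic protease assay in a 96-well plate:
default 0.02 μg enzyme per 100 μL well, substrate grid
{12.5, 25, 50, 100, 150, 200} μM plus S = 0 blanks, inhibitor grid
{0, 6.25, 12, 20, 25} μM, triplicates, reads every 45 s for 1400 s. The
substrate grid is a documented stand-in: assays of this design rarely
report their exact levels, only the 0–200 μM span.

Product formation is either the constant-rate regime
P(t) = v·m·t (used for exactness checks) or, by default, the integrated
rate law dS/dt = −v(S(t), I)·m/V with a fixed-step RK4 integrator at 1 s
internal resolution sampled at the read times — at the default enzyme
load the run consumes well under 1% of the substrate, so the curvature is
mild, which is precisely the regime in which fitting straight lines to
whole progress curves is defensible. Fluorescence is
gain·P(t) + baseline + Gaussian read noise. The default gain
(300 AU/pmol) puts the uninhibited 200 μM well at a few thousand AU over
the run; no absolute AU calibration is claimed.

Noise has two modes. Absolute: a single per-read SD in AU (default 75 AU,
roughly 2% slope CV at the half-saturation well). Relative
(`noise_cv`): each well's read-noise SD is scaled to its own true slope
so that the whole-trace OLS slope has exactly the requested CV — the
shot-noise-like regime used for all quantitative noise studies, where
"2% CV noise" means every extracted rate carries a 2% coefficient of
variation. Blank wells see only the baseline, so in relative mode they
carry baseline-level noise (noise_cv·baseline): tying blank noise to the
signal wells would inject a column-correlated error through blank
subtraction that the assay physics does not support. Optional lognormal
pipetting error perturbs the dispensed concentrations while the metadata
records nominal values. Each well draws from its own generator spawned in
a fixed order from the design seed, so plates are reproducible and
iteration-order independent.

What the generator does **not** model: inner-filter effects,
photobleaching, enzyme inactivation, temperature drift, and well-to-well
systematic gradients. Passing tests therefore demonstrate correctness of
the inference chain under the stated noise model, not robustness to every
artefact of real plates.

## Rate extraction

Rates are OLS slopes of fluorescence vs time over the full 1400 s trace
by default (a sub-window is a config knob; whether real analyses use the
whole trace or a sub-window is usually unstated). An R² curvature guard
(default 0.98) warns when depletion bends a trace. Blank correction is
applied at the slope level — the mean S = 0 slope at the same inhibitor
level is subtracted — because only slopes propagate downstream and
slope-level correction is insensitive to baseline offsets. Replicates
aggregate as mean ± SEM.

## Model fitting

Per-inhibitor Michaelis–Menten fits and the global inhibitor-model fit
use `lmfit` nonlinear least squares, initialised from the Hanes
linearisation (S/v vs S), which is deterministic and derivative-free.
Fits are unweighted by default (optional 1/SEM² weighting); under each
mechanism hypothesis only the constants that mechanism allows are free
parameters, and an infinite constant is structurally removed from the
model expression rather than fitted against a bound. Mechanisms are
compared by small-sample-corrected AIC as a diagnostic only — the verdict
belongs to the graphical method.

Standard errors of the unweighted global fit use the HC3 sandwich
(leverage-adjusted heteroscedasticity-robust) covariance: velocity errors
in these assays are closer to proportional than homoscedastic, and the
classical covariance of an unweighted fit then undercovers (Wald 95%
intervals for Ki′ covered the truth in ~76% of simulated runs; HC3
restores ~92%, verified at 100 seeds in the test suite).

## Graphical discrimination

Secondary lines are unweighted OLS fits of 1/v (Dixon) and S/v vs I on
replicate-mean points, one line per substrate level; levels with any
non-positive velocity are excluded with a warning. The closest-neighbour
intersection minimises the summed **squared** perpendicular distances
Σ (aᵢx + bᵢy + cᵢ)²/(aᵢ² + bᵢ²) via the closed-form 2×2 normal
equations (the squared form is what admits this closed form); two
non-parallel lines give their exact crossing, and a family whose
relative slope spread is below 10⁻⁸ (or a singular normal matrix) returns
an explicit "no finite intersection" value rather than raising.

Parallelism is an extra-sum-of-squares F-test of a shared slope against
free slopes. Internally both models are fitted with variance-stabilising
1/y² weights: the secondary-plot ordinates inherit near-proportional
errors from the velocities, and on raw residuals the test is oversized
(~9% at a nominal 5%). A family counts as parallel when the F-test fails
to reject at α (default 0.05) **and** the relative slope spread stays
below a guard (default 2.0 — generous, because near-zero mean Dixon
slopes under an uncompetitive truth make relative spread a noisy
statistic; the guard exists only to catch gross disparity the F-test
could miss on degenerate inputs). Exactly collinear noise-free families
are decided by the spread alone.

Verdict rule table: Dixon parallel ∧ S/v crossing at x < 0 →
uncompetitive (Ki′ = −x*); S/v parallel ∧ Dixon crossing at x < 0 →
competitive (Ki = −x*); both crossing at x < 0 → noncompetitive when the
two abscissae are statistically compatible, else mixed; anything else
(positive-x crossings, both families parallel, no finite intersection,
untestable parallelism) → indeterminate. Compatibility uses the SE of the
*difference* of the two crossing abscissae from a wild bootstrap on
leverage-corrected Dixon residuals with chi-square scale uncertainty —
the two plots are deterministic transforms of the same velocities
(S/v = S_nM·(1/v)), so their crossings are strongly correlated and
per-plot SEs combined independently would be wrong — against a t-quantile
at the pooled residual dof.

The consistency check reports
100·|y* − r| / mean(y*, r) with r = KM_nM/Vmax from the uninhibited fit.
The mean-denominator convention is used; applied to the reference values
(2843.73 and 3116.68 min μg) it gives 9.16%, matching the reported 9.15%
within rounding, which no other simple relative-difference convention
does.

One naming wrinkle: an uncompetitive pattern is sometimes described as
crossing "in the fourth quadrant" of the S/v plot even though the
crossing sits at x < 0, y > 0 (second quadrant in the usual orientation);
the equations, not the quadrant label, are followed here.

## Calibration and problem sizes

Study conditions for all stochastic checks: the default design,
triplicates, 2% CV rate noise, inhibition constants at 44.3 μM
(competitive, noncompetitive, uncompetitive) and (30, 90) μM for mixed.
Classifier accuracy is assessed over 200 seeded plates per mechanism
(~93–100% per mechanism; the binding error sources are the 5% size of the
parallelism test and the noncompetitive/mixed compatibility boundary).
Median Ki′ recovery error at these conditions is ~4%. The Ki′
confidence-interval coverage property is tested at 100 seeds and the
SEM ∝ 1/√n replicate-scaling property at 25 seeds per arm, sizes chosen
to keep the default suite fast while leaving the binomial noise on each
asserted bar small.

Noise-free checks run in the constant-rate regime: with depletion on and
zero noise, the integrator's deterministic ~0.1% curvature is model
error, not noise, and a significance-based parallelism test has no noise
scale against which to judge it (its p-value degenerates). This is a
limitation of any pure significance rule, not of the estimator.

## Known limitations

* The classifier's operating characteristics are calibrated for the
  default grids; very different S or I spans may need the α and guard
  knobs revisited.
* Tight-binding inhibition (inhibitor comparable to enzyme
  concentration), enzyme depletion, and Bayesian uncertainty are out of
  scope.
* Printed-table SEs of apparent constants from least-squares covariance
  can look implausibly small for triplicate data; only point estimates,
  not SE conventions, are reproduced here.
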