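# Methods

## The measurement model

A well's OD600 time course is treated as a noisy read-out of exponential
culture growth. All kinetics are computed on ln(OD): in the exponential
phase ln(OD) is linear in time with slope μ (h⁻¹), and doubling time is
t_d = ln2/μ (hours per cycle). OD is used as given — no blank subtraction
or path-length correction is applied, and non-positive OD readings are
rejected as errors rather than floored, since ln is undefined there and a
silent floor would bias the slope.

The default measurement schedule has 13 points: hours 12–24 every 2 h and
35–45 every 2 h. The gap mirrors common practice of skipping the late
transition into stationary phase; the paired test below requires matched
time grids across conditions, so missing time points are errors, never
imputed.

## Exponential-window selection

The search interval is 12–20 h (closed endpoints, membership tested on
scheduled times). "Strongest linearity" is operationalized as: enumerate
every contiguous run of at least `min_points` (default 3) scheduled times
inside the interval, fit each by OLS, and among runs with R² ≥ 0.98 choose
the longest, breaking ties by higher R² and then earlier start. Contiguity
is required because growth phases are contiguous in time; longest-first
prefers using all exponential-phase data over cherry-picking a short,
accidentally straight run. If no run passes the gate the best-R² run is
used and the fit is flagged (`below_threshold_flag`), so one noisy well
never aborts a whole-plate analysis; the flag propagates into the kinetics
report.

R² is the OLS coefficient of determination, 1 − SS_res/SS_tot (identical
to squared Pearson r for a simple linear fit). For zero-variance responses
R² is defined as 1 when the residuals are exactly zero and 0 otherwise; a
fitted slope ≤ 0 makes the doubling time undefined and raises.

## Paired time-course test

Two conditions measured on the same replicate layout are compared on
ln(OD), paired by (trial, biological replicate, technical replicate, time).
Replicates are ordered by (bio_rep, tech_rep) ascending — a deterministic
convention; the data provide no intrinsic pairing order. The hierarchy is

- d_i(t) = a_i,after(t) − a_i,before(t) for each replicate i and matched
  time t (all time points, stationary phase included);
- D_i = mean over t of d_i(t);
- D̄_j = mean over the replicates of trial j;
- D̄_bio = mean of the D̄_j, S_bio = their sample SD with denominator
  n_trials − 1 (for three trials this is the usual 1/2 coefficient).

t_obs = D̄_bio/(S_bio/√n_trials) is referred to Student's t with
df = n_trials − 1 and a two-sided tail, p = 2·Pr(T_df ≥ |t_obs|), computed
through the regularized incomplete beta function (scipy's t distribution);
for df = 2 this equals the closed form 1 − |t|/√(2 + t²), which the tests
verify together with numeric quadrature of the density.

When S_bio = 0 the statistic is undefined; the result is flagged
degenerate with p = 1 if D̄_bio = 0 (identical conditions) and p = 0
otherwise. This convention keeps noiseless synthetic inputs from crashing
pipelines while making the degeneracy visible.

Trial-level doubling times are compared with the same one-sample t on the
per-trial differences. The trial-level doubling time is the unweighted
mean of the replicate estimates within the trial — mirroring the
hierarchy above; weighting by biological replicate would be an equally
defensible choice but is not implemented.

## Multiple-testing correction

BH step-up: sort the m raw p-values ascending with a stable sort (ties
keep input order), set q(i) = min(1, m·p(i)/i), then enforce monotonicity
q(i) = min(q(i), q(i+1)) from the largest p downward, and map back to
input order. Capping at 1 follows universal practice. Significance is
q < α with α = 0.05 by default. Stable sorting plus the monotonicity pass
makes the final q tie-order-invariant (asserted by test).

Two family policies are exposed for a strains × comparisons grid:
`per_comparison` (default) adjusts each comparison type across strains as
its own family of m = #strains; `pooled` adjusts all strains ×
comparisons as one family. The worked-example p-value set bundled with the
package yields zero significant calls under either policy; only its
family-maximum adjusted values (0.931 and 0.965) are treated as exact
regression anchors, because intermediate published q-values for such
tables are frequently irreproducible from rounded raw p-values alone —
the bundled set is no exception, and the discrepancy is left documented
rather than resolved.

## Synthetic data generator

The generator emulates the study design the analysis assumes: per strain ×
treatment, `n_trials` (3) × `n_bio` (3) × `n_tech` (3) wells — nine
replicate curves per condition per trial — on the 13-point schedule.

The mean curve is piecewise log-linear: ln n0 for t ≤ t_lag, then slope μ,
then ln k after t_sat = t_lag + (ln k − ln n0)/μ; continuous and
non-decreasing. Defaults: n0 = 0.05 (the standard dilution target),
t_lag = 12 h, μ = ln2/5.2 ≈ 0.1333 h⁻¹ (a 5.2 h doubling time typical of
fission yeast in microculture), k = 2.0. A piecewise model, not a
logistic, was chosen deliberately: the estimator fits an ln-linear window,
so exact in-window linearity makes estimator correctness provable
(zero-noise data must return R² = 1 and slope = μ to machine precision).
The smoothness of real growth transitions is the main feature this shape
does not emulate; passing tests therefore certify the estimator and test
machinery, not the adequacy of any parametric growth law for real data.

Noise is hierarchical and multiplicative on the rate,
μ_eff = μ·exp(ε_trial + ε_bio + ε_tech)/td_multiplier, keeping rates
positive (log-normal), with additive Gaussian noise on each ln(OD) reading
(equivalently log-normal OD — standard for turbidity measurements).
Defaults σ_trial = σ_bio = 0.01, σ_tech = 0.005, σ_meas = 0.01 put the
replicate SD of t_d on the order of 0.05–0.1 h and the trial-to-trial SD
near the few-hundredths-of-an-hour scale reported for well-behaved
wild-type cultures; they are configuration values, not claims about any
particular instrument.

Sharing scope: the trial effect is drawn per (strain, trial) and the
biological effect per (strain, trial, bio_rep), both shared **across
treatments** — emulating a design in which one culture is split across
the parallel treatment plates, which is what makes pairing by replicate
key informative. The technical effect and measurement noise are per well.
The treatment multiplier acts only on μ; lag and plateau are shared, so a
treatment changes growth rate without altering final biomass.

Every random draw comes from its own `SeedSequence(seed, spawn_key)`
stream keyed by the sample labels (strings hashed by CRC-32), so a design
plus seed is bit-reproducible and adding a strain or treatment never
perturbs the draws of another. With all SDs zero no noise is added and
the output is seed-independent.

## Operating characteristics

`run_null_calibration` simulates complete studies under the null
(all multipliers 1.0) and reports the fraction of raw p < α, with binomial
Monte-Carlo SE; `run_power_curve` does the same across a grid of
doubling-time multipliers and also reports the mean estimated %Δt_d from
the kinetics fits. The validation suite uses a one-strain, two-treatment
study of the canonical 3 × 3 × 3 replicate layout as the simulation unit —
the statistical unit of the paired test — with 2000 simulations for the
level check and 200 per multiplier for the power curve; these sizes give
MC SEs of ~0.005 on the level and ~0.035 on power, small enough to resolve
the [0.03, 0.07] calibration band and power monotonicity.

## Numerical and design notes

- Long-CSV I/O writes 17 significant digits and parses with pandas'
  round-trip float precision, so a PlateSet survives a write/read cycle
  bit-exactly; the plate-grid dialect does the same.
- Window enumeration is exhaustive (≤ 6 runs on the default 5-point
  interval), so no greedy search artifacts exist.
- OLS is the closed-form centered computation; the test suite checks it
  against a direct normal-equations solve.
- Comparison direction is "after − before" with the report label
  `{after}_vs_{before}`; two-sided p-values are direction-invariant, so
  the convention only fixes signs.
- p and q are printed to 3 decimals in TSV reports; JSON mirrors keep full
  precision.

## Limitations

- No blank correction, well-position (edge) effects, evaporation, or
  sedimentation dynamics are modeled.
- No parametric (logistic/Gompertz) curve fitting, lag-time or
  carrying-capacity estimation, smoothing, or per-time-point testing.
- The generator's piecewise-linear transitions are sharper than real
  growth curves; conclusions about real-data window selection near phase
  boundaries should not be drawn from synthetic results alone.
- Alternative inference routes (mixed-effects models, repeated-measures
  ANOVA, equivalence testing) are out of scope.
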