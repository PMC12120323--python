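# Methods

This note records the models implemented, the conventions chosen where the
field literature admits more than one, and what the synthetic generator
does and does not emulate.

## Data model and filtering

The atomic record is a detection (timestamp, transmitter, receiver). All
timestamps are converted to a single configurable timezone (default
`Africa/Johannesburg`, UTC+02:00, no DST) before any day binning; a "day"
is a calendar date in that zone, not a rolling 24-h window, because the
detection indices are ratios of day counts.

Inclusion filtering proceeds in a fixed order: unknown transmitter IDs are
dropped with a logged count (untagged animals and false detections are
routine in receiver downloads, so they are not an error); estuary-zone
receivers and their detections are removed (the analyses concern marine
use); detections outside an individual's monitoring window are removed;
finally individuals with fewer than `min_days = 10` distinct marine
detection days are excluded. "Fewer than 10" is read literally: exactly 10
days is retained. Filtering is idempotent and the exclusion log partitions
the excluded individuals by reason.

The monitoring window runs from the tagging date to the earliest of study
end, recapture, battery expiry, and last known detection outside the bay.
Day counts include both endpoints (`(end − start).days + 1`); the
alternative (excluding the tagging day) differs by at most one day and is
switchable via `AnalysisConfig.inclusive_days`. Receiver regions
(west/central/east) are assigned from longitude with half-open breaks
(defaults 25.85°E and 26.25°E, partitioning a bay spanning roughly
25.7–26.5°E into thirds); a receiver exactly at the first break is
central.

## Detection indices and group tests

`DI_total` divides distinct detection days by the monitored days;
`DI_bay` divides the same numerator by the days at liberty up to the last
in-bay detection, `(last bay detection − tag date) + 1`. Because the
`DI_bay` denominator can never exceed the `DI_total` one, `DI_total ≤
DI_bay` is asserted as an invariant.

Monthly detection tables carry one row per individual × calendar month
overlapping the monitoring window, including zero-count months;
`days_in_month` is the full calendar month length, matching the offset
used by the seasonal model (partial first/last months are not pro-rated —
a deliberate simplification that biases those two months' monthly DI
downward by at most one month per individual).

Two-group comparisons use the asymptotic tie-corrected Mann–Whitney U;
three or more use Kruskal–Wallis (tie-corrected, χ² reference with
k − 1 df) followed by Dunn's test: `z = (R̄_a − R̄_b) / se` with
`se² = (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_a + 1/n_b)`, two-sided normal
p-values, Benjamini–Hochberg adjusted. A response with zero rank variance
returns the degenerate statistic 0 / p 1 rather than failing.

## Seasonal detection model

Monthly counts are modelled by a penalized quasi-Poisson regression:

```
E[count] = days_in_month · exp(a_species + f_species(month) + u_individual)
```

* `f_species` uses a periodic cubic B-spline basis of size k = 12 with
  equally spaced knots on the month circle, built by folding an ordinary
  uniform B-spline design matrix (wrap-around continuity to the second
  derivative; rows sum to 1). Each smooth is constrained to average zero
  over the year — implemented by reparameterizing into the null space of
  the mean-value constraint — so species intercepts carry mean levels and
  the design stays full rank. The penalty is the circulant
  second-difference quadratic form mapped through the same
  reparameterization.
* `u_individual` is a ridge-penalized intercept block (the standard
  random-effect/ridge equivalence).
* Fitting is penalized IRLS on the Poisson log-likelihood with the
  month-length offset; the linear predictor is capped at ±30 to survive
  separation (a species never detected converges to fitted probability 0
  with a warning rather than diverging).
* The two smoothing parameters (one shared by all species smooths, one
  for the individual ridge) are selected by grid-search GCV,
  `n·X²_Pearson/(n − edf)²`, over log-spaced grids (10⁻³…10⁶ and
  10⁻²…10⁴); both can be fixed through `FitConfig`. The fit is
  deterministic given data and configuration.
* Dispersion is estimated as Pearson χ²/(n − edf); it scales the
  coefficient covariance but not the mean fit (quasi-likelihood).

Smooth-term significance is a Wald-type statistic `γ' V_γ⁻¹ γ / ν` on the
penalized coefficients with ν the rounded block EDF, referred to
F(ν, n − edf). `V_γ` is the **Bayesian** posterior covariance
(dispersion × penalized inverse): simulation with a flat-truth species
showed the frequentist sandwich alternative rejecting a true null ~48% of
the time at the 5% level, while the Bayesian form is near-nominal (~2–3%)
with essentially full power against a cosine peak of amplitude 0.8. The
test remains approximate by construction (EDF rounding, penalized bias)
and is flagged as such; exact reproduction of mgcv's EDF/F/p reporting is
a non-goal.

Predictions set the random intercept to zero (a typical individual) and
report `exp(η)` per month as a per-day detection probability, clipped to
[0, 1], with delta-method standard errors.

## Movement networks and PERMANOVA

An individual's movement network adds one unit of weight to the unordered
receiver pair of every consecutive-detection transition with distinct
receivers and a gap ≤ 24 h (inclusive). Undirected is the default
(directed available); self-loops are excluded. "Available nodes/edges" for
the density denominators are the full deployed marine array and all its
unordered pairs — not just visited receivers — so densities are comparable
across individuals. Aggregated networks sum edge weights and per-receiver
detection counts across individuals.

The PERMANOVA operates on Euclidean distances between per-individual
receiver-use proportion profiles. With `G = −½ J D² J` the Gower-centred
inner-product matrix, sequential (Type I) sums of squares for each term
are trace differences of cumulative orthogonal projectors applied to `G`,
in the user's term order; `pseudo-F = (SS_t/df_t)/(SS_res/df_res)`;
`R²_t = SS_t/SS_total`. Term df are realized column ranks, so aliased
columns in unbalanced designs (e.g. a species observed in only one life
stage) are dropped with a warning and interaction df shrink accordingly;
`Σ df = N − 1` and `Σ R² = 1` always hold. p-values use free permutation
of observations, `p = (1 + #{F* ≥ F})/(1 + n_perm)` with 999 permutations
by default; passing an explicit permutation set (e.g. a full enumeration)
switches to the exact fraction over that set.

## Co-occurrence network and assortment

Sampling periods are consecutive clock-aligned hour bins (a deterministic
reading of "within an hour"; sliding-window co-detection is not
implemented). A grouping event is a (bin, receiver) pair with its member
set; an individual at two receivers in one bin is "observed" once in that
period, and a pair seen only at different receivers in a period counts
once toward `y_AB`. The simple-ratio denominator is then exactly the
number of periods in which at least one of the pair was observed; dyads
sharing no periods get SRI 0 and are flagged. Only individuals detected in
the analysis window appear as nodes.

Weighted categorical assortativity builds the mixing matrix `e_ij` from
SRI weights (both edge directions counted) and computes
`r = (Σ e_ii − Σ a_i b_i)/(1 − Σ a_i b_i)`; it is invariant to scaling all
weights and to renaming classes. If a labelling concentrates all weight
inside one class the coefficient is taken at its assortative limit 1
(the formula is 0/0 there). The node-permutation test shuffles trait
labels over nodes, keeping the network fixed; the default alternative is
one-tailed (excess assortment), with the +1-corrected p-value, so
`p ≥ 1/(n_perm + 1)`.

## Synthetic generator

The generator's defaults are the study-like conditions: a 59-receiver
marine array split 20/20/19 across west/central/east, the tagged cohort
of 132 individuals in four species × life-stage strata, a 2011–2020 span,
teleosts tagged in estuaries and sharks at the coast, species batteries of
~3.3 y (teleosts) and ~10 y (sharks), and recapture modelled as a
per-species mixture (20% of dusky kob recaptured after exponential mean
60 d; 30% of leervis after mean 190 d; sharks none) matching the reported
recapture pattern. Daily presence follows
`p = clamp(base(1 + A·cos(2π(month − m₀)/12)), 0, 1)` with species base
rates 0.15/0.17/0.22/0.39 (kob/leervis/ragged-tooth/white shark) chosen to
match the reported mean DI ordering, peaks in summer (ragged-tooth,
month 1), winter (leervis, month 6) and early spring (white shark,
month 9), and amplitudes 0/0.5/0.8/0.6. A single cosine cannot represent
leervis' reported bimodal (winter + summer) presence; the generator keeps
one winter peak and this is a known mismatch with the real system. Region
preferences concentrate kob centrally, leervis and ragged-tooth sharks in
the west, and white sharks in the east.

On a present day an individual occupies one receiver (region from its
species weights, uniform within region) and emits 1–20 pings over ≤4
distinct hours. Conspecific co-occurrence is manufactured by
co-assignment: with probability `assortment_strength` a present individual
adds one ping at the receiver and hour of a random present conspecific.
Adding (rather than moving) the ping makes the conspecific co-detection
count provably monotone in the strength parameter under common random
numbers, which the tests exploit. All draws flow through seed-derived
independent streams, so outputs are byte-identical given a scenario and
the assortment dial can move without disturbing presence or placement.

What the generator does **not** emulate: movement kinematics or
autocorrelated tracks (transitions between receivers arise only from
independent daily placements), detection-range decay, receiver downtime,
tides/temperature, estuarine behaviour beyond optional random estuary
pings, and tag loss. Passing tests therefore demonstrate correctness of
the estimators and calibration of the permutation/null machinery under
the generator's assumptions — not robustness to the full messiness of
field telemetry data.

## Problem sizes used in validation

The end-to-end suites run at desk scale chosen to keep the full test run
in a few minutes while leaving comfortable statistical margins: SRI
brute-force equivalence on 200 random schedules (≤15 individuals, ≤100
bins); assortativity oracle equality on 100 random networks (|Δr| <
10⁻¹²); node-permutation calibration over 500 null simulations with 200
permutations each; PERMANOVA exact enumeration on an n = 6 toy (all 720
orderings) plus 1000 null simulations (n = 30, 5 receivers, 199
permutations); seasonal peak recovery and assortment detection over 100
simulated cohorts each. The acceptance script runs the full default
scenario (132 individuals, 10 years) once.
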