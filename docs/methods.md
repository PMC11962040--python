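# Methods

`oxitrack` links central-place foraging behavior, derived from GPS
biologging of seabirds (black-tailed gull–like and streaked
shearwater–like study systems), to oxidative-stress physiology measured
in paired blood samples.  This note documents the models, the constants
and conventions they depend on, what the synthetic-data generator does
and does not emulate, and the design choices made where more than one
reasonable implementation existed.

## Track processing

**Distances.** All distances are great-circle (haversine) on a sphere of
radius 6371.0 km.  At trip scales (1–300 km) the difference from an
ellipsoidal geodesic is well below GPS positional noise.

**Speed filter.** Fixes implying ground speed above `vmax` (default
90 km/h) are removed in a single forward sweep: the first fix is kept and
each later fix is kept iff the speed from the last *kept* fix is at most
`vmax`.  Removal is strictly-greater ("exceeding"), the sweep is
idempotent, and after filtering every consecutive pair satisfies the
bound.  Alternatives (iterative bidirectional filters) differ only on
pathological tracks; the forward sweep is deterministic and easy to
reason about.

**Resampling.** Tracks are resampled to a regular grid (10 min for the
behavioral model, 1 min for land use) by piecewise-linear interpolation
of latitude and longitude independently, with longitudes unwrapped so
antimeridian crossings interpolate the short way.  Positions are never
fabricated across recording gaps: a gap longer than `max_gap` (default
3× the target interval) splits the output into segments, and every
downstream consumer (HMM, trips) treats segments independently.

**Steps and turns.** Step length is the net displacement between
consecutive fixes; the turning angle at an interior fix is the signed
change of bearing between the incoming and outgoing steps, wrapped to
(−π, π].  Positive is counterclockwise (left turn).  Turns are undefined
(missing) at segment endpoints and next to zero-length steps.

## Trips and flight metrics

A foraging trip is a maximal run of consecutive fixes strictly farther
from the colony than the species rule (gull: 1 km, shearwater: 3 km)
whose first-to-last span strictly exceeds the duration rule (1 h / 6 h).
Boundary (colony-side) crossing fixes are excluded by default; a flag
includes them.  Brief re-approaches inside the distance threshold split a
trip in two — the maximal-run reading — since the alternative
(gap-tolerant merging) needs an arbitrary tolerance.

Per trip we compute duration, summed step length ("total flight
distance"), maximum colony distance, takeoff count, and takeoff
frequency (count/duration).  Flight is ground speed ≥ 15 km/h; the
boundary value counts as flight (a single documented convention where
"more than"/"less than" phrasing leaves equality open, configurable).  A
takeoff is a stationary→flight switch between consecutive fixes.

Individual-level aggregation follows fixed rules: totals are sums over
trips; average maximum distance is the sum of per-trip maxima divided by
the trip count; average takeoff frequency is the *unweighted mean of
per-trip frequencies* (deliberately not total takeoffs / total duration);
percent foraging is 100 × foraging duration / logger-recorded duration.
Individuals with no trips report missing (NaN) averages, never zeros.

**Land use (gulls).** On the 1-min resampled track, land utilization is
100 × (trip fixes in flight phase and inside a land polygon) / (all trip
fixes).  Point-in-polygon containment includes the boundary.  The
numerator counting only flight-phase points is the default reading; a
flag counts all over-land points instead, since the defining sentence is
ambiguous between the two.

## Movement HMM

Behavior is classified by a 3-state hidden Markov model on the 10-min
resampled series: step length ~ Gamma(mean, sd), turning angle ~
von Mises(μ, κ), per state, with a first-order Markov chain on states.

* **Likelihood** is computed by the scaled forward recursion; missing
  angles simply omit the angular term.  Zero steps are floored at 1 m
  instead of adding a zero-inflation mixture — a documented
  simplification appropriate when true zero distances essentially never
  occur after interpolation.
* **Fitting** is Baum–Welch EM over all individuals jointly (shared
  parameters, independent forward passes), with exact weighted M-steps:
  the gamma shape solves log k − ψ(k) = log(w-mean) − w-mean(log) by
  Newton; κ inverts the Bessel ratio A(κ) = I₁/I₀ by bisection.  Exact
  M-steps keep the EM log-likelihood monotone (checked to tolerance 1e−6).
  Ten seeded random restarts (short runs, then the best is refined)
  start from step-length tercile moments with multiplicative jitter.  A
  state capturing less than a configurable minimal share of posterior
  mass triggers a warning and that restart is discarded.
* **Decoding** is global (Viterbi) by default; pointwise posterior-max
  decoding is available behind a flag.
* **Labels**: states ranked by mean step length map to resting <
  foraging < flight.  The foraging state is expected to be the least
  directionally concentrated; if the fitted κs disagree the labels are
  still assigned by step length and a warning is raised.  Exactly tied
  means are rejected as unidentifiable.
* **Foraging phases** are maximal foraging runs of at least `run_min`
  points (default 2; the defining phrase "more than two" is ambiguous
  between ≥2 and ≥3, and a phase needs ≥2 points to have nonzero
  duration, so 2 is the permissive default — both readings are tested).
  Foraging duration sums first-to-last spans of the phases.

## Oxidative-stress statistics

Assay units: d-ROMs in Carratelli units (1 U. CARR = 0.08 mg H₂O₂/dL),
BAP in µM/L.  Changes are retrieval minus deployment per individual;
unpaired individuals are reported missing, duplicated timepoints are an
error.  Analyzer detection limits are 40–1,000 U. CARR (d-ROMs) and
500–6,000 µM/L (BAP); values at or beyond a limit are censored at it.
The pipeline can also reproduce the exclusion rule that drops individuals
whose d-ROMs fall below the lower limit from d-ROMs analyses entirely
(`regression.exclude_below_detection`).

* **Tobit**: Gaussian regression with interval censoring at the
  detection limits, fit by BFGS on the exact log-likelihood with analytic
  gradient (parameterized in log σ); standard errors from the observed
  information (central-difference Hessian of the gradient).  With no
  censored observations the estimates coincide with OLS; this is tested
  to 1e−6, and the censored fit is cross-checked against
  `survival::survreg` in R to 1e−4.
* **Linear models** are OLS with classical homoskedastic inference.
* **VIF pruning**: predictors are standardized; VIF_j = 1/(1−R²_j) with
  column j regressed on the rest; the single highest-VIF column is
  dropped per round until all VIFs are below 3.  Ties drop the later
  column in input order (logged); perfect collinearity reports an
  infinite VIF and is dropped first.
* **Bayesian regression**: Gaussian likelihood with improper flat priors
  on coefficients and inverse-gamma(0.001, 0.001) on σ², sampled by a
  conjugate Gibbs sampler (β | σ² normal around OLS; σ² | β
  inverse-gamma), 4 chains with overdispersed σ² starts, first half
  discarded, split-R̂ > 1.05 on any coefficient is an error.  With these
  priors the posterior mean tracks OLS, matching the Gaussian-family
  usage without claiming equivalence to any particular package default.
  A coefficient is called positive/negative when its 95% equal-tailed
  credible interval excludes zero; no multiple-testing adjustment is
  applied across metrics or years, and results are surfaced raw.
  Sex enters as a binary covariate with female as the reference level.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.  One simulated individual alternates colony dwell periods
(exponential, mean 4 h) with foraging trips (lognormal length around a
per-bird mean of 7 h); within trips a 3-state Markov chain drives
per-state gamma steps and von Mises turns at the 5-min logger interval
(resting 10 m, foraging 0.6 km ≈ 7 km/h, flight 2.5 km ≈ 30 km/h —
comfortably under the 90 km/h filter).  Flight headings are additionally
pulled away from the colony on the outbound leg and back toward it on
the return; searching and resting keep their own tortuosity.  Local
planar steps convert to latitude/longitude by a small-step
equirectangular approximation (error ≪ 1 m below 10-km steps).  Dwell
periods move by the same resting-state gamma walk with a homing pull, so
resting emissions are distributionally consistent inside and outside
trips.

Deployments default to 7 days of continuous 5-min sampling (field
deployments in this system average about a week), 40 individuals.
Between-individual heterogeneity — lognormal spreads on trip length,
dwell time (sd 0.7 on the log scale) and on the rate of initiating
flight (sd 0.8) — produces the wide covariate ranges real colonies show
and gives the regression stage genuine signal variance.

Assays: deployment levels are Gaussian baselines at gull-like scales
(d-ROMs 131.5 ± 76.5 U. CARR, BAP 1437.5 ± 416.7 µM/L); the change adds
a configured linear effect of per-individual behavioral covariates plus
Gaussian noise.  Default effects: Δd-ROMs = −10 + 0.06·total flight
distance (km) + 50·male + ε(σ = 30); ΔBAP = 45 − 450·takeoff frequency
(per h) + 600·male + ε(σ = 120).  The residual sds are chosen so that
the *total* spread of simulated changes is comparable to field-scale
variability while the configured effects remain detectable at n = 40
(design power > 80% per effect).  Censoring flags follow the detection
limits.

What the generator does **not** emulate: GPS positional error beyond
resting jitter, irregular duty-cycling, environmental covariates (wind,
prey), inter-annual scenario structure, sex differences in movement, or
any nonlinearity/heteroskedasticity in the assay model.  Passing
recovery tests therefore demonstrates internal consistency of the
pipeline under its own modeling assumptions — not robustness to the many
ways field data violate them.

## Numerical choices and degenerate inputs

* Trip thresholds are strict inequalities; ties at a threshold are
  excluded.
* Resampling tolerates 1e−6 s of floating-point jitter when counting
  grid points.
* The Tobit fit rejects problems where all observations are censored on
  one side (non-identifiable) and errors if the scale collapses.
* `vif_prune` requires ≥2 columns and terminates in at most p−1 rounds.
* Empty trip lists yield missing averages; zero-duration trips are
  rejected.
* All simulation and sampling randomness flows from explicit seeds
  (NumPy `SeedSequence` spawning); pipeline reruns with the same config
  are byte-identical up to the manifest, which embeds the output path.

## Validation studies and problem sizes

`oxitrack.validation` (exercised by the test suite and
`scripts/acceptance.py`) uses these sizes: 50 random models × T ≤ 8 for
the exhaustive-enumeration oracle (3^T paths); 10 replicates of 20
tracks × 500 points for parameter recovery; n = 500 with ~20% censoring
for the Tobit study; 200 replicates each for credible-interval
calibration and power; 1,000 random phase sequences for the takeoff
oracle; and a 40-individual, 7-day synthetic study (run twice to verify
determinism) for the end-to-end round trip.

## Known limitations

* The HMM assumes emissions are conditionally independent given states;
  resampled tracks violate this mildly through interpolation smoothing,
  and 10-min windows spanning state switches blur the fitted κs (the
  step-length separation, not the angular one, carries most of the
  classification signal in the synthetic study).
* No covariates on transition probabilities and no model-order selection
  beyond fixed K = 3.
* No random effects or hierarchical structure in the regressions; each
  species-year cell is fit independently.
* The species-contrast Tobit/linear stage requires both species in one
  input bundle; the default synthetic study is single-species and
  exercises that stage only in two-species configurations.
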