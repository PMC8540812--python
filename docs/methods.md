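# Methods

## Model and assumptions

A single trap is characterized by the catch probability curve
`spTfer(r) = spTfer(0)/(1 + (r/D50)²)` for `r ≤ Rmax` and 0 beyond, where
`r` is the insect's distance from the trap in meters.  The curve is
phenomenological — no plume-dispersion or anemotaxis mechanics — and rests
on three assumptions: insects move in an effectively two-dimensional space,
have a finite active life span, and the trapping interval is long enough
that the catch has *converged* (it no longer grows with extra trapping
time; the interval itself therefore never appears as a rate parameter and
is carried only as metadata).  The point `r = Rmax` belongs to the non-zero
branch (closed interval).

For a radially symmetric density `ρ(r)` (insects/m²) the expected catch is
`M̄ = 2π ∫₀^Rmax spTfer(r) ρ(r) r dr`.  For uniform ρ̄ this is `ρ̄/μ` with
`μ = 1/(spTfer(0)·π·D50²·ln(1+(Rmax/D50)²))`; the grouping of the
logarithm inside the denominator is not a typographic guess — it is pinned
by an always-on oracle test comparing `1/μ` against adaptive quadrature of
the integral (relative agreement < 1e-6 for all bundled and randomized
parameter sets).  Dependence on `Rmax` is logarithmic, so rough collection
radii suffice; `μ` scales exactly as `c⁻²` when both distances are scaled
by `c`.

## Parameters

| parameter | units | meaning | constraints |
|---|---|---|---|
| `spTfer(0)` | probability | catch probability next to the trap | (0, 1] |
| `D50` | m | distance at which the probability halves | > 0 |
| `Rmax` | m | collection-area radius | > 0, or unknown (`None`) |
| `p` | probability | confidence level of the density interval | (0, 1), default 0.95 |

`Rmax < D50` is mathematically legal and allowed, but warned about, since
the half-catch distance then lies outside the collection disk.  `Rmax` is
never estimated here; fitted parameter sets may carry `Rmax = None`, in
which case density conversion raises until the user supplies a radius.
Densities are insects/m² internally; the ×10,000 per-hectare conversion
happens only at the reporting boundary, and both sets of fields are carried
in results to avoid ambiguity.

## Fitting

Step 1 fits the untransformed curve to the (distance, proportion) pairs by
bounded nonlinear least squares (`spTfer(0) ∈ (0,1]`, `D50 > 0`) and keeps
only `spTfer(0)`.  Step 2 fixes `spTfer(0)` and fits `D50` alone on the
log-transformed proportions, giving the low far-distance catches equal
leverage.  Starting values are deterministic and scale-aware: the maximum
observed proportion, and the median distance whose proportion is at least
half that maximum.  Both steps are unweighted ordinary least squares by
default (published ladders often lack SEMs); `weighted=True` uses the
per-record SEMs when every record has one.  Zero-catch records are retained
in step 1, excluded from step 2 (log undefined) and listed in the result —
no pseudo-count option is offered because it would silently change the
estimator.  Records at duplicate distances are pooled (counts summed) with
a warning.  Datasets are screened against three design criteria (≥ 4
distances, non-decreasing cohorts with distance, no interior zero catches);
violations are warnings, never errors, mirroring how imperfect literature
data must still be usable.

### D50 uncertainty

The reported `D50` SEM is obtained by first-order (delta-method)
propagation of the per-record proportion SEMs through the *entire* fitting
pipeline, using central finite differences with a one-SEM step per record.
The naive alternative — the scaled least-squares covariance of step 2 —
understates the uncertainty roughly twofold in simulation, for two reasons:
binomial noise on log proportions is strongly heteroscedastic (far, rare
catches are noisiest exactly where the curvature in `D50` concentrates),
and the two-step protocol's step-1 `spTfer(0)` error propagates into `D50`
but is invisible to a conditional step-2 covariance.  The delta-method SEM
was cross-checked against a parametric bootstrap and is slightly
conservative on average (z-score SD ≈ 0.6–0.8 across simulated scenarios).
When records carry no SEMs (e.g. idealized ladders), the classic covariance
SEM is the fallback.  The goodness-of-fit `R` is the Pearson correlation
between observed and predicted proportions on the untransformed scale over
the non-excluded points; reporting scale is a convention and is recorded in
the result so it is auditable.

## Density estimation

`ρ̄ₘₚ = μ·M`, with the exact chi-squared interval
`[μ/2·χ²((1−p)/2; 2M), μ/2·χ²(1−(1−p)/2; 2M+2)]` and the 0-df quantile
defined as 0 (so `M = 0` gives a zero lower bound and a positive upper
bound — the detection threshold).  The interval is the exact Poisson-count
construction: coverage is ≥ p for every true density, verified empirically
at 10⁴ draws per grid point.  `M` must be an integer count; fractional
"average catches" are rejected because the degrees of freedom are `2M` and
`2M+2`.

## Simulator

The simulator is the package's fixture generator and Monte-Carlo engine.
Release–recapture cohorts are **binomial** (`n_caught ~ Binomial(n,
spTfer(r))` independently per distance, one trap, no competition between
release points), because cohorts are finite and proportions bounded by 1;
recorded SEMs are the binomial standard errors of the observed proportions.
Wild-population trap catches are **Poisson** with mean `ρ/μ`, the model
under which the interval above is exact.  Identical seeds reproduce
datasets exactly.

What the simulator deliberately does *not* emulate: insect movement and
diffusion, trap interference, weather- or age-dependent catchability, and
overdispersion beyond binomial/Poisson.  Passing recovery and coverage
tests therefore demonstrates correctness of the estimators *under the
model*, not that any particular field dataset satisfies the model; the
latter is what the design-criteria screening and the per-dataset `R`
diagnostic are for.

## Test problem sizes and numerical choices

Quadrature uses adaptive tolerance 1e-9 (the integrand is smooth).
Parameter-recovery checks run 50 seeded replicates whose truths cycle over
three scenarios spanning the bundled parameter range — (0.70, 6.5 m),
(0.09, 250 m), (0.02, 27.7 m) — on a relative distance ladder
(0–4 × D50, clipped at Rmax) with cohorts of 10⁴, a size at which binomial
noise is small but non-negligible; coverage checks use 10⁴ Poisson draws
per true-density grid point.  A replicate estimate landing beyond 3
reported SEMs is a ≲1% tail event even for a perfectly calibrated SEM, so
replicate-level checks at 3 SEM are meaningful only at this replicate
count.  Noiseless ladders are represented by rounding exact proportions at
cohort size 10⁹ (per-point error 5e-10, far below the 1e-4 recovery
tolerance).

## Known limitations

* Single trap only; no multi-trap fusion or spatially varying density
  inference.
* `Rmax` must come from experiment or prior literature; the package never
  estimates it.
* The two-step `spTfer(0)` estimate can deviate from the field-measured
  value on unbalanced ladders (short- or long-distance heavy); whenever a
  measured `spTfer(0)` exists, the fixed-`spTfer(0)` path should be used.
* No bootstrap or profile-likelihood intervals for `D50`; the SEM is a
  first-order propagation.
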