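# trapdensity

Estimate the **absolute population density** of an insect — and exact
statistical bounds on it — from the catch of a **single trap**.

Traps are the workhorse of pest detection, monitoring and conservation, but
a raw trap count by itself says almost nothing quantitative about how many
insects are actually out there: the same catch can correspond to population
densities orders of magnitude apart depending on the trap–insect system.
`trapdensity` closes that gap for anyone running pheromone-, chemical- or
light-trap programs: it models the probability of catching an insect as a
function of its distance from the trap, fits that model to release–recapture
experiments, and inverts it into the most probable density with exact
confidence bounds — including a rigorous reading of "catch zero".

## The model

The probability of (eventually, over the converged-catch interval) catching
an insect located a distance *r* from the trap is

```
spTfer(r) = spTfer(0) / (1 + (r/D50)²)   for r ≤ Rmax,   0 beyond Rmax
```

where `spTfer(0)` is the catch probability next to the trap, `D50` the
distance at which it halves (the effective attractive distance), and `Rmax`
the collection-area radius.  For a uniform density ρ̄ (insects/m²) the
expected catch is M̄ = 2π ∫₀^Rmax spTfer(r) ρ̄ r dr = ρ̄/μ with

```
μ = 1 / (spTfer(0) · π · D50² · ln(1 + (Rmax/D50)²))
```

so a trap catch `M` converts to the most probable density ρ̄ₘₚ = μ·M, and
the exact (Garwood-type) chi-squared interval

```
μ/2 · χ²((1−p)/2; 2M)  ≤  ρ̄  ≤  μ/2 · χ²(1−(1−p)/2; 2M+2)
```

brackets the truth with confidence at least *p* for any Poisson catch —
even `M = 0`, which yields a hard upper bound (a detection threshold).

Parameters are fitted from release–recapture ladders by a two-step
protocol: step 1 estimates `spTfer(0)` on the untransformed proportions;
step 2 fixes it and fits `D50` on the log scale, so the sparse far-distance
points carry equal weight.  When `spTfer(0)` was measured directly in the
field, only step 2 is used.

## Worked example

Ten published trap–insect systems are bundled (`trapdensity presets`).
A codling-moth pheromone trap that caught 3 males:

```
$ trapdensity estimate --preset codling_moth --catch 3
{
  "label": "Codling moth (C. pomonella) / Pheromone trap",
  "sptfer0": 0.7,
  "d50_m": 6.5,
  "rmax_m": 260.0,
  "M": 3,
  "confidence": 0.95,
  "mu_per_ha": 14.58693799970598,
  "rho_mp_per_ha": 43.760813999117936,
  "lower_per_ha": 9.024531898824616,
  "upper_per_ha": 127.88766869482318
}
```

Reading: each caught moth represents μ ≈ 14.6 insects/ha, so the most
probable density is ≈ 44 insects/ha, and with 95% confidence the true
density lies between ≈ 9 and ≈ 128 insects/ha.  With `--catch 0` the lower
bound and most probable density are 0 and the upper bound ≈ 54 insects/ha —
the densest population an empty trap is consistent with.

The same workflow from the library:

```python
import trapdensity as td

params = td.get_preset("pine_sawfly")
est = td.estimate_density(3, params, p=0.95)
print(est.rho_mp_per_ha, est.lower_per_ha, est.upper_per_ha)
```

Fitting your own release–recapture CSV (columns `distance_m, released,
caught[, sem]`):

```
trapdensity fit --input ladder.csv --rmax 1600          # two-step protocol
trapdensity fit --input ladder.csv --sptfer0 0.37 --rmax 1600   # measured spTfer(0)
trapdensity validate --input ladder.csv                 # design-criteria check
trapdensity simulate --preset l_dispar --distances 0,25,50,100,200 \
    --released 200 --seed 1 --output sim.csv            # synthetic ladder
```

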