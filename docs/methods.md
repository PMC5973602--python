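# Methods

## Model

The primary tumor holds four clonal phenotypes indexed (x, y) ∈ {0,1}²:
x flags participation in local niche construction (production of a shared
resource R that raises the carrying capacity), y flags participation in
pre-metastatic niche construction (secretions that prepare a distant site
and benefit nobody locally). The canonical ordering everywhere is
[(0,0), (0,1), (1,0), (1,1)] = [cheater, secondary producer, local
producer, global producer]. The dynamics are competitive Lotka–Volterra
plus one resource:

    dn_i/dt = r_i n_i (1 − (C n)_i / K_i(R)) − m_i(N, R) n_i
    dR/dt   = g (n10 + n11) − l R

* **Carrying capacities.** K_i = k + β0·R for x = 0 clones and k + β1·R
  for x = 1 clones. β1/β0 > 1 means the constructed niche preferentially
  feeds its constructors ("specificity").
* **Dispersal (intravasation).** m_i = αN/(k + β_x R). The denominator is
  the *focal* clone's carrying capacity: this is the reading under which
  dividing the invader's growth equation by r·n reproduces the analytic
  invasion inequalities exactly (the α-terms enter as α/r). A
  `shared_dispersal_beta` option provides a single-denominator variant for
  sensitivity checks.
* **Competition structures.** C[i, j] is the effect of clone j on clone i;
  the diagonal is 1 and off-diagonal entries are ≤ 1 (intraclonal
  competition is at least as strong as interclonal, reflecting spatial
  clustering of clones and divergent metabolic profiles). Structure I is
  the general symmetric matrix with coefficients θ, φ, ψ, ω, μ, ν;
  structure II sets all producer–producer couplings (ω, ν, μ) to 1;
  structure III groups the clones into two niches by the x flag with
  intra-niche coupling 1, effect of producers on non-producers θ, and the
  reverse effect φ.

Time is measured in days (one cell cycle ≈ one day). Producers pay a
growth-rate cost, so the defaults order r00 > r10, r01 > r11; a violated
ordering (e.g. a therapy scenario that depresses cheater growth) warns
rather than errors.

### Default parameters

The registry entry `published_defaults` holds the published defaults: r00 =
0.07, r10 = 0.05, r01 = 0.045, r11 = 0.02 /day, k = 10⁵ cells, β0 = 1,
β1 = 1.2, θ = φ = 0.9, g = 0.004, l = 0.001, α = 10⁻⁶, structure I. Only θ
and φ are published; **ψ, ω, ν, μ = 0.9 are this package's assumption**
(chosen equal to the published couplings). The nascent-tumor initial
condition n00(0) = 10³ cells, R(0) = 1 is likewise an assumption recorded
in the config defaults ("cheaters only and a small amount of resource" is
all that is published).

## Fast/slow analysis

With the defaults, cells equilibrate on a 1/r ≈ 15–50 day timescale while
R evolves on 1/l = 1000 days, so the package analyses fixed points of the
cell subsystem at frozen R ("quasi-equilibria") and the induced slow flow
dR/dt = g(n10* + n11*) − l R. One- and two-clone quasi-equilibria are
closed-form (a single logistic balance n* = K r/(r + α), and a 2×2 linear
system for coexistence, kept exact in α); larger resident sets use
multi-start Powell-hybrid root finding (starts at the vertices and
centroid of [0, K_max]^m, duplicates merged at 10⁻⁶ relative, every
root verified against a residual bound of 10⁻⁸ relative to r_max·K_max).
The coexistence system is declared degenerate when its determinant falls
below 10⁻⁹ of scale (parallel isoclines, c01·c10 → 1); feasibility
requires both components > 10⁻¹²·K to reject sign noise.

On the producer branch the slow flow is g k + (g β1 − l) R; the default
slope +0.0038/day is positive, so **the resource never equilibrates on
clinically relevant timescales** — the tumor keeps growing for a decade
and more. Two consequences matter for interpretation:

* The fast subsystem "equilibrates" only relative to the moving manifold.
  `detect_fast_equilibration` therefore offers two measures: raw relative
  change of the populations (which on a producer run never drops below
  ≈ 4×10⁻³/day, because n10 rides the growing capacity), and a
  capacity-normalised measure on n_i/K_i(R), which settles below
  10⁻⁴/day within ≈ 230 days of a producer run.
* The populations lag the moving capacity by the quasi-static offset
  (d ln K/dt)/r = β1(g n10 − l R)/(K1 r10) ≈ 7–8% under the defaults.
  "N closely tracks k + β1 R" is therefore true at the ~8% level, not
  better; the lag is physical (independent of solver tolerance and equal
  to the analytic prediction pointwise).

## Invasion and stability

A rare mutant's fate is decided by its per-capita growth rate at the
resident quasi-equilibrium, λ = r_inv(1 − (C n*)_inv/K_inv) − m_inv, which
is also the invader's diagonal Jacobian entry at the boundary fixed point.
Three routes are implemented and cross-checked:

1. **Numeric**: λ evaluated directly; internal stability from the
   eigenvalues of the analytic Jacobian restricted to resident
   coordinates (validated against central differences at 10⁻⁶ relative).
   "Stability" of a quasi-equilibrium additionally requires negative
   invasion rates for the absent clones among {(0,0), (1,0)} — a
   producer-only tumor is only called stable if cheaters cannot re-invade.
   Coexistence stability is decided numerically only; no closed form is
   attempted.
2. **Exact inequalities**: Σ_res n_res(C[inv, res] + α/r_inv) < K_inv,
   algebraically identical to λ > 0 under the focal-denominator dispersal
   convention; agreement with route 1 is exact up to floating point.
3. **Limit grid**: the large-R (producer-containing residents) /
   R ≈ 0 (cheater-only) / α ≈ 0 verdicts, e.g. producer-only stability
   θ > β0/β1, secondary-producer invasion ω < β0/β1 (structure I),
   β0 > β1 (II), θ < β0/β1 (III). The structure-II coexistence condition
   with the inline fraction is evaluated as
   (φ + θ(θ−1) − 1)/(φθ − 1) > β1/β0; this grouping is confirmed by the
   numeric route over random draws.

**Knife-edge grid cells.** In five cells the invader is exactly neutral in
the limit (λ → 0 as α → 0) because its competition row coincides with a
resident's: structure II and III producer-only vs global producers, and
the structure-III cheater-only/secondary-producer and both structure-III
coexistence invasions. Published limit verdicts exist for some of these
cells, but no sign test can distinguish them numerically: λ vanishes
identically, and the exact route shows the verdict is carried entirely by
O(α) terms (e.g. r01 > r00 at the structure-III coexistence, obtained by
cancelling the resident's own equilibrium condition). The consistency
harness therefore excludes draws within a nondimensional margin (10⁻³) of
the boundary — sign tests are meaningless at a knife edge — and reports
such cells as "all-boundary" (n_effective = 0) rather than scoring them.
For all informative cells, limit-grid agreement with the numeric verdict
is 100% at R = 10⁶k.

The **window of specificity** follows from the grid: for ω < β0/β1 < θ a
producer-only tumor is simultaneously stable against cheaters and open to
secondary producers. Note the window logic does not extend to global
producers: they use the resource as efficiently as its constructors, so
their invasion of a producer-only tumor (structure I) is governed by μ < 1
alone, independent of specificity.

## Numerical integration

`solve_ivp` with LSODA, rtol = 10⁻⁸, atol = 10⁻⁶ cells, daily dense
output. Negative undershoots are clipped; a clone below 1 cell whose
per-capita growth is negative is zeroed ("pseudo-extinction"), which makes
competitive exclusion realizable in finite time; the threshold is
configurable and can be disabled. Halving tolerances moves the default
3650-day run by < 10⁻⁴ relative.

## Stochastic mutation ensemble

Demographic noise is negligible at 10⁵–10⁷ cells, so the simulator is
hybrid: deterministic ODE between mutation events, Poisson mutation
arrivals at day boundaries. Each day and each allowed transition draws
Poisson(n_src · u · p) events, with u = 2×10⁻⁷ /cell/day and p = 1/500 for
the four one-flag transitions from (0,0) and (1,0), p = 1/1000 for the
two-flag transitions (0,0)→(1,1) and (0,1)→(1,0); the probabilities are
per transition, and the residual mutation mass is phenotypically silent
and untracked. Each event moves the drawn number of cells (almost always
one) from source to target — the minimal perturbation consistent with "a
small but nonzero number". For efficiency the ODE is integrated in
multi-day chunks with daily dense-output sampling; draws are made from the
sampled states in chronological order and the chunk is truncated at the
first event day, so the event stream equals strict daily stepping and is
bit-reproducible from the master seed (per-tumor SeedSequence substreams).

**Lineage scoring.** A seeded lineage is *established* once it exceeds
max(100 × seeded cells, 0.1% of N) with nonnegative per-capita growth;
*failed* once it falls below the pseudo-extinction threshold; lineages
pending at the horizon resolve by the sign of their current per-capita
growth. The resident community at arrival is classified by composition: a
clone is resident when it holds ≥ 1% of N (labels cheater_only /
producer_only / coexistence / metastatic). A tumor's fate is
metastasis_competent as soon as any (0,1) or (1,1) lineage establishes —
pre-metastatic niche construction being the model's necessary condition
for metastasis — otherwise the final composition decides.

**What the ensemble shows.** Over 200 tumors, 3650 days, at the default
parameters: tumors that stay cheater-only plateau at ≈ k and see ~0.2
pre-metastatic arrivals each, essentially all of which establish (the
cheater-only community is open: λ > 0 for every producer type). Tumors
invaded early by local producers grow by orders of magnitude and generate
many more mutants, but by then R has accumulated and the specific niche
blocks secondary producers — their arrivals fail. Establishments
concentrate entirely in small, cheater-only residents: metastatic
competence is acquired early or not at all. Two fine points: (i) an
arrival during the takeover transient (resource still low, both clones
above 1%) can still establish — the invasion window closes with R, not
with the takeover itself — so occasional establishments into mixed
communities are a real model property at some seeds; (ii) with the
assumed μ = 0.9 < 1, a (1,0)→(1,1) mutant in a mature producer tumor has
λ = r11(1 − μ) > 0 and could in principle establish, but such arrivals
are rare within the horizon (the exposure ∫n10 dt is small until late)
and none establishes at the protocol seed.

## Synthetic data and scope

There is no external data: all inputs are parameter sets (the registry
defaults above, or TOML configs) and seeds, and all experiments are
simulations of the model itself. The ensemble emulates the published
study conditions (200 tumors, 10-year horizon, printed mutation rates,
fixed master seed = 1 as the protocol seed; runtime ≈ 35 s). What passing
tests show is therefore internal consistency of the theory and simulator
— analytic conditions, numeric rates, and stochastic outcomes agreeing —
not agreement with clinical data; real tumors have spatial structure,
demographic noise in small lineages, continuous phenotype space, and
treatment effects, none of which are modeled. The bloodstream and
secondary-tumor compartments are deliberately out of scope: "metastasis
competent" is the endpoint.

## Known limitations

* Fates and arrival strata depend mildly on the 1%-of-N residency
  threshold during takeover transients (see fine point (i) above).
* The limit-grid route is only meaningful away from condition boundaries;
  the five knife-edge cells carry no numeric information by construction.
* Establishment scoring uses clone-level bookkeeping: simultaneous
  lineages of the same phenotype are not distinguished.
* The ~7–8% capacity-tracking lag means "N ≈ k + β1 R" should be read as
  a leading-order, not a percent-level, statement under the defaults.
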