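# Methods

## The model

The spatial Λ-Fleming-Viot (SLFV) process describes ancestry in a
population spread over a continuous landscape. Backward in time, the
sample's ancestral lineages `C(t)` — each a (label, location, state)
triple — are hit by a Poisson process of events. An event consists of a
time, a center `e` drawn uniformly (or with density proportional to a
heterogeneity raster), and a kernel `E(x)`:

* **uniform disc**: a lineage within torus distance `r` of the center is
  affected with probability `u`; lineages outside are untouched;
* **Gaussian**: a lineage at distance `d` is affected with probability
  `u·exp(−d²/2r²)` (untruncated; the disc and Gaussian families are
  distinct models, not approximations of each other).

If no lineage is affected the event is a no-op. If exactly one is
affected, it is *moved*: its location is resampled from the event's
replacement distribution `R(x|C′)` (uniform on the disc for the disc
family, Gaussian about the center for the Gaussian family; the ancestor
is centered on the event center, not on the centroid of the affected
set — the latter is a documented alternative). If two or more are
affected, they *coalesce*: a single ancestor appears at a
replacement-drawn location and adopts all affected lineages, so the
genealogy may contain multiple mergers. Iteration continues to the MRCA.

Assumptions baked into this implementation: haploid, single-locus
(one-ancestor) events; selective neutrality; state-independent kernels
(a `state_modifier` hook exists with a no-op default, since no concrete
state-dependent form is standard); periodic (toroidal) boundaries, which
remove edge effects and match the homogeneous theory. Movement events do
not create genealogy nodes — lineage locations are updated in place,
with an optional movement log for debugging — because downstream
consumers (mutation overlay, summaries) need only topology, times and
merger locations.

## Exact thinned sampling

Naive simulation draws every event on the landscape at rate
`λ·area`, and almost all miss every lineage when `r` is small. The
accelerated sampler for the homogeneous 2-D disc kernel proposes
candidates at rate `λ·u·k·πr²` (`k` = current lineage count), centers
uniform on the multiplicity-weighted union of lineage-centered discs
(pick a lineage, then a uniform point of its disc), and accepts a
candidate whose disc covers `m` lineages with probability
`(1−(1−u)^m)/(u·m)`. The accepted process has intensity
`λ·(1−(1−u)^m(y))` at center `y` — exactly the naive intensity of
events affecting at least one lineage — and the affected set is then
drawn as Binomial(`m`,`u`) conditioned on ≥ 1 (inverse-CDF on the
conditional counts, uniform choice of members). Proposal waiting times
accumulate, so elapsed time is exact as well. Equivalence with the
naive sampler is asserted by a two-sample KS test in the suite, and
against an independently coded forward-in-time Moran-type pair
simulation.

The thinned sampler requires the disc not to wrap onto itself
(`r < min(extent)/2`), so its support area is exactly `πr²`; larger
radii (e.g. torus-spanning "panmixia" events), Gaussian kernels, 1-D
landscapes and heterogeneity rasters are routed to the naive sampler
automatically. Event-time ties have probability zero; if an RNG ever
produced one, processing follows generation order. The hot loop runs on
a Python Mersenne stream seeded from the caller's numpy generator —
determinism per seed is preserved and tested. `max_events` (default
10⁷ candidate events) bounds runaway simulations; exhaustion returns a
multi-root partial genealogy flagged `coalesced=False`, never a silent
truncation.

## Mutation

Mutation is overlaid on completed genealogies (equivalent to in-loop
mutation for neutral, state-independent kernels; the in-loop hook
`S(s|C′)` is intentionally not implemented). `mu` is the expected number
of substitutions per site per unit model time.

* **Infinite sites**: each branch of length `t` receives
  Poisson(`mu·L·t`) mutations, each at a fresh site; output is a 0/1
  haplotype matrix over segregating sites (compatible with a perfect
  phylogeny by construction).
* **K2P**: transition rate `α = κβ`, transversion rate `β`, normalized
  so the total rate is `mu = α + 2β`; the closed-form transition
  probabilities (checked against the matrix exponential to 1e-9) are

      P_same = 1/4 + 1/4·e^(−4βt) + 1/2·e^(−2(α+β)t)
      P_ts   = 1/4 + 1/4·e^(−4βt) − 1/2·e^(−2(α+β)t)
      P_tv   = 1/4 − 1/4·e^(−4βt)        (each of two targets)

  `κ = 1` recovers Jukes-Cantor. Root sequences are uniform per site
  (the stationary distribution).

Loci are unlinked: every locus gets an independent genealogy.

## Parameter dictionary

For the homogeneous disc model on a torus of area `A`:

* a lineage is hit at rate `λ·u·πr²`, so one **generation** is
  `g = 1/(λ·u·πr²)` model-time units;
* two co-located lineages coalesce (fast-mixing regime) at rate
  `λ·u²·(πr²)²/A`, so the expected pair coalescence time is
  `A/(u·πr²)` generations — an **effective density**
  `d_eff = 1/(u·πr²)`;
* combining with the event-based neighborhood size `N_s = d·πr²`
  gives `u = 1/N_s` (valid for `N_s ≥ 1`).

The inference layer specifies mutation rates per generation and converts
through `g`, which makes expected diversity scale as `2·μ_gen·N_s·A/(πr²)`
— monotone in neighborhood size, the structure the ABC exploits.
`λ` only sets the time unit and is fixed at 1.

## Summaries

Per dataset: per-locus π (mean per-site pairwise difference) and
Watterson's `θ_W = S/(a_n·L)`; an OLS regression of the across-locus
mean pairwise genetic distance on minimal-image torus distance
(IBD slope and intercept); and a variogram of mean genetic distance in
10 fixed equal-width distance classes covering (0, half-diagonal]
(fixed bins keep ABC vectors comparable across simulations; classes
empty under the fixed sampling geometry report 0 and are dropped by the
ABC's zero-spread filter). The vector used for ABC distances carries the
across-locus mean and SD of π and θ_W rather than raw per-locus columns,
which keeps it invariant under locus reordering (loci are exchangeable).

The classical quantities `F_ST = 1/(4·N_e·m+1)` and Wright's
`N_s = 4π·σ²·d` (2-D; `2d·√(2πσ²)` in 1-D, constants fixed by the
classical convention) are provided as reference contrasts only — the
package deliberately estimates nothing by imposing discrete
subpopulations.

## Rejection ABC

Reference tables draw `(N_s, r)` from independent priors (log-uniform
for `N_s`, uniform for `r` by default), convert to `(u, r)` as above,
simulate a dataset conditioned on the observed sampling locations, and
store the summary vector; non-coalescing draws are redrawn and counted.
Each row carries its own pre-drawn seed, so tables reproduce
row-for-row regardless of redraws. Distances are Euclidean after
per-column scaling by the table's median absolute deviation (zero-MAD
columns dropped and logged); the accepted set is the `⌈tolerance·n⌉`
nearest rows, ties broken by row order. Point estimates are posterior
medians (robust to the skewed posteriors log-uniform priors produce);
intervals are HPDIs — the shortest contiguous window of the sorted
sample holding the requested mass. No regression adjustment is applied:
the method is plain rejection by design.

Cross-validation holds out one table row at a time (replicated
`n_heldout` times over randomly chosen rows), queries the remainder,
and reports per-parameter least-squares R² of estimates on truths,
alongside a permuted-truth baseline R² as the identifiability floor and
an optional 95%-HPDI coverage rate.

## Validation study and problem sizes

The packaged study uses a 2,000-row reference table of datasets with 8
individuals (uniform-random locations on the unit torus, fixed across
the table) at 10 unlinked 1-kb K2P loci (`κ = 3`,
`μ = 1e-5`/site/generation), `N_s` log-uniform on [3, 100] (1.5
decades), `r` uniform on [0.1, 0.3], 5% tolerance, 100 leave-one-out
replicates. `μ` was chosen so expected pairwise diversity spans roughly
2e-4–0.06 per site across the prior — polymorphic but far from
saturation. These sizes keep the full study at a few CPU-minutes.

Measured at this scale, the cross-validated R² for neighborhood size is
about 0.6 (dispersal radius ≈ 0.25–0.37), both far above their
permuted-truth baselines (≈ 0.01): both parameters are identifiable,
`N_s` strongly and `r` weakly. A ceiling analysis (cross-validated
linear read-out of log `N_s` from the full summary set ≈ 0.70) shows
rejection ABC operates near the information limit of this design: with
8 individuals, diversity scales with `N_s/πr²`, and the spatial
summaries constrain `r` only loosely, so uncertainty in `r` leaks into
`N_s`. Larger samples, more loci, tighter dispersal priors, or larger
reference tables would all raise the ceiling.

## What the generator does and does not emulate

Synthetic datasets are conditioned on known sampling locations,
homogeneous landscapes (except the explicit raster scenarios), a single
panmictic-ancestry-free history, equilibrium demography, and neutral,
recombination-free 1-kb loci. Real georeferenced datasets add missing
data, genotyping error, non-equilibrium history (expansions,
bottlenecks), selection and linkage — none of which are modeled, so
passing tests demonstrate correctness of the method under its own
assumptions, not robustness to their violation.

## Numerical choices and degenerate inputs

* All randomness flows from caller-supplied `numpy.random.Generator`
  streams; derived seeds stay below 2³¹.
* Coordinates are wrapped into `[0, extent)`; inputs outside the
  landscape are rejected, not wrapped silently.
* `n = 1` samples return a single-node genealogy; `mu = 0` produces
  monomorphic data; degenerate (all-zero) rasters are rejected at
  construction.
* HPDI with fewer than 2 samples, tolerances outside (0, 1], empty
  reference tables, and all-zero-spread summary sets raise immediately.
* R² of a constant predictor is defined as 0.

## Known limitations

Selection, recombination, multi-parent (sexual) events, MCMC inference
under the SLFV likelihood, regression-adjusted or sequential ABC, and
non-raster heterogeneity surfaces are out of scope. The Gaussian kernel
is untruncated and always uses the naive sampler; 1-D landscapes are
supported but not accelerated. The `u = 1/N_s` dictionary rests on the
fast-mixing approximation of the effective density; it is the model's
*definition* of neighborhood size here, consistent across simulation
and inference, but not an exact continuum identity at strong spatial
structure.
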