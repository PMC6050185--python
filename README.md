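# slfv

Spatially explicit coalescent simulation and inference for georeferenced
genetic data, built around the **spatial Λ-Fleming-Viot (SLFV) model**.

Most population-genetic inference forces continuously distributed
organisms into discrete demes before anything can be estimated. The SLFV
model avoids that: individuals live at continuous locations on a
landscape, and ancestry is shaped by localized *reproduction/movement
events*. Running backward in time, each event has a center `e`, a radius
`r` and an impact `u`; every extant ancestral lineage within the event's
kernel is affected independently with probability up to `u`. An event
affecting one lineage moves it; an event affecting several merges them
into a single ancestor placed inside the event region — so genealogies
can contain *multiple mergers*, as in Λ-coalescents. Two biologically
central quantities fall out of this construction and can be estimated
**separately**:

* **neighborhood size** `N_s` — the expected number of individuals
  within one event area (`N_s = d · π r²` for density `d`); in the disc
  SLFV the effective density is `1/(u·π r²)`, giving the dictionary
  `u = 1/N_s`;
* **dispersal radius** `r` — the maximum distance an individual moves in
  one event.

The package provides, for working population geneticists and people
running genetic-monitoring programs:

* an exact backward-in-time SLFV simulator on 1-D/2-D toroidal
  landscapes (uniform-disc and Gaussian kernels, optional
  piecewise-constant spatial heterogeneity in the event intensity), with
  an accelerated thinned sampler whose law provably matches naive global
  event sampling;
* neutral mutation overlays (infinite sites, Kimura 2-parameter) for
  unlinked loci, each locus on its own independent genealogy;
* spatial summary statistics: per-locus π and Watterson's θ_W, an
  isolation-by-distance regression and a distance-class variogram, plus
  the classical island-model `F_ST ≈ 1/(4 N_e m + 1)` and Wright
  neighborhood size `4π σ² d` for contrast;
* rejection-ABC estimation of `(N_s, r)` with reference tables,
  highest-posterior-density intervals and leave-one-out
  cross-validation.

## Worked example

```python
import numpy as np
import slfv

landscape = slfv.Landscape(2, (1.0, 1.0))              # unit torus
kernel = slfv.EventKernel("disc", radius=0.2, impact=0.1, rate_density=1.0)
rng = np.random.default_rng(7)
sample = slfv.individuals_from_array(
    [f"ind{i}" for i in range(8)], landscape.random_points(8, rng)
)

g = slfv.simulate_genealogy(sample, landscape, kernel, rng)
print(f"TMRCA {g.tmrca:.1f}, mergers {g.merger_sizes}")

cfg = slfv.MutationConfig(model="K2P", mu=2e-5, kappa=3.0,
                          seq_length=1000, n_loci=10)
alignments = slfv.simulate_dataset(sample, landscape, kernel, cfg, rng)
sv = slfv.compute_summaries(alignments, sample, landscape)
print(f"mean pi {np.mean(sv.pi):.5f}, IBD slope {sv.ibd_slope:.4f}")
```

prints (seed 7):

```
TMRCA 7636.4, mergers [2, 2, 3, 2, 2, 2]
mean pi 0.17245, IBD slope 0.0291
```

TMRCA is in model time (events per unit area per unit time = 1). One
merger joined three lineages at once — a multiple merger, impossible
under Kingman's coalescent. Mean π is the across-locus average per-site
pairwise diversity; the positive isolation-by-distance slope says
genetically similar individuals sit geographically closer, the signature
of limited dispersal (here `r = 0.2` against a torus of diameter ≈ 0.71).

Estimating `(N_s, r)` from data follows the ABC path:

```python
from slfv import PriorSpec, build_reference_table, rejection_abc, hpdi
from slfv.abc import PARAM_NS, PARAM_R, SimulationDesign

design = SimulationDesign(landscape=landscape, sample=sample)
priors = PriorSpec({PARAM_NS: ("log-uniform", 3.0, 100.0),
                    PARAM_R: ("uniform", 0.1, 0.3)})
table = build_reference_table(priors, design, 2000, rng)
post = rejection_abc(sv, table, tolerance=0.05)
lo, hi = hpdi(post.accepted[PARAM_NS].to_numpy(), 0.95)
print(f"N_s median {post.median(PARAM_NS):.1f}, 95% HPDI [{lo:.1f}, {hi:.1f}]")
```

The same operations are available from a shell:

```bash
slfv scenario --name validation --out cfg/
slfv simulate --config cfg/config.yaml --sample cfg/sample.tsv --out run1 --seed 7
slfv abc-build --sims 2000 --out table.tsv --seed 7
slfv abc-cv --table table.tsv --tolerance 0.05 --heldout 100 --out cv.tsv
```

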