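"""Named simulation scenarios and edge-case fixtures.

Self-contained scenario generator: every configuration needed to
exercise the simulator, the mutation overlays, the summaries and the
ABC layer is built programmatically (no downloads).  The central one is
the *validation* scenario -- eight individuals on a unit torus, ten
unlinked 1-kb loci per dataset, disc events -- used by the
leave-one-out cross-validation study.  The *triangle corner* scenarios
probe the qualitative extremes of spatial structure: isolation by
distance (small events), two discrete patches (a heterogeneity raster
concentrating events in two areas), and panmixia (events spanning the
whole torus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .abc import (
    PARAM_NS,
    PARAM_R,
    CVReport,
    PriorSpec,
    ReferenceTable,
    SimulationDesign,
    build_reference_table,
    loo_cv_r2,
    permuted_truth_r2,
)
from .landscape import (
    EventKernel,
    Individual,
    Landscape,
    Raster,
    individuals_from_array,
    save_config,
    write_sample_sheet,
)
from .mutations import MutationConfig, simulate_dataset, write_fasta
from .summaries import generation_time

__all__ = [
    "Scenario",
    "make_validation_scenario",
    "make_triangle_corner_scenarios",
    "make_edge_fixtures",
    "run_validation_study",
]


@dataclass
class Scenario:
    """A named, fully specified simulation configuration."""

    name: str
    landscape: Landscape
    sample: list[Individual]
    kernel: Optional[EventKernel] = None          # fixed-kernel scenarios
    priors: Optional[PriorSpec] = None            # inference scenarios
    mutation_model: str = "K2P"
    mu_per_generation: float = 1e-5
    kappa: float = 3.0
    seq_length: int = 1000
    n_loci: int = 10
    rate_density: float = 1.0
    max_events: int = 2_000_000
    seed: int = 0

    def design(self) -> SimulationDesign:
        return SimulationDesign(
            landscape=self.landscape,
            sample=self.sample,
            rate_density=self.rate_density,
            mutation_model=self.mutation_model,
            mu_per_generation=self.mu_per_generation,
            kappa=self.kappa,
            seq_length=self.seq_length,
            n_loci=self.n_loci,
            max_events=self.max_events,
        )

    def mutation_config(self) -> MutationConfig:
        if self.kernel is None:
            raise ValueError(f"scenario {self.name!r} has no fixed kernel")
        # translate the per-generation mutation rate into model time;
        # for kernels spanning the torus the per-event hit rate
        # lambda*u*pi r^2 is capped by the torus area
        try:
            g = generation_time(self.kernel, self.landscape)
        except ValueError:
            g = 1.0 / (
                self.kernel.rate_density * self.kernel.impact * self.landscape.area
            )
        return MutationConfig(
            model=self.mutation_model,
            mu=self.mu_per_generation / g,
            kappa=self.kappa,
            seq_length=self.seq_length,
            n_loci=self.n_loci,
        )

    def simulate(self, seed: Optional[int] = None):
        """Simulate one dataset (list of LocusAlignment) under the fixed kernel."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return simulate_dataset(
            self.sample, self.landscape, self.kernel, self.mutation_config(),
            rng, max_events=self.max_events,
        )

    def render(self, outdir: Union[str, Path]) -> None:
        """Write config.yaml, sample.tsv (and raster.txt if present)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raster_path = None
        kernel = self.kernel
        if kernel is None:
            # render a mid-prior kernel so the config is runnable as-is
            mid = {
                k: float(np.sqrt(lo * hi)) if kind == "log-uniform" else (lo + hi) / 2
                for k, (kind, lo, hi) in self.priors.params.items()
            }
            design = self.design()
            kernel = design.kernel_for(mid[PARAM_NS], mid[PARAM_R])
        if kernel.heterogeneity is not None:
            raster_path = "raster.txt"
            kernel.heterogeneity.to_text(outdir / raster_path)
        save_config(
            outdir / "config.yaml", self.landscape, kernel,
            seed=self.seed, raster_path=raster_path,
        )
        write_sample_sheet(outdir / "sample.tsv", self.sample)

    def write_dataset(self, outdir: Union[str, Path], seed: Optional[int] = None) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for aln in self.simulate(seed=seed):
            p = outdir / f"{self.name}.{aln.locus_id}.fasta"
            write_fasta(aln, p)
            paths.append(p)
        return paths


def _uniform_sample(
    n: int, landscape: Landscape, seed: int, prefix: str = "ind"
) -> list[Individual]:
    rng = np.random.default_rng(seed)
    locs = landscape.random_points(n, rng)
    return individuals_from_array([f"{prefix}{i}" for i in range(n)], locs)


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

def make_validation_scenario(seed: int = 2024, n: int = 8) -> Scenario:
    """The cross-validation study design: n individuals on the unit
    torus, 10 unlinked 1-kb loci, disc events; neighborhood size
    log-uniform over 1.5 decades and dispersal radius uniform."""
    landscape = Landscape(2, (1.0, 1.0))
    return Scenario(
        name="validation",
        landscape=landscape,
        sample=_uniform_sample(n, landscape, seed),
        priors=PriorSpec(
            {
                PARAM_NS: ("log-uniform", 3.0, 100.0),
                PARAM_R: ("uniform", 0.1, 0.3),
            }
        ),
        mutation_model="K2P",
        mu_per_generation=1e-5,
        kappa=3.0,
        seq_length=1000,
        n_loci=10,
        seed=seed,
    )


def make_triangle_corner_scenarios(seed: int = 2024) -> list[Scenario]:
    """Three corners of the population-structure triangle:

    * ``ibd`` -- small-radius events on a homogeneous torus: genetic
      distance grows with geographic distance;
    * ``two_patch`` -- events concentrated in two habitat patches by a
      heterogeneity raster: discrete-population structure emerges;
    * ``panmixia`` -- events spanning the torus: location is irrelevant.
    """
    landscape = Landscape(2, (1.0, 1.0))
    sample = _uniform_sample(12, landscape, seed)

    ibd = Scenario(
        name="ibd",
        landscape=landscape,
        sample=sample,
        kernel=EventKernel("disc", radius=0.08, impact=0.5, rate_density=1.0),
        mu_per_generation=5e-5,
        n_loci=8,
        seq_length=500,
        seed=seed,
    )

    # two habitat patches along x with a near-inert corridor between
    weights = np.ones((8, 1))
    weights[2:4, 0] = 0.02
    weights[6:8, 0] = 0.02
    raster = Raster(weights, landscape)
    patch_ids = [f"p{i}" for i in range(8)]
    patch_locs = np.column_stack(
        [
            np.concatenate([0.05 + 0.15 * np.arange(4) / 4, 0.55 + 0.15 * np.arange(4) / 4]),
            np.full(8, 0.5),
        ]
    )
    two_patch = Scenario(
        name="two_patch",
        landscape=landscape,
        sample=individuals_from_array(patch_ids, patch_locs),
        kernel=EventKernel(
            "disc", radius=0.15, impact=0.5, rate_density=1.0,
            heterogeneity=raster,
        ),
        mu_per_generation=5e-5,
        n_loci=8,
        seq_length=500,
        seed=seed,
    )

    panmixia = Scenario(
        name="panmixia",
        landscape=landscape,
        sample=sample,
        kernel=EventKernel("disc", radius=1.0, impact=0.2, rate_density=1.0),
        mu_per_generation=5e-5,
        n_loci=8,
        seq_length=500,
        seed=seed,
    )
    return [ibd, two_patch, panmixia]


def make_edge_fixtures(seed: int = 7) -> list[Scenario]:
    """Degenerate cases: a single individual, a mutation-free dataset,
    and a sparse landscape that exhausts its event budget without
    coalescing (the non-coalesced status must surface explicitly)."""
    landscape = Landscape(2, (1.0, 1.0))
    single = Scenario(
        name="single_individual",
        landscape=landscape,
        sample=_uniform_sample(1, landscape, seed),
        kernel=EventKernel("disc", radius=0.1, impact=0.5, rate_density=1.0),
        n_loci=1,
        seq_length=100,
        seed=seed,
    )
    monomorphic = Scenario(
        name="monomorphic",
        landscape=landscape,
        sample=_uniform_sample(4, landscape, seed),
        kernel=EventKernel("disc", radius=0.4, impact=1.0, rate_density=1.0),
        mu_per_generation=0.0,
        n_loci=1,
        seq_length=100,
        seed=seed,
    )
    sparse = Scenario(
        name="sparse_non_coalescing",
        landscape=Landscape(2, (1.0, 1.0)),
        sample=_uniform_sample(6, landscape, seed),
        kernel=EventKernel("disc", radius=0.02, impact=0.02, rate_density=1.0),
        n_loci=1,
        seq_length=100,
        max_events=2_000,
        seed=seed,
    )
    return [single, monomorphic, sparse]


# ---------------------------------------------------------------------------
# Validation study pipeline
# ---------------------------------------------------------------------------

def run_validation_study(
    seed: int,
    n_sims: int = 2000,
    tolerance: float = 0.05,
    n_heldout: int = 100,
    n: int = 8,
    compute_coverage: bool = False,
) -> dict:
    """Build a reference table under the validation scenario and run the
    leave-one-out cross-validation.

    Returns the table, the CV report, per-parameter R^2 and the
    permuted-truth baseline R^2 for each parameter.
    """
    rng = np.random.default_rng(seed)
    scenario = make_validation_scenario(seed=int(rng.integers(0, 2**31 - 1)), n=n)
    table = build_reference_table(
        scenario.priors, scenario.design(), n_sims, rng
    )
    report = loo_cv_r2(
        table, tolerance, n_heldout, rng, compute_coverage=compute_coverage
    )
    baselines = {
        p: permuted_truth_r2(report, p, rng) for p in table.param_names
    }
    return {
        "scenario": scenario,
        "table": table,
        "report": report,
        "r2": report.r2,
        "permuted_r2": baselines,
    }
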