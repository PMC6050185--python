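"""Rejection ABC for neighborhood size and dispersal radius.

The inference layer treats the SLFV simulator as a generative model:
parameters (neighborhood size N_s and disc dispersal radius r) are
drawn from priors, a georeferenced multi-locus dataset is simulated for
each draw, and its summary vector is stored in a reference table.
Estimation is plain rejection ABC: the accepted posterior sample is the
tolerance-quantile of reference rows nearest to the observed summaries
in MAD-scaled Euclidean distance.  Point estimates are posterior
medians; intervals are highest-posterior-density intervals (HPDI).
Validation follows the leave-one-out design: hold out a table row, use
its summaries as pseudo-observed data against the remaining rows, and
regress estimates on truths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import EventKernel, Individual, Landscape
from .mutations import MutationConfig, simulate_dataset
from .summaries import (
    SummaryVector,
    compute_summaries,
    generation_time,
    impact_from_neighborhood_size,
)

__all__ = [
    "PriorSpec",
    "SimulationDesign",
    "ReferenceTable",
    "PosteriorSample",
    "CVReport",
    "build_reference_table",
    "rejection_abc",
    "hpdi",
    "loo_cv_r2",
    "permuted_truth_r2",
]

logger = logging.getLogger(__name__)

PARAM_NS = "neighborhood_size"
PARAM_R = "dispersal_radius"


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors.

    ``params`` maps a parameter name to ``(kind, low, high)`` where kind
    is ``"uniform"`` or ``"log-uniform"``; bounds are finite, positive
    and ordered.
    """

    params: dict[str, tuple[str, float, float]]

    def __post_init__(self) -> None:
        for name, (kind, lo, hi) in self.params.items():
            if kind not in ("uniform", "log-uniform"):
                raise ValueError(f"{name}: unknown prior kind {kind!r}")
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(f"{name}: prior bounds must be finite")
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < low <= high")

    @property
    def names(self) -> list[str]:
        return list(self.params)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name, (kind, lo, hi) in self.params.items():
            if kind == "uniform":
                out[name] = float(rng.uniform(lo, hi))
            else:
                out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return out

    def sample_n(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame([self.sample(rng) for _ in range(n)])


# ---------------------------------------------------------------------------
# Simulation design and reference table
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """Everything needed to simulate one dataset given (N_s, r).

    The mutation rate is specified per site per *generation* and
    converted to model time through the kernel's generation time, so
    expected diversity scales with neighborhood size (see the summaries
    module).  Sample locations are fixed across the table: reference
    simulations are conditioned on the observed sampling geometry.
    """

    landscape: Landscape
    sample: list[Individual]
    rate_density: float = 1.0
    mutation_model: str = "K2P"
    mu_per_generation: float = 1e-5
    kappa: float = 3.0
    seq_length: int = 1000
    n_loci: int = 10
    bin_edges: Optional[np.ndarray] = None
    max_events: int = 2_000_000

    def kernel_for(self, neighborhood_size: float, radius: float) -> EventKernel:
        return EventKernel(
            family="disc",
            radius=float(radius),
            impact=impact_from_neighborhood_size(neighborhood_size),
            rate_density=self.rate_density,
        )

    def mutation_config_for(self, kernel: EventKernel) -> MutationConfig:
        mu_time = self.mu_per_generation / generation_time(kernel, self.landscape)
        return MutationConfig(
            model=self.mutation_model,
            mu=mu_time,
            kappa=self.kappa,
            seq_length=self.seq_length,
            n_loci=self.n_loci,
        )

    def simulate_summaries(
        self, neighborhood_size: float, radius: float, rng: np.random.Generator
    ) -> SummaryVector:
        kernel = self.kernel_for(neighborhood_size, radius)
        config = self.mutation_config_for(kernel)
        alignments = simulate_dataset(
            self.sample, self.landscape, kernel, config, rng,
            max_events=self.max_events,
        )
        return compute_summaries(
            alignments, self.sample, self.landscape, bin_edges=self.bin_edges
        )


@dataclass
class ReferenceTable:
    """Prior draws with their summary vectors.

    ``frame`` holds one row per simulation: the parameter columns
    followed by the summary columns.
    """

    frame: pd.DataFrame
    param_names: list[str]
    seed: Optional[int] = None
    n_redraws: int = 0

    @property
    def summary_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.param_names]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: Union[str, Path],
        param_names: Sequence[str] = (PARAM_NS, PARAM_R),
    ) -> "ReferenceTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame=frame, param_names=list(param_names))


def build_reference_table(
    priors: PriorSpec,
    design: SimulationDesign,
    n_sims: int,
    rng: np.random.Generator,
    max_redraws_per_row: int = 20,
) -> ReferenceTable:
    """Simulate ``n_sims`` datasets from the prior and summarize each.

    Rows whose simulation fails to coalesce within the design's event
    budget are redrawn (fresh parameters and seed); redraw counts are
    logged and recorded.  Each row carries its own seed derived up front
    from ``rng``, so tables are reproducible row-for-row.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    row_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    rows = []
    n_redraws = 0
    for i in range(n_sims):
        row_rng = np.random.default_rng(int(row_seeds[i]))
        for attempt in range(max_redraws_per_row + 1):
            theta = priors.sample(row_rng)
            try:
                summ = design.simulate_summaries(
                    theta[PARAM_NS], theta[PARAM_R], row_rng
                )
            except RuntimeError:
                n_redraws += 1
                logger.warning("row %d: non-coalescence, redrawing (%d)", i, attempt + 1)
                continue
            break
        else:
            raise RuntimeError(
                f"row {i}: exceeded {max_redraws_per_row} redraws"
            )
        rows.append({**theta, **summ.to_series().to_dict()})
    frame = pd.DataFrame(rows, columns=list(priors.names) + list(rows[0])[len(priors.names):])
    return ReferenceTable(
        frame=frame, param_names=priors.names, n_redraws=n_redraws
    )


# ---------------------------------------------------------------------------
# Rejection sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """Accepted parameter rows of a rejection-ABC run."""

    accepted: pd.DataFrame
    tolerance: float
    acceptance_count: int
    dropped_columns: list[str] = field(default_factory=list)
    distances: Optional[np.ndarray] = None

    def median(self, param: str) -> float:
        return float(self.accepted[param].median())


def _scaled_distances(
    observed: pd.Series, summaries: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    mads = summaries.apply(
        lambda col: stats.median_abs_deviation(col.to_numpy()), axis=0
    )
    keep = [c for c in summaries.columns if mads[c] > 0]
    dropped = [c for c in summaries.columns if mads[c] <= 0]
    if not keep:
        raise ValueError("every summary column has zero spread; cannot rank")
    S = summaries[keep].to_numpy(dtype=float)
    obs = observed[keep].to_numpy(dtype=float)
    scale = mads[keep].to_numpy(dtype=float)
    z = (S - obs) / scale
    return np.sqrt((z * z).sum(axis=1)), dropped


def rejection_abc(
    observed: Union[SummaryVector, pd.Series],
    table: ReferenceTable,
    tolerance: float,
) -> PosteriorSample:
    """Accept the ``tolerance`` fraction of reference rows nearest to
    ``observed`` in MAD-scaled Euclidean distance.

    Summary columns with zero median absolute deviation are dropped
    (and logged); ties at the acceptance cutoff are broken by row order.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    if table.n_rows == 0:
        raise ValueError("reference table is empty")
    if isinstance(observed, SummaryVector):
        observed = observed.to_series()
    summaries = table.frame[table.summary_names]
    missing = set(table.summary_names) - set(observed.index)
    if missing:
        raise ValueError(f"observed summaries missing columns {sorted(missing)}")
    d, dropped = _scaled_distances(observed, summaries)
    if dropped:
        logger.info("dropped zero-spread summary columns: %s", dropped)
    n_accept = math.ceil(tolerance * table.n_rows)
    order = np.argsort(d, kind="stable")[:n_accept]
    return PosteriorSample(
        accepted=table.frame.iloc[order][table.param_names].reset_index(drop=True),
        tolerance=tolerance,
        acceptance_count=n_accept,
        dropped_columns=dropped,
        distances=d[order],
    )


# ---------------------------------------------------------------------------
# HPDI
# ---------------------------------------------------------------------------

def hpdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` of the
    sorted samples (highest posterior density interval)."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("hpdi needs at least two samples")
    m = max(2, math.ceil(mass * n))
    if m > n:
        m = n
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _r_squared(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Least-squares R^2 of estimates regressed on truths (0 for a
    constant predictor)."""
    if np.ptp(estimate) == 0 or np.ptp(truth) == 0:
        return 0.0
    res = stats.linregress(truth, estimate)
    return float(res.rvalue ** 2)


@dataclass
class CVReport:
    """Leave-one-out cross-validation results."""

    estimates: pd.DataFrame        # columns: <param>_true, <param>_est per parameter
    r2: dict[str, float]
    tolerance: float
    n_heldout: int
    coverage_95: Optional[dict[str, float]] = None


def loo_cv_r2(
    table: ReferenceTable,
    tolerance: float,
    n_heldout: int,
    rng: np.random.Generator,
    compute_coverage: bool = False,
) -> CVReport:
    """Hold out ``n_heldout`` random table rows one at a time; for each,
    run rejection ABC of its summaries against the remaining rows and
    estimate parameters by the posterior median.  Reports per-parameter
    R^2 of estimates versus truths (and, optionally, the fraction of
    held-out truths inside the 95% HPDI)."""
    if n_heldout > table.n_rows:
        raise ValueError("cannot hold out more rows than the table has")
    if tolerance * (table.n_rows - 1) < 1:
        raise ValueError("tolerance too small: no rows would be accepted")
    chosen = rng.choice(table.n_rows, size=n_heldout, replace=False)
    records = []
    covered = {p: 0 for p in table.param_names}
    for i in chosen:
        i = int(i)
        obs = table.frame.iloc[i][table.summary_names]
        rest = ReferenceTable(
            frame=table.frame.drop(index=table.frame.index[i]).reset_index(drop=True),
            param_names=table.param_names,
        )
        post = rejection_abc(obs, rest, tolerance)
        rec = {}
        for p in table.param_names:
            rec[f"{p}_true"] = float(table.frame.iloc[i][p])
            rec[f"{p}_est"] = post.median(p)
            if compute_coverage:
                lo, hi = hpdi(post.accepted[p].to_numpy(), 0.95)
                covered[p] += int(lo <= rec[f"{p}_true"] <= hi)
        records.append(rec)
    est = pd.DataFrame(records)
    r2 = {
        p: _r_squared(est[f"{p}_true"].to_numpy(), est[f"{p}_est"].to_numpy())
        for p in table.param_names
    }
    coverage = (
        {p: covered[p] / n_heldout for p in table.param_names}
        if compute_coverage
        else None
    )
    return CVReport(
        estimates=est, r2=r2, tolerance=tolerance, n_heldout=n_heldout,
        coverage_95=coverage,
    )


def permuted_truth_r2(
    report: CVReport, param: str, rng: np.random.Generator
) -> float:
    """Baseline R^2 after permuting the truth column: what the
    cross-validation would score if the parameter were unidentifiable."""
    truth = report.estimates[f"{param}_true"].to_numpy().copy()
    rng.shuffle(truth)
    return _r_squared(truth, report.estimates[f"{param}_est"].to_numpy())
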