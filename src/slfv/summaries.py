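"""Spatial-genetic summary statistics and classical reference quantities.

Links observable genetic variation to the SLFV parameters: per-locus
nucleotide diversity and Watterson's estimator, an isolation-by-distance
(IBD) regression of pairwise genetic distance on torus geographic
distance, and a distance-class variogram.  Also provides the classical
island-model F_ST and Wright neighborhood-size formulas used as
contrasts, and the parameter conversions between the event-based
description (radius r, impact u, rate density lambda) and the
density/dispersal description (d, sigma^2, N_s).

Parameter conversions
---------------------
For the homogeneous 2-D disc kernel, a lineage is hit by events at rate
``lambda * u * pi r^2`` (one hit = one reproduction seen backward), so a
natural generation time is ``g = 1 / (lambda * u * pi r^2)``.  Two
co-located lineages coalesce, under fast mixing, at rate
``lambda u^2 (pi r^2)^2 / A`` on a torus of area ``A``, giving an
expected pairwise coalescence time of ``A / (u pi r^2)`` generations --
an effective density ``d_eff = 1 / (u pi r^2)``.  Combining with the
event-based neighborhood size ``N_s = d * pi r^2`` yields the simple
dictionary ``u = 1 / N_s`` used by the inference layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import EventKernel, Individual, Landscape
from .mutations import LocusAlignment

__all__ = [
    "SummaryVector",
    "island_model_fst",
    "wright_neighborhood_size",
    "event_neighborhood_size",
    "impact_from_neighborhood_size",
    "effective_density",
    "generation_time",
    "nucleotide_diversity",
    "watterson_theta",
    "compute_summaries",
    "default_bin_edges",
]

N_VARIOGRAM_BINS = 10


# ---------------------------------------------------------------------------
# Classical closed forms and parameter conversions
# ---------------------------------------------------------------------------

def island_model_fst(Ne_m: float) -> float:
    """Expected island-model F_ST = 1 / (4 Ne m + 1).

    ``Ne_m`` is the effective number of migrants per generation.
    """
    if Ne_m < 0:
        raise ValueError("Ne*m must be >= 0")
    return 1.0 / (4.0 * Ne_m + 1.0)


def wright_neighborhood_size(sigma2: float, density: float, dimension: int = 2) -> float:
    """Wright's neighborhood size from dispersal variance and density.

    2-D: ``N_s = 4 pi sigma^2 d`` (the classical convention); 1-D:
    ``N_s = 2 d sqrt(2 pi sigma^2)``.
    """
    if sigma2 <= 0 or density <= 0:
        raise ValueError("sigma2 and density must be > 0")
    if dimension == 2:
        return 4.0 * math.pi * sigma2 * density
    if dimension == 1:
        return 2.0 * density * math.sqrt(2.0 * math.pi * sigma2)
    raise ValueError("dimension must be 1 or 2")


def event_neighborhood_size(density: float, radius: float, dimension: int = 2) -> float:
    """Event-based neighborhood size: individuals within one event area.

    2-D: ``d * pi r^2``; 1-D: ``d * 2 r``.
    """
    if density <= 0 or radius <= 0:
        raise ValueError("density and radius must be > 0")
    if dimension == 2:
        return density * math.pi * radius ** 2
    if dimension == 1:
        return density * 2.0 * radius
    raise ValueError("dimension must be 1 or 2")


def impact_from_neighborhood_size(neighborhood_size: float) -> float:
    """Event impact u realizing a target neighborhood size (u = 1/N_s).

    Follows from equating the event-based N_s with the disc model's
    effective density 1/(u * event area); see the module docstring.
    Requires ``N_s >= 1`` since u is a probability.
    """
    if neighborhood_size < 1:
        raise ValueError("neighborhood size must be >= 1 (u = 1/N_s <= 1)")
    return 1.0 / neighborhood_size


def effective_density(kernel: EventKernel, landscape: Landscape) -> float:
    """Effective density 1 / (u * event area) of a disc kernel."""
    return 1.0 / (kernel.impact * kernel.support_area(landscape))


def generation_time(kernel: EventKernel, landscape: Landscape) -> float:
    """Expected model time between reproduction events hitting a lineage:
    ``1 / (lambda * u * event area)``."""
    return 1.0 / (
        kernel.rate_density * kernel.impact * kernel.support_area(landscape)
    )


# ---------------------------------------------------------------------------
# Per-locus statistics
# ---------------------------------------------------------------------------

def _locus_length(aln: LocusAlignment) -> int:
    # infinite-sites matrices only store segregating columns; the nominal
    # locus length carries the per-site scale
    if aln.alphabet == "binary" and aln.seq_length is not None:
        return int(aln.seq_length)
    return aln.n_sites


def _pairwise_diff_matrix(aln: LocusAlignment) -> np.ndarray:
    """Per-site difference fraction for every ordered pair (n, n)."""
    L = _locus_length(aln)
    if aln.n_sites == 0:
        return np.zeros((aln.n_sequences, aln.n_sequences))
    d = aln.data
    diffs = (d[:, None, :] != d[None, :, :]).sum(axis=2)
    return diffs / float(L)


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """Mean per-site pairwise difference (pi) for one locus."""
    n = aln.n_sequences
    if n < 2:
        raise ValueError("pi needs at least two sequences")
    m = _pairwise_diff_matrix(aln)
    iu = np.triu_indices(n, k=1)
    return float(m[iu].mean())


def watterson_theta(aln: LocusAlignment) -> float:
    """Watterson's estimator S / (a_n * L) per site for one locus."""
    n = aln.n_sequences
    if n < 2:
        raise ValueError("Watterson's estimator needs at least two sequences")
    a_n = sum(1.0 / i for i in range(1, n))
    return aln.segregating_sites() / (a_n * _locus_length(aln))


# ---------------------------------------------------------------------------
# Summary vector
# ---------------------------------------------------------------------------

def default_bin_edges(landscape: Landscape, n_bins: int = N_VARIOGRAM_BINS) -> np.ndarray:
    """Equal-width distance-class edges covering (0, max torus distance]."""
    return np.linspace(0.0, landscape.max_distance, n_bins + 1)


@dataclass
class SummaryVector:
    """Summaries of one georeferenced multi-locus dataset.

    Stores per-locus pi and Watterson's theta; the flattened vector used
    for ABC distances (:meth:`to_series`) carries their across-locus
    mean and SD -- keeping the vector invariant under locus reordering --
    together with the IBD regression and the variogram.
    """

    pi: np.ndarray                 # per locus
    watterson: np.ndarray          # per locus
    ibd_slope: float
    ibd_intercept: float
    variogram: np.ndarray          # mean genetic distance per distance class
    bin_edges: np.ndarray
    n: int
    n_loci: int

    def to_series(self) -> pd.Series:
        vals = {
            "pi_mean": float(np.mean(self.pi)),
            "pi_sd": float(np.std(self.pi)),
            "theta_w_mean": float(np.mean(self.watterson)),
            "theta_w_sd": float(np.std(self.watterson)),
            "ibd_slope": self.ibd_slope,
            "ibd_intercept": self.ibd_intercept,
        }
        for i, v in enumerate(self.variogram):
            vals[f"vario_{i:02d}"] = float(v)
        return pd.Series(vals)

    @staticmethod
    def column_names(n_bins: int = N_VARIOGRAM_BINS) -> list[str]:
        return [
            "pi_mean", "pi_sd", "theta_w_mean", "theta_w_sd",
            "ibd_slope", "ibd_intercept",
        ] + [f"vario_{i:02d}" for i in range(n_bins)]


def compute_summaries(
    alignments: Sequence[LocusAlignment],
    sample: Sequence[Individual],
    landscape: Landscape,
    bin_edges: Optional[np.ndarray] = None,
) -> SummaryVector:
    """Summaries of a set of unlinked loci for georeferenced individuals.

    Genetic distance between two individuals is their per-site
    difference fraction averaged over loci; geographic distance is the
    minimal-image torus distance.  The IBD slope/intercept come from an
    ordinary least-squares fit over all pairs; the variogram is the mean
    genetic distance within fixed distance classes (empty classes
    report 0).
    """
    if len(sample) < 2:
        raise ValueError("summaries need at least two individuals")
    ids = [ind.id for ind in sample]
    order = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    if bin_edges is None:
        bin_edges = default_bin_edges(landscape)
    bin_edges = np.asarray(bin_edges, dtype=float)

    pis, thetas = [], []
    mean_gd = np.zeros((n, n))
    for aln in alignments:
        missing = set(ids) - set(aln.ids)
        if missing:
            raise ValueError(
                f"locus {aln.locus_id}: missing individuals {sorted(missing)}"
            )
        perm = [aln.ids.index(s) for s in ids]
        reordered = LocusAlignment(
            ids=ids, data=aln.data[perm], alphabet=aln.alphabet,
            locus_id=aln.locus_id, seq_length=aln.seq_length,
        )
        m = _pairwise_diff_matrix(reordered)
        pis.append(float(m[np.triu_indices(n, k=1)].mean()))
        thetas.append(watterson_theta(reordered))
        mean_gd += m
    mean_gd /= len(alignments)

    locs = np.vstack([ind.location for ind in sample])
    geo = landscape.pairwise_distances(locs)
    iu = np.triu_indices(n, k=1)
    gen = mean_gd[iu]

    if np.ptp(geo) > 0:
        slope, intercept = np.polyfit(geo, gen, 1)
    else:
        slope, intercept = 0.0, float(gen.mean())

    which = np.clip(
        np.searchsorted(bin_edges, geo, side="left") - 1, 0, len(bin_edges) - 2
    )
    vario = np.zeros(len(bin_edges) - 1)
    for b in range(len(vario)):
        mask = which == b
        if mask.any():
            vario[b] = gen[mask].mean()

    return SummaryVector(
        pi=np.asarray(pis),
        watterson=np.asarray(thetas),
        ibd_slope=float(slope),
        ibd_intercept=float(intercept),
        variogram=vario,
        bin_edges=bin_edges,
        n=n,
        n_loci=len(alignments),
    )
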