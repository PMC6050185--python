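"""Toroidal landscapes, individuals and spatial event kernels.

The spatial Lambda-Fleming-Viot (SLFV) process acts on a continuous,
periodic landscape: reproduction/movement events fall as a Poisson
process in time and space, and each event affects nearby lineages
according to a spatial kernel.  This module provides the geometric
primitives shared by the simulator and the inference layers:

* :class:`Landscape` -- a 1- or 2-dimensional torus with periodic
  (wrap-around) boundaries, eliminating edge effects;
* :class:`Individual` -- a sampled individual with an id, a location and
  an optional state (haplotype label or similar);
* :class:`EventKernel` -- the family of event kernels E(x): a uniform
  disc of radius ``r`` or an (untruncated) Gaussian of scale ``r``, with
  per-lineage impact ``u`` and event rate density ``lambda``;
* :class:`Raster` -- an optional piecewise-constant weight map
  multiplying the local event intensity (spatial heterogeneity in the
  event process only; radius and impact stay homogeneous).

All randomness flows through :class:`numpy.random.Generator` instances
supplied by the caller.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Landscape",
    "Individual",
    "Raster",
    "EventKernel",
    "Event",
    "torus_displacement",
    "selection_probability",
    "sample_event",
    "load_config",
    "save_config",
    "read_sample_sheet",
    "write_sample_sheet",
]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landscape:
    """A ``dimension``-dimensional torus with the given extent per axis.

    Coordinates live in ``[0, extent_i)`` on each axis; all distances are
    minimal-image (torus) distances.
    """

    dimension: int
    extent: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError(f"dimension must be 1 or 2, got {self.dimension}")
        ext = tuple(float(e) for e in np.atleast_1d(np.asarray(self.extent, dtype=float)))
        if len(ext) != self.dimension:
            raise ValueError(
                f"extent has {len(ext)} entries for dimension {self.dimension}"
            )
        if any(e <= 0 for e in ext):
            raise ValueError(f"all extents must be > 0, got {ext}")
        object.__setattr__(self, "extent", ext)

    @property
    def area(self) -> float:
        """Total volume of the torus (length in 1D, area in 2D)."""
        return float(np.prod(self.extent))

    @property
    def max_distance(self) -> float:
        """Largest possible torus distance: half the main diagonal."""
        return 0.5 * math.sqrt(sum(e * e for e in self.extent))

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates into the fundamental domain ``[0, extent)``."""
        return np.mod(np.asarray(x, dtype=float), np.asarray(self.extent))

    def contains(self, x: np.ndarray) -> bool:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ext = np.asarray(self.extent)
        return bool(np.all(x >= 0) and np.all(x < ext))

    def require_inside(self, x: np.ndarray, what: str = "coordinate") -> None:
        if not self.contains(x):
            raise ValueError(f"{what} {np.asarray(x)} outside landscape extent {self.extent}")

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimal-image displacement vector from ``a`` to ``b``."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ext = np.asarray(self.extent)
        d = (b - a + 0.5 * ext) % ext - 0.5 * ext
        return d

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        return float(np.linalg.norm(self.displacement(a, b)))

    def pairwise_distances(self, points: np.ndarray) -> np.ndarray:
        """Condensed-form torus distances between rows of ``points``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ext = np.asarray(self.extent)
        diff = pts[:, None, :] - pts[None, :, :]
        diff = (diff + 0.5 * ext) % ext - 0.5 * ext
        full = np.sqrt((diff ** 2).sum(axis=-1))
        iu = np.triu_indices(len(pts), k=1)
        return full[iu]

    def random_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.random((n, self.dimension)) * np.asarray(self.extent)


def torus_displacement(
    a: np.ndarray, b: np.ndarray, landscape: Landscape
) -> tuple[np.ndarray, float]:
    """Minimal-image displacement and distance from ``a`` to ``b``.

    Raises ``ValueError`` when either coordinate lies outside the landscape.
    """
    landscape.require_inside(a, "coordinate a")
    landscape.require_inside(b, "coordinate b")
    vec = landscape.displacement(a, b)
    return vec, float(np.linalg.norm(vec))


# ---------------------------------------------------------------------------
# Individuals
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    """A sampled individual: opaque id, location, optional state label."""

    id: str
    location: np.ndarray
    state: object = None

    def __post_init__(self) -> None:
        self.location = np.atleast_1d(np.asarray(self.location, dtype=float))


def individuals_from_array(
    ids: Sequence[str], locations: np.ndarray
) -> list[Individual]:
    if len(set(ids)) != len(ids):
        raise ValueError("individual ids must be unique within a sample")
    return [Individual(str(i), loc) for i, loc in zip(ids, np.atleast_2d(locations))]


# ---------------------------------------------------------------------------
# Heterogeneity raster
# ---------------------------------------------------------------------------

class Raster:
    """Piecewise-constant nonnegative weight map over a landscape.

    ``weights`` is indexed ``[i]`` (1D) or ``[ix, iy]`` (2D) over a regular
    grid of tiles spanning the full extent.  Weights multiply the local
    event intensity; they are relative (only ratios matter for center
    placement, while the absolute scale enters the total event rate).
    """

    def __init__(self, weights: np.ndarray, landscape: Landscape):
        w = np.asarray(weights, dtype=float)
        if landscape.dimension == 1:
            w = np.atleast_1d(w)
        if w.ndim != landscape.dimension:
            raise ValueError(
                f"raster has {w.ndim} axes for a {landscape.dimension}-D landscape"
            )
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("raster weights must be finite and nonnegative")
        if not np.any(w > 0):
            raise ValueError("raster weights are zero everywhere")
        self.weights = w
        self.landscape = landscape
        self.tile_shape = w.shape
        self.tile_size = np.asarray(landscape.extent) / np.asarray(w.shape)
        self.tile_area = float(np.prod(self.tile_size))
        flat = w.ravel(order="C")
        self._cum = np.cumsum(flat * self.tile_area)
        self.total_weighted_area = float(self._cum[-1])
        self._probs = (flat * self.tile_area) / self.total_weighted_area

    def tile_index(self, x: np.ndarray) -> tuple[int, ...]:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.floor(x / self.tile_size).astype(int)
        idx = np.minimum(idx, np.asarray(self.tile_shape) - 1)
        return tuple(int(i) for i in idx)

    def weight_at(self, x: np.ndarray) -> float:
        return float(self.weights[self.tile_index(x)])

    def sample_point(self, rng: np.random.Generator) -> np.ndarray:
        # Inverse-CDF over tile weights, then uniform within the tile.
        u = rng.random() * self.total_weighted_area
        flat = int(np.searchsorted(self._cum, u, side="right"))
        flat = min(flat, self._cum.size - 1)
        idx = np.unravel_index(flat, self.tile_shape, order="C")
        lo = np.asarray(idx) * self.tile_size
        return lo + rng.random(self.landscape.dimension) * self.tile_size

    @classmethod
    def from_text(cls, path: Union[str, Path], landscape: Landscape) -> "Raster":
        w = np.loadtxt(path, ndmin=2)
        if landscape.dimension == 1:
            w = w.ravel()
        return cls(w, landscape)

    def to_text(self, path: Union[str, Path]) -> None:
        np.savetxt(path, np.atleast_2d(self.weights), fmt="%.8g")


# ---------------------------------------------------------------------------
# Event kernels
# ---------------------------------------------------------------------------

#: the kernel may in principle depend on lineage state; the default ignores it
StateModifier = Callable[[object], float]


@dataclass(frozen=True)
class EventKernel:
    """Spatial event kernel E(x).

    family
        ``"disc"``: an event at center ``e`` affects each lineage within
        torus distance ``radius`` independently with probability
        ``impact``.  ``"gaussian"``: the per-lineage probability decays
        smoothly as ``impact * exp(-d^2 / (2 radius^2))`` (untruncated).
    radius
        Disc radius or Gaussian scale, in landscape units.
    impact
        Per-lineage selection probability at full kernel weight, in (0, 1].
    rate_density
        Events per unit time per unit area (``lambda``), multiplied
        locally by the heterogeneity raster if present.
    heterogeneity
        Optional :class:`Raster` scaling event intensity (not radius or
        impact).
    state_modifier
        Extension hook: multiplies the selection probability by a factor
        in [0, 1] depending on lineage state.  The default returns 1 for
        every state (state-independent kernels).
    """

    family: str
    radius: float
    impact: float
    rate_density: float
    heterogeneity: Optional[Raster] = None
    state_modifier: Optional[StateModifier] = None

    def __post_init__(self) -> None:
        if self.family not in ("disc", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if not 0 < self.impact <= 1:
            raise ValueError("impact u must lie in (0, 1]")
        if not self.rate_density > 0:
            raise ValueError("rate_density lambda must be > 0")

    def self_overlapping(self, landscape: Landscape) -> bool:
        """True when a disc of this radius wraps onto itself on the torus.

        The thinned event sampler requires a non-self-overlapping disc
        (so its area is exactly pi r^2 / 2r); larger radii are handled by
        the naive global sampler.
        """
        return self.radius >= min(landscape.extent) / 2.0

    def support_area(self, landscape: Landscape) -> float:
        """Area of the disc support on the torus (disc family only)."""
        if self.family != "disc":
            raise ValueError("support_area is defined for the disc family")
        if self.self_overlapping(landscape):
            raise ValueError(
                "disc self-overlaps on the torus; area is not pi r^2"
            )
        if landscape.dimension == 1:
            return 2.0 * self.radius
        return math.pi * self.radius ** 2


@dataclass(frozen=True)
class Event:
    """A single reproduction/movement event in backward time."""

    time: float
    center: np.ndarray
    kernel: EventKernel

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.atleast_1d(np.asarray(self.center, dtype=float))
        )
        if not self.time > 0:
            raise ValueError("event time must be strictly positive")


def selection_probability(
    kernel: EventKernel,
    center: np.ndarray,
    x: np.ndarray,
    landscape: Landscape,
    state: object = None,
) -> float:
    """Probability that a lineage at ``x`` is affected by an event at ``center``.

    Disc family: ``u`` inside the disc, 0 outside.  Gaussian family:
    ``u * exp(-d^2 / (2 r^2))`` with ``d`` the torus distance.
    """
    _, dist = torus_displacement(center, x, landscape)
    u = kernel.impact
    if kernel.state_modifier is not None:
        u = u * float(kernel.state_modifier(state))
    if kernel.family == "disc":
        p = u if dist <= kernel.radius else 0.0
    else:
        p = u * math.exp(-(dist * dist) / (2.0 * kernel.radius ** 2))
    return float(p)


def sample_event(
    landscape: Landscape,
    kernel: EventKernel,
    current_time: float,
    rng: np.random.Generator,
) -> Event:
    """Draw the next event of the space-time Poisson process.

    The waiting time is exponential with rate ``lambda * W`` where ``W``
    is the (heterogeneity-weighted) area of the landscape; the center is
    drawn with density proportional to the heterogeneity weights
    (uniform when the landscape is homogeneous).
    """
    if kernel.heterogeneity is not None:
        w = kernel.heterogeneity.total_weighted_area
        center = kernel.heterogeneity.sample_point(rng)
    else:
        w = landscape.area
        center = landscape.random_points(1, rng)[0]
    wait = rng.exponential(1.0 / (kernel.rate_density * w))
    return Event(time=current_time + wait, center=center, kernel=kernel)


# ---------------------------------------------------------------------------
# Config and sample-sheet IO
# ---------------------------------------------------------------------------

def save_config(
    path: Union[str, Path],
    landscape: Landscape,
    kernel: EventKernel,
    seed: Optional[int] = None,
    raster_path: Optional[str] = None,
) -> None:
    """Write a landscape/kernel configuration as a YAML key-value file."""
    cfg = {
        "dimension": landscape.dimension,
        "extents": list(landscape.extent),
        "family": kernel.family,
        "r": kernel.radius,
        "u": kernel.impact,
        "lambda": kernel.rate_density,
    }
    if raster_path is not None:
        cfg["raster"] = raster_path
    if seed is not None:
        cfg["seed"] = int(seed)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(
    path: Union[str, Path],
) -> tuple[Landscape, EventKernel, Optional[int]]:
    """Read a configuration written by :func:`save_config`.

    A relative ``raster`` path is resolved against the config file's
    directory.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    landscape = Landscape(int(cfg["dimension"]), tuple(cfg["extents"]))
    raster = None
    if cfg.get("raster"):
        rp = Path(cfg["raster"])
        if not rp.is_absolute():
            rp = path.parent / rp
        raster = Raster.from_text(rp, landscape)
    kernel = EventKernel(
        family=str(cfg["family"]),
        radius=float(cfg["r"]),
        impact=float(cfg["u"]),
        rate_density=float(cfg["lambda"]),
        heterogeneity=raster,
    )
    seed = cfg.get("seed")
    return landscape, kernel, None if seed is None else int(seed)


def write_sample_sheet(path: Union[str, Path], sample: Sequence[Individual]) -> None:
    """Tab-separated sheet with columns id, x (and y in 2D)."""
    dim = len(sample[0].location)
    cols = {"id": [ind.id for ind in sample]}
    cols["x"] = [float(ind.location[0]) for ind in sample]
    if dim == 2:
        cols["y"] = [float(ind.location[1]) for ind in sample]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: Union[str, Path]) -> list[Individual]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "x" not in df.columns:
        raise ValueError("sample sheet must have columns id, x[, y]")
    axes = ["x"] + (["y"] if "y" in df.columns else [])
    locs = df[axes].to_numpy(dtype=float)
    return individuals_from_array(df["id"].tolist(), locs)
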