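"""Backward-in-time spatial Lambda-Fleming-Viot event loop.

Starting from ``n`` sampled lineages at known locations, reproduction/
movement events are generated backward in time.  Each event has a center
and a kernel; every extant lineage is affected independently with the
kernel's selection probability at its location.  An event affecting one
lineage moves it (the lineage's location is resampled from the event's
replacement distribution); an event affecting two or more lineages
merges them into a single ancestor placed by the same replacement
distribution -- so the genealogy can contain multiple mergers.  The loop
runs until a single ancestor (the MRCA of the sample) remains, or until
an event budget is exhausted, in which case the partial genealogy is
returned with an explicit non-coalesced status.

Two exact samplers are provided:

* a *naive global* sampler that draws every event of the space-time
  Poisson process (most of which affect nobody) -- simple, supports both
  kernel families, both dimensions and heterogeneity rasters;
* a *thinned* sampler for the homogeneous 2-D disc kernel that proposes
  only candidate events capable of selecting at least one lineage and
  corrects the rate exactly, so the law of (waiting time, center,
  affected set | affected set nonempty) matches the naive sampler with
  empty events discarded.

``simulate_genealogy(..., method="auto")`` picks the thinned sampler
whenever it applies.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .landscape import (
    Event,
    EventKernel,
    Individual,
    Landscape,
    sample_event,
    selection_probability,
)

__all__ = [
    "LineageSet",
    "Genealogy",
    "select_affected",
    "replacement_location",
    "apply_event",
    "simulate_genealogy",
    "pair_tmrca_forward_dual",
    "write_genealogy",
    "read_genealogy",
]

_TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# Genealogy container
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A timed, spatially embedded (possibly multifurcating) genealogy.

    Nodes ``0 .. n_leaves-1`` are the sampled individuals at time 0;
    internal nodes follow in order of (strictly increasing) event time.
    ``parents[i] == -1`` marks a root.  A fully coalesced genealogy has
    exactly one root; when the event budget ran out first, ``coalesced``
    is False and several roots remain.
    """

    times: np.ndarray
    locations: np.ndarray
    parents: np.ndarray
    n_leaves: int
    leaf_ids: list[str]
    coalesced: bool
    n_candidate_events: int = 0
    merger_sizes: list[int] = field(default_factory=list)
    movements: Optional[list[tuple[float, int, np.ndarray]]] = None

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parents < 0)

    @property
    def root(self) -> int:
        roots = self.roots
        if len(roots) != 1:
            raise ValueError("genealogy is not coalesced; multiple roots remain")
        return int(roots[0])

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def children_of(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                ch[p].append(i)
        return ch

    def branch_lengths(self) -> np.ndarray:
        """Edge length above each node (0 for roots)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parents >= 0
        bl[has_parent] = (
            self.times[self.parents[has_parent]] - self.times[has_parent]
        )
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_descendants(self) -> list[np.ndarray]:
        """For every node, the sorted leaf indices below it (inclusive)."""
        sets: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i in range(self.n_leaves):
            sets[i].add(i)
        # internal nodes are stored in increasing time order, so a single
        # forward pass propagates leaf sets rootward
        order = np.argsort(self.times, kind="stable")
        for i in order:
            p = self.parents[i]
            if p >= 0:
                sets[p] |= sets[i]
        return [np.array(sorted(s), dtype=int) for s in sets]

    def to_dendropy(self) -> dendropy.Tree:
        if not self.coalesced:
            raise ValueError("cannot export a non-coalesced genealogy as one tree")
        taxa = dendropy.TaxonNamespace(self.leaf_ids)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for i in range(self.n_nodes):
            nd = dendropy.Node()
            if i < self.n_leaves:
                nd.taxon = taxa.get_taxon(self.leaf_ids[i])
            else:
                nd.label = f"n{i}"
            nodes[i] = nd
        bl = self.branch_lengths()
        for i, p in enumerate(self.parents):
            if p >= 0:
                nodes[p].add_child(nodes[i])
                nodes[i].edge.length = float(bl[i])
        tree.seed_node = nodes[self.root]
        return tree

    def node_table(self) -> pd.DataFrame:
        names = [
            self.leaf_ids[i] if i < self.n_leaves else f"n{i}"
            for i in range(self.n_nodes)
        ]
        cols = {"node": names, "time": self.times}
        cols["x"] = self.locations[:, 0]
        if self.locations.shape[1] == 2:
            cols["y"] = self.locations[:, 1]
        return pd.DataFrame(cols)


class _GenealogyBuilder:
    """Accumulates nodes while a simulation runs."""

    def __init__(self, sample: Sequence[Individual], record_movements: bool):
        self.times: list[float] = [0.0] * len(sample)
        self.locations: list[np.ndarray] = [
            np.array(ind.location, dtype=float) for ind in sample
        ]
        self.parents: list[int] = [-1] * len(sample)
        self.leaf_ids = [ind.id for ind in sample]
        self.n_leaves = len(sample)
        self.merger_sizes: list[int] = []
        self.movements: Optional[list] = [] if record_movements else None

    def add_merger(
        self, time: float, location: np.ndarray, children: Sequence[int]
    ) -> int:
        nid = len(self.times)
        self.times.append(float(time))
        self.locations.append(np.asarray(location, dtype=float))
        self.parents.append(-1)
        for c in children:
            self.parents[c] = nid
        self.merger_sizes.append(len(children))
        return nid

    def note_movement(self, time: float, node: int, location: np.ndarray) -> None:
        if self.movements is not None:
            self.movements.append((float(time), int(node), np.asarray(location)))

    def finish(self, coalesced: bool, n_candidate_events: int) -> Genealogy:
        return Genealogy(
            times=np.asarray(self.times),
            locations=np.vstack(self.locations),
            parents=np.asarray(self.parents, dtype=int),
            n_leaves=self.n_leaves,
            leaf_ids=list(self.leaf_ids),
            coalesced=coalesced,
            n_candidate_events=n_candidate_events,
            merger_sizes=list(self.merger_sizes),
            movements=self.movements,
        )


# ---------------------------------------------------------------------------
# Lineage set and per-event operations
# ---------------------------------------------------------------------------

@dataclass
class LineageSet:
    """The extant ancestral lineages C(t) at backward time ``clock``."""

    locations: np.ndarray            # (k, dim)
    node_ids: list[int]              # genealogy node index of each lineage
    landscape: Landscape
    clock: float = 0.0
    states: Optional[list[object]] = None

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        if len(self.node_ids) != len(self.locations):
            raise ValueError("node_ids and locations length mismatch")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("lineage ids must be unique")
        if len(self.node_ids) < 1:
            raise ValueError("a lineage set holds at least one lineage")
        for loc in self.locations:
            self.landscape.require_inside(loc, "lineage location")

    @classmethod
    def from_sample(cls, sample: Sequence[Individual], landscape: Landscape) -> "LineageSet":
        locs = np.vstack([ind.location for ind in sample])
        return cls(locations=locs, node_ids=list(range(len(sample))),
                   landscape=landscape,
                   states=[ind.state for ind in sample])

    @property
    def size(self) -> int:
        return len(self.node_ids)


def select_affected(
    C: LineageSet, event: Event, rng: np.random.Generator
) -> np.ndarray:
    """Indices of lineages affected by ``event``.

    Every lineage is included independently with the kernel's selection
    probability at its location; the result may be empty.
    """
    probs = np.array(
        [
            selection_probability(
                event.kernel, event.center, loc, C.landscape,
                state=None if C.states is None else C.states[i],
            )
            for i, loc in enumerate(C.locations)
        ]
    )
    return np.flatnonzero(rng.random(C.size) < probs)


def replacement_location(
    kernel: EventKernel,
    center: np.ndarray,
    landscape: Landscape,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from the replacement distribution R(x|C') of an event.

    Disc kernel: uniform over the disc of radius ``r`` around the event
    center; Gaussian kernel: Gaussian of scale ``r`` around the center.
    Both are wrapped onto the torus.
    """
    dim = landscape.dimension
    if kernel.family == "disc":
        if dim == 1:
            off = (2.0 * rng.random() - 1.0) * kernel.radius
            new = np.array([center[0] + off])
        else:
            rho = kernel.radius * math.sqrt(rng.random())
            th = _TWO_PI * rng.random()
            new = center + rho * np.array([math.cos(th), math.sin(th)])
    else:
        new = center + rng.normal(0.0, kernel.radius, size=dim)
    return landscape.wrap(new)


def apply_event(
    C: LineageSet,
    affected: np.ndarray,
    event: Event,
    builder: _GenealogyBuilder,
    rng: np.random.Generator,
) -> LineageSet:
    """Apply one event to the lineage set, recording any merger.

    * no affected lineage: C unchanged;
    * one affected lineage: pure movement -- its location is resampled
      from the replacement distribution;
    * two or more: a single ancestor is created at a replacement-drawn
      location and becomes the parent of all affected lineages.
    """
    affected = np.asarray(affected, dtype=int)
    if np.any(affected < 0) or np.any(affected >= C.size):
        raise ValueError("affected set is not a subset of the lineage set")
    if len(set(affected.tolist())) != len(affected):
        raise ValueError("affected set contains duplicates")
    C.clock = float(event.time)
    if len(affected) == 0:
        return C
    new_loc = replacement_location(event.kernel, event.center, C.landscape, rng)
    if len(affected) == 1:
        i = int(affected[0])
        C.locations[i] = new_loc
        builder.note_movement(event.time, C.node_ids[i], new_loc)
        return C
    children = [C.node_ids[int(i)] for i in affected]
    nid = builder.add_merger(event.time, new_loc, children)
    keep = np.setdiff1d(np.arange(C.size), affected)
    C.locations = np.vstack([C.locations[keep], new_loc[None, :]])
    C.node_ids = [C.node_ids[int(i)] for i in keep] + [nid]
    if C.states is not None:
        C.states = [C.states[int(i)] for i in keep] + [None]
    return C


# ---------------------------------------------------------------------------
# Naive global sampler
# ---------------------------------------------------------------------------

def _simulate_global(
    sample: Sequence[Individual],
    landscape: Landscape,
    kernel: EventKernel,
    rng: np.random.Generator,
    max_events: int,
    record_movements: bool,
) -> Genealogy:
    builder = _GenealogyBuilder(sample, record_movements)
    C = LineageSet.from_sample(sample, landscape)
    C.states = None  # neutral loop: states play no role in the core kernels
    ev = 0
    while C.size > 1 and ev < max_events:
        ev += 1
        event = sample_event(landscape, kernel, C.clock, rng)
        affected = select_affected(C, event, rng)
        C = apply_event(C, affected, event, builder, rng)
    return builder.finish(coalesced=C.size == 1, n_candidate_events=ev)


# ---------------------------------------------------------------------------
# Thinned sampler (homogeneous 2-D disc kernel)
# ---------------------------------------------------------------------------

def _simulate_thinned_disc_2d(
    sample: Sequence[Individual],
    landscape: Landscape,
    kernel: EventKernel,
    rng: np.random.Generator,
    max_events: int,
    record_movements: bool,
) -> Genealogy:
    """Exact accelerated sampler for the homogeneous disc kernel in 2D.

    Candidate events are proposed at rate ``lambda * u * k * pi r^2``
    with centers uniform on the (multiplicity-weighted) union of the
    lineage-centered discs; a candidate whose disc holds ``m`` lineages
    is accepted with probability ``(1 - (1-u)^m) / (u m)``, which makes
    accepted events a Poisson process with intensity equal to the naive
    rate of events affecting at least one lineage.  Given acceptance,
    the affected count is Binomial(m, u) conditioned on being >= 1.
    Waiting times accumulate over rejected proposals, so elapsed time is
    distributed exactly as under naive global sampling.
    """
    if kernel.self_overlapping(landscape):
        raise ValueError("thinned sampler requires radius < min(extent)/2")
    builder = _GenealogyBuilder(sample, record_movements)
    n = len(sample)
    Lx, Ly = landscape.extent
    hx, hy = Lx / 2.0, Ly / 2.0
    r = kernel.radius
    rr = r * r
    u = kernel.impact
    one_mu = 1.0 - u
    disc_area = math.pi * rr
    lam = kernel.rate_density

    # hot loop state as plain Python floats/lists; RNG is a Python
    # Mersenne stream seeded from the caller's generator (documented in
    # the methods note) -- determinism is preserved per seed
    prand = _pyrandom.Random(int(rng.integers(0, 2**63)))
    rnd = prand.random
    ax = [float(ind.location[0]) for ind in sample]
    ay = [float(ind.location[1]) for ind in sample]
    node = list(range(n))
    k = n
    t = 0.0
    ev = 0
    while k > 1 and ev < max_events:
        ev += 1
        t += prand.expovariate(lam * u * k * disc_area)
        j = int(rnd() * k)
        rho = r * math.sqrt(rnd())
        th = _TWO_PI * rnd()
        cx = (ax[j] + rho * math.cos(th)) % Lx
        cy = (ay[j] + rho * math.sin(th)) % Ly
        within = []
        for i in range(k):
            dx = ax[i] - cx
            if dx < 0.0:
                dx = -dx
            if dx > hx:
                dx = Lx - dx
            if dx > r:
                continue
            dy = ay[i] - cy
            if dy < 0.0:
                dy = -dy
            if dy > hy:
                dy = Ly - dy
            if dx * dx + dy * dy <= rr:
                within.append(i)
        m = len(within)
        if m > 1:
            if u >= 1.0:
                if rnd() * m > 1.0:
                    continue
                chosen = within
            else:
                if rnd() * (u * m) > 1.0 - one_mu ** m:
                    continue
                # |C'| ~ Binomial(m, u) conditioned on >= 1, by inverse CDF
                target = rnd() * (1.0 - one_mu ** m)
                c = 1
                w = m * u * one_mu ** (m - 1)
                acc = w
                while acc < target and c < m:
                    w *= (m - c) * u / ((c + 1) * one_mu)
                    c += 1
                    acc += w
                chosen = within if c == m else prand.sample(within, c)
        else:
            chosen = within
        # replacement location, uniform in the event disc
        rho = r * math.sqrt(rnd())
        th = _TWO_PI * rnd()
        nx = (cx + rho * math.cos(th)) % Lx
        ny = (cy + rho * math.sin(th)) % Ly
        if len(chosen) == 1:
            i = chosen[0]
            ax[i] = nx
            ay[i] = ny
            builder.note_movement(t, node[i], np.array([nx, ny]))
        else:
            nid = builder.add_merger(t, np.array([nx, ny]),
                                     [node[i] for i in chosen])
            for i in sorted(chosen, reverse=True):
                ax.pop(i)
                ay.pop(i)
                node.pop(i)
            ax.append(nx)
            ay.append(ny)
            node.append(nid)
            k -= len(chosen) - 1
    return builder.finish(coalesced=k == 1, n_candidate_events=ev)


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def simulate_genealogy(
    sample: Sequence[Individual],
    landscape: Landscape,
    kernel: EventKernel,
    rng: np.random.Generator,
    max_events: int = 10_000_000,
    method: str = "auto",
    record_movements: bool = False,
) -> Genealogy:
    """Simulate the genealogy of ``sample`` under the SLFV process.

    ``method`` is ``"auto"`` (thinned sampler when it applies, else the
    naive global sampler), ``"thinned"`` or ``"global"``.  When
    ``max_events`` candidate events are exhausted before the MRCA is
    reached the partial genealogy is returned with ``coalesced=False``.
    """
    if len(sample) < 1:
        raise ValueError("need at least one sampled individual")
    ids = [ind.id for ind in sample]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    for ind in sample:
        landscape.require_inside(ind.location, f"sample {ind.id}")
    if len(sample) == 1:
        b = _GenealogyBuilder(sample, record_movements)
        return b.finish(coalesced=True, n_candidate_events=0)
    thinnable = (
        kernel.family == "disc"
        and landscape.dimension == 2
        and kernel.heterogeneity is None
        and kernel.state_modifier is None
        and not kernel.self_overlapping(landscape)
    )
    if method == "auto":
        method = "thinned" if thinnable else "global"
    if method == "thinned":
        if not thinnable:
            raise ValueError(
                "thinned sampler requires a homogeneous 2-D disc kernel "
                "with radius < min(extent)/2"
            )
        return _simulate_thinned_disc_2d(
            sample, landscape, kernel, rng, max_events, record_movements
        )
    if method != "global":
        raise ValueError(f"unknown method {method!r}")
    return _simulate_global(
        sample, landscape, kernel, rng, max_events, record_movements
    )


# ---------------------------------------------------------------------------
# Forward-in-time dual (independent cross-check)
# ---------------------------------------------------------------------------

def pair_tmrca_forward_dual(
    x1: np.ndarray,
    x2: np.ndarray,
    landscape: Landscape,
    kernel: EventKernel,
    rng: np.random.Generator,
    max_events: int = 10_000_000,
) -> float:
    """Coalescence time of two tagged lineages under a Moran-type event
    process, simulated naively and independently of the main event loop.

    Events fall uniformly on the torus at rate ``lambda * area``; each
    tagged lineage inside the event disc is replaced with probability
    ``u`` and takes a uniform position in the disc; when both are
    replaced by the same event they have found their common ancestor.
    Used as a validation oracle for the backward sampler.  Returns
    ``inf`` if the budget runs out first.
    """
    if kernel.family != "disc":
        raise ValueError("the forward dual is defined for the disc kernel")
    Ls = np.asarray(landscape.extent)
    dim = landscape.dimension
    r = kernel.radius
    u = kernel.impact
    lam_total = kernel.rate_density * landscape.area
    p1 = np.asarray(x1, dtype=float).copy()
    p2 = np.asarray(x2, dtype=float).copy()
    t = 0.0
    for _ in range(max_events):
        t += rng.exponential(1.0 / lam_total)
        center = rng.random(dim) * Ls
        d1 = (p1 - center + 0.5 * Ls) % Ls - 0.5 * Ls
        d2 = (p2 - center + 0.5 * Ls) % Ls - 0.5 * Ls
        hit1 = float(d1 @ d1) <= r * r and rng.random() < u
        hit2 = float(d2 @ d2) <= r * r and rng.random() < u
        if hit1 and hit2:
            return t
        if hit1 or hit2:
            if dim == 1:
                new = center + (2.0 * rng.random(1) - 1.0) * r
            else:
                rho = r * math.sqrt(rng.random())
                th = _TWO_PI * rng.random()
                new = center + rho * np.array([math.cos(th), math.sin(th)])
            new = np.mod(new, Ls)
            if hit1:
                p1 = new
            else:
                p2 = new
    return math.inf


# ---------------------------------------------------------------------------
# Genealogy IO: Newick + node table
# ---------------------------------------------------------------------------

def write_genealogy(genealogy: Genealogy, prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Write ``<prefix>.nwk`` (Newick, multifurcations allowed) and
    ``<prefix>.nodes.tsv`` (node, time, x[, y])."""
    prefix = Path(prefix)
    nwk = prefix.with_suffix(prefix.suffix + ".nwk")
    tsv = prefix.with_suffix(prefix.suffix + ".nodes.tsv")
    tree = genealogy.to_dendropy()
    tree.write(
        path=str(nwk),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    genealogy.node_table().to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    return nwk, tsv


def read_genealogy(prefix: Union[str, Path]) -> Genealogy:
    """Read the pair written by :func:`write_genealogy`."""
    prefix = Path(prefix)
    nwk = prefix.with_suffix(prefix.suffix + ".nwk")
    tsv = prefix.with_suffix(prefix.suffix + ".nodes.tsv")
    tree = dendropy.Tree.get(
        path=str(nwk), schema="newick", preserve_underscores=True
    )
    table = pd.read_csv(tsv, sep="\t", dtype={"node": str})
    axes = ["x"] + (["y"] if "y" in table.columns else [])
    info = {
        row["node"]: (float(row["time"]), np.array([row[a] for a in axes]))
        for _, row in table.iterrows()
    }
    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    # node table preserves simulation order: leaves first, then internal
    # nodes by increasing time
    names_in_order = table["node"].tolist()
    leaf_ids = [nm for nm in names_in_order if nm in set(leaf_names)]
    internal = [nm for nm in names_in_order if nm not in set(leaf_names)]
    index = {nm: i for i, nm in enumerate(leaf_ids + internal)}
    n_total = len(index)
    times = np.zeros(n_total)
    locs = np.zeros((n_total, len(axes)))
    parents = np.full(n_total, -1, dtype=int)
    for nm, (tt, xy) in info.items():
        times[index[nm]] = tt
        locs[index[nm]] = xy
    for nd in tree.preorder_node_iter():
        nm = nd.taxon.label if nd.taxon is not None else nd.label
        if nd.parent_node is not None:
            pnm = (
                nd.parent_node.taxon.label
                if nd.parent_node.taxon is not None
                else nd.parent_node.label
            )
            parents[index[nm]] = index[pnm]
    return Genealogy(
        times=times,
        locations=locs,
        parents=parents,
        n_leaves=len(leaf_ids),
        leaf_ids=leaf_ids,
        coalesced=True,
    )
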