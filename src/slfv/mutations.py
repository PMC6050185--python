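"""Neutral mutation overlays on SLFV genealogies.

Mutation is decoupled from the spatial event loop: a genealogy is
simulated first, then sequences are dropped down it.  This is exact for
neutral, state-independent kernels.  Two models:

* infinite sites -- each branch receives Poisson(mu * L * length)
  mutations, each at a fresh site, producing a 0/1 haplotype matrix over
  the segregating sites;
* Kimura 2-parameter (K2P) -- the root sequence is uniform over
  {A,C,G,T} per site and every site evolves independently along each
  branch under the K2P substitution process.

Rate convention: ``mu`` is the total expected number of substitutions
per site per unit of (model) time; ``kappa`` is the transition /
transversion *rate* ratio (kappa = 1 recovers Jukes-Cantor).  Loci are
unlinked: each locus gets its own independent genealogy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .landscape import EventKernel, Individual, Landscape
from .simulator import Genealogy, simulate_genealogy

__all__ = [
    "MutationConfig",
    "LocusAlignment",
    "k2p_transition_matrix",
    "overlay_mutations",
    "simulate_dataset",
    "write_fasta",
    "read_fasta",
    "write_sites_matrix",
    "read_sites_matrix",
]

BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# base order A, C, G, T: transitions are A<->G and C<->T
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


@dataclass(frozen=True)
class MutationConfig:
    """Mutation parameters for one dataset.

    model: ``"infinite-sites"`` or ``"K2P"``; mu: substitutions per site
    per unit time; kappa: transition/transversion rate ratio (K2P);
    seq_length: sites per locus; n_loci: number of independent loci.
    """

    model: str
    mu: float
    seq_length: int = 1000
    n_loci: int = 1
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.model not in ("infinite-sites", "K2P"):
            raise ValueError(f"unknown mutation model {self.model!r}")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.seq_length < 1 or self.n_loci < 1:
            raise ValueError("seq_length and n_loci must be >= 1")


@dataclass
class LocusAlignment:
    """Sequences for one locus, keyed to genealogy leaves.

    ``data`` is an integer matrix, one row per individual: base indices
    into ``ACGT`` for nucleotide alignments, or 0/1 for infinite-sites
    haplotypes (one column per segregating site).
    """

    ids: list[str]
    data: np.ndarray
    alphabet: str            # "nucleotide" | "binary"
    locus_id: str = "locus"
    seq_length: Optional[int] = None   # nominal locus length (infinite sites)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if len(self.ids) != self.data.shape[0]:
            raise ValueError("one sequence per individual id required")
        if self.alphabet not in ("nucleotide", "binary"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequences(self) -> list[str]:
        if self.alphabet == "nucleotide":
            return ["".join(BASES[row]) for row in self.data]
        return ["".join("01"[v] for v in row) for row in self.data]

    def segregating_sites(self) -> int:
        if self.n_sites == 0:
            return 0
        return int((self.data.min(axis=0) != self.data.max(axis=0)).sum())


# ---------------------------------------------------------------------------
# K2P transition probabilities
# ---------------------------------------------------------------------------

def k2p_transition_matrix(t: float, mu: float, kappa: float) -> np.ndarray:
    """4x4 substitution probability matrix of the K2P model after time ``t``.

    The rate matrix has transition rate ``alpha = kappa * beta`` and
    transversion rate ``beta``, normalized so the total substitution
    rate per site is ``mu = alpha + 2 beta``.  Base order is A, C, G, T.
    """
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    if mu < 0 or kappa <= 0:
        raise ValueError("mu must be >= 0 and kappa > 0")
    beta = mu / (kappa + 2.0)
    alpha = kappa * beta
    e4 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    for i, j in enumerate(_TRANSITION_PARTNER):
        P[i, j] = p_ts
    return P


def _evolve_sites(
    parent_seq: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw child base per site given parent bases and a transition matrix."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_seq.shape[0])
    return (u[:, None] > cum[parent_seq]).sum(axis=1).astype(np.int8)


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

def overlay_mutations(
    genealogy: Genealogy,
    config: MutationConfig,
    rng: np.random.Generator,
    locus_id: str = "locus",
) -> LocusAlignment:
    """Drop mutations along a coalesced genealogy, returning one locus."""
    if not genealogy.coalesced:
        raise ValueError("cannot overlay mutations on a non-coalesced genealogy")
    if config.model == "K2P":
        return _overlay_k2p(genealogy, config, rng, locus_id)
    return _overlay_infinite_sites(genealogy, config, rng, locus_id)


def _overlay_k2p(
    genealogy: Genealogy, config: MutationConfig, rng: np.random.Generator,
    locus_id: str,
) -> LocusAlignment:
    L = config.seq_length
    bl = genealogy.branch_lengths()
    seqs: dict[int, np.ndarray] = {}
    root = genealogy.root
    seqs[root] = rng.integers(0, 4, size=L).astype(np.int8)
    # parents precede children when walking nodes by decreasing time
    order = np.argsort(-genealogy.times, kind="stable")
    for i in order:
        if int(i) == root:
            continue
        p = int(genealogy.parents[i])
        P = k2p_transition_matrix(float(bl[i]), config.mu, config.kappa)
        seqs[int(i)] = _evolve_sites(seqs[p], P, rng)
    data = np.vstack([seqs[i] for i in range(genealogy.n_leaves)])
    return LocusAlignment(
        ids=list(genealogy.leaf_ids), data=data, alphabet="nucleotide",
        locus_id=locus_id, seq_length=L,
    )


def _overlay_infinite_sites(
    genealogy: Genealogy, config: MutationConfig, rng: np.random.Generator,
    locus_id: str,
) -> LocusAlignment:
    L = config.seq_length
    bl = genealogy.branch_lengths()
    counts = rng.poisson(config.mu * L * bl)
    counts[genealogy.roots] = 0
    n_sites = int(counts.sum())
    n = genealogy.n_leaves
    data = np.zeros((n, n_sites), dtype=np.int8)
    if n_sites:
        below = genealogy.leaf_descendants()
        col = 0
        for node in range(genealogy.n_nodes):
            for _ in range(int(counts[node])):
                data[below[node], col] = 1
                col += 1
    return LocusAlignment(
        ids=list(genealogy.leaf_ids), data=data, alphabet="binary",
        locus_id=locus_id, seq_length=L,
    )


def simulate_dataset(
    sample: Sequence[Individual],
    landscape: Landscape,
    kernel: EventKernel,
    config: MutationConfig,
    rng: np.random.Generator,
    max_events: int = 10_000_000,
    method: str = "auto",
    return_genealogies: bool = False,
):
    """Simulate ``config.n_loci`` unlinked loci: one independent genealogy
    per locus, with mutations overlaid on each.

    Raises ``RuntimeError`` if any locus fails to coalesce within
    ``max_events`` -- callers that can redraw (e.g. the ABC reference
    table builder) catch this and log the redraw.
    """
    alignments: list[LocusAlignment] = []
    genealogies: list[Genealogy] = []
    for locus in range(config.n_loci):
        g = simulate_genealogy(
            sample, landscape, kernel, rng, max_events=max_events, method=method
        )
        if not g.coalesced:
            raise RuntimeError(
                f"locus {locus}: genealogy did not coalesce within "
                f"{max_events} candidate events"
            )
        alignments.append(
            overlay_mutations(g, config, rng, locus_id=f"locus_{locus}")
        )
        genealogies.append(g)
    if return_genealogies:
        return alignments, genealogies
    return alignments


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_fasta(alignment: LocusAlignment, path: Union[str, Path]) -> None:
    """FASTA, 80-column wrapped, record ids = individual ids."""
    records = [
        SeqRecord(Seq(seq), id=ind, description="")
        for ind, seq in zip(alignment.ids, alignment.sequences())
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)


def read_fasta(path: Union[str, Path], locus_id: str = "locus") -> LocusAlignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        s = str(rec.seq).upper()
        if set(s) <= {"0", "1"}:
            rows.append([int(c) for c in s])
            alphabet = "binary"
        else:
            rows.append([_BASE_INDEX[c] for c in s])
            alphabet = "nucleotide"
    if not ids:
        raise ValueError(f"no records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    return LocusAlignment(
        ids=ids, data=np.array(rows, dtype=np.int8), alphabet=alphabet,
        locus_id=locus_id,
    )


def write_sites_matrix(alignment: LocusAlignment, path: Union[str, Path]) -> None:
    """Tab-separated 0/1 site matrix (infinite-sites output)."""
    if alignment.alphabet != "binary":
        raise ValueError("site matrix output is for binary haplotypes")
    with open(path, "w") as fh:
        sites = alignment.n_sites
        fh.write("id\t" + "\t".join(f"s{i}" for i in range(sites)) + "\n")
        for ind, row in zip(alignment.ids, alignment.data):
            fh.write(ind + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_sites_matrix(path: Union[str, Path], locus_id: str = "locus") -> LocusAlignment:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    data = df.drop(columns=["id"]).to_numpy(dtype=np.int8)
    return LocusAlignment(
        ids=df["id"].tolist(), data=data, alphabet="binary", locus_id=locus_id
    )
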