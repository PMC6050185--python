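"""The backward-in-time SLFV event loop."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import slfv
from slfv import (
    Event,
    EventKernel,
    Landscape,
    LineageSet,
    apply_event,
    individuals_from_array,
    select_affected,
    simulate_genealogy,
)
from slfv.simulator import _GenealogyBuilder


def _pair(unit_torus, d):
    locs = np.array([[0.5, 0.5], [(0.5 + d) % 1.0, 0.5]])
    return individuals_from_array(["a", "b"], locs)


class TestSelectAffected:
    def test_empty_when_all_outside_disc(self, unit_torus, rng):
        k = EventKernel("disc", radius=0.05, impact=1.0, rate_density=1.0)
        C = LineageSet(
            locations=np.array([[0.9, 0.9], [0.8, 0.1]]),
            node_ids=[0, 1], landscape=unit_torus,
        )
        ev = Event(time=1.0, center=np.array([0.4, 0.4]), kernel=k)
        assert len(select_affected(C, ev, rng)) == 0

    def test_certain_selection_at_center_with_full_impact(self, unit_torus, rng):
        k = EventKernel("disc", radius=0.1, impact=1.0, rate_density=1.0)
        C = LineageSet(
            locations=np.tile([0.4, 0.4], (5, 1)),
            node_ids=list(range(5)), landscape=unit_torus,
        )
        ev = Event(time=1.0, center=np.array([0.4, 0.4]), kernel=k)
        assert len(select_affected(C, ev, rng)) == 5

    def test_selection_count_within_binomial_bounds(self, unit_torus, rng):
        n, u = 1000, 0.5
        k = EventKernel("disc", radius=0.2, impact=u, rate_density=1.0)
        C = LineageSet(
            locations=np.tile([0.5, 0.5], (n, 1)),
            node_ids=list(range(n)), landscape=unit_torus,
        )
        ev = Event(time=1.0, center=np.array([0.5, 0.5]), kernel=k)
        got = len(select_affected(C, ev, rng))
        # 99.9% two-sided binomial bounds
        half = 3.29 * math.sqrt(n * u * (1 - u))
        assert abs(got - n * u) < half


class TestApplyEvent:
    def _setup(self, unit_torus):
        sample = individuals_from_array(
            ["a", "b", "c", "d"],
            np.array([[0.5, 0.5], [0.52, 0.5], [0.48, 0.5], [0.9, 0.9]]),
        )
        builder = _GenealogyBuilder(sample, record_movements=False)
        C = LineageSet.from_sample(sample, unit_torus)
        return C, builder

    def test_empty_set_changes_nothing(self, unit_torus, disc_kernel, rng):
        C, builder = self._setup(unit_torus)
        before = C.locations.copy()
        ev = Event(time=1.0, center=np.array([0.5, 0.5]), kernel=disc_kernel)
        C = apply_event(C, np.array([], dtype=int), ev, builder, rng)
        assert C.size == 4
        np.testing.assert_array_equal(C.locations, before)
        assert len(builder.merger_sizes) == 0

    def test_triple_merger_creates_one_parent(self, unit_torus, disc_kernel, rng):
        C, builder = self._setup(unit_torus)
        ev = Event(time=1.0, center=np.array([0.5, 0.5]), kernel=disc_kernel)
        C = apply_event(C, np.array([0, 1, 2]), ev, builder, rng)
        assert C.size == 2
        assert builder.merger_sizes == [3]
        g = builder.finish(coalesced=False, n_candidate_events=1)
        assert list(g.parents[:3]) == [4, 4, 4]

    def test_single_lineage_moves_within_disc(self, unit_torus, disc_kernel, rng):
        C, builder = self._setup(unit_torus)
        center = np.array([0.5, 0.5])
        ev = Event(time=1.0, center=center, kernel=disc_kernel)
        C = apply_event(C, np.array([1]), ev, builder, rng)
        assert C.size == 4
        assert unit_torus.distance(C.locations[1], center) <= disc_kernel.radius

    def test_rejects_out_of_range_subset(self, unit_torus, disc_kernel, rng):
        C, builder = self._setup(unit_torus)
        ev = Event(time=1.0, center=np.array([0.5, 0.5]), kernel=disc_kernel)
        with pytest.raises(ValueError):
            apply_event(C, np.array([0, 7]), ev, builder, rng)


class TestSimulateGenealogy:
    def test_single_individual_is_trivial(self, unit_torus, disc_kernel, rng):
        sample = individuals_from_array(["only"], np.array([[0.5, 0.5]]))
        g = simulate_genealogy(sample, unit_torus, disc_kernel, rng)
        assert g.coalesced and g.n_nodes == 1 and len(g.merger_sizes) == 0

    def test_torus_covering_events_coalesce_pair_exponentially(self, unit_torus, rng):
        # u = 1 with events spanning the torus: the pair coalesces at the
        # very first event, so TMRCA ~ Exponential(lambda * area)
        lam = 3.0
        k = EventKernel("disc", radius=1.0, impact=1.0, rate_density=lam)
        sample = _pair(unit_torus, 0.4)
        times = np.array(
            [
                simulate_genealogy(sample, unit_torus, k, rng).tmrca
                for _ in range(1500)
            ]
        )
        res = stats.kstest(times, "expon", args=(0, 1.0 / (lam * unit_torus.area)))
        assert res.pvalue > 0.01

    def test_mean_tmrca_increases_with_pair_separation(self, unit_torus, rng):
        k = EventKernel("disc", radius=0.1, impact=1.0, rate_density=1.0)
        means = []
        for d in (0.0, 0.4):
            times = [
                simulate_genealogy(_pair(unit_torus, d), unit_torus, k, rng).tmrca
                for _ in range(800)
            ]
            means.append(np.mean(times))
        assert means[0] < means[1]

    def test_non_coalescence_is_flagged_not_silent(self, unit_torus, rng):
        k = EventKernel("disc", radius=0.02, impact=0.05, rate_density=1.0)
        sample = individuals_from_array(
            ["a", "b", "c"], np.array([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]])
        )
        g = simulate_genealogy(sample, unit_torus, k, rng, max_events=50)
        assert not g.coalesced
        assert len(g.roots) > 1
        with pytest.raises(ValueError):
            _ = g.root

    def test_one_dimensional_landscape_coalesces(self, line_torus, rng):
        k = EventKernel("disc", radius=0.2, impact=0.8, rate_density=1.0)
        sample = individuals_from_array(
            ["a", "b", "c"], np.array([[0.1], [0.5], [0.9]])
        )
        g = simulate_genealogy(sample, line_torus, k, rng)
        assert g.coalesced
        assert np.all((g.locations >= 0) & (g.locations < 1))
        assert g.locations.shape[1] == 1

    def test_gaussian_kernel_coalesces_globally(self, unit_torus, rng):
        k = EventKernel("gaussian", radius=0.15, impact=0.8, rate_density=1.0)
        sample = _pair(unit_torus, 0.3)
        g = simulate_genealogy(sample, unit_torus, k, rng)
        assert g.coalesced and len(g.merger_sizes) == 1

    def test_thinned_method_rejected_for_unsupported_kernel(
        self, unit_torus, gaussian_kernel, rng
    ):
        sample = _pair(unit_torus, 0.2)
        with pytest.raises(ValueError):
            simulate_genealogy(
                sample, unit_torus, gaussian_kernel, rng, method="thinned"
            )


class TestStructuralInvariants:
    def _run(self, rng, n=6, method="auto"):
        landscape = Landscape(2, (1.0, 1.0))
        k = EventKernel("disc", radius=0.2, impact=0.7, rate_density=1.0)
        sample = individuals_from_array(
            [f"i{j}" for j in range(n)], landscape.random_points(n, rng)
        )
        return (
            simulate_genealogy(sample, landscape, k, rng, method=method),
            landscape,
            k,
        )

    @pytest.mark.parametrize("method", ["thinned", "global"])
    def test_lineage_count_decreases_only_at_mergers(self, rng, method):
        g, _, _ = self._run(rng, method=method)
        n_internal = g.n_nodes - g.n_leaves
        assert len(g.merger_sizes) == n_internal
        # each merger of size m removes m-1 lineages; full coalescence
        # removes n-1 in total
        assert sum(m - 1 for m in g.merger_sizes) == g.n_leaves - 1
        assert all(m >= 2 for m in g.merger_sizes)

    @pytest.mark.parametrize("method", ["thinned", "global"])
    def test_node_times_increase_rootward(self, rng, method):
        g, _, _ = self._run(rng, method=method)
        has_parent = g.parents >= 0
        assert np.all(
            g.times[g.parents[has_parent]] > g.times[has_parent] - 1e-12
        )
        assert (g.parents < 0).sum() == 1

    def test_node_locations_inside_landscape(self, rng):
        g, landscape, _ = self._run(rng)
        assert landscape.contains(g.locations)

    def test_exchangeability_of_colocated_leaves(self, rng):
        # four co-located leaves: with torus-spanning events the first
        # merger treats all leaf subsets of a given size symmetrically
        landscape = Landscape(2, (1.0, 1.0))
        k = EventKernel("disc", radius=1.0, impact=0.5, rate_density=1.0)
        sample = individuals_from_array(
            ["a", "b", "c", "d"], np.tile([0.5, 0.5], (4, 1))
        )
        pair_counts = Counter()
        n_rep = 5000
        for _ in range(n_rep):
            g = simulate_genealogy(sample, landscape, k, rng)
            first = int(np.argmin(g.times[4:]) + 4)
            children = tuple(sorted(np.flatnonzero(g.parents == first)))
            if len(children) == 2:
                pair_counts[children] += 1
        pairs = list(itertools.combinations(range(4), 2))
        counts = np.array([pair_counts[p] for p in pairs])
        expected = counts.sum() / 6.0
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=5)

    def test_merger_nodes_lie_within_creating_event_support(self, rng):
        # every internal node must sit within radius r of some point that
        # also covers all its children at merge time; weaker necessary
        # condition checked: node within 2r (torus) of every child's
        # last known position is not recorded, so check the replacement
        # support indirectly via movement records
        landscape = Landscape(2, (1.0, 1.0))
        k = EventKernel("disc", radius=0.15, impact=0.9, rate_density=1.0)
        sample = individuals_from_array(
            [f"i{j}" for j in range(5)], landscape.random_points(5, rng)
        )
        g = simulate_genealogy(
            sample, landscape, k, rng, record_movements=True
        )
        # reconstruct each lineage's location just before its merger
        last_loc = {i: g.locations[i] for i in range(g.n_leaves)}
        moves = sorted(g.movements, key=lambda m: m[0])
        events = []  # (time, node, kind)
        for t, node, loc in moves:
            events.append((t, node, loc))
        for idx in np.argsort(g.times[g.n_leaves:]) + g.n_leaves:
            t_merge = g.times[idx]
            children = np.flatnonzero(g.parents == idx)
            for t, node, loc in events:
                if t < t_merge and node in last_loc:
                    last_loc[node] = loc
            for c in children:
                # ancestor and child both lie in the event disc of
                # radius r, so they are within 2r of each other
                assert landscape.distance(g.locations[idx], last_loc[int(c)]) <= 2 * k.radius + 1e-9
            last_loc[int(idx)] = g.locations[idx]


class TestSamplerEquivalence:
    def test_thinned_matches_naive_global_tmrca_distribution(self, rng):
        # the thinned proposal scheme must reproduce the naive global
        # sampler's law exactly (two-sample KS on pair TMRCA)
        landscape = Landscape(2, (1.0, 1.0))
        k = EventKernel("disc", radius=0.25, impact=0.9, rate_density=1.0)
        sample = _pair(landscape, 0.2)
        n_rep = 800
        t_thin = [
            simulate_genealogy(sample, landscape, k, rng, method="thinned").tmrca
            for _ in range(n_rep)
        ]
        t_glob = [
            simulate_genealogy(sample, landscape, k, rng, method="global").tmrca
            for _ in range(n_rep)
        ]
        res = stats.ks_2samp(t_thin, t_glob)
        assert res.pvalue > 0.01

    def test_kingman_oracle_msprime(self, rng):
        # torus-covering events with small impact converge to the
        # Kingman coalescent; for n=2 the pair rate is lambda*A*u^2,
        # matched against msprime with haploid Ne = 1/(lambda*A*u^2)
        msprime = pytest.importorskip("msprime")
        landscape = Landscape(2, (1.0, 1.0))
        lam, u = 1.0, 0.3
        k = EventKernel("disc", radius=1.0, impact=u, rate_density=lam)
        sample = _pair(landscape, 0.3)
        n_rep = 1200
        slfv_t = [
            simulate_genealogy(sample, landscape, k, rng).tmrca
            for _ in range(n_rep)
        ]
        Ne = 1.0 / (lam * landscape.area * u**2)
        msp_t = [
            ts.first().time(ts.first().root)
            for ts in msprime.sim_ancestry(
                samples=2, ploidy=1, population_size=Ne,
                num_replicates=n_rep, random_seed=4321,
            )
        ]
        res = stats.ks_2samp(slfv_t, msp_t)
        assert res.pvalue > 0.01


class TestGenealogyIO:
    def test_newick_and_node_table_roundtrip(self, rng, tmp_path):
        landscape = Landscape(2, (1.0, 1.0))
        k = EventKernel("disc", radius=0.3, impact=0.8, rate_density=1.0)
        sample = individuals_from_array(
            [f"ind_{j}" for j in range(5)], landscape.random_points(5, rng)
        )
        g = simulate_genealogy(sample, landscape, k, rng)
        prefix = tmp_path / "tree"
        slfv.write_genealogy(g, prefix)
        g2 = slfv.read_genealogy(prefix)
        assert g2.leaf_ids == g.leaf_ids
        np.testing.assert_allclose(np.sort(g2.times), np.sort(g.times), rtol=1e-8)
        np.testing.assert_allclose(g2.total_branch_length, g.total_branch_length, rtol=1e-8)
        # same leaf partitions below the root's children
        def partitions(gen):
            below = gen.leaf_descendants()
            return sorted(
                tuple(sorted(gen.leaf_ids[i] for i in below[c]))
                for c in np.flatnonzero(gen.parents == gen.root)
            )
        assert partitions(g2) == partitions(g)
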