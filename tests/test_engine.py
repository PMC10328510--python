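"""Ancestry engine: rates, tract lengths, genealogy invariants, oracles."""

import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

from popgensim.demography import (
    DemographicModel,
    MigrationChange,
    SizeChange,
    Split,
    constant_size_model,
)
from popgensim.engine import (
    gc_initiation_rate,
    marginal_tree,
    sample_tract_length,
    simulate_ancestry,
)
from tests.conftest import make_contig


class TestGcInitiationRate:
    def test_drosophila_ratio_83_to_17(self):
        rate = gc_initiation_rate(1e-8, 0.83)
        assert rate == pytest.approx(1e-8 * 83 / 17, rel=1e-12)
        assert rate == pytest.approx(4.882e-8, rel=1e-3)

    def test_zero_fraction(self):
        assert gc_initiation_rate(1e-8, 0.0) == 0.0

    def test_half_fraction_equal_rates(self):
        assert gc_initiation_rate(3e-9, 0.5) == pytest.approx(3e-9)

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            gc_initiation_rate(1e-8, bad)


class TestSampleTractLength:
    def test_mean_recovered_at_518(self, rng):
        draws = np.array([sample_tract_length(518.0, rng) for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 518.0) <= 3 * se

    def test_degenerate_mean_one(self, rng):
        assert all(sample_tract_length(1.0, rng) == 1 for _ in range(100))

    def test_geometric_pmf_goodness_of_fit(self, rng):
        # mean 3 -> success probability 1/3 on {1, 2, ...}
        draws = np.array([sample_tract_length(3.0, rng) for _ in range(10_000)])
        kmax = 12
        observed = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)[1:]
        p = 1 / 3
        expected = np.array(
            [p * (1 - p) ** (k - 1) for k in range(1, kmax)]
            + [(1 - p) ** (kmax - 1)]  # tail lumped
        ) * len(draws)
        result = sps.chisquare(observed, expected)
        assert result.pvalue > 1e-3

    def test_mean_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_tract_length(0.5, rng)


class TestCoalescentBaseline:
    def test_pairwise_tmrca_mean_diploid(self, constant_model):
        # E[T2] = ploidy * Ne = 20,000 generations for diploid Ne = 1e4
        contig = make_contig(1000)
        times = []
        for seed in range(2000):
            g, _ = simulate_ancestry({"pop0": 2}, contig, constant_model, seed)
            times.append(g.node_times[-1])
        times = np.array(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 20_000.0) <= 3 * se

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_tmrca_scaling_with_sample_size(self, n, constant_model):
        # E[TMRCA] = 2 * ploidy * Ne * (1 - 1/n)
        contig = make_contig(1000)
        expected = 2 * 2 * 1e4 * (1 - 1 / n)
        times = []
        for seed in range(2000):
            g, _ = simulate_ancestry({"pop0": n}, contig, constant_model, seed)
            times.append(max(g.node_times))
        times = np.array(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected) <= 3 * se

    def test_haploid_convention(self):
        # pairwise rate 1/Ne for haploids: E[T2] = Ne
        contig = make_contig(1000, ploidy=1)
        model = constant_size_model(1e4)
        times = [
            simulate_ancestry({"pop0": 2}, contig, model, seed)[0].node_times[-1]
            for seed in range(2000)
        ]
        times = np.array(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 1e4) <= 3 * se

    def test_zero_recombination_single_tree(self, constant_model):
        contig = make_contig(50_000)
        g, log = simulate_ancestry({"pop0": 7}, contig, constant_model, seed=5)
        assert log.coalescence == 6
        assert log.crossover_drawn == 0 and log.gc_drawn == 0
        t0 = marginal_tree(g, 0)
        t1 = marginal_tree(g, g.contig_length - 1)
        assert t0.parent == t1.parent

    def test_determinism(self, constant_model):
        contig = make_contig(10_000, recombination_rate=1e-7)
        a = simulate_ancestry({"pop0": 5}, contig, constant_model, seed=9)
        b = simulate_ancestry({"pop0": 5}, contig, constant_model, seed=9)
        assert a[0].node_times == b[0].node_times
        assert a[0].edges_parent == b[0].edges_parent
        assert a[0].edges_left == b[0].edges_left
        assert a[1].counts() == b[1].counts()

    def test_msprime_tmrca_distribution_cross_check(self, constant_model):
        # independent oracle: pairwise coalescence time distributions agree
        import msprime

        contig = make_contig(100)
        ours = np.array([
            simulate_ancestry({"pop0": 2}, contig, constant_model, seed)[0]
            .node_times[-1]
            for seed in range(1000)
        ])
        theirs = np.array([
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=1, ploidy=2, population_size=1e4,
                sequence_length=100, num_replicates=1000, random_seed=7,
            )
        ])
        result = sps.ks_2samp(ours, theirs)
        assert result.pvalue > 1e-3


def _topology_label(tree, node=None):
    node = tree.root if node is None else node
    kids = tree.children()
    if node not in kids:
        return f"s{node}"
    inner = sorted(_topology_label(tree, c) for c in kids[node])
    return "(" + ",".join(inner) + ")"


def _exact_topology_distribution(n=4):
    """Closed-form oracle: enumerate all equally likely merge histories of
    the n-coalescent and count the induced labeled topologies."""
    counts = Counter()
    total = [0]

    def recurse(lineages, weight):
        if len(lineages) == 1:
            label = _render(lineages[0])
            counts[label] += weight
            total[0] += weight
            return
        pairs = list(itertools.combinations(range(len(lineages)), 2))
        for i, j in pairs:
            merged = [
                lin for k, lin in enumerate(lineages) if k not in (i, j)
            ]
            merged.append((lineages[i], lineages[j]))
            recurse(merged, weight / len(pairs))

    def _render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(sorted(_render(c) for c in node)) + ")"

    recurse([f"s{i}" for i in range(n)], 1.0)
    return {k: v for k, v in counts.items()}


class TestTopologyDistribution:
    def test_matches_exact_coalescent_probabilities(self, constant_model):
        # n = 4, no recombination: labeled topology frequencies match the
        # exact enumeration of ranked merge histories
        contig = make_contig(10)
        observed = Counter()
        n_reps = 5000
        for seed in range(n_reps):
            g, _ = simulate_ancestry({"pop0": 4}, contig, constant_model, seed)
            observed[_topology_label(marginal_tree(g, 0))] += 1
        expected = _exact_topology_distribution(4)
        labels = sorted(expected)
        assert set(observed) <= set(labels)
        obs = np.array([observed.get(l, 0) for l in labels])
        exp = np.array([expected[l] * n_reps for l in labels])
        result = sps.chisquare(obs, exp)
        assert result.pvalue > 1e-3


class TestRecombinationClasses:
    def test_drawn_gc_fraction(self, constant_model):
        contig = make_contig(
            50_000, recombination_rate=1e-8,
            gene_conversion_fraction=0.83, gene_conversion_length=518.0,
        )
        gc = cross = 0
        for seed in range(80):
            _, log = simulate_ancestry(
                {"pop0": 6}, contig, constant_model, seed,
                gene_conversion=True,
            )
            gc += log.gc_drawn
            cross += log.crossover_drawn
        total = gc + cross
        frac = gc / total
        se = np.sqrt(0.83 * 0.17 / total)
        assert abs(frac - 0.83) <= 3 * se

    def test_logged_tract_lengths_mean(self, constant_model):
        contig = make_contig(
            100_000, recombination_rate=1e-8,
            gene_conversion_fraction=0.83, gene_conversion_length=518.0,
        )
        tracts = []
        for seed in range(30):
            _, log = simulate_ancestry(
                {"pop0": 6}, contig, constant_model, seed,
                gene_conversion=True,
            )
            tracts.extend(log.tract_lengths)
        tracts = np.array(tracts)
        se = tracts.std(ddof=1) / np.sqrt(len(tracts))
        assert abs(tracts.mean() - 518.0) <= 3 * se

    def test_bacterial_mode_no_crossovers(self):
        # E. coli configuration: initiation 8.9e-11, mean tract 542
        contig = make_contig(
            1_000_000, recombination_rate=8.9e-11, ploidy=1,
            gene_conversion_length=542.0, non_crossover_only=True,
        )
        model = constant_size_model(1e5)
        _, log = simulate_ancestry({"pop0": 5}, contig, model, seed=17)
        assert log.crossover_drawn == 0
        assert log.gc_drawn > 0

    def test_effective_counts_bounded_by_drawn(self, constant_model):
        contig = make_contig(
            100_000, recombination_rate=1e-8,
            gene_conversion_fraction=0.83, gene_conversion_length=518.0,
        )
        _, log = simulate_ancestry(
            {"pop0": 8}, contig, constant_model, seed=3, gene_conversion=True
        )
        assert log.gc_effective <= log.gc_drawn
        assert log.crossover_effective <= log.crossover_drawn


class TestGenealogyInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_tree_at_every_position_with_recombination(self, seed, constant_model):
        contig = make_contig(
            2000, recombination_rate=1e-6,
            gene_conversion_fraction=0.5, gene_conversion_length=100.0,
        )
        n = 5
        g, _ = simulate_ancestry(
            {"pop0": n}, contig, constant_model, seed, gene_conversion=True
        )
        # parent older than child on every edge
        for p, c in zip(g.edges_parent, g.edges_child):
            assert g.node_times[p] > g.node_times[c]
        # per parent-child pair, edge intervals disjoint
        intervals = {}
        for p, c, l, r in zip(
            g.edges_parent, g.edges_child, g.edges_left, g.edges_right
        ):
            intervals.setdefault((p, c), []).append((l, r))
        for spans in intervals.values():
            spans.sort()
            for (l1, r1), (l2, r2) in zip(spans, spans[1:]):
                assert r1 <= l2
        # at every breakpoint interval: a single rooted tree over all samples
        breaks = g.breakpoints()
        for pos in breaks[:-1]:
            tree = marginal_tree(g, pos)
            roots = set()
            for s in g.samples:
                path = tree.path_to_root(s)
                roots.add(path[-1])
                assert len(path) == len(set(path))
            assert len(roots) == 1
            assert tree.leaves_below(tree.root) == sorted(g.samples)

    def test_ancestral_material_conservation(self, constant_model):
        # every sample's material at every position sits on exactly one
        # root-to-sample path: equivalently, the marginal tree at each
        # position contains each sample exactly once (checked above) and
        # total tree coverage spans the full contig
        contig = make_contig(500, recombination_rate=1e-5)
        g, _ = simulate_ancestry({"pop0": 4}, contig, constant_model, seed=2)
        covered = np.zeros(g.contig_length, dtype=int)
        for s in g.samples:
            for p, c, l, r in zip(
                g.edges_parent, g.edges_child, g.edges_left, g.edges_right
            ):
                if c == s:
                    covered[l:r] += 1
        # each sample has exactly one parent edge at each position
        assert np.all(covered == len(g.samples))


class TestStructuredCoalescent:
    def test_split_funnels_lineages(self):
        model = DemographicModel(
            id="iso", populations=("A", "B"),
            initial_sizes={"A": 1e3, "B": 1e3},
            events=(Split(500.0, "B", "A"),),
        )
        contig = make_contig(1000)
        g, log = simulate_ancestry(
            {"A": 3, "B": 3}, contig, model, seed=11
        )
        assert log.coalescence == 5
        # cross-population pairs cannot coalesce before the split
        tree = marginal_tree(g, 0)
        for a in (0, 1, 2):
            for b in (3, 4, 5):
                assert tree.tmrca(a, b) >= 500.0

    def test_migration_events_logged_and_mixing(self):
        model = DemographicModel(
            id="mig", populations=("A", "B"),
            initial_sizes={"A": 1e3, "B": 1e3},
            initial_migration={("A", "B"): 0.01, ("B", "A"): 0.01},
            events=(Split(1e7, "B", "A"),),
        )
        contig = make_contig(1000)
        g, log = simulate_ancestry({"A": 2, "B": 2}, contig, model, seed=21)
        assert log.migration > 0
        assert log.coalescence == 3

    def test_size_change_shifts_coalescence_times(self):
        # ancient expansion: bigger ancestral size -> deeper mean TMRCA than
        # the small recent size alone would give
        model = DemographicModel(
            id="step", populations=("pop0",),
            initial_sizes={"pop0": 100.0},
            events=(SizeChange(50.0, "pop0", 1e5),),
        )
        contig = make_contig(1000)
        times = [
            simulate_ancestry({"pop0": 2}, contig, model, seed)[0].node_times[-1]
            for seed in range(500)
        ]
        times = np.array(times)
        # P(T2 > 50) = exp(-50/200) ~ 0.78; deep coalescences at rate 1/2e5
        assert times.mean() > 10 * 200.0

    def test_zero_size_population_is_error(self):
        model = DemographicModel(
            id="bad", populations=("pop0",), initial_sizes={"pop0": 100.0},
            events=(SizeChange(10.0, "pop0", 0.0),),
        )
        contig = make_contig(1000)
        with pytest.raises(ValueError):
            simulate_ancestry({"pop0": 2}, contig, model, seed=1)

    def test_unknown_population_rejected(self, constant_model):
        with pytest.raises(ValueError, match="unknown sample population"):
            simulate_ancestry(
                {"ghost": 2}, make_contig(100), constant_model, seed=1
            )

    def test_sample_count_below_one_rejected(self, constant_model):
        with pytest.raises(ValueError):
            simulate_ancestry(
                {"pop0": 0}, make_contig(100), constant_model, seed=1
            )


class TestMarginalTree:
    def test_position_out_of_range(self, pair_genealogy):
        with pytest.raises(ValueError):
            marginal_tree(pair_genealogy, 100)
        with pytest.raises(ValueError):
            marginal_tree(pair_genealogy, -1)

    def test_crossover_boundary_trees_match_edge_table(self, constant_model):
        contig = make_contig(1000, recombination_rate=1e-5)
        for seed in range(20):
            g, log = simulate_ancestry(
                {"pop0": 3}, contig, constant_model, seed
            )
            if log.crossover_effective > 0:
                break
        breaks = g.breakpoints()
        assert len(breaks) > 2
        b = breaks[1]
        for pos in (b - 1, b):
            tree = marginal_tree(g, pos)
            expected = {
                c: p
                for p, c, l, r in zip(
                    g.edges_parent, g.edges_child, g.edges_left, g.edges_right
                )
                if l <= pos < r
            }
            assert tree.parent == expected

    def test_root_unique_and_paths_finite(self, balanced_genealogy):
        tree = marginal_tree(balanced_genealogy, 50)
        assert tree.root == 6
        assert tree.path_to_root(0) == [0, 4, 6]
        assert tree.tmrca(0, 1) == 1000.0
        assert tree.tmrca(0, 3) == 3000.0

    def test_single_sample_degenerate(self, constant_model):
        g, log = simulate_ancestry(
            {"pop0": 1}, make_contig(100), constant_model, seed=1
        )
        assert g.num_edges == 0
        tree = marginal_tree(g, 0)
        assert tree.root == 0
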