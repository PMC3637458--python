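"""Core DP: embedding profiles, lineage schedules, and P[G|T].

Expected values come from independent oracles: brute-force enumeration of
feasible interval assignments (for the minimum lineage counts), labeled-
history enumeration (for H), a single-population coalescent formula built
from first principles with exact rationals, and Monte-Carlo simulation.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from rankedcoal import (
    H,
    PairAnalysis,
    SpeciesTreeModel,
    compute_g,
    compute_k,
    compute_lambda,
    dp_recursion,
    enumerate_all_ranked_topologies,
    estimate_distribution,
    interval_prob,
    parse_ranked_newick,
    ranked_probability,
)
from rankedcoal.msc_simulator import random_species_tree


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_g(G, T):
    """Minimum lineage counts by enumerating interval assignments.

    Gene node of rank r may coalesce in species interval j only if
    j <= rank of its species-side lca, and interval indices must be
    non-decreasing in node rank (older nodes sit in older intervals).
    """
    top = T.topology if isinstance(T, SpeciesTreeModel) else T
    n = G.n
    lca = {r: top.lca_rank(G.clade(r)) for r in range(1, n)}
    best = {i: n for i in range(1, n)}
    choices = [range(1, lca[r] + 1) for r in range(1, n)]
    for assign in itertools.product(*choices):
        if any(a > b for a, b in zip(assign, assign[1:])):
            continue  # violates the temporal order of the ranks
        for i in range(1, n):
            below = sum(1 for j in assign if j > i)
            best[i] = min(best[i], n - below)
    return tuple(best[i] for i in range(1, n))


def tavare_gij(i, j, t):
    """Single-population probability that i lineages become j in time t."""
    total = 0.0
    for k in range(j, i + 1):
        rising = lambda a, b: math.prod(a + x for x in range(b))
        falling = lambda a, b: math.prod(a - x for x in range(b))
        coef = Fraction(
            (2 * k - 1) * (-1) ** (k - j) * rising(j, k - 1) * falling(i, k),
            math.factorial(j) * math.factorial(k - j) * rising(i, k),
        )
        total += float(coef) * math.exp(-k * (k - 1) * t / 2.0)
    return total


# ---------------------------------------------------------------------------
# g_i
# ---------------------------------------------------------------------------


class TestComputeG:
    def test_rank_swapped_worked_example(self, gene_rank_swapped, fig_model):
        assert compute_g(gene_rank_swapped, fig_model).g[1:] == (2, 3, 5, 5)

    def test_deep_coalescence_worked_example(self, gene_deep_coalescence, fig_model):
        assert compute_g(gene_deep_coalescence, fig_model).g[1:] == (2, 4, 5, 5)
        # cross-check the frozen value with the brute-force oracle
        assert brute_force_g(gene_deep_coalescence, fig_model) == (2, 4, 5, 5)

    def test_matching_topology_gives_minimal_counts(self, gene_matching, fig_model):
        assert compute_g(gene_matching, fig_model).g[1:] == (2, 3, 4, 5)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        T = random_species_tree(n, seed=seed)
        G = random_species_tree(n, seed=seed + 100, labels=sorted(T.labels)).topology
        prof = compute_g(G, T)
        assert prof.g[1:] == brute_force_g(G, T)
        for i in range(1, n):
            assert i < prof.g[i] <= n

    def test_leaf_set_mismatch(self, fig_model):
        G = parse_ranked_newick("(((A,B)3,C)2,(D,X)4)1;")
        with pytest.raises(ValueError):
            compute_g(G, fig_model)


# ---------------------------------------------------------------------------
# k_{i,j,z} and rates
# ---------------------------------------------------------------------------


class TestComputeK:
    def test_deep_coalescence_interval_two(self, gene_deep_coalescence, fig_model):
        # two coalescences in the ABC ancestral population
        sched = compute_k(gene_deep_coalescence, fig_model, 2, 4, 2)
        z_abc = sched.populations.index(frozenset("ABC"))
        z_de = sched.populations.index(frozenset("DE"))
        assert [sched.k[j][z_abc] for j in (0, 1, 2)] == [1, 2, 3]
        assert [sched.k[j][z_de] for j in (0, 1, 2)] == [1, 1, 1]

    def test_rank_swapped_interval_two(self, gene_rank_swapped, fig_model):
        # all coalescences as recent as possible: one event in tau_2
        sched = compute_k(gene_rank_swapped, fig_model, 2, 3, 2)
        z_abc = sched.populations.index(frozenset("ABC"))
        assert (sched.k[0][z_abc], sched.k[1][z_abc]) == (1, 2)

    def test_delayed_coalescences_shift_counts(self, gene_rank_swapped, fig_model):
        # same ranked gene tree, but the AB coalescence delayed into tau_2:
        # one more lineage throughout the interval
        sched = compute_k(gene_rank_swapped, fig_model, 2, 4, 3)
        z_abc = sched.populations.index(frozenset("ABC"))
        assert (sched.k[0][z_abc], sched.k[1][z_abc]) == (2, 3)

    def test_rates_of_most_recent_interval(self, gene_rank_swapped, fig_model):
        sched = compute_k(gene_rank_swapped, fig_model, 3, 5, 3)
        assert sched.rates == (0, 1, 2)
        assert compute_lambda(sched) == (0, 1, 2)

    def test_no_events_means_constant_counts(self, gene_rank_swapped, fig_model):
        sched = compute_k(gene_rank_swapped, fig_model, 2, 3, 3)
        assert sched.m == 0
        assert sched.k[0] == sched.k[-1]

    def test_column_sums_match_lineage_counts(self, gene_deep_coalescence, fig_model):
        sched = compute_k(gene_deep_coalescence, fig_model, 2, 4, 2)
        assert sum(sched.k[0]) == 2
        assert sum(sched.k[-1]) == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_bottom_counts_equal_daughter_sums(self, seed):
        """Entering counts of a row equal the summed exiting counts of the
        daughter populations in the row below (leaf populations exit one)."""
        n = 6
        T = random_species_tree(n, seed=seed)
        G = random_species_tree(n, seed=seed + 50, labels=sorted(T.labels)).topology
        prof = compute_g(G, T)
        bead = T.bead()
        for i in range(2, n - 1):
            for ell in range(prof.g[i + 1], n + 1):
                sched = compute_k(G, T, i, ell, prof.g[i - 1])
                below = compute_k(G, T, i + 1, ell, ell).k[0]
                for z in range(i):
                    expect = sum(below[d] for d in bead.daughters[(i, z)])
                    assert sched.k[-1][z] == expect

    def test_strictly_increasing_rates(self, fig_model):
        rng = np.random.default_rng(0)
        for seed in range(5):
            n = 6
            T = random_species_tree(n, seed=seed)
            G = random_species_tree(n, seed=seed + 7, labels=sorted(T.labels)).topology
            prof = compute_g(G, T)
            for i in range(2, n):
                for ell_in in range(prof.g[i], n + 1):
                    for ell_out in range(prof.g[i - 1], ell_in + 1):
                        sched = compute_k(G, T, i, ell_in, ell_out)
                        assert all(
                            a < b for a, b in zip(sched.rates, sched.rates[1:])
                        )

    def test_precondition_violations(self, gene_rank_swapped, fig_model):
        with pytest.raises(ValueError):
            compute_k(gene_rank_swapped, fig_model, 1, 2, 2)  # i out of range
        with pytest.raises(ValueError):
            compute_k(gene_rank_swapped, fig_model, 3, 4, 3)  # ell_in < g_3
        with pytest.raises(ValueError):
            compute_k(gene_rank_swapped, fig_model, 2, 3, 1)  # ell_out < g_1


# ---------------------------------------------------------------------------
# H and the DP
# ---------------------------------------------------------------------------


class TestH:
    def test_against_labeled_history_enumeration(self):
        for k in range(2, 6):
            labels = [chr(ord("A") + i) for i in range(k)]
            enumerated = sum(1 for _ in enumerate_all_ranked_topologies(labels))
            assert H(k) == enumerated
        assert H(1) == 1

    def test_requires_positive_argument(self):
        with pytest.raises(ValueError):
            H(0)


class TestDP:
    def test_two_taxon_table(self):
        T = SpeciesTreeModel(parse_ranked_newick("(A,B)1;"), {1: 1.0})
        table = dp_recursion(parse_ranked_newick("(A,B)1;"), T)
        assert table.entries == {(1, 2): 1.0}
        assert table.probability == 1.0

    def test_most_recent_state_is_certain(self, gene_rank_swapped, fig_model):
        table = dp_recursion(gene_rank_swapped, fig_model)
        assert table.P(fig_model.n - 1, fig_model.n) == 1.0
        assert table.P(2, 2) == 0.0  # below g_2 = 3

    def test_worked_conditional_closed_form(self, gene_rank_swapped, fig_model):
        # two coalescences in separate populations of the most recent
        # interval, order constrained: ((1-e^-d)^2)/2
        analysis = PairAnalysis(gene_rank_swapped, fig_model.topology)
        d = fig_model.time(2) - fig_model.time(3)
        expected = 0.5 * (-math.expm1(-d)) ** 2
        assert analysis.conditional(3, 3, 5, d) == pytest.approx(expected, rel=1e-12)

    def test_three_taxon_closed_forms(self, three_taxon_model):
        t = three_taxon_model.gaps[0]
        match = parse_ranked_newick("((A,B)2,C)1;")
        mism = parse_ranked_newick("((A,C)2,B)1;")
        assert ranked_probability(match, three_taxon_model) == pytest.approx(
            1 - 2 / 3 * math.exp(-t), abs=1e-12
        )
        assert ranked_probability(mism, three_taxon_model) == pytest.approx(
            math.exp(-t) / 3, abs=1e-12
        )

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_total_probability_is_one(self, n):
        T = random_species_tree(n, seed=n)
        total = sum(
            ranked_probability(G, T)
            for G in enumerate_all_ranked_topologies(T.labels)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_every_ranked_topology_is_possible(self):
        T = random_species_tree(4, seed=11)
        for G in enumerate_all_ranked_topologies(T.labels):
            assert ranked_probability(G, T) > 0.0

    def test_time_translation_invariance(self, gene_deep_coalescence, fig_model):
        p0 = ranked_probability(gene_deep_coalescence, fig_model)
        shifted = fig_model.with_times(
            {i: t + 2.5 for i, t in zip(range(1, 5), fig_model.times)}
        )
        assert ranked_probability(gene_deep_coalescence, shifted) == pytest.approx(
            p0, rel=1e-12
        )
        # changing s_{n-1} alone (gaps fixed) also leaves P unchanged
        squeezed = fig_model.with_times({1: 3.3, 2: 1.3, 3: 1.0, 4: 0.3})
        assert ranked_probability(gene_deep_coalescence, squeezed) == pytest.approx(
            p0, rel=1e-12
        )

    def test_single_population_reduction(self, gene_deep_coalescence, fig_model):
        """When all events of an interval fall in one population, the
        conditional factorizes into a coalescent count probability, the
        survival of the other populations, and one over the number of
        merge orders."""
        # tau_2 of the deep-coalescence case: both events in the ABC pop
        analysis = PairAnalysis(gene_deep_coalescence, fig_model.topology)
        d = fig_model.time(1) - fig_model.time(2)
        got = analysis.conditional(2, 2, 4, d)
        a, b = 3, 1  # ABC population: 3 lineages in, 1 out
        # DE holds a single lineage: background rate 0, survival 1
        orders = math.prod(k * (k - 1) // 2 for k in range(b + 1, a + 1))
        expected = tavare_gij(a, b, d) / orders
        assert got == pytest.approx(expected, rel=1e-10)

    def test_single_population_reduction_with_background(self):
        # balanced 4-taxon species tree; the gene tree delays the CD
        # coalescence, so in tau_2 the AB pair merges while the CD
        # population keeps two lineages alive (background rate 1).
        T = SpeciesTreeModel(
            parse_ranked_newick("((A,B)2,(C,D)3)1;"), {1: 3.0, 2: 2.0, 3: 1.0}
        )
        G = parse_ranked_newick("((A,B)3,(C,D)2)1;")
        analysis = PairAnalysis(G, T.topology)
        d = T.time(1) - T.time(2)
        got = analysis.conditional(2, 3, 4, d)
        expected = tavare_gij(2, 1, d) * math.exp(-1.0 * d)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_conditional_limits_in_interval_length(self, gene_rank_swapped, fig_model):
        analysis = PairAnalysis(gene_rank_swapped, fig_model.topology)
        # with events required, shrinking the interval kills the probability
        vals = [analysis.conditional(3, 3, 5, d) for d in (2.0, 1.0, 0.1, 1e-4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-7
        # with no events, shrinking the interval approaches certainty
        vals0 = [analysis.conditional(3, 5, 5, d) for d in (2.0, 1.0, 0.1, 1e-4)]
        assert all(a < b for a, b in zip(vals0, vals0[1:]))
        assert vals0[-1] > 0.999

    def test_monte_carlo_agreement_three_taxa(self, three_taxon_model):
        N = 20000
        table = estimate_distribution(three_taxon_model, N, seed=17)
        match = parse_ranked_newick("((A,B)2,C)1;")
        p = ranked_probability(match, three_taxon_model)
        se = math.sqrt(p * (1 - p) / N)
        assert abs(table.freq(match) - p) < 4 * se
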