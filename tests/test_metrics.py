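"""Structure metrics (NODF, modularity) and species metrics (closeness, d')
against independent oracles."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollinet import (
    AnnealingConfig,
    find_modules,
    modularity_q,
    nodf,
    specialisation_dprime,
    weighted_closeness,
)
from pollinet.metrics import _adjacency

from conftest import make_network


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def nodf_oracle(binary):
    """Plain pair-enumeration NODF on a 0/1 matrix."""
    binary = np.asarray(binary, dtype=bool)

    def axis_terms(mat):
        terms = []
        for i, j in combinations(range(mat.shape[0]), 2):
            fi, fj = mat[i].sum(), mat[j].sum()
            if fi == fj:
                terms.append(0.0)
            else:
                hi, lo = (i, j) if fi > fj else (j, i)
                shared = np.logical_and(mat[hi], mat[lo]).sum()
                terms.append(shared / mat[lo].sum())
        return terms

    terms = axis_terms(binary) + axis_terms(binary.T)
    return 100.0 * float(np.mean(terms))


def q_oracle_networkx(net, partition):
    """Weighted Newman-Girvan Q via networkx on the bipartite graph."""
    g = net.to_graph()
    modules = {}
    for species, label in partition.items():
        modules.setdefault(label, set()).add(species)
    return nx.community.modularity(g, modules.values(), weight="weight")


def set_partitions(n):
    """All set partitions of range(n) as restricted-growth label strings."""

    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield tuple(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))

    yield from rec([], 0)


def exhaustive_best_q(net):
    W, ids = _adjacency(net)
    two_m = W.sum()
    k = W.sum(axis=1)
    B = W - np.outer(k, k) / two_m
    best = -np.inf
    for labels in set_partitions(len(ids)):
        lab = np.array(labels)
        q = B[lab[:, None] == lab[None, :]].sum() / two_m
        best = max(best, q)
    return best


def dprime_oracle(counts):
    """Direct implementation of the standardized specialisation index for the
    rows of a count matrix."""
    counts = np.asarray(counts, dtype=float)
    m = counts.sum()
    q = counts.sum(axis=0) / m
    out = []
    for row in counts:
        A = row.sum()
        p = row / A
        d = sum(pi * math.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
        d_max = math.log(m / A)
        # most generalized achievable integer allocation of A events
        quota = A * q
        alloc = np.floor(quota)
        rem = int(round(A - alloc.sum()))
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:rem]] += 1
        pa = alloc / A
        d_min = sum(pi * math.log(pi / qi) for pi, qi in zip(pa, q) if pi > 0)
        out.append(
            0.0 if d_max <= d_min else min(1.0, max(0.0, (d - d_min) / (d_max - d_min)))
        )
    return np.array(out)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------


class TestNodf:
    def test_perfectly_nested_triangle(self):
        net = make_network([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert nodf(net) == pytest.approx(100.0)

    def test_checkerboard_is_zero(self):
        net = make_network([[1, 0], [0, 1]])
        assert nodf(net) == pytest.approx(0.0)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 30:
            binary = rng.random((5, 4)) < 0.5
            if binary.sum(axis=1).min() == 0 or binary.sum(axis=0).min() == 0:
                continue
            net = make_network(binary.astype(int))
            assert nodf(net) == pytest.approx(nodf_oracle(binary), abs=1e-12)
            checked += 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(37)
        counts = rng.integers(1, 5, size=(4, 5)) * (rng.random((4, 5)) < 0.7)
        counts[counts.sum(axis=1) == 0, 0] = 1
        counts[0, counts.sum(axis=0) == 0] = 1
        base = nodf(make_network(counts))
        for _ in range(5):
            rp, cp = rng.permutation(4), rng.permutation(5)
            assert nodf(make_network(counts[np.ix_(rp, cp)])) == pytest.approx(
                base, abs=1e-12
            )

    def test_degenerate_matrix_errors(self):
        with pytest.raises(ValueError):
            nodf(make_network([[1, 1]]))
        with pytest.raises(ValueError):
            nodf(make_network([[1, 0], [1, 0]]))


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


class TestModularityQ:
    def test_single_community_is_zero(self, small_net):
        partition = {s: 0 for s in small_net.species_ids()}
        assert modularity_q(small_net, partition) == pytest.approx(0.0, abs=1e-12)

    def test_two_blocks_half(self, two_blocks_net):
        partition = {s: 0 for s in ("p1", "p2", "a1", "a2")}
        partition.update({s: 1 for s in ("p3", "p4", "a3", "a4")})
        assert modularity_q(two_blocks_net, partition) == pytest.approx(0.5)

    def test_matches_networkx_oracle(self, small_net):
        rng = np.random.default_rng(41)
        for _ in range(10):
            labels = rng.integers(0, 3, size=small_net.n_species)
            partition = dict(zip(small_net.species_ids(), labels.tolist()))
            assert modularity_q(small_net, partition) == pytest.approx(
                q_oracle_networkx(small_net, partition), abs=1e-12
            )

    def test_unknown_species_errors(self, small_net):
        partition = {s: 0 for s in small_net.species_ids()}
        partition["ghost"] = 1
        with pytest.raises(ValueError):
            modularity_q(small_net, partition)


class TestFindModules:
    def test_recovers_two_blocks(self, two_blocks_net):
        result = find_modules(two_blocks_net, rng=3)
        assert result.modularity_q == pytest.approx(0.5)
        assert result.n_modules == 2
        part = result.partition
        assert part["p1"] == part["p2"] == part["a1"] == part["a2"]
        assert part["p3"] == part["p4"] == part["a3"] == part["a4"]
        assert part["p1"] != part["p3"]

    def test_complete_bipartite_has_low_q(self):
        net = make_network(np.ones((3, 3), int))
        result = find_modules(net, rng=5)
        assert result.modularity_q == pytest.approx(exhaustive_best_q(net), abs=1e-12)

    def test_annealing_matches_exhaustive_on_small_graphs(self):
        rng = np.random.default_rng(43)
        for _ in range(5):
            n_p, n_a = rng.integers(2, 5), rng.integers(2, 5)
            counts = (rng.random((n_p, n_a)) < 0.5) * rng.integers(1, 4, (n_p, n_a))
            counts[counts.sum(axis=1) == 0, 0] = 1
            counts[0, counts.sum(axis=0) == 0] = 1
            net = make_network(counts)
            result = find_modules(net, rng=int(rng.integers(2**31)))
            assert result.modularity_q == pytest.approx(
                exhaustive_best_q(net), abs=1e-10
            )

    def test_deterministic_given_seed(self, small_net):
        a = find_modules(small_net, rng=7)
        b = find_modules(small_net, rng=7)
        assert a.partition == b.partition
        assert a.modularity_q == b.modularity_q


# ---------------------------------------------------------------------------
# Weighted closeness
# ---------------------------------------------------------------------------


class TestWeightedCloseness:
    def test_star_hand_computed(self):
        # 1 plant hub, k pollinator leaves, unit counts: hub closeness 1,
        # each leaf (before rescaling) k / (2k - 1)
        k = 5
        net = make_network(np.ones((1, k), int))
        c = weighted_closeness(net).weighted_closeness
        assert c["p1"] == pytest.approx(1.0)
        for leaf in net.pollinator_ids:
            assert c[leaf] == pytest.approx(k / (2 * k - 1))

    def test_symmetry_on_uniform_k22(self):
        net = make_network(np.full((2, 2), 3))
        values = list(weighted_closeness(net).weighted_closeness.values())
        assert np.ptp(values) < 1e-12

    def test_strengthening_an_edge_weakly_increases_endpoint_closeness(self):
        rng = np.random.default_rng(47)
        counts = rng.integers(1, 4, size=(3, 3)) * (rng.random((3, 3)) < 0.8)
        counts[counts.sum(axis=1) == 0, 0] = 1
        counts[0, counts.sum(axis=0) == 0] = 1
        net = make_network(counts)
        base = weighted_closeness(net).weighted_closeness
        rows, cols = np.nonzero(counts)
        boosted = counts.copy()
        boosted[rows[0], cols[0]] *= 10
        after = weighted_closeness(make_network(boosted)).weighted_closeness
        plant = net.plant_ids[rows[0]]
        poll = net.pollinator_ids[cols[0]]
        assert after[plant] >= base[plant] - 1e-12
        assert after[poll] >= base[poll] - 1e-12

    def test_matches_scipy_dijkstra_oracle(self):
        from scipy.sparse.csgraph import dijkstra

        rng = np.random.default_rng(53)
        counts = rng.integers(1, 6, size=(4, 4)) * (rng.random((4, 4)) < 0.6)
        counts[counts.sum(axis=1) == 0, 0] = 1
        counts[0, counts.sum(axis=0) == 0] = 1
        net = make_network(counts)
        W, ids = _adjacency(net)
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1), 0.0)
        dist = dijkstra(lengths, directed=False)
        ours = weighted_closeness(net).weighted_closeness
        for i, sid in enumerate(ids):
            finite = np.isfinite(dist[i]) & (np.arange(len(ids)) != i)
            expected = finite.sum() / dist[i][finite].sum() if finite.any() else 0.0
            assert ours[sid] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Specialisation d'
# ---------------------------------------------------------------------------


class TestDprime:
    def test_proportional_use_is_zero(self):
        # every plant uses partners exactly proportionally to availability
        counts = np.outer([4, 2, 2], [3, 2, 1])
        net = make_network(counts)
        d = specialisation_dprime(net).d_prime
        for p in net.plant_ids:
            assert d[p] == pytest.approx(0.0, abs=1e-12)

    def test_exclusive_specialist_is_one(self):
        # p3 places all its interactions on a partner nobody else uses, so its
        # raw divergence reaches d_max = ln(m / A_i)
        counts = np.array([[6, 6, 0], [6, 6, 0], [0, 0, 4]])
        net = make_network(counts)
        row = counts[2] / counts[2].sum()
        q = counts.sum(axis=0) / counts.sum()
        d_raw = sum(p * math.log(p / qq) for p, qq in zip(row, q) if p > 0)
        assert d_raw == pytest.approx(math.log(counts.sum() / counts[2].sum()))
        assert specialisation_dprime(net).d_prime["p3"] == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        counts = np.array([[4, 1, 1], [1, 4, 1], [1, 1, 4]])
        net = make_network(counts)
        d = specialisation_dprime(net).d_prime
        expected_rows = dprime_oracle(counts)
        expected_cols = dprime_oracle(counts.T)
        for i, p in enumerate(net.plant_ids):
            assert d[p] == pytest.approx(expected_rows[i], abs=1e-12)
        for k, a in enumerate(net.pollinator_ids):
            assert d[a] == pytest.approx(expected_cols[k], abs=1e-12)

    def test_zero_total_species_errors(self):
        with pytest.raises(Exception):
            specialisation_dprime(make_network([[1, 0], [0, 0]]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(factor=st.integers(min_value=2, max_value=7))
    def test_invariant_to_integer_scaling(self, factor):
        # d and d_max are exactly scale-invariant; d_min is computed on an
        # integer allocation whose granularity changes with the total, so the
        # standardized index is invariant only up to that discretisation
        counts = np.array([[5, 2, 0], [1, 3, 2], [0, 1, 6]])
        base = specialisation_dprime(make_network(counts)).d_prime
        scaled = specialisation_dprime(make_network(counts * factor)).d_prime
        for s in base:
            assert scaled[s] == pytest.approx(base[s], abs=0.02)
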