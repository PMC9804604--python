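"""Structure and centrality metrics used as persistence predictors.

Network level: NODF nestedness on the binary incidence matrix, and weighted
Newman–Girvan modularity with module detection by simulated annealing of the
spin-glass objective (at resolution 1 the two coincide).  Species level:
weighted closeness centrality on the bipartite graph, and the
Kullback–Leibler specialisation index d' comparing each species' partner-use
distribution with partner availability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import InteractionNetwork

__all__ = [
    "StructureMetrics",
    "SpeciesMetrics",
    "AnnealingConfig",
    "nodf",
    "modularity_q",
    "find_modules",
    "weighted_closeness",
    "specialisation_dprime",
    "species_metrics",
]


@dataclass
class StructureMetrics:
    """Network-level structure: NODF (0–100) and the best modularity found."""

    nodf: float
    modularity_q: float
    partition: dict[str, int]
    n_modules: int
    final_epoch_accepts: int = 0
    converged: bool = True


@dataclass
class SpeciesMetrics:
    """Species-level centrality: weighted closeness and specialisation d'."""

    weighted_closeness: dict[str, float] = field(default_factory=dict)
    d_prime: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# NODF nestedness
# ---------------------------------------------------------------------------


def _nodf_axis(binary: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap terms over all unordered row pairs of ``binary``.

    For a pair with strictly decreasing fill (the fuller row first), the term
    is the fraction of the sparser row's partners shared with the fuller row;
    equal fills contribute zero.
    """
    fills = binary.sum(axis=1)
    overlap = binary @ binary.T
    n = binary.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if fills[i] == fills[j]:
                continue
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            total += overlap[hi, lo] / fills[lo]
    return total, n * (n - 1) // 2


def nodf(net: InteractionNetwork) -> float:
    """NODF nestedness (0–100) of the presence/absence incidence matrix.

    NODF is 100 times the mean paired-overlap term over all row pairs and
    all column pairs, with the "decreasing fill" rule: a pair contributes
    only when one species' partner count strictly exceeds the other's.
    """
    binary = net.binary().astype(np.float64)
    if binary.shape[0] < 2 or binary.shape[1] < 2:
        raise ValueError("NODF requires at least 2 plants and 2 pollinators")
    if np.any(binary.sum(axis=1) == 0) or np.any(binary.sum(axis=0) == 0):
        raise ValueError("NODF undefined with all-zero rows or columns")
    row_sum, row_pairs = _nodf_axis(binary)
    col_sum, col_pairs = _nodf_axis(binary.T)
    return 100.0 * (row_sum + col_sum) / (row_pairs + col_pairs)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------


def _adjacency(net: InteractionNetwork) -> tuple[np.ndarray, list[str]]:
    """Symmetric weighted adjacency of the bipartite graph (counts)."""
    n_p, n_a = net.n_plants, net.n_pollinators
    n = n_p + n_a
    W = np.zeros((n, n))
    W[:n_p, n_p:] = net.counts
    W[n_p:, :n_p] = net.counts.T
    return W, list(net.species_ids())


def _q_from_labels(W: np.ndarray, labels: np.ndarray) -> float:
    two_m = W.sum()
    k = W.sum(axis=1)
    B = W - np.outer(k, k) / two_m
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum() / two_m)


def modularity_q(net: InteractionNetwork, partition: dict[str, int]) -> float:
    """Weighted Newman–Girvan modularity Q of a given partition.

    The bipartite network is treated as a unipartite weighted graph whose
    edge weights are the interaction counts:
    ``Q = (1/2m) sum_ij [w_ij - k_i k_j / 2m] delta(c_i, c_j)``.
    """
    W, ids = _adjacency(net)
    unknown = set(partition) - set(ids)
    if unknown:
        raise ValueError(f"partition labels unknown species: {sorted(unknown)}")
    missing = set(ids) - set(partition)
    if missing:
        raise ValueError(f"partition misses species: {sorted(missing)}")
    labels = np.array([partition[s] for s in ids])
    return _q_from_labels(W, labels)


@dataclass(frozen=True)
class AnnealingConfig:
    """Simulated-annealing schedule for module detection.

    Geometric cooling from ``t_start`` to ``t_min`` by factor ``cooling``,
    with ``proposals_per_node * n`` single-node relabel proposals per
    temperature; defaults are sized so that exhaustive-search optima are
    recovered on small (<= 10 species) graphs.
    """

    t_start: float = 1.0
    cooling: float = 0.99
    proposals_per_node: int = 50
    t_min: float = 1e-3


def find_modules(
    net: InteractionNetwork,
    annealing_cfg: AnnealingConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> StructureMetrics:
    """Detect modules by simulated annealing of the modularity objective.

    The spin-glass community objective at resolution 1 coincides with
    Newman–Girvan Q, which is what the Metropolis scheme maximises here:
    random singleton start, proposal = relabel one node (into any existing
    or empty module slot), acceptance ``min(1, exp(dQ / T))``, geometric
    cooling.  Reproducible given ``rng``.
    """
    cfg = annealing_cfg or AnnealingConfig()
    rng = np.random.default_rng(rng)
    W, ids = _adjacency(net)
    n = len(ids)
    if n == 0:
        raise ValueError("empty network")
    two_m = W.sum()
    if two_m == 0:
        raise ValueError("network has no interactions")
    m = two_m / 2.0
    k = W.sum(axis=1)
    neighbors = [np.nonzero(W[i])[0] for i in range(n)]
    nbr_weights = [W[i, neighbors[i]] for i in range(n)]

    labels = np.arange(n)
    sigma = k.copy()  # total degree per module label
    q = _q_from_labels(W, labels)
    best_q = q
    best_labels = labels.copy()

    temperature = cfg.t_start
    proposals = cfg.proposals_per_node * n
    accepts = 0
    while temperature > cfg.t_min:
        nodes = rng.integers(0, n, size=proposals)
        slots = rng.integers(0, n, size=proposals)
        # mostly adopt a random neighbour's label (merges communities along
        # edges); sometimes a uniform slot, which can split one off
        guided = rng.random(size=proposals) < 0.9
        us = rng.random(size=proposals)
        accepts = 0
        for i, slot, guide, u in zip(nodes, slots, guided, us):
            a = labels[i]
            nbrs = neighbors[i]
            if guide and nbrs.size:
                b = labels[nbrs[slot % nbrs.size]]
            else:
                b = slot
            if a == b:
                continue
            w_ia = 0.0
            w_ib = 0.0
            for j, w in zip(neighbors[i], nbr_weights[i]):
                lj = labels[j]
                if lj == a:
                    w_ia += w
                elif lj == b:
                    w_ib += w
            dq = (w_ib - w_ia) / m - k[i] * (sigma[b] - (sigma[a] - k[i])) / (
                2.0 * m * m
            )
            if dq >= 0 or u < math.exp(dq / temperature):
                labels[i] = b
                sigma[a] -= k[i]
                sigma[b] += k[i]
                q += dq
                accepts += 1
                if q > best_q:
                    best_q = q
                    best_labels = labels.copy()
        temperature *= cfg.cooling
    # chain counts as frozen (converged) when the last epoch accepted no move
    converged = accepts == 0
    # canonical relabelling (modules numbered by first appearance) and an
    # exact Q recomputation to shed accumulated float drift
    canon: dict[int, int] = {}
    final = np.array([canon.setdefault(lab, len(canon)) for lab in best_labels])
    q_exact = _q_from_labels(W, final)
    partition = {s: int(c) for s, c in zip(ids, final)}
    try:
        nodf_value = nodf(net)
    except ValueError:
        warnings.warn("NODF undefined for this network; recording NaN", stacklevel=2)
        nodf_value = float("nan")
    return StructureMetrics(
        nodf=nodf_value,
        modularity_q=q_exact,
        partition=partition,
        n_modules=int(final.max()) + 1,
        final_epoch_accepts=int(accepts),
        converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# Weighted closeness
# ---------------------------------------------------------------------------


def weighted_closeness(net: InteractionNetwork) -> SpeciesMetrics:
    """Shortest-path closeness on the bipartite graph, edge length 1/count.

    Stronger interactions are shorter edges, so species connected through
    high-frequency interaction chains are more central.  For species *i* in a
    component of ``n`` species, ``C(i) = (n - 1) / sum_j dist(i, j)``;
    isolated species score 0.  Values are raw here; per-network max-rescaling
    happens downstream when analysis tables are exported.
    """
    g = net.to_graph()
    for _u, _v, data in g.edges(data=True):
        data["length"] = 1.0 / data["weight"]
    closeness: dict[str, float] = {}
    for component in nx.connected_components(g):
        comp_n = len(component)
        for node in component:
            if comp_n == 1:
                closeness[node] = 0.0
                continue
            dists = nx.single_source_dijkstra_path_length(g, node, weight="length")
            total = sum(dists[v] for v in component)
            closeness[node] = (comp_n - 1) / total
    return SpeciesMetrics(weighted_closeness=closeness)


# ---------------------------------------------------------------------------
# Specialisation d'
# ---------------------------------------------------------------------------


def _largest_remainder_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` events proportional to weights ``q``."""
    quota = total * q / q.sum()
    alloc = np.floor(quota).astype(np.int64)
    remainder = total - int(alloc.sum())
    if remainder > 0:
        frac = quota - alloc
        # ties resolved toward lower index: stable argsort on -frac
        order = np.argsort(-frac, kind="stable")
        alloc[order[:remainder]] += 1
    return alloc


def _d_value(a: np.ndarray, q: np.ndarray) -> float:
    """KL divergence of use proportions a/sum(a) from availability q."""
    total = a.sum()
    mask = a > 0
    p = a[mask] / total
    return float(np.sum(p * np.log(p / q[mask])))


def _dprime_axis(counts: np.ndarray) -> np.ndarray:
    """d' for each row of ``counts`` against column availability."""
    m = counts.sum()
    if m <= 0:
        raise ValueError("d' requires a positive interaction total")
    q = counts.sum(axis=0) / m
    out = np.empty(counts.shape[0])
    for i, row in enumerate(counts):
        A_i = row.sum()
        if A_i == 0:
            raise ValueError("d' undefined for a species with zero interactions")
        d = _d_value(row.astype(float), q)
        d_max = math.log(m / A_i)
        d_min = _d_value(
            _largest_remainder_allocation(int(A_i), q).astype(float), q
        )
        if d_max - d_min <= 0:
            out[i] = 0.0
        else:
            out[i] = min(1.0, max(0.0, (d - d_min) / (d_max - d_min)))
    return out


def specialisation_dprime(net: InteractionNetwork) -> SpeciesMetrics:
    """Standardised specialisation d' in [0, 1] for every species.

    For species *i* with partner-use proportions ``p_ij = a_ij / A_i`` and
    partner availability ``q_j = A_j / m``, the raw index is the KL
    divergence ``d_i = sum_j p_ij ln(p_ij / q_j)``.  It is standardised as
    ``(d - d_min) / (d_max - d_min)`` with ``d_max = ln(m / A_i)`` and
    ``d_min`` the divergence of the most generalised achievable integer
    distribution (largest-remainder allocation of ``A_i`` events
    proportional to availability), then clamped to [0, 1].
    """
    counts = net.counts.astype(np.float64)
    d_p = _dprime_axis(counts)
    d_a = _dprime_axis(counts.T)
    values = {s: float(v) for s, v in zip(net.plant_ids, d_p)}
    values.update({s: float(v) for s, v in zip(net.pollinator_ids, d_a)})
    return SpeciesMetrics(d_prime=values)


def species_metrics(net: InteractionNetwork) -> SpeciesMetrics:
    """Convenience: closeness and d' combined in one object."""
    out = weighted_closeness(net)
    out.d_prime = specialisation_dprime(net).d_prime
    return out
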