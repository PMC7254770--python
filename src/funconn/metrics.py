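"""Weighted graph topological properties of functional networks.

Conventions (fixed across the package):

- Edge length for shortest paths is the inverse weight 1/w: a stronger
  correlation is a shorter functional distance.
- Weighted clustering uses the geometric-mean-of-triangle-weights form with
  weights rescaled by the graph maximum, so values lie in [0, 1].
- Disconnected pairs have d = inf; they contribute 0 to efficiencies, and the
  characteristic path length averages finite distances only, with the number
  of unreachable pairs reported alongside.
- Small-worldness sigma = gamma / lambda, where gamma = Cp / Cp_rand and
  lambda = Lp / Lp_rand against degree- and weight-preserving rewired nulls.
- Hierarchy beta is the power-law exponent of clustering against degree,
  c ~ k^(-beta), estimated by least squares on log-log scale over nodes with
  degree >= 2 and positive clustering.
- Assortativity is the Pearson correlation of endpoint degrees over edges
  (each undirected edge counted in both orientations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .construction import WeightedNetwork

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "nodal_metrics",
    "global_metrics",
    "rewire_null",
    "NODAL_METRIC_NAMES",
    "GLOBAL_METRIC_NAMES",
]

NODAL_METRIC_NAMES = (
    "strength",
    "clustering",
    "shortest_path_length",
    "global_efficiency",
    "local_efficiency",
)
GLOBAL_METRIC_NAMES = (
    "network_strength",
    "clustering_coefficient",
    "shortest_path_length",
    "small_worldness",
    "global_efficiency",
    "local_efficiency",
    "hierarchy",
    "assortativity",
)


@dataclass(frozen=True)
class NodalMetrics:
    """The five per-region properties (arrays aligned with region_labels)."""

    region_labels: tuple[str, ...]
    strength: np.ndarray = field(repr=False)
    clustering: np.ndarray = field(repr=False)
    shortest_path_length: np.ndarray = field(repr=False)
    global_efficiency: np.ndarray = field(repr=False)
    local_efficiency: np.ndarray = field(repr=False)
    n_unreachable_pairs: int = 0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODAL_METRIC_NAMES}


@dataclass(frozen=True)
class GlobalMetrics:
    """The eight whole-network properties.

    ``small_worldness`` = gamma / lambda exactly; undefined quantities
    (e.g. sigma without nulls, hierarchy on a near-empty graph) are NaN.
    """

    network_strength: float
    clustering_coefficient: float
    shortest_path_length: float
    small_worldness: float
    gamma: float
    lambda_: float
    global_efficiency: float
    local_efficiency: float
    hierarchy: float
    assortativity: float
    n_null: int = 0
    null_seed: int | None = None
    n_unreachable_pairs: int = 0
    hierarchy_excluded_nodes: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLOBAL_METRIC_NAMES}


def _check_nonnegative(net: WeightedNetwork) -> None:
    if np.any(net.weights < 0):
        raise ValueError(
            "negative edge weights: graph metrics require a nonnegative "
            "network (use the 'positive' or 'absolute' negative-edge policy)"
        )


def _distance_matrix(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances on edge lengths 1/w (inf if none)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def _weighted_clustering(weights: np.ndarray) -> np.ndarray:
    """Geometric-mean triangle clustering, weights scaled by the graph max."""
    wmax = weights.max()
    if wmax <= 0:
        return np.zeros(weights.shape[0])
    w13 = np.cbrt(weights / wmax)
    cycles = np.diag(w13 @ w13 @ w13)
    k = (weights > 0).sum(axis=1)
    denominator = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denominator > 0, cycles / denominator, 0.0)
    return c


def _pair_efficiency(dist: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def nodal_metrics(net: WeightedNetwork) -> NodalMetrics:
    """Strength, clustering, path length, and both efficiencies per region.

    Isolated nodes get strength, efficiencies and clustering of 0; their
    shortest path length is NaN (no finite distances to average).
    """
    _check_nonnegative(net)
    w = net.weights
    n = w.shape[0]
    strength = w.sum(axis=1)
    clustering = _weighted_clustering(w)
    dist = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    inv = _pair_efficiency(dist)
    e_glob = inv.sum(axis=1) / max(n - 1, 1)
    finite = np.isfinite(dist) & off
    with np.errstate(invalid="ignore"):
        lengths = np.where(finite, dist, np.nan)
        counts = finite.sum(axis=1)
        spl = np.where(counts > 0, np.nansum(lengths, axis=1) / counts, np.nan)
    unreachable = int((~np.isfinite(dist) & off).sum() // 2)

    adjacency = w > 0
    e_loc = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adjacency[i])[0]
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        sub_dist = _distance_matrix(sub)
        sub_inv = _pair_efficiency(sub_dist)
        m = nbrs.size
        e_loc[i] = sub_inv[~np.eye(m, dtype=bool)].mean()

    return NodalMetrics(
        region_labels=net.region_labels,
        strength=strength,
        clustering=clustering,
        shortest_path_length=spl,
        global_efficiency=e_glob,
        local_efficiency=e_loc,
        n_unreachable_pairs=unreachable,
    )


def _hierarchy(net: WeightedNetwork, clustering: np.ndarray) -> tuple[float, int]:
    k = net.degrees.astype(float)
    mask = (k >= 2) & (clustering > 0)
    excluded = int((~mask).sum())
    if mask.sum() < 2 or np.ptp(k[mask]) == 0:
        # fewer than two usable nodes, or a regular graph: slope undefined
        return np.nan, excluded
    slope = np.polyfit(np.log(k[mask]), np.log(clustering[mask]), 1)[0]
    return float(-slope), excluded  # sign convention: c ~ k^(-beta)


def _assortativity(net: WeightedNetwork) -> float:
    i, j, _ = net.edge_arrays()
    if i.size < 2:
        return np.nan
    k = net.degrees.astype(float)
    x = np.concatenate([k[i], k[j]])
    y = np.concatenate([k[j], k[i]])
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _cp_lp(net: WeightedNetwork) -> tuple[float, float]:
    """Mean clustering and mean nodal path length (nulls need only these)."""
    c = _weighted_clustering(net.weights)
    dist = _distance_matrix(net.weights)
    n = net.n_regions
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        lengths = np.where(finite, dist, np.nan)
        spl = np.where(counts > 0, np.nansum(lengths, axis=1) / counts, np.nan)
    return float(c.mean()), float(np.nanmean(spl))


def global_metrics(
    net: WeightedNetwork,
    n_null: int = 100,
    seed: int = 0,
    null_networks: list[WeightedNetwork] | None = None,
) -> GlobalMetrics:
    """The eight global properties, with sigma normalized against nulls.

    ``null_networks`` overrides the internally generated rewired ensemble
    (useful for identity-null checks); otherwise ``n_null`` Maslov-Sneppen
    rewired surrogates seeded from ``seed`` are used.
    """
    _check_nonnegative(net)
    nodal = nodal_metrics(net)
    n = net.n_regions
    off = ~np.eye(n, dtype=bool)
    dist = _distance_matrix(net.weights)
    inv = _pair_efficiency(dist)
    e_glob = float(inv[off].mean()) if n > 1 else 0.0
    cp = float(nodal.clustering.mean())
    lp = float(np.nanmean(nodal.shortest_path_length))

    if null_networks is None and net.n_edges >= 2 and n_null >= 1:
        rng = np.random.default_rng(seed)
        null_networks = [
            rewire_null(net, seed=int(rng.integers(2**31)))
            for _ in range(n_null)
        ]
    if null_networks:
        cps, lps = zip(*(_cp_lp(g) for g in null_networks))
        cp_rand, lp_rand = float(np.mean(cps)), float(np.nanmean(lps))
        gamma = cp / cp_rand if cp_rand > 0 else np.nan
        lam = lp / lp_rand if lp_rand > 0 else np.nan
        sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else np.nan
        n_used = len(null_networks)
    else:
        gamma = lam = sigma = np.nan
        n_used = 0

    hierarchy, excluded = _hierarchy(net, nodal.clustering)
    return GlobalMetrics(
        network_strength=float(nodal.strength.mean()),
        clustering_coefficient=cp,
        shortest_path_length=lp,
        small_worldness=sigma,
        gamma=gamma,
        lambda_=lam,
        global_efficiency=e_glob,
        local_efficiency=float(nodal.local_efficiency.mean()),
        hierarchy=hierarchy,
        assortativity=_assortativity(net),
        n_null=n_used,
        null_seed=seed,
        n_unreachable_pairs=nodal.n_unreachable_pairs,
        hierarchy_excluded_nodes=excluded,
    )


def rewire_null(
    net: WeightedNetwork, seed: int = 0, swap_factor: int = 10
) -> WeightedNetwork:
    """Degree-preserving Maslov-Sneppen rewiring carrying edge weights.

    Attempts ``swap_factor * |E|`` double-edge swaps; each accepted swap
    replaces edges (a, b), (c, d) by (a, d), (c, b), moving the weights with
    their original edges.  The binary degree sequence is preserved exactly
    and the weight multiset is unchanged.  Connectedness is not enforced.
    The number of accepted swaps is recorded in provenance.
    """
    rng = np.random.default_rng(seed)
    i, j, w = net.edge_arrays()
    m = i.size
    if m < 2:
        return WeightedNetwork(net.weights.copy(), net.region_labels,
                               {**net.provenance, "null_swaps": 0})
    u = list(i)
    v = list(j)
    weights = list(w)
    existing = {(a, b) for a, b in zip(u, v)} | {(b, a) for a, b in zip(u, v)}
    accepted = 0
    attempts = swap_factor * m
    for _ in range(attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if (a, d) in existing or (c, b) in existing:
            continue
        for pair in ((a, b), (b, a), (c, d), (d, c)):
            existing.discard(pair)
        u[e1], v[e1] = a, d
        u[e2], v[e2] = c, b
        existing |= {(a, d), (d, a), (c, b), (b, c)}
        accepted += 1
    out = np.zeros_like(net.weights)
    for a, b, wt in zip(u, v, weights):
        out[a, b] = out[b, a] = wt
    return WeightedNetwork(out, net.region_labels,
                           {**net.provenance, "null_swaps": accepted,
                            "null_seed": seed})
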