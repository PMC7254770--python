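"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive relaxation for shortest
paths, triple enumeration for clustering, per-edge scans, and explicit
pair enumeration for the AUC.  None of it shares code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_shortest_paths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances on lengths 1/w by exhaustive relaxation."""
    n = weights.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                dist[i, j] = 1.0 / weights[i, j]
    for _ in range(n):  # n rounds of full relaxation reach a fixed point
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    if dist[i, k] + dist[k, j] < dist[i, j]:
                        dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_clustering(weights: np.ndarray) -> np.ndarray:
    """Geometric-mean triangle clustering with weights scaled by the max."""
    n = weights.shape[0]
    wmax = weights.max()
    out = np.zeros(n)
    if wmax <= 0:
        return out
    scaled = weights / wmax
    for i in range(n):
        k = int((weights[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (scaled[i, j] * scaled[j, h] * scaled[h, i]) ** (1 / 3)
        out[i] = total / (k * (k - 1))
    return out


def brute_global_efficiency_from(dist: np.ndarray) -> float:
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1)) if n > 1 else 0.0


def brute_nodal(weights: np.ndarray) -> dict[str, np.ndarray]:
    """All five nodal metrics, brute force."""
    n = weights.shape[0]
    dist = brute_shortest_paths(weights)
    strength = weights.sum(axis=1)
    clustering = brute_clustering(weights)
    spl = np.full(n, np.nan)
    e_glob = np.zeros(n)
    e_loc = np.zeros(n)
    for i in range(n):
        finite = [dist[i, j] for j in range(n)
                  if j != i and np.isfinite(dist[i, j])]
        if finite:
            spl[i] = float(np.mean(finite))
        e_glob[i] = sum(1.0 / dist[i, j] for j in range(n)
                        if j != i and np.isfinite(dist[i, j])
                        and dist[i, j] > 0) / (n - 1)
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) >= 2:
            sub = weights[np.ix_(nbrs, nbrs)]
            e_loc[i] = brute_global_efficiency_from(brute_shortest_paths(sub))
    return {
        "strength": strength,
        "clustering": clustering,
        "shortest_path_length": spl,
        "global_efficiency": e_glob,
        "local_efficiency": e_loc,
    }


def brute_rich_club_phi(weights: np.ndarray, k: int) -> float:
    """Weighted rich-club coefficient at level k by direct enumeration."""
    n = weights.shape[0]
    degrees = (weights > 0).sum(axis=1)
    members = [i for i in range(n) if degrees[i] > k]
    if len(members) < 2:
        return np.nan
    club_weights = [weights[a, b] for ai, a in enumerate(members)
                    for b in members[ai + 1:] if weights[a, b] > 0]
    if not club_weights:
        return np.nan
    all_weights = sorted(
        (weights[i, j] for i in range(n) for j in range(i + 1, n)
         if weights[i, j] > 0),
        reverse=True)
    return sum(club_weights) / sum(all_weights[:len(club_weights)])


def brute_class_summaries(weights: np.ndarray, labels, hub_set):
    """Per-edge class and per-class summaries by an exhaustive edge scan."""
    n = weights.shape[0]
    summaries = {cls: {"strength": 0.0, "degree": 0.0}
                 for cls in ("rich_club", "feeder", "local")}
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] <= 0:
                continue
            ends = (labels[i] in hub_set) + (labels[j] in hub_set)
            cls = {2: "rich_club", 1: "feeder", 0: "local"}[ends]
            summaries[cls]["strength"] += weights[i, j]
            summaries[cls]["degree"] += 1
    for cls, s in summaries.items():
        s["average_strength"] = (s["strength"] / s["degree"]
                                 if s["degree"] else np.nan)
    return summaries


def brute_auc(scores, labels, positive="B") -> float:
    """Concordance AUC by explicit pair enumeration, ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_pooled_t(a, b) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t and its two-sided p."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
        / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def brute_pearson(x, y) -> float:
    """Sum-formula Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) \
        * np.sqrt(n * (y * y).sum() - y.sum() ** 2)
    return float(num / den)


def random_network(n: int, density: float, rng: np.random.Generator,
                   labels=None):
    """Random symmetric nonnegative weighted network for oracle tests."""
    from funconn.construction import WeightedNetwork

    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
    labels = labels or tuple(f"R{k:02d}" for k in range(n))
    return WeightedNetwork(w, labels)
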