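"""Group-level statistics: metric comparisons, NBS, covariate correlations.

Global network properties and connection-class summaries are compared by
two-sample t-tests (pooled variance by default, Welch optional) without
multiplicity adjustment; nodal properties are corrected per metric family by
Benjamini-Hochberg FDR (q = 0.05 by default).  The network-based statistic
(NBS) controls family-wise error over connected components of suprathreshold
edges: edgewise two-sample t-tests are thresholded at an uncorrected primary
alpha (0.001 by default) and each observed component's link count is referred
to a permutation null distribution of the maximal component size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .construction import WeightedNetwork
from .metrics import (GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, GlobalMetrics,
                      NodalMetrics)

__all__ = [
    "NBSComponent",
    "NBSResult",
    "compare_global",
    "compare_nodal",
    "nbs",
    "correlate_metrics",
    "compare_connection_classes",
    "mann_whitney",
    "chi_square",
]

NBS_TAILS = ("b_greater", "a_greater", "two_sided")


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t along axis 0; NaN where undefined."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var,
                              nan_policy="omit")
    return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)


def _comparison_frame(
    a: pd.DataFrame, b: pd.DataFrame, equal_var: bool
) -> pd.DataFrame:
    """t-test per column of two aligned subject x measure frames."""
    t, p = _two_sample_t(a.to_numpy(float), b.to_numpy(float), equal_var)
    return pd.DataFrame({
        "mean_a": a.mean(axis=0),
        "sd_a": a.std(axis=0, ddof=1),
        "mean_b": b.mean(axis=0),
        "sd_b": b.std(axis=0, ddof=1),
        "t": t,
        "p": p,
    }, index=a.columns)


def global_metrics_frame(metrics: list[GlobalMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in metrics])


def compare_global(
    group_a: list[GlobalMetrics],
    group_b: list[GlobalMetrics],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t per global property, uncorrected (alpha = 0.05).

    Metrics undefined in every subject of both groups (e.g. sigma without
    nulls) yield NaN statistics and are flagged non-significant.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    table = _comparison_frame(global_metrics_frame(group_a),
                              global_metrics_frame(group_b), equal_var)
    table["p_adjusted"] = table["p"]
    table["significant"] = table["p"] < 0.05
    table.attrs["adjustment"] = "none"
    table.index.name = "metric"
    return table


def nodal_metrics_frame(metrics: list[NodalMetrics]) -> pd.DataFrame:
    """Subjects x (metric, region) frame with a two-level column index."""
    rows = []
    for m in metrics:
        row = {}
        for name in NODAL_METRIC_NAMES:
            for lab, value in zip(m.region_labels, getattr(m, name)):
                row[(name, lab)] = value
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["metric", "region"])
    return frame


def compare_nodal(
    group_a: list[NodalMetrics],
    group_b: list[NodalMetrics],
    q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-region t-tests with Benjamini-Hochberg FDR within each metric family.

    The step-up correction is applied separately to each of the five nodal
    metric families (one family = all regions of one metric).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    table = _comparison_frame(nodal_metrics_frame(group_a),
                              nodal_metrics_frame(group_b), equal_var)
    table["p_adjusted"] = np.nan
    table["significant"] = False
    for metric in NODAL_METRIC_NAMES:
        family = table.loc[metric]
        valid = family["p"].notna()
        if valid.any():
            reject, p_adj, _, _ = multipletests(
                family.loc[valid, "p"], alpha=q, method="fdr_bh")
            table.loc[(metric, family.index[valid]), "p_adjusted"] = p_adj
            table.loc[(metric, family.index[valid]), "significant"] = reject
    table.attrs["adjustment"] = "fdr_bh"
    table.attrs["q"] = q
    return table


@dataclass(frozen=True)
class NBSComponent:
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    size_in_links: int
    corrected_p: float
    edge_t: tuple[float, ...] = ()


@dataclass(frozen=True)
class NBSResult:
    """Edgewise statistics plus component-level permutation inference."""

    region_labels: tuple[str, ...]
    t_matrix: np.ndarray = field(repr=False)
    p_matrix: np.ndarray = field(repr=False)
    primary_alpha: float
    tail: str
    components: tuple[NBSComponent, ...]
    null_max_sizes: np.ndarray = field(repr=False)
    n_permutations: int
    seed: int

    @property
    def significant_components(self) -> tuple[NBSComponent, ...]:
        return tuple(c for c in self.components if c.corrected_p < 0.05)


def _edge_matrix(networks: list[WeightedNetwork]) -> tuple[np.ndarray, tuple]:
    labels = networks[0].region_labels
    n = len(labels)
    iu = np.triu_indices(n, 1)
    rows = []
    for net in networks:
        if net.region_labels != labels:
            raise ValueError("all networks must share the same region ordering")
        rows.append(net.weights[iu])
    return np.vstack(rows), iu


def _pooled_t(x: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance t of (mean_B - mean_A) per column; NaN where undefined."""
    na = int(is_a.sum())
    nb = x.shape[0] - na
    sum_a = is_a @ x
    ssq_a = is_a @ (x * x)
    total = x.sum(axis=0)
    total_sq = (x * x).sum(axis=0)
    mean_a = sum_a / na
    mean_b = (total - sum_a) / nb
    ss_a = ssq_a - sum_a**2 / na
    ss_b = (total_sq - ssq_a) - (total - sum_a)**2 / nb
    df = na + nb - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = (ss_a + ss_b) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = (mean_b - mean_a) / se
    return t


def _max_component_size(edge_idx: np.ndarray, iu: tuple) -> int:
    """Largest connected component (in links) among the given edges."""
    if edge_idx.size == 0:
        return 0
    parents: dict[int, int] = {}

    def find(x: int) -> int:
        while parents[x] != x:
            parents[x] = parents[parents[x]]
            x = parents[x]
        return x

    counts: dict[int, int] = {}
    for e in edge_idx:
        a, b = int(iu[0][e]), int(iu[1][e])
        for node in (a, b):
            parents.setdefault(node, node)
        ra, rb = find(a), find(b)
        if ra != rb:
            parents[rb] = ra
    for e in edge_idx:
        root = find(int(iu[0][e]))
        counts[root] = counts.get(root, 0) + 1
    return max(counts.values())


def _components(edge_idx: np.ndarray, iu: tuple, labels, t_values):
    """Maximal connected components of the suprathreshold edge set."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if edge_idx.size == 0:
        return []
    n = len(labels)
    i = iu[0][edge_idx]
    j = iu[1][edge_idx]
    adj = coo_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    _, member = connected_components(adj + adj.T, directed=False)
    comps = []
    for comp_id in np.unique(member[np.concatenate([i, j])]):
        mask = member[i] == comp_id
        nodes = np.unique(np.concatenate([i[mask], j[mask]]))
        comps.append({
            "nodes": tuple(labels[k] for k in nodes),
            "edges": tuple((labels[a], labels[b])
                           for a, b in zip(i[mask], j[mask])),
            "edge_t": tuple(float(t) for t in t_values[edge_idx[mask]]),
            "size": int(mask.sum()),
        })
    comps.sort(key=lambda c: -c["size"])
    return comps


def nbs(
    group_a: list[WeightedNetwork],
    group_b: list[WeightedNetwork],
    primary_alpha: float = 0.001,
    n_permutations: int = 5000,
    seed: int = 0,
    tail: str = "b_greater",
    batch_size: int = 500,
) -> NBSResult:
    """Network-based statistic with a maximal-component permutation null.

    Edgewise pooled two-sample t-tests on weights (absent edges contribute
    weight 0) are thresholded at the uncorrected ``primary_alpha``;
    ``tail`` selects the contrast: "b_greater" (default, group B > group A),
    "a_greater", or "two_sided".  Per permutation of group labels the maximal
    suprathreshold component size (number of links) is recorded, and each
    observed component gets corrected p = (1 + #{null >= observed}) /
    (1 + n_permutations).
    """
    if not 0.0 < primary_alpha < 1.0:
        raise ValueError("primary_alpha must lie in (0, 1)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    if tail not in NBS_TAILS:
        raise ValueError(f"tail must be one of {NBS_TAILS}")
    x, iu = _edge_matrix(group_a + group_b)
    labels = group_a[0].region_labels
    n = len(labels)
    na, nb = len(group_a), len(group_b)
    df = na + nb - 2
    if df < 1:
        raise ValueError("need at least 3 subjects in total")
    is_a = np.zeros(na + nb)
    is_a[:na] = 1.0

    t_obs = _pooled_t(x, is_a)
    if tail == "two_sided":
        t_crit = stats.t.ppf(1.0 - primary_alpha / 2.0, df)
        exceed = np.abs(t_obs) > t_crit
        p_obs = 2.0 * stats.t.sf(np.abs(t_obs), df)
    else:
        t_crit = stats.t.ppf(1.0 - primary_alpha, df)
        signed = t_obs if tail == "b_greater" else -t_obs
        exceed = signed > t_crit
        p_obs = stats.t.sf(signed, df)
    exceed &= np.isfinite(t_obs)
    supra = np.nonzero(exceed)[0]

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations, dtype=int)
    done = 0
    while done < n_permutations:
        size = min(batch_size, n_permutations - done)
        order = np.argsort(rng.random((size, na + nb)), axis=1)
        p_mask = np.zeros((size, na + nb))
        np.put_along_axis(p_mask, order[:, :na], 1.0, axis=1)
        sum_a = p_mask @ x
        ssq_a = p_mask @ (x * x)
        total = x.sum(axis=0)
        total_sq = (x * x).sum(axis=0)
        mean_a = sum_a / na
        mean_b = (total - sum_a) / nb
        ss_a = ssq_a - sum_a**2 / na
        ss_b = (total_sq - ssq_a) - (total - sum_a)**2 / nb
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt((ss_a + ss_b) / df * (1.0 / na + 1.0 / nb))
            t_null = (mean_b - mean_a) / se
        if tail == "two_sided":
            exceed_null = np.abs(t_null) > t_crit
        elif tail == "b_greater":
            exceed_null = t_null > t_crit
        else:
            exceed_null = -t_null > t_crit
        exceed_null &= np.isfinite(t_null)
        for row in range(size):
            null_max[done + row] = _max_component_size(
                np.nonzero(exceed_null[row])[0], iu)
        done += size

    comps = _components(supra, iu, labels, t_obs)
    components = tuple(
        NBSComponent(
            nodes=c["nodes"],
            edges=c["edges"],
            edge_t=c["edge_t"],
            size_in_links=c["size"],
            corrected_p=float(
                (1 + int((null_max >= c["size"]).sum()))
                / (1 + n_permutations)
            ),
        )
        for c in comps
    )
    t_matrix = np.zeros((n, n))
    p_matrix = np.ones((n, n))
    t_matrix[iu] = np.nan_to_num(t_obs)
    p_matrix[iu] = np.where(np.isfinite(p_obs), p_obs, 1.0)
    t_matrix += t_matrix.T
    p_matrix = np.minimum(p_matrix, p_matrix.T)
    np.fill_diagonal(p_matrix, 1.0)
    return NBSResult(
        region_labels=labels,
        t_matrix=t_matrix,
        p_matrix=p_matrix,
        primary_alpha=primary_alpha,
        tail=tail,
        components=components,
        null_max_sizes=null_max,
        n_permutations=n_permutations,
        seed=seed,
    )


def correlate_metrics(
    metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise-complete Pearson r between metric and covariate columns.

    Subjects are aligned by index; rows with a missing value in either
    member of a pair are dropped, and a pair with fewer than 3 complete
    observations is flagged missing (NaN r and p).
    """
    rows = []
    for metric_col, cov_col in pairs:
        if metric_col not in metrics.columns:
            raise KeyError(f"unknown metric column {metric_col!r}")
        if cov_col not in covariates.columns:
            raise KeyError(f"unknown covariate column {cov_col!r}")
        sub = pd.concat(
            [metrics[metric_col], covariates[cov_col]], axis=1, join="inner"
        ).dropna()
        n_used = len(sub)
        if n_used < 3:
            rows.append((metric_col, cov_col, np.nan, np.nan, n_used))
            continue
        r, p = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
        rows.append((metric_col, cov_col, float(r), float(p), n_used))
    return pd.DataFrame(rows, columns=["metric", "covariate", "r", "p", "n"])


def compare_connection_classes(
    summaries_a: list[dict[str, dict[str, float]]],
    summaries_b: list[dict[str, dict[str, float]]],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t per (class, measure) on per-subject class summaries.

    Input format matches :class:`ConnectionClassSummary.summaries`: one dict
    per subject, class -> {strength, degree, average_strength}.
    """
    def frame(summaries):
        rows = []
        for s in summaries:
            rows.append({(cls, measure): s[cls][measure]
                         for cls in s for measure in s[cls]})
        f = pd.DataFrame(rows)
        f.columns = pd.MultiIndex.from_tuples(f.columns,
                                              names=["class", "measure"])
        return f

    table = _comparison_frame(frame(summaries_a), frame(summaries_b),
                              equal_var)
    table["p_adjusted"] = table["p"]
    table["significant"] = table["p"] < 0.05
    table.attrs["adjustment"] = "none"
    return table


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (demographics utility)."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chi_square(table) -> tuple[float, float]:
    """Chi-squared test of independence on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table))
    return float(res.statistic), float(res.pvalue)
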