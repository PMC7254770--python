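"""Per-subject functional network construction.

Edges are Pearson correlations between regional mean time series; an edge is
retained only when its two-sided correlation-test p-value survives Bonferroni
correction over all region pairs (alpha = 0.05 over N(N-1)/2 tests by
default, i.e. 4005 tests for a 90-region atlas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synthetic import TimeSeriesMatrix

__all__ = [
    "ConnectivityMatrix",
    "WeightedNetwork",
    "correlation_matrix",
    "threshold_network",
]

NEGATIVE_EDGE_POLICIES = ("positive", "absolute", "keep-signed")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson r matrix with per-pair two-sided test p-values."""

    r: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    n_timepoints: int
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, float)
        p = np.asarray(self.p, float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
        n = len(self.region_labels)
        if r.shape != (n, n) or p.shape != (n, n):
            raise ValueError("r and p must be square and match the label count")
        if not np.allclose(r, r.T, equal_nan=True):
            raise ValueError("r must be symmetric")
        if np.nanmax(np.abs(r)) > 1.0 + 1e-12:
            raise ValueError("|r| must not exceed 1")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass(frozen=True)
class WeightedNetwork:
    """Thresholded weighted graph: symmetric weights, zero diagonal.

    ``adjacency`` is derived (nonzero weight = edge).  Weights are nonnegative
    under the default thresholding policies; the "keep-signed" policy may
    produce negative weights, which the metric stages reject explicitly.
    """

    weights: np.ndarray = field(repr=False)
    region_labels: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        n = len(self.region_labels)
        if w.shape != (n, n):
            raise ValueError("weights must be square and match the label count")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("weight diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights != 0.0).astype(int)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle edges as (i, j, weight) index arrays."""
        i, j = np.nonzero(np.triu(self.weights, 1))
        return i, j, self.weights[i, j]


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation of regional series with two-sided test p-values.

    p-values come from the exact null distribution of r under bivariate
    normality, ``t = r * sqrt(df / (1 - r^2))`` with df = T - 2, equivalent
    to the textbook two-sided t-test.
    """
    values = ts.values
    if values.shape[0] < 3:
        raise ValueError("need at least 3 time points to test correlations")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.region_labels[k] for k in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance region(s): {', '.join(bad)}")
    r = np.corrcoef(values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = values.shape[0] - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, np.nan)  # self-correlation: undefined, ignored
    return ConnectivityMatrix(r=r, p=p, n_timepoints=values.shape[0],
                              region_labels=ts.region_labels)


def connectivity_from_r(
    r: np.ndarray, region_labels: tuple[str, ...], n_timepoints: int
) -> ConnectivityMatrix:
    """Wrap a precomputed correlation matrix; p-values re-derived from r.

    Supports workflows that start from stored correlation matrices rather
    than raw time series; ``n_timepoints`` is required to form the p-values.
    """
    r = np.clip(np.asarray(r, float), -1.0, 1.0)
    df = n_timepoints - 2
    if df < 1:
        raise ValueError("n_timepoints must be at least 3")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, np.nan)
    return ConnectivityMatrix(r=r, p=p, n_timepoints=n_timepoints,
                              region_labels=tuple(region_labels))


def threshold_network(
    C: ConnectivityMatrix,
    alpha: float = 0.05,
    n_tests: int | None = None,
    policy: str = "positive",
) -> WeightedNetwork:
    """Bonferroni edge retention: keep edge (i, j) iff p_ij < alpha / n_tests.

    ``n_tests`` defaults to the full pair count N(N-1)/2 regardless of how
    many pairs are testable.  The negative-edge policy decides what happens
    to significant negative correlations:

    - ``"positive"`` (default): drop them, weight = r for positive edges;
    - ``"absolute"``: keep them with weight = |r|;
    - ``"keep-signed"``: keep them signed (metric stages reject such input).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if policy not in NEGATIVE_EDGE_POLICIES:
        raise ValueError(f"policy must be one of {NEGATIVE_EDGE_POLICIES}")
    n = C.n_regions
    if n_tests is None:
        n_tests = n * (n - 1) // 2
    per_edge = alpha / n_tests
    with np.errstate(invalid="ignore"):
        significant = C.p < per_edge
    np.fill_diagonal(significant, False)
    r = C.r
    if policy == "positive":
        w = np.where(significant & (r > 0), r, 0.0)
    elif policy == "absolute":
        w = np.where(significant, np.abs(r), 0.0)
    else:
        w = np.where(significant, r, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(
        weights=w,
        region_labels=C.region_labels,
        provenance={"alpha": alpha, "n_tests": n_tests,
                    "per_edge_threshold": per_edge, "policy": policy},
    )
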