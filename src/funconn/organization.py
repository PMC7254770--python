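"""Rich-club organization and Euclidean distance stratification of edges.

The weighted rich-club coefficient at degree level k is the ratio of the
total weight among nodes of degree > k to the sum of the equally many
strongest weights anywhere in the graph; values are normalized by the mean
coefficient of degree- and weight-preserving rewired surrogates.  Hubs are
the top fraction of regions by mean degree across all subjects (both groups
pooled), and every edge is classed as rich-club (hub-hub), feeder
(hub-nonhub) or local (nonhub-nonhub).

Connection distance is the straight-line mm distance between region
centroids, ``d_ij = sqrt((x_i-x_j)^2 + (y_i-y_j)^2 + (z_i-z_j)^2)``, binned
into three equal-width ranges between the shortest and longest possible
inter-centroid distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasDefinition
from .construction import WeightedNetwork
from .metrics import rewire_null

__all__ = [
    "RichClubProfile",
    "ConnectionClassSummary",
    "DistanceStratification",
    "rich_club_curve",
    "identify_hubs",
    "classify_connections",
    "distance_bins",
    "tercile_boundaries",
    "stratify_edges",
]

EDGE_CLASSES = ("rich_club", "feeder", "local")
DISTANCE_BINS = ("short", "medium", "long")


@dataclass(frozen=True)
class RichClubProfile:
    """Rich-club curve(s) indexed by degree level k = 1 .. max degree - 1.

    Undefined levels (fewer than 2 nodes above k, or no club edges) are NaN,
    never 0, so they cannot corrupt the normalized curve.
    """

    k_levels: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    phi_rand: np.ndarray | None = field(default=None, repr=False)
    phi_norm: np.ndarray | None = field(default=None, repr=False)
    n_null: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class ConnectionClassSummary:
    """Per-edge classes plus per-class strength / degree / average strength."""

    edge_index: tuple[tuple[int, int], ...]
    edge_class: tuple[str, ...]
    summaries: dict[str, dict[str, float]]
    hub_set: frozenset[str]


@dataclass(frozen=True)
class DistanceStratification:
    """Equal-width distance terciles over [d_min, d_max].

    Intervals: short = [d_min, b1], medium = (b1, b2], long = (b2, d_max].
    """

    d_min: float
    d_max: float
    boundaries: tuple[float, float]

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Bin labels for an array of distances (mm)."""
        b1, b2 = self.boundaries
        out = np.where(np.asarray(distances, float) <= b1, "short",
                       np.where(np.asarray(distances, float) <= b2,
                                "medium", "long"))
        return out


def rich_club_curve(
    net: WeightedNetwork,
    n_null: int = 100,
    seed: int = 0,
    null_networks: list[WeightedNetwork] | None = None,
) -> RichClubProfile:
    """Weighted rich-club coefficient with rewired-null normalization."""
    if np.any(net.weights < 0):
        raise ValueError("rich-club analysis requires nonnegative weights")
    k_max = int(net.degrees.max(initial=0))
    if net.n_edges == 0 or k_max < 2:
        empty = np.array([])
        return RichClubProfile(empty, empty, empty, empty, 0, seed)
    k_levels = np.arange(1, k_max)
    phi = _phi_weighted(net, k_levels)
    if null_networks is None and n_null >= 1:
        rng = np.random.default_rng(seed)
        null_networks = [rewire_null(net, seed=int(rng.integers(2**31)))
                         for _ in range(n_null)]
    if null_networks:
        null_phis = np.vstack([_phi_weighted(g, k_levels)
                               for g in null_networks])
        defined = (~np.isnan(null_phis)).sum(axis=0)
        sums = np.nansum(null_phis, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_rand = np.where(defined > 0, sums / defined, np.nan)
            phi_norm = np.where(phi_rand > 0, phi / phi_rand, np.nan)
        n_used = len(null_networks)
    else:
        phi_rand = phi_norm = None
        n_used = 0
    return RichClubProfile(k_levels, phi, phi_rand, phi_norm, n_used, seed)


def _phi_weighted(net: WeightedNetwork, k_levels: np.ndarray) -> np.ndarray:
    degrees = net.degrees
    _, _, all_w = net.edge_arrays()
    ranked = np.sort(all_w)[::-1]
    phi = np.full(k_levels.shape, np.nan)
    for idx, k in enumerate(k_levels):
        members = degrees > k
        if members.sum() < 2:
            continue
        club = net.weights[np.ix_(members, members)]
        iu = np.triu_indices(club.shape[0], 1)
        club_w = club[iu]
        m = int(np.count_nonzero(club_w))
        if m == 0:
            continue  # degenerate level: no club edges, stored missing
        phi[idx] = club_w.sum() / ranked[:m].sum()
    return phi


def identify_hubs(
    group_networks: list[WeightedNetwork],
    fraction: float = 0.15,
    ranking: str = "degree",
) -> tuple[tuple[str, ...], dict]:
    """Top-fraction regions by mean degree across all subjects (pooled).

    ``ranking`` may be "degree" (binary degree on the thresholded network;
    the default) or "strength".  The target count is ceil(fraction * N); ties
    at the boundary are all included and the inflation reported.
    Returns (hub labels in rank order, info dict).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if ranking not in {"degree", "strength"}:
        raise ValueError("ranking must be 'degree' or 'strength'")
    if not group_networks:
        raise ValueError("need at least one network")
    labels = group_networks[0].region_labels
    for net in group_networks:
        if net.region_labels != labels:
            raise ValueError("all networks must share the same region ordering")
    per_subject = np.vstack([
        net.degrees if ranking == "degree" else net.weights.sum(axis=1)
        for net in group_networks
    ]).astype(float)
    mean_rank = per_subject.mean(axis=0)
    n = len(labels)
    target = math.ceil(fraction * n)
    order = np.argsort(-mean_rank, kind="stable")
    cutoff = mean_rank[order[target - 1]]
    selected = [k for k in order if mean_rank[k] > cutoff]
    tied = [k for k in order if mean_rank[k] == cutoff]
    selected += tied
    info = {
        "target_count": target,
        "selected_count": len(selected),
        "tie_inflation": len(selected) - target,
        "ranking": ranking,
    }
    return tuple(labels[k] for k in selected), info


def classify_connections(
    net: WeightedNetwork, hub_set: set[str] | tuple[str, ...]
) -> ConnectionClassSummary:
    """Label every edge rich-club / feeder / local by endpoint hub membership.

    Per class: strength = sum of weights, degree = edge count, and
    average_strength = strength / degree (NaN when the class is empty).
    """
    hubs = frozenset(hub_set)
    unknown = hubs - set(net.region_labels)
    if unknown:
        raise ValueError(f"hub set names unknown regions: {sorted(unknown)}")
    is_hub = np.array([lab in hubs for lab in net.region_labels])
    i, j, w = net.edge_arrays()
    n_hub_ends = is_hub[i].astype(int) + is_hub[j].astype(int)
    classes = np.array(["local", "feeder", "rich_club"])[n_hub_ends]
    summaries = {}
    for cls in EDGE_CLASSES:
        mask = classes == cls
        count = int(mask.sum())
        strength = float(w[mask].sum())
        summaries[cls] = {
            "strength": strength,
            "degree": float(count),
            "average_strength": strength / count if count else np.nan,
        }
    return ConnectionClassSummary(
        edge_index=tuple(zip(i.tolist(), j.tolist())),
        edge_class=tuple(classes.tolist()),
        summaries=summaries,
        hub_set=hubs,
    )


def tercile_boundaries(d_min: float, d_max: float) -> tuple[float, float]:
    """Equal-width three-range boundaries between the distance extremes."""
    if not d_max > d_min >= 0:
        raise ValueError("need 0 <= d_min < d_max")
    step = (d_max - d_min) / 3.0
    return d_min + step, d_min + 2.0 * step


def distance_bins(atlas: AtlasDefinition) -> DistanceStratification:
    """Three equal distance ranges from the atlas's centroid geometry."""
    if atlas.n_regions < 2:
        raise ValueError("need at least 2 regions to define distance bins")
    d_min, d_max = atlas.pairwise_distance_range()
    b1, b2 = tercile_boundaries(d_min, d_max)
    return DistanceStratification(d_min=d_min, d_max=d_max, boundaries=(b1, b2))


def stratify_edges(
    edges: list[tuple[str, str]],
    atlas: AtlasDefinition,
    bins: DistanceStratification,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Assign each (label_i, label_j) edge a distance and a bin.

    Returns (distances_mm, bin_labels, proportions over the edge set).
    """
    dist_matrix = atlas.distance_matrix()
    distances = np.empty(len(edges))
    for k, (lab_i, lab_j) in enumerate(edges):
        distances[k] = dist_matrix[atlas.index_of(lab_i), atlas.index_of(lab_j)]
    bin_labels = bins.assign(distances)
    n = max(len(edges), 1)
    proportions = {b: float((bin_labels == b).sum()) / n for b in DISTANCE_BINS}
    return distances, bin_labels, proportions
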