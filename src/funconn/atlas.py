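"""Region atlases: labels and centroid coordinates of network nodes.

A functional connectome is defined on a fixed parcellation of the brain into
regions of interest (ROIs).  Analyses in this package only need two things
from the parcellation: an ordered list of unique region labels and one
stereotactic centroid (x, y, z, in mm) per region, used for Euclidean
connection-distance measures.  The atlas size is a parameter throughout —
a 3-region toy atlas is as valid as the default 90-region one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AtlasDefinition",
    "make_default_atlas",
    "read_atlas",
    "write_atlas",
    "default_communities",
]

#: Default mode network regions (base abbreviations, both hemispheres) used
#: by the default synthetic-cohort community structure.
DMN_BASES = frozenset(
    {"SFGmed", "ORBsupmed", "ACG", "PCG", "HIP", "PHG", "ANG", "PCUN",
     "MTG", "TPOsup"}
)


@dataclass(frozen=True)
class AtlasDefinition:
    """Ordered region labels plus one centroid per region.

    Invariants enforced at construction: labels unique, exactly one centroid
    per label, and all pairwise centroid distances strictly positive.
    """

    labels: tuple[str, ...]
    centroids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        centroids = np.asarray(self.centroids, dtype=float)
        object.__setattr__(self, "centroids", centroids)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        if centroids.shape != (len(self.labels), 3):
            raise ValueError(
                f"expected one (x, y, z) centroid per region: "
                f"{len(self.labels)} labels vs centroid array {centroids.shape}"
            )
        if not np.all(np.isfinite(centroids)):
            raise ValueError("centroid coordinates must be finite")
        if len(self.labels) >= 2 and pdist(centroids).min() <= 0.0:
            raise ValueError(
                "coincident centroids: zero pairwise distance between "
                "distinct regions"
            )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances in mm (symmetric, zero diag)."""
        return squareform(pdist(self.centroids))

    def pairwise_distance_range(self) -> tuple[float, float]:
        """(min, max) pairwise centroid distance in mm."""
        d = pdist(self.centroids)
        return float(d.min()), float(d.max())


def read_atlas(path: str | Path) -> AtlasDefinition:
    """Read an atlas from a tab-separated table with columns label, x, y, z."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise ValueError(f"atlas table {path} must have columns {sorted(required)}")
    return AtlasDefinition(
        labels=tuple(table["label"].astype(str)),
        centroids=table[["x", "y", "z"]].to_numpy(float),
    )


def write_atlas(atlas: AtlasDefinition, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"label": atlas.labels,
         "x": atlas.centroids[:, 0],
         "y": atlas.centroids[:, 1],
         "z": atlas.centroids[:, 2]}
    ).to_csv(path, sep="\t", index=False, float_format="%.2f")


def make_default_atlas() -> AtlasDefinition:
    """Bundled 90-region atlas (AAL-90 label scheme, synthetic centroids).

    The label set follows the standard 90-region automated anatomical
    labelling scheme (45 bilateral pairs, left before right).  The centroid
    coordinates are a synthetic stand-in: anatomically plausible, bilaterally
    mirrored MNI-like positions generated deterministically, NOT the
    published atlas table.  They support distance stratification of synthetic
    cohorts; analyses of real data should supply the genuine centroid table
    via :func:`read_atlas`.
    """
    ref = resources.files("funconn.data").joinpath("aal90_centroids_synthetic.tsv")
    with resources.as_file(ref) as path:
        return read_atlas(path)


def default_communities(atlas: AtlasDefinition) -> dict[str, str]:
    """Default community map for the synthetic cohort generator.

    Regions whose base abbreviation belongs to the default mode network get
    community ``"DMN"``; the remaining regions are split deterministically
    into three roughly equal communities by their atlas order.
    """
    labels = atlas.labels
    communities: dict[str, str] = {}
    rest = [lab for lab in labels if lab.split(".")[0] not in DMN_BASES]
    third = (len(rest) + 2) // 3
    for lab in labels:
        if lab.split(".")[0] in DMN_BASES:
            communities[lab] = "DMN"
        else:
            communities[lab] = f"C{rest.index(lab) // third + 1}"
    return communities
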