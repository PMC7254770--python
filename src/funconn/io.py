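"""Readers and writers for the package's plain-text interchange formats.

All tables are tab-separated with header rows; matrices carry region labels
as both header and index so downstream indexing is label-based, never
positional.  A cohort on disk is a subject manifest (subject_id, file,
group, covariate columns) plus one T x N time-series table per subject.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition
from .construction import WeightedNetwork
from .synthetic import TimeSeriesMatrix

__all__ = [
    "write_cohort",
    "read_subject_manifest",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "write_key_values",
    "read_key_values",
]

FLOAT_FORMAT = "%.10g"


def write_cohort(
    subjects: list[TimeSeriesMatrix],
    covariates: pd.DataFrame,
    directory: str | Path,
) -> Path:
    """Write per-subject series tables and the manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in subjects:
        filename = f"{subject.subject_id}_timeseries.tsv"
        frame = pd.DataFrame(subject.values, columns=subject.region_labels)
        frame.to_csv(directory / filename, sep="\t", index=False,
                     float_format=FLOAT_FORMAT)
        row = {"subject_id": subject.subject_id, "file": filename,
               "group": subject.group_label,
               "tr_seconds": subject.tr_seconds}
        rows.append(row)
    manifest = pd.DataFrame(rows)
    for column in covariates.columns:
        if column == "group":
            continue
        manifest[column] = covariates.loc[manifest["subject_id"],
                                          column].to_numpy()
    path = directory / "manifest.tsv"
    manifest.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def read_subject_manifest(
    path: str | Path, atlas: AtlasDefinition | None = None
) -> tuple[list[TimeSeriesMatrix], pd.DataFrame]:
    """Load a cohort from its manifest; validates shape against the atlas.

    Returns (subjects, covariate table indexed by subject_id, including the
    group column).  Errors identify the offending file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = pd.read_csv(path, sep="\t")
    required = {"subject_id", "file", "group"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    base = path.parent
    subjects = []
    for _, row in manifest.iterrows():
        series_path = base / str(row["file"])
        if not series_path.exists():
            raise FileNotFoundError(
                f"manifest entry {row['subject_id']}: missing file {series_path}")
        frame = pd.read_csv(series_path, sep="\t")
        if str(row["group"]) not in {"A", "B"}:
            raise ValueError(
                f"manifest entry {row['subject_id']}: unknown group "
                f"label {row['group']!r} (expected 'A' or 'B')")
        if atlas is not None:
            if tuple(frame.columns) != atlas.labels:
                raise ValueError(
                    f"{series_path}: {frame.shape[1]} regions do not match "
                    f"the {atlas.n_regions}-region atlas (or labels differ)")
        tr = float(row["tr_seconds"]) if "tr_seconds" in manifest.columns else 3.0
        subjects.append(TimeSeriesMatrix(
            subject_id=str(row["subject_id"]),
            group_label=str(row["group"]),
            values=frame.to_numpy(float),
            tr_seconds=tr,
            region_labels=tuple(frame.columns),
        ))
    covariates = manifest.drop(columns=["file", "tr_seconds"],
                               errors="ignore").set_index("subject_id")
    return subjects, covariates


def write_matrix(
    matrix: np.ndarray, labels: tuple[str, ...], path: str | Path
) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index_label="region")


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(float), tuple(frame.columns)


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """One undirected edge per line, lexicographic label order per edge."""
    i, j, w = net.edge_arrays()
    rows = []
    for a, b, weight in zip(i, j, w):
        la, lb = sorted((net.region_labels[a], net.region_labels[b]))
        rows.append((la, lb, weight))
    rows.sort()
    pd.DataFrame(rows, columns=["region_i", "region_j", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_key_values(values: dict, path: str | Path) -> None:
    """Machine-readable key-value text (one `key<TAB>value` per line)."""
    with open(path, "w") as fh:
        for key in values:
            value = values[key]
            if isinstance(value, float):
                value = FLOAT_FORMAT % value
            fh.write(f"{key}\t{value}\n")


def read_key_values(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = value
    return out
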