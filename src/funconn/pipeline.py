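"""End-to-end pipeline: simulate, construct, analyse, infer, classify.

Each stage reads the shared :class:`PipelineConfig`, writes plain-text
result tables into the output directory, and echoes the configuration hash
and seed into a config echo file.  Stage timings go to the run log; all
numeric outputs are deterministic functions of (config, seed), so reruns
with an identical config are byte-identical except for the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .atlas import make_default_atlas
from .classify import MKLConfig, build_features, mkl_svm_loocv
from .construction import correlation_matrix, threshold_network
from .inference import (compare_connection_classes, compare_global,
                        compare_nodal, correlate_metrics, nbs)
from .metrics import global_metrics, nodal_metrics
from .organization import (classify_connections, distance_bins,
                           identify_hubs, stratify_edges)
from .synthetic import default_cohort_spec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "config_hash", "ALL_STAGES"]

log = logging.getLogger("funconn")

ALL_STAGES = ("simulate", "construct", "metrics", "richclub", "distance",
              "nbs", "compare", "classify")


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold, seed and toggle of the pipeline in one place."""

    seed: int = 0
    output_dir: str = "funconn_results"
    stages: tuple[str, ...] = ALL_STAGES
    # cohort (demo-scale defaults; the study scale is 64 / 66 subjects)
    n_group_a: int = 12
    n_group_b: int = 12
    n_volumes: int = 197
    tr_seconds: float = 3.0
    input_manifest: str | None = None  # skip simulation, read this cohort
    # construction
    bonferroni_alpha: float = 0.05
    negative_edge_policy: str = "positive"
    # metrics / organization
    n_null: int = 10
    hub_fraction: float = 0.15
    hub_ranking: str = "degree"
    # inference
    fdr_q: float = 0.05
    nbs_primary_alpha: float = 0.001
    nbs_permutations: int = 500
    nbs_tail: str = "b_greater"
    # classification
    svm_C: float = 1.0
    selection_alpha: float = 0.001
    selection_mode: str = "per_fold"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        object.__setattr__(self, "stages", tuple(self.stages))

    def to_yaml(self, path: str | Path) -> None:
        """Write the semantic configuration (where results land is not part
        of what they are, so output_dir is omitted)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.semantic_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def semantic_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d.pop("output_dir")  # where results land does not change what they are
        return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.semantic_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the toggled stages; returns the output directory.

    Any stage error aborts with the stage named; outputs of completed stages
    are retained alongside a failure marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_echo.yaml")
    fio.write_key_values(
        {"config_hash": config_hash(config), "seed": config.seed},
        out / "run_info.txt")
    state: dict = {"atlas": make_default_atlas()}
    timings = []
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        start = time.perf_counter()
        try:
            _STAGES[stage](config, state, out)
        except Exception as exc:
            (out / "FAILED.txt").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        elapsed = time.perf_counter() - start
        timings.append((stage, elapsed))
        log.info("stage %s finished in %.2f s", stage, elapsed)
    with open(out / "run_log.txt", "w") as fh:
        for stage, elapsed in timings:
            fh.write(f"{stage}\t{elapsed:.3f}s\n")
    return out


def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> None:
    spec = default_cohort_spec(
        state["atlas"], n_group_a=config.n_group_a,
        n_group_b=config.n_group_b, seed=config.seed)
    spec = replace(spec, n_volumes=config.n_volumes,
                   tr_seconds=config.tr_seconds)
    subjects, covariates, info = generate_cohort(spec)
    state["subjects"], state["covariates"] = subjects, covariates
    if info["psd_projection_max_dev"] > 0:
        log.warning("latent matrix projected to PSD, max deviation %.3g",
                    info["psd_projection_max_dev"])
    fio.write_cohort(subjects, covariates, out / "cohort")


def _stage_construct(config: PipelineConfig, state: dict, out: Path) -> None:
    if "subjects" not in state:
        manifest = config.input_manifest
        if manifest is None:
            raise ValueError("no cohort: enable the simulate stage or set "
                             "input_manifest")
        state["subjects"], state["covariates"] = fio.read_subject_manifest(
            manifest, state["atlas"])
    networks = []
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for subject in state["subjects"]:
        net = threshold_network(
            correlation_matrix(subject),
            alpha=config.bonferroni_alpha,
            policy=config.negative_edge_policy)
        networks.append(net)
        fio.write_matrix(net.weights, net.region_labels,
                         net_dir / f"{subject.subject_id}_network.tsv")
    state["networks"] = networks
    state["groups"] = np.asarray([s.group_label for s in state["subjects"]])


def _split(state: dict, values: list):
    groups = state["groups"]
    return ([v for v, g in zip(values, groups) if g == "A"],
            [v for v, g in zip(values, groups) if g == "B"])


def _stage_metrics(config: PipelineConfig, state: dict, out: Path) -> None:
    rng = np.random.default_rng(config.seed + 1)
    nodal, global_ = [], []
    for net in state["networks"]:
        nodal.append(nodal_metrics(net))
        global_.append(global_metrics(net, n_null=config.n_null,
                                      seed=int(rng.integers(2**31))))
    state["nodal"], state["global"] = nodal, global_
    tidy_global = []
    tidy_nodal = []
    for subject, g, m in zip(state["subjects"], global_, nodal):
        for name, value in g.as_dict().items():
            tidy_global.append((subject.subject_id, name, value))
        for name, values in m.as_dict().items():
            for lab, value in zip(m.region_labels, values):
                tidy_nodal.append((subject.subject_id, lab, name, value))
    pd.DataFrame(tidy_global, columns=["subject", "metric", "value"]).to_csv(
        out / "global_metrics.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FORMAT)
    pd.DataFrame(tidy_nodal,
                 columns=["subject", "region", "metric", "value"]).to_csv(
        out / "nodal_metrics.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FORMAT)


def _stage_richclub(config: PipelineConfig, state: dict, out: Path) -> None:
    hubs, info = identify_hubs(state["networks"], config.hub_fraction,
                               config.hub_ranking)
    state["hubs"] = hubs
    pd.DataFrame({"hub": list(hubs)}).to_csv(out / "hubs.tsv", sep="\t",
                                             index=False)
    summaries = [classify_connections(net, hubs).summaries
                 for net in state["networks"]]
    state["class_summaries"] = summaries
    rows = []
    for subject, summary in zip(state["subjects"], summaries):
        for cls, measures in summary.items():
            for measure, value in measures.items():
                rows.append((subject.subject_id, cls, measure, value))
    pd.DataFrame(rows, columns=["subject", "class", "measure", "value"]).to_csv(
        out / "connection_classes.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FORMAT)
    fio.write_key_values(
        {"hub_count": len(hubs), "tie_inflation": info["tie_inflation"],
         "ranking": info["ranking"]}, out / "hub_info.txt")


def _stage_distance(config: PipelineConfig, state: dict, out: Path) -> None:
    bins = distance_bins(state["atlas"])
    state["distance_bins"] = bins
    fio.write_key_values(
        {"d_min_mm": bins.d_min, "d_max_mm": bins.d_max,
         "boundary_short_medium_mm": bins.boundaries[0],
         "boundary_medium_long_mm": bins.boundaries[1]},
        out / "distance_bins.txt")


def _stage_nbs(config: PipelineConfig, state: dict, out: Path) -> None:
    nets_a, nets_b = _split(state, state["networks"])
    result = nbs(nets_a, nets_b,
                 primary_alpha=config.nbs_primary_alpha,
                 n_permutations=config.nbs_permutations,
                 seed=config.seed + 2, tail=config.nbs_tail)
    state["nbs"] = result
    rows = []
    bins = state.get("distance_bins")
    atlas = state["atlas"]
    for idx, comp in enumerate(result.components):
        for (la, lb), t in zip(comp.edges, comp.edge_t):
            row = [idx, la, lb, t, comp.size_in_links, comp.corrected_p]
            if bins is not None:
                d, bin_label, _ = stratify_edges([(la, lb)], atlas, bins)
                row += [d[0], bin_label[0]]
            rows.append(row)
    columns = ["component", "region_i", "region_j", "t", "size_in_links",
               "corrected_p"]
    if bins is not None:
        columns += ["distance_mm", "distance_bin"]
    pd.DataFrame(rows, columns=columns).to_csv(
        out / "nbs_components.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FORMAT)
    fio.write_key_values(
        {"tail": result.tail, "primary_alpha": result.primary_alpha,
         "n_permutations": result.n_permutations,
         "n_components": len(result.components),
         "n_significant": len(result.significant_components)},
        out / "nbs_summary.txt")


def _stage_compare(config: PipelineConfig, state: dict, out: Path) -> None:
    global_a, global_b = _split(state, state["global"])
    nodal_a, nodal_b = _split(state, state["nodal"])
    compare_global(global_a, global_b).to_csv(
        out / "global_comparison.tsv", sep="\t",
        float_format=fio.FLOAT_FORMAT)
    compare_nodal(nodal_a, nodal_b, q=config.fdr_q).to_csv(
        out / "nodal_comparison.tsv", sep="\t", float_format=fio.FLOAT_FORMAT)
    if "class_summaries" in state:
        cls_a, cls_b = _split(state, state["class_summaries"])
        compare_connection_classes(cls_a, cls_b).to_csv(
            out / "class_comparison.tsv", sep="\t",
            float_format=fio.FLOAT_FORMAT)
    covariates = state.get("covariates")
    if covariates is not None:
        value_columns = [c for c in covariates.columns if c != "group"]
        if value_columns:
            metric_frame = pd.DataFrame(
                {"strength__" + lab: [m.strength[k] for m in state["nodal"]]
                 for k, lab in enumerate(state["networks"][0].region_labels)},
                index=[s.subject_id for s in state["subjects"]])
            pairs = [(m, c) for c in value_columns
                     for m in list(metric_frame.columns)[:4]]
            correlate_metrics(metric_frame, covariates, pairs).to_csv(
                out / "covariate_correlations.tsv", sep="\t", index=False,
                float_format=fio.FLOAT_FORMAT)


def _stage_classify(config: PipelineConfig, state: dict, out: Path) -> None:
    features = build_features(
        state["networks"], state["nodal"],
        labels=list(state["groups"]),
        subject_ids=[s.subject_id for s in state["subjects"]])
    report = mkl_svm_loocv(features, MKLConfig(
        C=config.svm_C, selection_alpha=config.selection_alpha,
        selection_mode=config.selection_mode, seed=config.seed + 3))
    fio.write_key_values(
        {"accuracy": report.accuracy, "sensitivity": report.sensitivity,
         "specificity": report.specificity, "auc": report.auc,
         "tp": report.tp, "tn": report.tn, "fp": report.fp, "fn": report.fn,
         "kernel_weight_connections": report.kernel_weights[0],
         "kernel_weight_nodal": report.kernel_weights[1]},
        out / "classification_summary.txt")
    pd.DataFrame({
        "subject": report.subject_ids,
        "label": report.labels,
        "prediction": report.predictions,
        "score": report.scores,
        "beta": report.fold_betas,
    }).to_csv(out / "classification_folds.tsv", sep="\t", index=False,
              float_format=fio.FLOAT_FORMAT)
    pd.DataFrame(report.roc_points,
                 columns=["one_minus_specificity", "sensitivity"]).to_csv(
        out / "roc_points.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FORMAT)
    freq_rows = []
    for fam, freq in report.selected_feature_frequency.items():
        names = (features.connection_names if fam == "connections"
                 else features.nodal_names)
        for name, f in zip(names, freq):
            if f > 0:
                freq_rows.append((fam, name, f))
    pd.DataFrame(freq_rows, columns=["family", "feature", "frequency"]).to_csv(
        out / "selected_features.tsv", sep="\t", index=False,
        float_format=fio.FLOAT_FORMAT)
    state["classification"] = report


_STAGES = {
    "simulate": _stage_simulate,
    "construct": _stage_construct,
    "metrics": _stage_metrics,
    "richclub": _stage_richclub,
    "distance": _stage_distance,
    "nbs": _stage_nbs,
    "compare": _stage_compare,
    "classify": _stage_classify,
}
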