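"""Simulation experiments that validate the pipeline against planted truth.

Each function here builds a synthetic cohort whose ground truth is known by
construction, runs the corresponding analysis stage from scratch, and
returns the measured quantity: family-wise error calibration and planted-
subnetwork recovery for the network-based statistic, planted-covariate
correlation recovery, the feeder/local-but-not-rich-club group-difference
pattern, and classifier sanity measurements.  The test suite and the
reproduction script both drive these entry points.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .atlas import make_default_atlas
from .classify import (MKLConfig, make_separable_feature_cohort,
                       mkl_svm_loocv)
from .construction import correlation_matrix, threshold_network
from .inference import compare_connection_classes, correlate_metrics, nbs
from .organization import classify_connections, identify_hubs
from .synthetic import (CohortSpec, CovariateModel, default_cohort_spec,
                        generate_cohort)

__all__ = [
    "nbs_null_calibration",
    "nbs_planted_recovery",
    "covariate_recovery",
    "class_difference_pattern",
    "separable_loocv_accuracy",
    "permuted_label_accuracy",
    "forced_beta_matches_single_kernel",
    "fusion_accuracy_gap",
    "pipeline_determinism",
]


def _networks(subjects):
    return [threshold_network(correlation_matrix(s)) for s in subjects]


def _null_spec(n_per_group: int, seed: int) -> CohortSpec:
    spec = default_cohort_spec(make_default_atlas(), n_group_a=n_per_group,
                               n_group_b=n_per_group, seed=seed)
    return replace(spec, planted_edges=(), covariate_models=())


def nbs_null_calibration(
    n_replicates: int = 200,
    n_per_group: int = 20,
    n_permutations: int = 500,
    primary_alpha: float = 0.001,
    seed: int = 0,
) -> dict:
    """Family-wise error of the NBS under the null (identical generators).

    Both groups are drawn from the same latent structure; a replicate counts
    as a family-wise error when any component reaches corrected p < 0.05.
    Returns the empirical FWE rate with its replicate count.
    """
    rng = np.random.default_rng(seed)
    errors = 0
    for _ in range(n_replicates):
        spec = _null_spec(n_per_group, seed=int(rng.integers(2**31)))
        subjects, _, _ = generate_cohort(spec)
        nets = _networks(subjects)
        result = nbs(nets[:n_per_group], nets[n_per_group:],
                     primary_alpha=primary_alpha,
                     n_permutations=n_permutations,
                     seed=int(rng.integers(2**31)))
        if result.significant_components:
            errors += 1
    return {"fwe_rate": errors / n_replicates, "errors": errors,
            "n_replicates": n_replicates}


PLANTED_CLIQUE = ("PHG.L", "PHG.R", "PCUN.L", "ANG.R", "MFG.L", "IPL.R")


def nbs_planted_recovery(
    n_seeds: int = 20,
    n_per_group: int = 30,
    delta: float = 0.3,
    n_permutations: int = 500,
    seed: int = 0,
) -> dict:
    """Edge-set recovery of a planted 6-node clique effect by the NBS.

    All 15 pairwise latent correlations of the clique are raised by ``delta``
    in group B; recovery is the Jaccard overlap between the largest
    significant component's edges and the planted edges, summarized as the
    median over independent cohort seeds.
    """
    clique_edges = [
        (PLANTED_CLIQUE[a], PLANTED_CLIQUE[b], delta)
        for a in range(len(PLANTED_CLIQUE))
        for b in range(a + 1, len(PLANTED_CLIQUE))
    ]
    planted = {frozenset((i, j)) for i, j, _ in clique_edges}
    rng = np.random.default_rng(seed)
    jaccards = []
    for _ in range(n_seeds):
        spec = replace(_null_spec(n_per_group, seed=int(rng.integers(2**31))),
                       planted_edges=tuple(clique_edges))
        subjects, _, _ = generate_cohort(spec)
        nets = _networks(subjects)
        result = nbs(nets[:n_per_group], nets[n_per_group:],
                     primary_alpha=0.001, n_permutations=n_permutations,
                     seed=int(rng.integers(2**31)))
        significant = result.significant_components
        if not significant:
            jaccards.append(0.0)
            continue
        largest = max(significant, key=lambda c: c.size_in_links)
        found = {frozenset(e) for e in largest.edges}
        jaccards.append(len(found & planted) / len(found | planted))
    return {"median_jaccard": float(np.median(jaccards)),
            "jaccards": jaccards, "n_seeds": n_seeds}


def covariate_recovery(
    n_subjects: int = 500,
    target_correlation: float = -0.671,
    target_region: str = "PHG.L",
    seed: int = 0,
) -> dict:
    """Recover a planted covariate-metric correlation from a large cohort.

    The generator plants a covariate correlated with the realized nodal
    strength of ``target_region``; the analysis then re-derives the metric
    from the generated series (threshold, strength) and measures the Pearson
    correlation, which should match the planted target.
    """
    import pandas as pd

    spec = default_cohort_spec(make_default_atlas(), n_group_a=1,
                               n_group_b=n_subjects, seed=seed)
    spec = replace(spec, planted_edges=(), covariate_models=(
        CovariateModel("planted_cov", "strength", target_region,
                       target_correlation, "B"),))
    subjects, covariates, _ = generate_cohort(spec)
    group_b = [s for s in subjects if s.group_label == "B"]
    idx = subjects[0].region_labels.index(target_region)
    strengths = pd.DataFrame(
        {"strength": [threshold_network(correlation_matrix(s))
                      .weights[idx].sum() for s in group_b]},
        index=[s.subject_id for s in group_b])
    table = correlate_metrics(strengths, covariates,
                              [("strength", "planted_cov")])
    row = table.iloc[0]
    return {"r": float(row["r"]), "p": float(row["p"]), "n": int(row["n"]),
            "target": target_correlation}


def _class_pattern_spec(n_per_group: int, delta: float, seed: int) -> tuple:
    """Cohort with a dominant hub community and planted feeder/local deltas.

    A 30-region community with high internal correlation dominates the degree
    ranking, so the pooled top-15% hub set lies inside it.  Baseline
    correlations sit far from the edge-retention boundary (0.55 within
    communities, 0.05 between), keeping class-strength summaries stable
    across subjects.  Group B receives correlation increments only on pairs
    with at least one periphery endpoint — feeder edges (hub endpoint
    selected) and local edges — never on hub-hub pairs, so the rich-club
    class carries no planted difference.
    """
    atlas = make_default_atlas()
    labels = atlas.labels
    hub_community = labels[:30]
    periphery = labels[30:]
    communities = {lab: "HUB" for lab in hub_community}
    for k, lab in enumerate(periphery):
        communities[lab] = f"P{k % 4}"
    planted = []
    # one increment per hub-community node and at most one planted edge per
    # periphery node: keeps every region's variance budget inside the PSD
    # cone and no periphery node gains enough degree to become a hub
    for k, hub_lab in enumerate(hub_community):
        planted.append((hub_lab, periphery[k], delta))
    # disjoint cross-community periphery pairs (local class by construction)
    for k in range(30, 45):
        planted.append((periphery[k], periphery[k + 15], delta))
    spec = CohortSpec(
        n_group_a=n_per_group,
        n_group_b=n_per_group,
        community_assignment=communities,
        base_within_community_corr=0.55,
        base_between_community_corr=0.05,
        planted_edges=tuple(planted),
        seed=seed,
    )
    return spec, hub_community


def class_difference_pattern(
    n_seeds: int = 20,
    n_per_group: int = 40,
    delta: float = 0.40,
    seed: int = 0,
) -> dict:
    """How often planted feeder/local effects produce the expected pattern.

    Per seed: generate the cohort, identify pooled hubs (top 15% by degree),
    classify connections, compare per-class strength between groups.  The
    expected pattern is feeder AND local strength significant (p < 0.05)
    with rich-club strength not significant.  Returns the fraction of seeds
    showing the pattern.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    details = []
    for _ in range(n_seeds):
        spec, hub_community = _class_pattern_spec(
            n_per_group, delta, seed=int(rng.integers(2**31)))
        subjects, _, _ = generate_cohort(spec)
        nets = _networks(subjects)
        hubs, _ = identify_hubs(nets, fraction=0.15)
        hubs_in_community = set(hubs) <= set(hub_community)
        summaries = [classify_connections(net, hubs).summaries
                     for net in nets]
        table = compare_connection_classes(summaries[:n_per_group],
                                           summaries[n_per_group:])
        sig = table["significant"]
        pattern = (bool(sig.loc[("feeder", "strength")])
                   and bool(sig.loc[("local", "strength")])
                   and not bool(sig.loc[("rich_club", "strength")]))
        hits += pattern
        details.append({"pattern": pattern,
                        "hubs_inside_hub_community": hubs_in_community})
    return {"pattern_rate": hits / n_seeds, "n_seeds": n_seeds,
            "details": details}


def separable_loocv_accuracy(seed: int = 0, n_per_group: int = 20) -> float:
    """LOOCV accuracy on a strongly separated Gaussian cohort (expect 1.0)."""
    features = make_separable_feature_cohort(
        n_per_group=n_per_group, separation=5.0, seed=seed)
    report = mkl_svm_loocv(features, MKLConfig(seed=seed))
    return report.accuracy


def permuted_label_accuracy(
    n_permutations: int = 50, seed: int = 0, n_per_group: int = 20
) -> dict:
    """Mean LOOCV accuracy with labels randomly permuted (chance band)."""
    features = make_separable_feature_cohort(
        n_per_group=n_per_group, separation=5.0, seed=seed)
    rng = np.random.default_rng(seed)
    labels = np.asarray(features.labels)
    accuracies = []
    for _ in range(n_permutations):
        permuted = tuple(rng.permutation(labels).tolist())
        shuffled = replace(features, labels=permuted)
        report = mkl_svm_loocv(shuffled, MKLConfig(seed=seed))
        accuracies.append(report.accuracy)
    return {"mean_accuracy": float(np.mean(accuracies)),
            "n_permutations": n_permutations}


def forced_beta_matches_single_kernel(seed: int = 0) -> bool:
    """Forcing beta = (1, 0) must reproduce the connections-only SVM."""
    features = make_separable_feature_cohort(n_per_group=12, separation=1.0,
                                             seed=seed)
    forced = mkl_svm_loocv(features, MKLConfig(forced_beta=1.0, seed=seed))
    single = mkl_svm_loocv(
        replace(features,
                nodal_features=np.zeros_like(features.nodal_features)),
        MKLConfig(forced_beta=1.0, seed=seed))
    return forced.predictions == single.predictions


def fusion_accuracy_gap(n_seeds: int = 5, seed: int = 0) -> dict:
    """Combined-kernel accuracy vs the best single family (both informative).

    Returns the median (over seeds) of combined minus best-single accuracy;
    fusion should not lose more than a small margin.
    """
    rng = np.random.default_rng(seed)
    gaps = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        features = make_separable_feature_cohort(
            n_per_group=15, separation=1.2, seed=s)
        combined = mkl_svm_loocv(features, MKLConfig(seed=s)).accuracy
        conn_only = mkl_svm_loocv(features,
                                  MKLConfig(forced_beta=1.0, seed=s)).accuracy
        nodal_only = mkl_svm_loocv(features,
                                   MKLConfig(forced_beta=0.0, seed=s)).accuracy
        gaps.append(combined - max(conn_only, nodal_only))
    return {"median_gap": float(np.median(gaps)), "gaps": gaps}


def pipeline_determinism(base_dir, seed: int = 0) -> dict:
    """Run the demo pipeline twice with one config; compare outputs byte-wise.

    The run log (stage timings) is excluded; every other file must match.
    """
    import filecmp
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    base_dir = Path(base_dir)
    outputs = []
    for name in ("run1", "run2"):
        config = PipelineConfig(
            seed=seed, output_dir=str(base_dir / name),
            n_group_a=8, n_group_b=8, n_null=5, nbs_permutations=100)
        outputs.append(run_pipeline(config))
    first, second = outputs
    mismatches = []
    for path in sorted(p for p in first.rglob("*") if p.is_file()):
        rel = path.relative_to(first)
        if rel.name == "run_log.txt":
            continue
        other = second / rel
        if not other.exists() or not filecmp.cmp(path, other, shallow=False):
            mismatches.append(str(rel))
    return {"identical": not mismatches, "mismatches": mismatches}
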