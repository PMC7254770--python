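"""Group classification with a two-kernel (MKL) linear SVM under LOOCV.

Feature families follow the connectome convention: one family of
N(N-1)/2 functional connections (upper-triangle vectorization of the
weighted network, 4005 features for 90 regions) and one family of 3N nodal
properties (strength, nodal global efficiency, nodal local efficiency; 270
features for 90 regions).  Within every leave-one-out fold, features are
selected by two-sample t-test (p < 0.001 by default) and z-scored on the
training subjects only; one linear kernel per family is fused as
K = beta * K_conn + (1 - beta) * K_nodal with beta chosen on the simplex by
inner cross-validation; a soft-margin SVM predicts the held-out subject.

Group B is the positive class throughout: sensitivity is the proportion of
group-B subjects correctly predicted, specificity the proportion of group-A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .construction import WeightedNetwork
from .metrics import NodalMetrics

__all__ = [
    "FeatureSet",
    "MKLConfig",
    "ClassificationReport",
    "build_features",
    "select_features",
    "mkl_svm_loocv",
    "confusion_metrics",
    "roc_auc",
    "vectorize_upper",
    "devectorize_upper",
    "make_separable_feature_cohort",
]

POSITIVE_LABEL = "B"


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle vectorization of a symmetric matrix."""
    n = matrix.shape[0]
    return matrix[np.triu_indices(n, 1)]


def devectorize_upper(vector: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (zero diagonal)."""
    out = np.zeros((n, n))
    out[np.triu_indices(n, 1)] = vector
    return out + out.T


@dataclass(frozen=True)
class FeatureSet:
    """Connection and nodal feature families for a set of subjects."""

    connection_features: np.ndarray = field(repr=False)
    nodal_features: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    subject_ids: tuple[str, ...]
    connection_names: tuple[str, ...]
    nodal_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if self.connection_features.shape[0] != n or \
                self.nodal_features.shape[0] != n:
            raise ValueError("feature matrices must have one row per subject")
        if len(self.labels) != n:
            raise ValueError("need one group label per subject")
        if self.connection_features.shape[1] != len(self.connection_names):
            raise ValueError("connection feature names misaligned")
        if self.nodal_features.shape[1] != len(self.nodal_names):
            raise ValueError("nodal feature names misaligned")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def families(self) -> dict[str, np.ndarray]:
        return {"connections": self.connection_features,
                "nodal": self.nodal_features}


def build_features(
    networks: list[WeightedNetwork],
    nodal: list[NodalMetrics],
    labels: list[str],
    subject_ids: list[str] | None = None,
) -> FeatureSet:
    """Vectorize networks and nodal metrics into the two feature families.

    Connection features are the upper-triangle weights in row-major pair
    order; nodal features are the blocks strength, global efficiency, local
    efficiency, in that order.
    """
    if not len(networks) == len(nodal) == len(labels):
        raise ValueError("networks, nodal metrics and labels must align")
    region_labels = networks[0].region_labels
    for net, m in zip(networks, nodal):
        if net.region_labels != region_labels or \
                m.region_labels != region_labels:
            raise ValueError("all subjects must share the same region ordering")
    iu = np.triu_indices(len(region_labels), 1)
    conn = np.vstack([net.weights[iu] for net in networks])
    nodal_x = np.vstack([
        np.concatenate([m.strength, m.global_efficiency, m.local_efficiency])
        for m in nodal
    ])
    conn_names = tuple(
        f"conn__{region_labels[a]}__{region_labels[b]}"
        for a, b in zip(*iu)
    )
    nodal_names = tuple(
        f"{block}__{lab}"
        for block in ("strength", "global_efficiency", "local_efficiency")
        for lab in region_labels
    )
    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        f"S{k + 1:03d}" for k in range(len(networks)))
    return FeatureSet(conn, nodal_x, tuple(labels), ids, conn_names,
                      nodal_names)


def select_features(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    alpha: float = 0.001,
) -> np.ndarray:
    """Boolean mask of features with two-sample t-test p < alpha.

    Computed on the supplied (training) subjects only.  Features constant in
    both classes are never selected.  If nothing survives, the single
    smallest-p feature is kept so that downstream folds always have input.
    """
    labels = np.asarray(train_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("feature selection needs exactly 2 classes present")
    a = train_features[labels == classes[0]]
    b = train_features[labels == classes[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0)
    p = np.asarray(res.pvalue, float)
    mask = np.where(np.isfinite(p), p < alpha, False)
    if not mask.any():
        finite = np.where(np.isfinite(p), p, np.inf)
        if np.isfinite(finite).any() and finite.min() < np.inf:
            mask[int(np.argmin(finite))] = True
        else:
            mask[0] = True  # fully degenerate input: keep one placeholder
    return mask


@dataclass(frozen=True)
class MKLConfig:
    """Hyperparameters of the LOOCV MKL-SVM pipeline."""

    C: float = 1.0
    selection_alpha: float = 0.001
    beta_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 11), 1))
    inner_folds: int = 5
    selection_mode: str = "per_fold"  # or "whole_sample" (select once, leaky)
    forced_beta: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_mode not in {"per_fold", "whole_sample"}:
            raise ValueError("selection_mode must be per_fold or whole_sample")


@dataclass(frozen=True)
class ClassificationReport:
    """LOOCV fold predictions, confusion counts, metrics and kernel weights."""

    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]
    predictions: tuple[str, ...]
    scores: tuple[float, ...]
    fold_betas: tuple[float, ...]
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: tuple[tuple[float, float], ...]
    auc: float
    kernel_weights: tuple[float, float]
    selected_feature_frequency: dict[str, np.ndarray]
    events: tuple[str, ...] = ()


def confusion_metrics(
    predictions, labels, positive: str = POSITIVE_LABEL
) -> dict[str, float]:
    """TP/TN/FP/FN counts and the accuracy / sensitivity / specificity ratios.

    accuracy = (TP + TN) / (TP + TN + FN + FP); sensitivity = TP / (TP + FN);
    specificity = TN / (FP + TN).  A metric whose class is absent is NaN.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    pos = labels == positive
    pred_pos = predictions == positive
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    n = tp + tn + fp + fn
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / n if n else np.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (fp + tn) if (fp + tn) else np.nan,
    }


def roc_auc(
    scores, labels, positive: str = POSITIVE_LABEL
) -> tuple[tuple[tuple[float, float], ...], float]:
    """ROC curve (1 - specificity, sensitivity) and trapezoid AUC.

    The threshold sweeps the unique scores; tied scores move the operating
    point jointly, so the trapezoid AUC equals the rank-statistic
    (tie-midpoint) AUC.  Constant scores give AUC 0.5 by convention.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    k = 0
    n = scores.size
    while k < n:
        threshold = sorted_scores[k]
        while k < n and sorted_scores[k] == threshold:
            if sorted_pos[k]:
                tp += 1
            else:
                fp += 1
            k += 1
        points.append((fp / n_neg, tp / n_pos))
    xs, ys = zip(*points)
    auc = float(np.trapezoid(ys, xs))
    return tuple(points), auc


def _family_kernel(
    x_train: np.ndarray, x_all: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Linear kernel on selected, train-standardized features, trace-normalized."""
    sel_train = x_train[:, mask]
    mean = sel_train.mean(axis=0)
    sd = sel_train.std(axis=0)
    sd[sd == 0] = 1.0
    z_all = (x_all[:, mask] - mean) / sd
    k = z_all @ z_all.T
    train_diag = np.einsum("ij,ij->i", (sel_train - mean) / sd,
                           (sel_train - mean) / sd).mean()
    if train_diag > 0:
        k = k / train_diag
    return k


def _inner_beta(
    kernels: dict[str, np.ndarray],
    train_idx: np.ndarray,
    y_train: np.ndarray,
    config: MKLConfig,
) -> float:
    """Choose beta (weight on the connection kernel) by inner stratified CV."""
    _, counts = np.unique(y_train, return_counts=True)
    n_splits = int(min(config.inner_folds, counts.min()))
    if n_splits < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=config.seed)
    best_beta, best_acc = 0.5, -1.0
    sub_kernels = {name: k[np.ix_(train_idx, train_idx)]
                   for name, k in kernels.items()}
    splits = list(skf.split(np.zeros(len(y_train)), y_train))
    for beta in config.beta_grid:
        combined = beta * sub_kernels["connections"] + \
            (1.0 - beta) * sub_kernels["nodal"]
        correct = 0
        total = 0
        for fit_idx, val_idx in splits:
            clf = SVC(C=config.C, kernel="precomputed")
            clf.fit(combined[np.ix_(fit_idx, fit_idx)], y_train[fit_idx])
            pred = clf.predict(combined[np.ix_(val_idx, fit_idx)])
            correct += int((pred == y_train[val_idx]).sum())
            total += len(val_idx)
        acc = correct / total
        # tie-break deterministically toward an even fusion
        if acc > best_acc + 1e-12 or (
            abs(acc - best_acc) <= 1e-12
            and abs(beta - 0.5) < abs(best_beta - 0.5)
        ):
            best_beta, best_acc = float(beta), acc
    return best_beta


def mkl_svm_loocv(
    features: FeatureSet, config: MKLConfig | None = None
) -> ClassificationReport:
    """Leave-one-out evaluation of the two-kernel SVM.

    Per fold: select features (t-test at ``selection_alpha``) and standardize
    on the training subjects only; build one linear kernel per family; choose
    the simplex weight beta by inner stratified CV on the training subjects
    (unless ``forced_beta`` is set); fit the soft-margin SVM and predict the
    held-out subject.  Aggregates confusion counts, the ratio metrics, the
    ROC/AUC over decision scores, mean kernel weights, and per-feature
    selection frequency.
    """
    config = config or MKLConfig()
    y = np.asarray(features.labels)
    n = features.n_subjects
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError("both classes need at least 2 subjects")
    families = features.families
    names = {"connections": features.connection_names,
             "nodal": features.nodal_names}
    sel_counts = {fam: np.zeros(x.shape[1]) for fam, x in families.items()}
    events: list[str] = []

    whole_masks = None
    if config.selection_mode == "whole_sample":
        whole_masks = {
            fam: select_features(x, y, config.selection_alpha)
            for fam, x in families.items()
        }

    predictions = []
    scores = []
    fold_betas = []
    for held in range(n):
        train_idx = np.array([k for k in range(n) if k != held])
        y_train = y[train_idx]
        kernels = {}
        for fam, x in families.items():
            mask = (whole_masks[fam] if whole_masks is not None
                    else select_features(x[train_idx], y_train,
                                         config.selection_alpha))
            sel_counts[fam] += mask
            if not np.any(x[train_idx][:, mask].std(axis=0) > 0):
                events.append(f"fold {held}: degenerate {fam} kernel")
            kernels[fam] = _family_kernel(x[train_idx], x, mask)
        if config.forced_beta is not None:
            beta = float(config.forced_beta)
        else:
            beta = _inner_beta(kernels, train_idx, y_train, config)
        combined = beta * kernels["connections"] + \
            (1.0 - beta) * kernels["nodal"]
        clf = SVC(C=config.C, kernel="precomputed")
        clf.fit(combined[np.ix_(train_idx, train_idx)], y_train)
        row = combined[np.ix_([held], train_idx)]
        predictions.append(str(clf.predict(row)[0]))
        # orient the decision score so larger = more positive-class evidence
        raw = float(clf.decision_function(row)[0])
        if tuple(clf.classes_)[-1] != POSITIVE_LABEL:
            raw = -raw
        scores.append(raw)
        fold_betas.append(beta)

    confusion = confusion_metrics(predictions, y)
    roc_points, auc = roc_auc(scores, y)
    return ClassificationReport(
        subject_ids=features.subject_ids,
        labels=tuple(y.tolist()),
        predictions=tuple(predictions),
        scores=tuple(scores),
        fold_betas=tuple(fold_betas),
        tp=confusion["tp"], tn=confusion["tn"],
        fp=confusion["fp"], fn=confusion["fn"],
        accuracy=confusion["accuracy"],
        sensitivity=confusion["sensitivity"],
        specificity=confusion["specificity"],
        roc_points=roc_points,
        auc=auc,
        kernel_weights=(float(np.mean(fold_betas)),
                        float(1.0 - np.mean(fold_betas))),
        selected_feature_frequency={
            fam: sel_counts[fam] / n for fam in sel_counts
        },
        events=tuple(events),
    )


def make_separable_feature_cohort(
    n_per_group: int = 20,
    n_connection_features: int = 45,
    n_nodal_features: int = 30,
    n_informative_connection: int = 6,
    n_informative_nodal: int = 4,
    separation: float = 5.0,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> FeatureSet:
    """Synthetic Gaussian feature cohort with planted class separation.

    Informative features differ between classes by ``separation`` pooled
    standard deviations (split across both families); all remaining features
    are pure noise.  ``separation = 0`` yields a null cohort.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    conn = rng.standard_normal((n, n_connection_features))
    nodal = rng.standard_normal((n, n_nodal_features))
    shift = np.zeros(n)
    shift[n_per_group:] = separation
    conn[:, :n_informative_connection] += shift[:, None]
    nodal[:, :n_informative_nodal] += shift[:, None]
    y = tuple([labels[0]] * n_per_group + [labels[1]] * n_per_group)
    ids = tuple(f"{g}{k + 1:03d}" for g in labels for k in range(n_per_group))
    return FeatureSet(
        connection_features=conn,
        nodal_features=nodal,
        labels=y,
        subject_ids=ids,
        connection_names=tuple(f"conn_f{k}" for k in range(n_connection_features)),
        nodal_names=tuple(f"nodal_f{k}" for k in range(n_nodal_features)),
    )

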