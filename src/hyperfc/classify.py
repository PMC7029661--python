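"""Multi-kernel SVM classification under leave-one-out cross-validation.

The two feature families (single-node and pairwise clustering coefficients)
each yield a centered linear kernel over subjects; the classifier uses their
convex combination k = a1*k1 + a2*k2 with a1 + a2 = 1, the mixing weight
found by grid search (step 0.1).  By default the weight is chosen by inner
leave-one-out accuracy on each training fold, which keeps the held-out
subject untouched; a post-hoc mode instead picks the weight whose
outer LOO accuracy is highest.  Features are z-scored and kernels centered
with training-fold statistics only.

Reported metrics (percent): accuracy, sensitivity (positive = patient
cohort), specificity, and balanced accuracy BAC = (sens + spec) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .comparison import select_features
from .metrics import FeatureTable

__all__ = [
    "MKLConfig",
    "ClassificationReport",
    "NoSignificantFeaturesError",
    "linear_kernel",
    "center_kernel",
    "combine_kernels",
    "classification_metrics",
    "balanced_accuracy",
    "loo_cv_classify",
]


class NoSignificantFeaturesError(RuntimeError):
    """Raised when a feature family has no significant features to classify on."""


@dataclass
class MKLConfig:
    weight_grid_step: float = 0.1
    svm_cost: float = 1.0
    n_repeats: int = 1
    rng_seed: int = 0
    weight_mode: str = "inner"  # "inner" (nested) or "outer" (post-hoc)

    def __post_init__(self) -> None:
        n_steps = 1.0 / self.weight_grid_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("weight_grid_step must divide 1 evenly")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")
        if self.weight_mode not in ("inner", "outer"):
            raise ValueError("weight_mode must be 'inner' or 'outer'")

    def weight_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.weight_grid_step))
        return np.linspace(0.0, 1.0, n + 1)


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    bac: float
    best_weights: tuple[float, float] | None = None
    predictions: np.ndarray | None = None
    repeat_accuracies: np.ndarray | None = None
    accuracy_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 2),
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "bac": round(self.bac, 2),
            "best_weights": self.best_weights,
            "accuracy_sd": round(self.accuracy_sd, 2),
        }


def linear_kernel(features: np.ndarray) -> np.ndarray:
    """Gram matrix of row inner products."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    return features @ features.T


def center_kernel(K: np.ndarray, train_idx: np.ndarray | None = None) -> np.ndarray:
    """Double-center a kernel in feature space.

    With ``train_idx`` given, means are computed over training rows/columns
    only, so test rows are centered with training statistics; without it the
    usual full double-centering K - 1K/n - K1/n + 1K1/n^2 is applied
    (idempotent: every row and column of the result sums to zero).
    """
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    idx = np.arange(K.shape[0]) if train_idx is None else np.asarray(train_idx)
    col_means = K[:, idx].mean(axis=1)  # mean over training subjects, per row
    row_means = K[idx, :].mean(axis=0)
    grand = K[np.ix_(idx, idx)].mean()
    return K - col_means[:, None] - row_means[None, :] + grand


def combine_kernels(kernels: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """Convex combination sum_i a_i K_i with nonnegative weights summing to 1."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
        raise ValueError("weights must be nonnegative and sum to 1")
    if len(kernels) != weights.size:
        raise ValueError("one weight per kernel")
    out = np.zeros_like(np.asarray(kernels[0], dtype=float))
    for w, K in zip(weights, kernels):
        if K.shape != out.shape:
            raise ValueError("kernels must share a shape")
        out += w * K
    return out


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive_label
) -> ClassificationReport:
    """Accuracy / sensitivity / specificity / BAC on the percent scale."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    pos = y_true == positive_label
    if pos.all() or not pos.any():
        raise ValueError("y_true must contain both classes")
    correct = y_true == y_pred
    sens = 100.0 * correct[pos].mean()
    spec = 100.0 * correct[~pos].mean()
    return ClassificationReport(
        accuracy=100.0 * correct.mean(),
        sensitivity=float(sens),
        specificity=float(spec),
        bac=balanced_accuracy(float(sens), float(spec)),
        predictions=y_pred,
    )


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """BAC, the mean of sensitivity and specificity (percent scale)."""
    return (sensitivity + specificity) / 2.0


def _zscore_train(features: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    mu = features[train_idx].mean(axis=0)
    sd = features[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    return (features - mu) / sd


def _fold_kernels(
    family_features: list[np.ndarray], train_idx: np.ndarray
) -> list[np.ndarray]:
    kernels = []
    for feats in family_features:
        K = linear_kernel(_zscore_train(feats, train_idx))
        kernels.append(center_kernel(K, train_idx))
    return kernels


def _loo_accuracy_precomputed(
    K: np.ndarray, y: np.ndarray, idx: np.ndarray, cost: float
) -> float:
    """LOO accuracy over the subjects in idx using the precomputed kernel."""
    correct = 0
    for i in range(idx.size):
        tr = np.delete(idx, i)
        te = idx[i : i + 1]
        if np.unique(y[tr]).size < 2:
            continue
        clf = SVC(kernel="precomputed", C=cost)
        clf.fit(K[np.ix_(tr, tr)], y[tr])
        correct += int(clf.predict(K[np.ix_(te, tr)])[0] == y[te][0])
    return correct / idx.size


def loo_cv_classify(
    table: FeatureTable,
    positive_label=None,
    config: MKLConfig | None = None,
    selection_scope: str = "nested",
    selection_mode: str = "asymptotic",
    selection_q: float = 0.05,
    n_permutations: int = 1000,
    families: tuple[str, ...] = ("hcc", "comhcc"),
    min_features_per_family: int = 1,
) -> ClassificationReport:
    """Leave-one-out multi-kernel SVM classification of a feature table.

    Per held-out subject: select significant features per family on the
    training rows (``selection_scope="nested"``; ``"global"`` selects once on
    all subjects), z-score with training statistics, build one centered
    linear kernel per family, choose the kernel weights on the weight grid,
    train an SVM on the combined training kernel, and predict the held-out
    subject.  With a single family the kernel weight is fixed at 1.

    Raises :class:`NoSignificantFeaturesError` when a family's selection is
    empty.  ``config.n_repeats`` repeats the procedure with fresh selection
    seeds and reports the mean accuracy (sd across repeats alongside); with
    deterministic selection the repeats coincide.
    """
    config = config or MKLConfig()
    y = np.asarray(table.labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two cohorts")
    if positive_label is None:
        positive_label = classes[-1]
    n = y.size
    if min((y == classes[0]).sum(), (y == classes[1]).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")

    blocks = {"hcc": table.hcc_block, "comhcc": table.comhcc_block}
    reports = []
    for rep in range(config.n_repeats):
        rep_seed = int(
            np.random.SeedSequence(
                entropy=config.rng_seed, spawn_key=(rep,)
            ).generate_state(1)[0]
        )
        preds = np.empty(n, dtype=y.dtype)
        weights_used = []

        def family_feats(train_idx: np.ndarray) -> list[np.ndarray]:
            if selection_scope == "global":
                sub = table
            else:
                sub = FeatureTable(
                    subjects=[table.subjects[i] for i in train_idx],
                    labels=y[train_idx],
                    values=table.values[train_idx],
                    n_nodes=table.n_nodes,
                )
            sel = select_features(
                sub,
                q=selection_q,
                mode=selection_mode,
                n_permutations=n_permutations,
                rng_seed=rep_seed,
            )
            feats = []
            for fam in families:
                cols = sel[fam].selected_indices
                if cols.size == 0:
                    if selection_scope == "global" or min_features_per_family == 0:
                        raise NoSignificantFeaturesError(
                            f"no significant {fam} features"
                            + ("" if selection_scope == "global" else " in this training fold")
                        )
                    # nested-CV fallback: a marginal training fold may pass
                    # nothing at q; keep the top-ranked features so the outer
                    # CV can proceed (documented, configurable)
                    cols = np.argsort(sel[fam].pvalues, kind="mergesort")[
                        :min_features_per_family
                    ]
                feats.append(blocks[fam][:, cols])
            return feats

        if selection_scope == "global":
            global_feats = family_feats(np.arange(n))

        if config.weight_mode == "outer":
            # post-hoc: evaluate each weight by full outer LOO, keep best
            grid = (
                config.weight_grid()
                if len(families) == 2
                else np.array([1.0])
            )
            best = None
            for a1 in grid:
                w = (a1, 1.0 - a1) if len(families) == 2 else (1.0,)
                p = np.empty(n, dtype=y.dtype)
                for i in range(n):
                    tr = np.delete(np.arange(n), i)
                    feats = global_feats if selection_scope == "global" else family_feats(tr)
                    Ks = _fold_kernels(feats, tr)
                    K = combine_kernels(Ks, w)
                    clf = SVC(kernel="precomputed", C=config.svm_cost)
                    clf.fit(K[np.ix_(tr, tr)], y[tr])
                    p[i] = clf.predict(K[i : i + 1, tr])[0]
                acc = (p == y).mean()
                if best is None or acc > best[0]:
                    best = (acc, w, p.copy())
            _, w, preds = best
            weights_used.append(w)
        else:
            for i in range(n):
                tr = np.delete(np.arange(n), i)
                feats = global_feats if selection_scope == "global" else family_feats(tr)
                Ks = _fold_kernels(feats, tr)
                if len(families) == 2:
                    grid = config.weight_grid()
                    best = None
                    for a1 in grid:
                        K = combine_kernels(Ks, (a1, 1.0 - a1))
                        acc = _loo_accuracy_precomputed(K, y, tr, config.svm_cost)
                        if best is None or acc > best[0]:
                            best = (acc, (a1, 1.0 - a1))
                    w = best[1]
                else:
                    w = (1.0,)
                weights_used.append(w)
                K = combine_kernels(Ks, w)
                clf = SVC(kernel="precomputed", C=config.svm_cost)
                clf.fit(K[np.ix_(tr, tr)], y[tr])
                preds[i] = clf.predict(K[i : i + 1, tr])[0]

        report = classification_metrics(y, preds, positive_label)
        report.best_weights = tuple(np.mean(np.atleast_2d(weights_used), axis=0))
        reports.append(report)

    accs = np.array([r.accuracy for r in reports])
    out = ClassificationReport(
        accuracy=float(accs.mean()),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        bac=float(np.mean([r.bac for r in reports])),
        best_weights=reports[0].best_weights,
        predictions=reports[0].predictions,
        repeat_accuracies=accs,
        accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
    )
    return out
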