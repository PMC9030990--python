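"""Workload-aware (narrow) utility: logistic-regression prediction fidelity.

The analytic workload is a prediction model for the designated outcome.
For each dataset (real or synthetic) a logistic regression — multinomial
when the outcome has more than two levels — is evaluated by stratified
3-fold cross-validation; discrimination is summarized by AUROC and AUPRC
on the pooled out-of-fold predictions.  Multicategory outcomes use the
average of pairwise two-class AUROCs (the Hand-and-Till construction) and
macro-averaged one-vs-rest AUPRC.  Narrow utility of a synthesizer is the
absolute difference in these scores between the real dataset's model and
the synthetic dataset's model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .tabular import Standardization, TabularDataset, encode, fit_standardization

__all__ = [
    "WorkloadScore",
    "binary_auroc",
    "multiclass_auroc",
    "multiclass_auprc",
    "cv_prediction_scores",
    "workload_difference",
]


@dataclass(frozen=True)
class WorkloadScore:
    """AUROC/AUPRC on real and synthetic models plus absolute differences."""

    auroc_real: float
    auroc_syn: float
    auprc_real: float
    auprc_syn: float
    dataset_name: str = ""
    method_name: str = ""
    replicate_index: int = 0

    @property
    def auroc_abs_diff(self) -> float:
        return abs(self.auroc_real - self.auroc_syn)

    @property
    def auprc_abs_diff(self) -> float:
        return abs(self.auprc_real - self.auprc_syn)


def binary_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Two-class AUROC as the Mann-Whitney concordance (ties count 1/2).

    ``labels`` are 0/1; ``scores`` are scores for the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    r = rankdata(scores, method="average")
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def multiclass_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average of pairwise AUROC values over all unordered class pairs.

    For a pair (i, j), the two-class AUROC is computed on the observations
    of those two classes, once with class i as positive using score column
    i and once with class j as positive, and the two are averaged (the
    Hand-and-Till pairwise measure).  Classes with zero observations are
    excluded from pairing with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.arange(scores.shape[1])
    present = [k for k in classes if (labels == k).any()]
    if len(present) < len(classes):
        warnings.warn("classes with no observations excluded from pairwise AUROC")
    if len(present) < 2:
        raise ValueError("need >= 2 observed classes")
    vals = []
    for i, j in combinations(present, 2):
        mask = (labels == i) | (labels == j)
        a_ij = binary_auroc(scores[mask, i], (labels[mask] == i))
        a_ji = binary_auroc(scores[mask, j], (labels[mask] == j))
        vals.append(0.5 * (a_ij + a_ji))
    return float(np.mean(vals))


def multiclass_auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUPRC (average precision) over classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.arange(scores.shape[1])
    present = [k for k in classes if (labels == k).any()]
    if len(present) < 2:
        raise ValueError("need >= 2 observed classes")
    if len(present) < len(classes):
        warnings.warn("classes with no observations excluded from macro AUPRC")
    vals = [average_precision_score((labels == k).astype(int), scores[:, k])
            for k in present]
    return float(np.mean(vals))


def cv_prediction_scores(
    ds: TabularDataset,
    folds: int = 3,
    seed: int = 0,
    standardization: Standardization | None = None,
    lr_c: float = 100.0,
) -> tuple[float, float]:
    """Stratified k-fold CV logistic regression; (AUROC, AUPRC) on pooled
    out-of-fold predictions.

    Predictors enter through the shared encoding (by default the real
    dataset's standardization is passed in, identically for real and
    synthetic fits).  The logistic model carries a small L2 penalty for
    stability under separation.  In the binary case the second declared
    outcome level is the positive class — a schema-fixed rule so real and
    synthetic evaluations always agree on orientation.
    """
    out = ds.outcome
    levels = list(out.levels)
    k_classes = len(levels)
    y = ds.values[out.name].map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    observed = np.unique(y)
    if len(observed) < 2:
        raise ValueError("outcome must have >= 2 observed levels")
    counts = np.bincount(y, minlength=k_classes)
    eff_folds = folds
    min_count = counts[counts > 0].min()
    if min_count < folds:
        # a level rarer than the fold count would vanish from training folds
        eff_folds = max(int(min_count), 2)
        warnings.warn(
            f"outcome level rarer than {folds} folds; using {eff_folds} folds"
        )
    std = standardization
    if std is None:
        std = fit_standardization(ds, include_outcome=False)
    X = encode(ds, reference=std).matrix

    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    oof = np.zeros((len(y), k_classes))
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(C=lr_c, max_iter=2000)
        clf.fit(X[tr], y[tr])
        proba = clf.predict_proba(X[te])
        for ci, cls in enumerate(clf.classes_):
            oof[te, cls] = proba[:, ci]

    if k_classes == 2:
        auroc = binary_auroc(oof[:, 1], (y == 1))
        auprc = float(average_precision_score((y == 1).astype(int), oof[:, 1]))
    else:
        auroc = multiclass_auroc(oof, y)
        auprc = multiclass_auprc(oof, y)
    return auroc, auprc


def workload_difference(
    real: TabularDataset,
    syn: TabularDataset,
    folds: int = 3,
    seed: int = 0,
    dataset_name: str | None = None,
    method_name: str = "",
    replicate_index: int = 0,
    real_scores: tuple[float, float] | None = None,
) -> WorkloadScore:
    """CV prediction scores on real and synthetic data and their absolute
    differences; both fits share the real data's predictor encoding and
    fold seed.  ``real_scores`` short-circuits the (replicate-invariant)
    real-data evaluation when scoring many replicates."""
    if not real.same_schema(syn):
        raise ValueError("real and synthetic schemas differ")
    std = fit_standardization(real, include_outcome=False)
    if real_scores is None:
        real_scores = cv_prediction_scores(real, folds, seed, standardization=std)
    syn_scores = cv_prediction_scores(syn, folds, seed, standardization=std)
    return WorkloadScore(
        auroc_real=real_scores[0],
        auroc_syn=syn_scores[0],
        auprc_real=real_scores[1],
        auprc_syn=syn_scores[1],
        dataset_name=dataset_name if dataset_name is not None else real.name,
        method_name=method_name,
        replicate_index=replicate_index,
    )
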