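import numpy as np
import pandas as pd
import pytest

from synthutil import ColumnMeta, TabularDataset, random_real_spec, simulate_real


@pytest.fixture
def tiny_dataset() -> TabularDataset:
    """Hand-written 3-row dataset: one continuous, one categorical, one outcome."""
    cols = [
        ColumnMeta("age", "continuous"),
        ColumnMeta("sex", "categorical", levels=("F", "M")),
        ColumnMeta("y", "categorical", levels=("no", "yes"), is_outcome=True),
    ]
    df = pd.DataFrame(
        {"age": [34.0, 51.5, 62.0], "sex": ["F", "M", "F"], "y": ["no", "yes", "yes"]}
    )
    return TabularDataset(cols, df, "tiny")


@pytest.fixture(scope="session")
def sim_dataset() -> TabularDataset:
    """One simulated health-like dataset at moderate size, shared read-only."""
    return simulate_real(random_real_spec(seed=42, n_rows=600, name="shared"))


def brute_force_auroc(scores, labels) -> float:
    """Pairwise concordance with ties counted 1/2 — the AUROC oracle."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_average_precision(scores, labels) -> float:
    """Average precision by direct summation over the ranked positives."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tp = 0
    ap = 0.0
    for i, lab in enumerate(labels, start=1):
        if lab == 1:
            tp += 1
            ap += tp / i
    return ap / labels.sum()
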