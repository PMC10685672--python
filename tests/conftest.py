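"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from osipheno import synth


def match_classes(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """Best bijection from predicted to true class labels.

    Returns ``mapping`` such that ``mapping[pred]`` is the matched true
    label, chosen to maximize agreement (Hungarian algorithm on the
    confusion matrix).
    """
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(np.asarray(true_labels), np.asarray(pred_labels)):
        conf[int(p), int(t)] += 1
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.empty(n_classes, dtype=int)
    mapping[rows] = cols
    return mapping


def matched_accuracy(true_labels, pred_labels, n_classes: int) -> float:
    mapping = match_classes(true_labels, pred_labels, n_classes)
    return float(np.mean(mapping[np.asarray(pred_labels)] == np.asarray(true_labels)))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-parameter cohort reused by read-only tests."""
    cfg = synth.GeneratorConfig(n_patients=400, seed=123)
    return synth.generate_cohort(cfg)
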