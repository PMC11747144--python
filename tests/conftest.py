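"""Shared fixtures and independent oracles for the test suite.

The metric oracles here are deliberately naive (pure-Python loops over
samples and classes) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from cupclf import CLASSES, SimConfig, TrainedClassifier, simulate_cohort


# ---------------------------------------------------------------------------
# brute-force metric oracles
# ---------------------------------------------------------------------------

def brute_force_metrics(p, truth, class_order):
    """Naive re-implementation of accuracy/top-2/macro-F1/confusion."""
    class_order = list(class_order)
    k = len(class_order)
    n = len(truth)
    conf = [[0] * k for _ in range(k)]
    n_correct = 0
    n_top2 = 0
    for i in range(n):
        row = list(p[i])
        t = class_order.index(truth[i])
        # argmax, earliest class on ties
        best = 0
        for j in range(1, k):
            if row[j] > row[best]:
                best = j
        conf[t][best] += 1
        if best == t:
            n_correct += 1
        # rank-2 ties broken by class_order position
        ranking = sorted(range(k), key=lambda j: (-row[j], j))
        if t in ranking[:2]:
            n_top2 += 1
    f1s = []
    for c in range(k):
        tp = conf[c][c]
        pred_c = sum(conf[r][c] for r in range(k))
        true_c = sum(conf[c])
        prec = tp / pred_c if pred_c else 0.0
        rec = tp / true_c if true_c else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return {
        "accuracy": n_correct / n,
        "top2_accuracy": n_top2 / n,
        "macro_f1": sum(f1s) / k,
        "confusion": np.array(conf),
    }


def random_instance(rng, n_max=50, n_classes=6):
    """A random probability matrix + truth labels for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    p = rng.dirichlet(np.ones(n_classes), size=n)
    truth = [CLASSES[i] for i in rng.integers(0, n_classes, size=n)]
    return p, truth


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (151 samples x 2000 probes, seed 0)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast balanced cohort for end-to-end tests that do not need scale."""
    cfg = SimConfig(
        n_per_class={c: 8 for c in CLASSES},
        n_probes=400,
        mqtl_per_class=30,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def toy_model():
    """A small, untrained but structurally valid 6-class model."""
    rng = np.random.default_rng(3)
    dims = [10, 8, 6]
    weights = [
        (rng.normal(size=(10, 8)).astype(np.float32),
         rng.normal(size=8).astype(np.float32)),
        (rng.normal(size=(8, 6)).astype(np.float32),
         rng.normal(size=6).astype(np.float32)),
    ]
    return TrainedClassifier(
        layer_dims=dims,
        dropout_rate=0.5,
        weights=weights,
        class_order=list(CLASSES),
        selected_probes=[f"cg{i:08d}" for i in range(10)],
        preprocessing_state={"impute_means": np.full(10, 0.5)},
    )
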