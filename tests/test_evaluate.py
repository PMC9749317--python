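"""Diagnostic evaluation: AUC, Youden cut-point, bootstrap CIs."""

import numpy as np
import pytest

from vpctrace import evaluate


def _auc_pair_count(scores, y):
    """Normalized Mann-Whitney count: concordant pairs + half ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _youden_brute_force(scores, y):
    """Max J over all candidate thresholds; ties -> highest threshold."""
    best_j, best_t = -np.inf, None
    for t in sorted(np.unique(scores), reverse=True) + [np.inf]:
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_j, best_t


def test_perfect_separation():
    scores = np.array([0.9, 0.8, 0.85, 0.2, 0.1, 0.15])
    labels = np.array([1, 1, 1, 0, 0, 0])
    rep = evaluate(scores, labels, positive_label=1, n_boot=50, seed=0)
    assert rep.auc == 1.0 and rep.accuracy == 1.0
    assert 0.2 < rep.threshold <= 0.8


def test_known_auc_three_quarters():
    labels = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.3, 0.5, 0.1])
    rep = evaluate(scores, labels, positive_label=1, n_boot=0)
    assert rep.auc == pytest.approx(0.75)
    assert _auc_pair_count(scores, labels) == pytest.approx(0.75)


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_pair_count_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    y = rng.integers(0, 2, n)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    scores = np.round(rng.random(n), 2)  # coarse grid forces ties
    rep = evaluate(scores, y, positive_label=1, n_boot=0)
    assert rep.auc == pytest.approx(_auc_pair_count(scores, y), abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_youden_threshold_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    n = 80
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    scores = np.round(rng.random(n), 2)
    rep = evaluate(scores, y, positive_label=1, n_boot=0)
    best_j, best_t = _youden_brute_force(scores, y)
    got_j = rep.sensitivity + rep.specificity - 1
    assert got_j == pytest.approx(best_j, abs=1e-10)
    # tie-break: among J-optimal thresholds the most specific one is chosen
    pred_ref = scores >= best_t
    pred_got = scores >= rep.threshold
    np.testing.assert_array_equal(pred_got, pred_ref)


def test_monotone_transform_invariance():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    scores = rng.random(60)
    a = evaluate(scores, y, positive_label=1, n_boot=0)
    b = evaluate(scores ** 3, y, positive_label=1, n_boot=0)  # monotone on [0,1]
    assert a.auc == pytest.approx(b.auc, abs=1e-12)
    assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(12)
    n = 2000
    y = np.repeat([0, 1], n // 2)
    scores = rng.random(n)
    rep = evaluate(scores, y, positive_label=1, n_boot=0)
    assert abs(rep.auc - 0.5) <= 0.03


def test_confusion_identities():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    scores = rng.random(100)
    rep = evaluate(scores, y, positive_label=1, n_boot=0)
    total = rep.tp + rep.fp + rep.tn + rep.fn
    assert total == 100
    assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / total)
    assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
    assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))


def test_cis_contain_point_estimates():
    rng = np.random.default_rng(21)
    y = np.repeat([0, 1], 40)
    scores = np.clip(rng.normal(0.35 + 0.3 * y, 0.2), 0, 1)
    rep = evaluate(scores, y, positive_label=1, n_boot=300, seed=5)
    for key, (lo, hi) in rep.ci.items():
        point = getattr(rep, key)
        assert lo <= point <= hi, key


def test_string_labels_and_errors():
    rep = evaluate([0.9, 0.1], ["VPC", "NOR"], n_boot=0)
    assert rep.auc == 1.0
    with pytest.raises(ValueError, match="both classes"):
        evaluate([0.5, 0.6], [1, 1], positive_label=1, n_boot=0)
    with pytest.raises(ValueError, match="0, 1"):
        evaluate([1.5, -0.2], [1, 0], positive_label=1, n_boot=0)
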