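"""Discretization, OAA RBF-SVM training, LOOCV evaluation and chance levels."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psyconn.classify import (
    ClassifierReport,
    FeatureMatrix,
    apply_classifiers,
    chance_levels,
    discretize,
    loocv_evaluate,
    significance_vs_chance,
    train_oaa_svm,
)
from psyconn.errors import AlignmentError, DegenerateDesignError


def _series(values, name="param-01"):
    return pd.Series(values, index=[f"sub-{k:03d}" for k in range(len(values))], name=name, dtype=float)


def _features(X, ids=None, edges=None):
    n, e = X.shape
    return FeatureMatrix(
        values=X,
        edge_ids=edges or [(1, k + 2) for k in range(e)],
        subject_ids=ids or [f"sub-{k:03d}" for k in range(n)],
    )


# ---------------------------------------------------------------------------
# discretization


def test_discretize_contract_exhaustive_over_integer_grid():
    """Labels equal clamp(ceil(8 (x - min)/(max - min)), 1, 8) — checked with
    an exact-rational oracle, monotone in x, attaining all 8 classes."""
    for vmin, vmax in [(0, 100), (10, 130), (-20, 44)]:
        xs = np.arange(vmin, vmax + 1, dtype=float)
        lab = discretize(_series(xs), n_classes=8)
        got = lab.labels.to_numpy()
        expected = [
            min(max(math.ceil(Fraction(8) * Fraction(int(x) - vmin, vmax - vmin)), 1), 8)
            for x in xs
        ]
        assert got.tolist() == expected
        assert (np.diff(got) >= 0).all()  # monotone in x
        assert set(got) == set(range(1, 9))  # all 8 classes attainable


@pytest.mark.parametrize(
    "x,expected",
    [(0.0, 1), (50.0, 4), (51.0, 5), (100.0, 8), (12.5, 1), (12.6, 2)],
)
def test_discretize_examples_on_0_100_scale(x, expected):
    lab = discretize(_series([0.0, 100.0, x]), n_classes=8)
    assert lab.labels.iloc[2] == expected


def test_discretize_constant_scores_rejected():
    with pytest.raises(DegenerateDesignError):
        discretize(_series([5.0, 5.0, 5.0]))


def test_discretize_out_of_range_new_scores_clamped_with_warning():
    lab = discretize(_series([0.0, 100.0]))
    new = pd.Series([-10.0, 120.0], index=["a", "b"])
    with pytest.warns(UserWarning, match="clamped"):
        out = lab.apply(new)
    assert out.tolist() == [1, 8]


def test_discretize_idempotent_on_representative_scores():
    lab = discretize(_series([0.0, 100.0, 30.0, 70.0]))
    again = lab.apply(_series([0.0, 100.0, 30.0, 70.0]))
    assert (again == lab.labels.to_numpy()).all()


# ---------------------------------------------------------------------------
# chance levels


def test_theoretical_chance_is_12_5_for_8_classes():
    for n in (10, 57, 150, 1000):
        theo, _ = chance_levels(8, n)
        assert theo == 12.5


def test_corrected_chance_matches_binomial_quantile_oracle():
    for n_classes, n in [(8, 150), (8, 57), (8, 153), (4, 100), (2, 30)]:
        _, corr = chance_levels(n_classes, n, alpha=0.05)
        k = stats.binom.ppf(0.95, n, 1.0 / n_classes)  # independent oracle
        assert corr == pytest.approx(100.0 * k / n)


def test_corrected_chance_for_150_samples_is_26_of_150():
    _, corr = chance_levels(8, 150, alpha=0.05)
    assert corr == pytest.approx(100.0 * 26 / 150)
    assert round(corr) == 17


def test_single_sample_must_be_correct():
    _, corr = chance_levels(2, 1, alpha=0.05)
    assert corr == 100.0


def test_corrected_chance_decreasing_in_n_and_above_theoretical():
    # non-increasing in n up to the one-count granularity of k/n
    ns = list(range(20, 800, 20))
    vals = [chance_levels(8, n)[1] for n in ns]
    for (a, _), (b, nb) in zip(zip(vals, ns), zip(vals[1:], ns[1:])):
        assert a >= b - 100.0 / nb
    assert all(v >= 12.5 for v in vals)


# ---------------------------------------------------------------------------
# significance vs chance


def test_binomial_significance_examples():
    # 36/153 correct (23.5%) clears the 12.5% chance level
    r = ClassifierReport("p", np.ones(153, int), np.r_[np.ones(36, int), np.full(117, 2)], 8)
    sig, p = significance_vs_chance(r)
    assert sig and p < 0.05
    assert p == pytest.approx(stats.binom.sf(35, 153, 0.125), rel=1e-6)

    # exactly at chance: not significant, p near one half
    n = 160
    y_true = np.tile(np.arange(1, 9), 20)
    y_pred = np.where(np.arange(n) < 20, y_true, (y_true % 8) + 1)  # 20/160 correct
    r = ClassifierReport("p", y_true, y_pred, 8)
    sig, p = significance_vs_chance(r)
    assert not sig and 0.3 < p < 0.7

    # all correct: p = 0.125^n
    r = ClassifierReport("p", y_true[:10], y_true[:10], 8)
    sig, p = significance_vs_chance(r)
    assert sig and p == pytest.approx(0.125**10, rel=1e-9)


def test_t_test_mode_agrees_directionally():
    y_true = np.tile(np.arange(1, 9), 20)
    y_pred = np.where(np.arange(160) < 60, y_true, (y_true % 8) + 1)  # 37.5% correct
    r = ClassifierReport("p", y_true, y_pred, 8)
    sig_b, _ = significance_vs_chance(r, method="binomial")
    sig_t, _ = significance_vs_chance(r, method="t")
    assert sig_b and sig_t


# ---------------------------------------------------------------------------
# OAA SVM training and evaluation


def test_well_separated_clusters_classified_in_loocv(rng):
    n_per = 15
    X = np.vstack([rng.normal(0, 0.2, (n_per, 3)), rng.normal(5, 0.2, (n_per, 3))])
    scores = _series(np.r_[np.full(n_per, 10.0), np.full(n_per, 90.0)] + rng.normal(0, 1, 2 * n_per))
    labels = discretize(scores, n_classes=8)
    model = train_oaa_svm(_features(X), labels, c_grid=(1.0, 100.0), gamma_grid=(0.1, 1.0))
    assert model.loocv_accuracy_pct >= 95.0


def test_shuffled_labels_give_chance_level_accuracy():
    """Random features with balanced shuffled 8-class labels: mean LOOCV
    accuracy stays within binomial noise of the class-prior maximum."""
    accs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        X = r.standard_normal((40, 4))
        y = r.permutation(np.tile(np.arange(1, 9), 5))
        scores = _series((y - 1) * (100 / 7) + r.uniform(0, 1, 40))  # maps back to y
        labels = discretize(scores, n_classes=8)
        model = train_oaa_svm(_features(X), labels, c_grid=(1.0,), gamma_grid=(0.25,))
        accs.append(model.loocv_accuracy_pct / 100)
    assert abs(np.mean(accs) - 0.125) < 0.06


def test_perfect_features_reach_100_percent(rng):
    y = np.tile(np.arange(1, 9), 4)
    X = np.column_stack([y + rng.normal(0, 1e-3, 32), -2.0 * y])
    scores = _series((y - 1) * (100 / 7))
    labels = discretize(scores, n_classes=8)
    report = loocv_evaluate(_features(X), labels, C=100.0, gamma=1.0)
    assert report.accuracy_pct == 100.0
    assert report.sensitivity_pct == 100.0
    assert report.specificity_pct == 100.0


def test_majority_only_predictions_score_the_prior():
    y_true = np.tile(np.arange(1, 9), 20)
    r = ClassifierReport("p", y_true, np.ones(160, int), 8)
    assert r.accuracy_pct == pytest.approx(12.5)
    # one-class confusion: sensitivity collapses to 1/8, specificity to 7/8
    assert r.sensitivity_pct == pytest.approx(12.5)
    assert r.specificity_pct == pytest.approx(87.5)


def test_grid_tie_breaks_toward_smaller_c_then_gamma(rng):
    n_per = 10
    X = np.vstack([rng.normal(0, 0.1, (n_per, 2)), rng.normal(8, 0.1, (n_per, 2))])
    scores = _series(np.r_[np.full(n_per, 5.0), np.full(n_per, 95.0)] + rng.normal(0, 0.5, 2 * n_per))
    labels = discretize(scores)
    model = train_oaa_svm(_features(X), labels, c_grid=(4.0, 1.0), gamma_grid=(2.0, 0.5))
    # wide-margin data: every grid point is perfect, so the smallest pair wins
    assert model.loocv_accuracy_pct == 100.0
    assert (model.C, model.gamma) == (1.0, 0.5)


def test_single_class_rejected(rng):
    from psyconn.classify import ClassLabelMap

    X = rng.standard_normal((10, 2))
    labels = ClassLabelMap(
        parameter="p",
        labels=pd.Series(np.ones(10, int), index=[f"sub-{k:03d}" for k in range(10)]),
        vmin=0.0,
        vmax=100.0,
    )
    with pytest.raises(DegenerateDesignError):
        train_oaa_svm(_features(X), labels, c_grid=(1.0,), gamma_grid=(1.0,))


def test_resubstitution_accuracy_bounds_loocv(rng):
    n = 48
    z = rng.normal(0, 1, n)
    scores = _series(60 + 10 * z)
    X = z[:, None] + rng.normal(0, 0.5, (n, 5))
    labels = discretize(scores)
    model = train_oaa_svm(_features(X), labels, c_grid=(1.0, 10.0), gamma_grid=(0.2,))
    resub = 100.0 * np.mean(model.predict(X) == labels.labels.to_numpy())
    assert resub >= model.loocv_accuracy_pct


def test_apply_requires_matching_edge_ids(rng):
    X = rng.standard_normal((20, 3))
    scores = _series(rng.normal(60, 10, 20))
    labels = discretize(scores)
    model = train_oaa_svm(_features(X), labels, c_grid=(1.0,), gamma_grid=(0.3,))
    wrong = _features(rng.standard_normal((5, 3)), ids=[f"n{k}" for k in range(5)],
                      edges=[(9, 10), (9, 11), (9, 12)])
    with pytest.raises(AlignmentError):
        apply_classifiers(wrong, model)


def test_all_zero_features_give_constant_prediction(rng):
    n = 24
    z = rng.normal(0, 1, n)
    scores = _series(60 + 10 * z)
    X = z[:, None] + rng.normal(0, 0.3, (n, 4))
    labels = discretize(scores)
    model = train_oaa_svm(_features(X), labels, c_grid=(1.0,), gamma_grid=(0.3,))
    new = _features(np.zeros((6, 4)), ids=[f"new{k}" for k in range(6)])
    preds, _ = apply_classifiers(new, model)
    assert len(set(preds)) == 1


def test_holdout_scores_discretized_with_training_minmax(rng):
    n = 30
    z = rng.normal(0, 1, n)
    scores = _series(60 + 10 * z)
    X = z[:, None] + rng.normal(0, 0.3, (n, 4))
    labels = discretize(scores)
    model = train_oaa_svm(_features(X), labels, c_grid=(1.0,), gamma_grid=(0.3,))
    new_ids = [f"new{k}" for k in range(8)]
    zn = rng.normal(0, 1, 8)
    new = FeatureMatrix(zn[:, None] + rng.normal(0, 0.3, (8, 4)), model.edge_ids, new_ids)
    true_scores = pd.Series(60 + 10 * zn, index=new_ids)
    preds, report = apply_classifiers(new, model, true_scores=true_scores)
    expected_true = model.label_map.apply(true_scores).to_numpy()
    assert (report.y_true == expected_true).all()
    assert report.n_subjects == 8
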