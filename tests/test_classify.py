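"""SMOTE, cross-validated AUC, Gini importance, robustness and direction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull, Delaunay
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from xlink3d import fixtures as fx
from xlink3d.classify import (CVConfig, Dataset, DirectionConfig,
                              PermutationConfig, RFConfig, SMOTEConfig,
                              alt_classifiers, apply_smote, crossval_auc,
                              fit_rf_importance, gini_importance,
                              permutation_robustness, rank_features,
                              rs_from_counts, signed_importance,
                              smote_oversample)


# --- SMOTE ------------------------------------------------------------------

def test_two_point_minority_interpolates_on_segment():
    minority = np.array([[0.0, 0.0], [2.0, 2.0]])
    synth = smote_oversample(minority, 50, SMOTEConfig(seed=1))
    # every synthetic point is x + u (x' - x) with the only neighbor available
    assert np.allclose(synth[:, 0], synth[:, 1])
    assert synth.min() >= 0.0 and synth.max() <= 2.0


def test_coincident_minority_points_reproduce_themselves():
    minority = np.ones((4, 3)) * 7.0
    synth = smote_oversample(minority, 10, SMOTEConfig(seed=2))
    assert np.allclose(synth, 7.0)


def test_synthetic_points_inside_convex_hull():
    rng = np.random.default_rng(6)
    minority = rng.normal(size=(20, 2))
    synth = smote_oversample(minority, 200, SMOTEConfig(seed=3))
    hull = Delaunay(minority[ConvexHull(minority).vertices])
    assert np.all(hull.find_simplex(synth) >= 0)


def test_single_minority_row_rejected():
    with pytest.raises(ValueError):
        smote_oversample(np.array([[1.0, 2.0]]), 5)


def test_apply_smote_balances_to_one_to_one():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 3))
    y = np.array([1] * 10 + [0] * 40)
    X2, y2 = apply_smote(X, y, SMOTEConfig(seed=4))
    assert (y2 == 1).sum() == (y2 == 0).sum() == 40
    # original rows untouched
    assert np.array_equal(X2[:50], X)


def test_smote_never_alters_heldout_predictions():
    # predictions of a fixed fitted model on held-out rows do not depend on
    # whether SMOTE was used to augment some other training set
    ds = fx.simulate_feature_table(fx.TableSimSpec(seed=5))
    X = ds.X.to_numpy()
    model = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, ds.y)
    before = model.predict_proba(X[:20])
    _ = apply_smote(X, ds.y, SMOTEConfig(seed=1))
    after = model.predict_proba(X[:20])
    assert np.array_equal(before, after)


# --- cross-validated AUC ----------------------------------------------------

def _null_dataset(n=400, p=20, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.poisson(0.6, size=(n, p)).astype(float))
    X.columns = [f"f{i}" for i in range(p)]
    y = rng.integers(0, 2, n)
    return Dataset(X=X, y=y)


def test_perfectly_separating_feature_gives_auc_one():
    ds = _null_dataset(seed=1)
    ds.X["f0"] = ds.y * 10.0
    r = crossval_auc(ds, "rf", CVConfig(seed=1), SMOTEConfig(seed=1))
    assert r.auc == pytest.approx(1.0)


def test_null_labels_give_auc_half():
    r = crossval_auc(_null_dataset(seed=2), "rf", CVConfig(seed=2),
                     SMOTEConfig(seed=2))
    assert abs(r.auc - 0.5) <= 0.1


def test_signal_auc_near_bayes_oracle():
    # large-sample regime so the forest can approach the generative optimum
    spec = fx.TableSimSpec(n_pos=300, n_neg=700, n_features=30,
                           informative=(0, 5, 10, 15, 20), beta=1.5, seed=21)
    ds = fx.simulate_feature_table(spec)
    r = crossval_auc(ds, "rf", CVConfig(seed=3), SMOTEConfig(seed=3),
                     RFConfig(ntree=200, mtry=10))
    bayes = roc_auc_score(
        ds.y, fx.bayes_scores(spec, ds.X.to_numpy(), ds.sim_intercept))
    assert abs(r.auc - bayes) <= 0.05


def test_bootstrap_ci_brackets_auc():
    ds = fx.simulate_feature_table(fx.TableSimSpec(seed=8))
    r = crossval_auc(ds, "rf", CVConfig(seed=4), SMOTEConfig(seed=4),
                     RFConfig(100, 17), n_bootstrap=60)
    assert r.ci_lower is not None
    assert r.ci_lower - 0.05 <= r.auc <= r.ci_upper + 0.05


def test_auc_invariant_under_monotone_score_transform():
    rng = np.random.default_rng(11)
    y = rng.integers(0, 2, 200)
    scores = rng.normal(size=200) + y
    a1 = roc_auc_score(y, scores)
    a2 = roc_auc_score(y, np.exp(3 * scores) + 7)
    assert a1 == pytest.approx(a2)


def test_pipeline_reproducible_with_fixed_seeds():
    ds = fx.simulate_feature_table(fx.TableSimSpec(seed=13))
    r1 = crossval_auc(ds, "rf", CVConfig(seed=5), SMOTEConfig(seed=5),
                      RFConfig(50, 17))
    r2 = crossval_auc(ds, "rf", CVConfig(seed=5), SMOTEConfig(seed=5),
                      RFConfig(50, 17))
    assert np.array_equal(r1.pooled_scores, r2.pooled_scores)
    imp1 = fit_rf_importance(ds, RFConfig(50, 17, seed=1), SMOTEConfig(seed=1))
    imp2 = fit_rf_importance(ds, RFConfig(50, 17, seed=1), SMOTEConfig(seed=1))
    assert np.array_equal(imp1, imp2)


# --- Gini importance --------------------------------------------------------

def test_stump_gini_decrease_hand_computed():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    y = np.array([0, 0, 1, 1])
    forest = RandomForestClassifier(n_estimators=1, max_depth=1,
                                    bootstrap=False, random_state=0).fit(X, y)
    imp = gini_importance(forest)
    # root Gini 0.5, both children pure: decrease 0.5
    assert imp[0] == pytest.approx(0.5)


def test_noise_feature_importance_far_below_informative():
    rng = np.random.default_rng(14)
    X = np.column_stack([rng.integers(0, 2, 500), rng.normal(size=500)])
    y = X[:, 0].astype(int)
    forest = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
    imp = gini_importance(forest)
    assert imp[1] < 0.1 * imp[0]


def test_importance_invariant_to_feature_permutation():
    # continuous features make the best split almost surely unique, so
    # deterministic trees are invariant to column order up to reindexing
    rng = np.random.default_rng(15)
    X = rng.normal(size=(300, 12))
    y = (X[:, 0] + 0.5 * X[:, 3] + rng.normal(scale=0.5, size=300) > 0)
    y = y.astype(int)
    perm = np.random.default_rng(1).permutation(12)
    kw = dict(n_estimators=10, max_features=None, bootstrap=False,
              random_state=7, min_samples_leaf=40)  # no near-leaf split ties
    f1 = RandomForestClassifier(**kw).fit(X, y)
    f2 = RandomForestClassifier(**kw).fit(X[:, perm], y)
    assert np.allclose(gini_importance(f1)[perm], gini_importance(f2))


# --- robustness R_s ---------------------------------------------------------

def test_rs_closed_form_values():
    n = 2000
    assert rs_from_counts(0, n) == pytest.approx(math.log10(2001))
    assert rs_from_counts(3, n) == pytest.approx(-math.log10(4 / 2001))
    assert rs_from_counts(n, n) == pytest.approx(-math.log10((n + 1) / (n + 1)))
    # antitone in the exceedance count, bounded by the pseudocount ceiling
    vals = rs_from_counts(np.arange(0, n + 1, 100), n)
    assert np.all(np.diff(vals) < 0)
    assert vals.max() <= math.log10(n + 1) + 1e-12


def test_permutation_robustness_separates_signal_from_null():
    spec = fx.TableSimSpec(n_features=40, informative=(0, 7), seed=16)
    ds = fx.simulate_feature_table(spec)
    rs = permutation_robustness(ds, RFConfig(60, 10, seed=0),
                                SMOTEConfig(seed=0),
                                PermutationConfig(40, seed=0))
    null = [i for i in range(40) if i not in spec.informative]
    assert all(rs[list(spec.informative)] > np.median(rs[null]))
    assert rs.max() <= math.log10(41) + 1e-12


# --- direction signs --------------------------------------------------------

def test_direction_signs_match_generator_and_irls_oracle():
    rng = np.random.default_rng(17)
    n = 400
    x_up = rng.normal(size=n)
    x_down = rng.normal(size=n)
    x_null = rng.normal(size=n)
    logits = 2.0 * x_up - 2.0 * x_down
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    X = pd.DataFrame({"up": x_up, "down": x_down, "null": x_null})
    ds = Dataset(X=X, y=y)
    coefs, signs, _ = signed_importance(
        ds, DirectionConfig(alpha=0.5, lam=0.1, seed=0))
    assert signs[0] == "+" and signs[1] == "-"
    # unpenalized IRLS (statsmodels-free: sklearn with tiny penalty) oracle
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler
    Xs = StandardScaler().fit_transform(X)
    oracle = LogisticRegression(C=1e6, max_iter=2000).fit(Xs, y).coef_.ravel()
    assert np.sign(oracle[0]) == 1 and np.sign(oracle[1]) == -1
    assert np.sign(coefs[0]) == np.sign(oracle[0])
    assert np.sign(coefs[1]) == np.sign(oracle[1])


# --- alternative classifiers ------------------------------------------------

def test_alt_classifiers_on_separable_and_signal_data():
    ds = _null_dataset(n=200, p=5, seed=18)
    ds.X["f0"] = ds.y * 10.0
    res = alt_classifiers(ds, CVConfig(k=5, seed=0), SMOTEConfig(seed=0))
    assert set(res) == {"logistic", "svm", "xgboost", "avnnet"}
    for name, roc in res.items():
        assert roc.auc > 0.97, name

    sig = fx.simulate_feature_table(fx.TableSimSpec(
        n_features=40, informative=(0, 5, 11, 22, 33), seed=19))
    res = alt_classifiers(sig, CVConfig(k=5, seed=1), SMOTEConfig(seed=1))
    aucs = [r.auc for r in res.values()]
    assert max(aucs) - min(aucs) <= 0.1
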