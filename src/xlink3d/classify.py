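"""Imbalance-aware classification of crosslinking status and feature ranking.

The workflow mirrors the analysis stack used for crosslink-determinant
studies: minority oversampling (SMOTE) applied *inside* each training fold,
random-forest classification scored by 10-fold cross-validated ROC AUC with a
bootstrap confidence interval, Mean GiniDecrease feature importance, a
label-permutation robustness score per feature, and an elastic-net logistic
fit that supplies each feature's direction of contribution.

The permutation-robustness score of feature s is

    R_s = -log10( (#permutations where s ranks better than in the true model + 1)
                  / (N + 1) )

with rank 1 = most important and ties averaged. The +1 pseudocounts exist
only because the plain fraction is undefined at zero exceedances; they cap
R_s at log10(N + 1).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


# --- containers & configs ---------------------------------------------------

@dataclass
class Dataset:
    """Feature matrix + binary labels for one classification task."""
    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray | None = None
    meta: pd.DataFrame | None = None
    sim_spec: object = None
    sim_intercept: float | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class CVConfig:
    k: int = 10
    seed: int = 0


@dataclass
class SMOTEConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # positives : negatives after oversampling
    seed: int = 0


@dataclass
class RFConfig:
    """Forest sizes per task: nucleotides (mtry 17, ntree 100), amino acids
    (mtry 6, ntree 1000), large-assembly amino acids (mtry 6, ntree 100)."""
    ntree: int = 100
    mtry: int = 17
    seed: int = 0

    @classmethod
    def for_task(cls, task: str, seed: int = 0) -> "RFConfig":
        presets = {"nucleotide": (100, 17), "amino-acid": (1000, 6),
                   "ribosome": (100, 6)}
        ntree, mtry = presets[task]
        return cls(ntree=ntree, mtry=mtry, seed=seed)


@dataclass
class PermutationConfig:
    n_permutations: int = 2000
    seed: int = 0


@dataclass
class DirectionConfig:
    """Elastic-net mixing alpha and penalty lam; None means tune by CV AUC."""
    alpha: float | None = None
    lam: float | None = None
    alpha_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    lam_grid: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
    cv_folds: int = 10
    seed: int = 0


@dataclass
class ROCResult:
    auc: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    per_fold: list[float] = field(default_factory=list)
    n_bootstrap: int = 0
    pooled_scores: np.ndarray | None = None


@dataclass
class ImportanceRecord:
    feature: str
    mean_gini_decrease: float
    direction_sign: str  # '+', '-', or '0' (undetermined)
    robustness: float


# --- SMOTE ------------------------------------------------------------------

def smote_oversample(minority: np.ndarray, n_synthetic: int,
                     config: SMOTEConfig | None = None,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Interpolated synthetic minority rows: x + u * (x' - x), u ~ U(0, 1),
    x' drawn from x's k nearest minority neighbors (Euclidean)."""
    config = config or SMOTEConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    minority = np.asarray(minority, dtype=float)
    n = minority.shape[0]
    if n < 2:
        raise ValueError("SMOTE needs >= 2 minority rows to interpolate")
    k = config.k_neighbors
    if k >= n:
        k = n - 1
        logger.warning("SMOTE k_neighbors reduced to %d (minority size %d)", k, n)
    dist = cdist(minority, minority)
    np.fill_diagonal(dist, np.inf)
    neighbor_idx = np.argsort(dist, axis=1)[:, :k]
    base = rng.integers(0, n, size=n_synthetic)
    pick = rng.integers(0, k, size=n_synthetic)
    u = rng.random(n_synthetic)
    x = minority[base]
    xp = minority[neighbor_idx[base, pick]]
    return x + u[:, None] * (xp - x)


def apply_smote(X: np.ndarray, y: np.ndarray,
                config: SMOTEConfig | None = None,
                rng: np.random.Generator | None = None):
    """Oversample the minority class to the configured ratio (default 1:1)."""
    config = config or SMOTEConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    if min(n_pos, n_neg) < 2:
        logger.warning("minority class has < 2 rows; SMOTE skipped")
        return X, y
    minority_label = 1 if n_pos < n_neg else 0
    n_min = min(n_pos, n_neg)
    n_maj = max(n_pos, n_neg)
    n_target = int(round(config.target_ratio * n_maj))
    n_synth = max(n_target - n_min, 0)
    if n_synth == 0:
        return X, y
    synth = smote_oversample(X[y == minority_label], n_synth, config, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_synth, minority_label)])
    return X_out, y_out


# --- model factory ----------------------------------------------------------

class AveragedMLP:
    """Model-averaged feed-forward network: the same single-hidden-layer
    architecture fit under different random seeds; predicted scores are
    averaged before use."""

    def __init__(self, n_models: int = 5, hidden: int = 5, max_iter: int = 500,
                 seed: int = 0):
        self.n_models = n_models
        self.hidden = hidden
        self.max_iter = max_iter
        self.seed = seed
        self.models_: list = []

    def fit(self, X, y):
        self.models_ = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(self.n_models):
                m = make_pipeline(
                    StandardScaler(),
                    MLPClassifier(hidden_layer_sizes=(self.hidden,),
                                  max_iter=self.max_iter,
                                  random_state=self.seed + i))
                m.fit(X, y)
                self.models_.append(m)
        return self

    def predict_proba(self, X):
        probs = np.mean([m.predict_proba(X) for m in self.models_], axis=0)
        return probs


def make_model(spec: str, rf: RFConfig | None = None, n_features: int = 1,
               seed: int = 0):
    rf = rf or RFConfig(seed=seed)
    if spec == "rf":
        return RandomForestClassifier(
            n_estimators=rf.ntree,
            max_features=min(rf.mtry, n_features),
            random_state=rf.seed, n_jobs=1)
    if spec == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, random_state=seed))
    if spec == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="rbf", random_state=seed))
    if spec == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.3,
                             random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss")
    if spec == "avnnet":
        return AveragedMLP(seed=seed)
    raise ValueError(f"unknown model spec {spec!r}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# --- cross-validated AUC ----------------------------------------------------

def crossval_auc(dataset: Dataset, model: str = "rf",
                 cv: CVConfig | None = None,
                 smote: SMOTEConfig | None = None,
                 rf: RFConfig | None = None,
                 n_bootstrap: int = 0) -> ROCResult:
    """Stratified k-fold ROC AUC with SMOTE applied inside training folds only.

    Held-out predictions are pooled across folds for a single AUC. When
    ``n_bootstrap`` > 0, a percentile confidence interval is added by
    retraining on row-resampled datasets and scoring out-of-bag rows
    (2.5/97.5 percentiles).
    """
    cv = cv or CVConfig()
    smote = smote or SMOTEConfig()
    X = dataset.X.to_numpy(dtype=float)
    y = dataset.y
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("both classes required for AUC")
    k = min(cv.k, n_pos, len(y) - n_pos)
    if k < 2:
        raise ValueError("not enough minority samples to stratify folds")
    if k < cv.k:
        logger.warning("folds reduced from %d to %d (minority size)", cv.k, k)
    rng = np.random.default_rng(smote.seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cv.seed)
    pooled = np.full(len(y), np.nan)
    per_fold = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train, test in skf.split(X, y):
            Xt, yt = apply_smote(X[train], y[train], smote, rng)
            m = make_model(model, rf, n_features=X.shape[1], seed=cv.seed)
            m.fit(Xt, yt)
            pooled[test] = _scores(m, X[test])
            if len(np.unique(y[test])) == 2:
                per_fold.append(float(roc_auc_score(y[test], pooled[test])))
    auc = float(roc_auc_score(y, pooled))

    ci_lo = ci_hi = None
    if n_bootstrap > 0:
        boot_rng = np.random.default_rng(cv.seed + 1)
        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_bootstrap):
                idx = boot_rng.integers(0, len(y), size=len(y))
                oob = np.setdiff1d(np.arange(len(y)), idx)
                if len(np.unique(y[idx])) < 2 or len(np.unique(y[oob])) < 2:
                    continue
                Xt, yt = apply_smote(X[idx], y[idx], smote, boot_rng)
                m = make_model(model, rf, n_features=X.shape[1], seed=cv.seed)
                m.fit(Xt, yt)
                aucs.append(float(roc_auc_score(y[oob], _scores(m, X[oob]))))
        if aucs:
            ci_lo, ci_hi = (float(np.percentile(aucs, 2.5)),
                            float(np.percentile(aucs, 97.5)))
    return ROCResult(auc=auc, ci_lower=ci_lo, ci_upper=ci_hi,
                     per_fold=per_fold, n_bootstrap=n_bootstrap,
                     pooled_scores=pooled)


def alt_classifiers(dataset: Dataset, cv: CVConfig | None = None,
                    smote: SMOTEConfig | None = None) -> dict[str, ROCResult]:
    """Logistic regression, SVM, gradient-boosted trees and the model-averaged
    network, all under the identical resampling protocol."""
    out = {}
    for name in ("logistic", "svm", "xgboost", "avnnet"):
        try:
            out[name] = crossval_auc(dataset, model=name, cv=cv, smote=smote)
        except Exception as exc:  # convergence failures reported, not fatal
            logger.warning("model %s failed: %s", name, exc)
    return out


# --- importance -------------------------------------------------------------

def gini_importance(forest: RandomForestClassifier) -> np.ndarray:
    """Mean GiniDecrease: per-tree sum over splits of node-size-weighted
    impurity decrease (normalized by root size), averaged over trees.

    Unlike sklearn's ``feature_importances_`` this is not rescaled to sum to
    one, so hand-computable cases keep their absolute values (a perfect
    single split on a balanced node has decrease 0.5).
    """
    n_features = forest.n_features_in_
    total = np.zeros(n_features)
    for est in forest.estimators_:
        tree = est.tree_
        imp = np.zeros(n_features)
        w = tree.weighted_n_node_samples
        root = w[0]
        for node in range(tree.node_count):
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:
                continue
            decrease = (w[node] * tree.impurity[node]
                        - w[left] * tree.impurity[left]
                        - w[right] * tree.impurity[right]) / root
            imp[tree.feature[node]] += decrease
        total += imp
    return total / len(forest.estimators_)


def fit_rf_importance(dataset: Dataset, rf: RFConfig | None = None,
                      smote: SMOTEConfig | None = None,
                      y: np.ndarray | None = None) -> np.ndarray:
    """Train one forest (SMOTE-balanced) on the full table; return importances."""
    rf = rf or RFConfig()
    smote = smote or SMOTEConfig()
    X = dataset.X.to_numpy(dtype=float)
    yy = dataset.y if y is None else np.asarray(y, int)
    Xt, yt = apply_smote(X, yy, smote, np.random.default_rng(smote.seed))
    model = make_model("rf", rf, n_features=X.shape[1])
    model.fit(Xt, yt)
    return gini_importance(model)


def rank_features(importances: np.ndarray) -> np.ndarray:
    """Rank 1 = most important; ties share the average rank."""
    return rankdata(-np.asarray(importances), method="average")


def rs_from_counts(n_better: np.ndarray | int, n_permutations: int) -> np.ndarray:
    """Closed-form robustness from exceedance counts, with +1 pseudocounts."""
    frac = (np.asarray(n_better, dtype=float) + 1.0) / (n_permutations + 1.0)
    return -np.log10(frac)


def permutation_robustness(dataset: Dataset, rf: RFConfig | None = None,
                           smote: SMOTEConfig | None = None,
                           perm: PermutationConfig | None = None,
                           true_importance: np.ndarray | None = None
                           ) -> np.ndarray:
    """Per-feature R_s from label permutations.

    Labels are shuffled, the model retrained with the same parameters, and
    features re-ranked; R_s counts how often a feature ranks strictly better
    than in the true model.
    """
    perm = perm or PermutationConfig()
    rf = rf or RFConfig()
    smote = smote or SMOTEConfig()
    if true_importance is None:
        true_importance = fit_rf_importance(dataset, rf, smote)
    true_ranks = rank_features(true_importance)
    rng = np.random.default_rng(perm.seed)
    n_better = np.zeros(dataset.n_features)
    for i in range(perm.n_permutations):
        y_perm = rng.permutation(dataset.y)
        if y_perm.sum() == 0 or y_perm.sum() == len(y_perm):
            continue
        rf_i = RFConfig(ntree=rf.ntree, mtry=rf.mtry, seed=rf.seed + i + 1)
        smote_i = SMOTEConfig(k_neighbors=smote.k_neighbors,
                              target_ratio=smote.target_ratio,
                              seed=smote.seed + i + 1)
        imp = fit_rf_importance(dataset, rf_i, smote_i, y=y_perm)
        n_better += (rank_features(imp) < true_ranks)
    return rs_from_counts(n_better, perm.n_permutations)


# --- direction sign ---------------------------------------------------------

def _elastic_net(alpha: float, lam: float, seed: int) -> LogisticRegression:
    # C = 1/lam; l1_ratio = alpha (alpha=0 is pure ridge)
    if alpha == 0.0:
        return LogisticRegression(penalty="l2", C=1.0 / lam, solver="lbfgs",
                                  max_iter=5000, random_state=seed)
    return LogisticRegression(penalty="elasticnet", l1_ratio=alpha,
                              C=1.0 / lam, solver="saga", max_iter=5000,
                              random_state=seed)


def signed_importance(dataset: Dataset,
                      config: DirectionConfig | None = None
                      ) -> tuple[np.ndarray, list[str], tuple[float, float]]:
    """Elastic-net logistic coefficients on standardized features.

    Returns (coefficients, signs, (alpha, lam)). A zero coefficient yields
    sign '0' (undetermined). When alpha/lam are not fixed in the config they
    are selected on a grid by cross-validated AUC.
    """
    cfg = config or DirectionConfig()
    X = StandardScaler().fit_transform(dataset.X.to_numpy(dtype=float))
    # constant columns standardize to zero and contribute sign '0'
    y = dataset.y
    if cfg.alpha is not None and cfg.lam is not None:
        alpha, lam = cfg.alpha, cfg.lam
    else:
        n_pos = int(y.sum())
        folds = max(2, min(cfg.cv_folds, n_pos, len(y) - n_pos))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
        best, best_auc = None, -np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a in cfg.alpha_grid:
                for l in cfg.lam_grid:
                    pooled = np.full(len(y), np.nan)
                    try:
                        for tr, te in skf.split(X, y):
                            m = _elastic_net(a, l, cfg.seed).fit(X[tr], y[tr])
                            pooled[te] = m.predict_proba(X[te])[:, 1]
                        auc = roc_auc_score(y, pooled)
                    except Exception:
                        continue
                    if auc > best_auc:
                        best, best_auc = (a, l), auc
        if best is None:
            raise RuntimeError("elastic-net grid search failed to converge")
        alpha, lam = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = _elastic_net(alpha, lam, cfg.seed).fit(X, y)
    if hasattr(model, "n_iter_") and np.max(model.n_iter_) >= 5000:
        raise RuntimeError(
            f"elastic-net did not converge at alpha={alpha}, lam={lam} "
            f"(n_iter={np.max(model.n_iter_)})")
    coefs = model.coef_.ravel()
    signs = ["+" if c > 1e-8 else "-" if c < -1e-8 else "0" for c in coefs]
    return coefs, signs, (alpha, lam)


# --- report -----------------------------------------------------------------

def importance_report(dataset: Dataset, rf: RFConfig | None = None,
                      smote: SMOTEConfig | None = None,
                      perm: PermutationConfig | None = None,
                      direction: DirectionConfig | None = None) -> pd.DataFrame:
    """Full per-feature table: Mean GiniDecrease, rank, direction sign, R_s."""
    imp = fit_rf_importance(dataset, rf, smote)
    rs = permutation_robustness(dataset, rf, smote, perm, true_importance=imp)
    _, signs, (alpha, lam) = signed_importance(dataset, direction)
    df = pd.DataFrame({
        "feature": dataset.X.columns,
        "mean_gini_decrease": imp,
        "rank": rank_features(imp),
        "direction_sign": signs,
        "robustness": rs,
    }).sort_values("rank").reset_index(drop=True)
    df.attrs["elastic_net"] = {"alpha": alpha, "lam": lam}
    return df
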