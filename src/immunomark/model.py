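"""Candidate biomarker construction and the dual-criterion final selection.

The biomarker is an L2-regularized logistic regression over a small,
greedily chosen subset of immune features.  For each value of the
regularization parameter C on a log2-spaced grid, forward selection grows
a feature path scored by stratified cross-validated AUC; every prefix of
every path is a candidate model.  Each candidate is then scored for
analytic variability on technical replicates (the 4*std metric: four
times the SD of replicate scores after mean-centering within biological
sample), and the final model maximizes CV AUC subject to an AUC floor and
a variability ceiling.

C follows the common inverse-penalty convention: the penalized objective
is  -loglik + ||w||^2 / (2C),  intercept unpenalized, so larger C means a
weaker penalty.  Features are standardized inside every fit using
training-portion statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc

__all__ = [
    "CandidateModel",
    "DEFAULT_C_GRID",
    "fit_regularized_logistic",
    "cv_auc",
    "forward_select",
    "train_candidate",
    "build_candidates",
    "evaluate_variability",
    "select_final_model",
]

# log2-spaced inverse-penalty grid spanning ~1e-3 .. ~1e2
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-10, 7))


@dataclass(frozen=True)
class CandidateModel:
    """A fitted candidate: feature subset, C, coefficients, and its two scores.

    `mean`/`scale` are the full-training-set standardization constants the
    coefficients refer to; `variability_4std` is populated by
    :func:`evaluate_variability` (score units on the 0-100 scale).
    """

    features: tuple
    C: float
    coef: tuple
    intercept: float
    mean: tuple
    scale: tuple
    cv_auc: float
    variability_4std: float | None = None

    def __post_init__(self):
        if len(self.coef) != len(self.features):
            raise ValueError("one coefficient per selected feature required")
        if not 0 <= self.cv_auc <= 1:
            raise ValueError(f"cv_auc must be in [0,1], got {self.cv_auc}")
        if self.variability_4std is not None and self.variability_4std < 0:
            raise ValueError("variability_4std must be >= 0")

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Predicted probability of non-progression, scaled to 0-100."""
        X = features.loc[:, list(self.features)].to_numpy(dtype=float)
        Z = (X - np.asarray(self.mean)) / np.asarray(self.scale)
        logit = Z @ np.asarray(self.coef) + self.intercept
        return 100.0 / (1.0 + np.exp(-logit))


def _check_Xy(X: np.ndarray, y: np.ndarray):
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; both classes required")


def _standardize(train: np.ndarray, *others: np.ndarray):
    """z using training statistics (ddof=0); zero-variance columns pass through."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (mu, sd, (train - mu) / sd, *[(o - mu) / sd for o in others])


def fit_regularized_logistic(X, y, C: float):
    """Maximize the L2-penalized logistic log-likelihood (penalty ||w||^2/(2C)).

    `X` is used as supplied — callers standardize with training statistics.
    Returns (coefficients, intercept); the intercept is unpenalized.
    """
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    _check_Xy(X, y)
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-10, max_iter=10_000)
    clf.fit(X, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def cv_auc(features: pd.DataFrame, labels, C: float, k_folds: int = 5, seed: int = 0) -> float:
    """Stratified k-fold CV AUC of the logistic model on a fixed feature set.

    Held-out predicted probabilities are pooled across folds and a single
    AUC is computed on the pool.  Deterministic given the seed.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    _check_Xy(X, y)
    counts = np.bincount(y)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {k_folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        _, _, Ztr, Zte = _standardize(X[train_idx], X[test_idx])
        coef, intercept = fit_regularized_logistic(Ztr, y[train_idx], C)
        pooled[test_idx] = 1.0 / (1.0 + np.exp(-(Zte @ coef + intercept)))
    auc, _ = roc_auc(pooled, y)
    return auc


def forward_select(
    features: pd.DataFrame,
    labels,
    C: float,
    k_max: int = 10,
    seed: int = 0,
    min_improvement: float = 0.001,
) -> tuple[list, list]:
    """Greedy forward feature selection scored by stratified CV AUC.

    At each step the feature that maximizes the CV AUC of the augmented
    set enters; ties go to the earlier panel (column) order.  Selection
    stops at `k_max` features or when the best achievable improvement
    falls below `min_improvement` (the first feature always enters).
    Returns the ordered selected features and the stepwise AUC path, so
    every prefix is a candidate model.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    k_max = min(k_max, features.shape[1])
    selected: list = []
    path_auc: list[float] = []
    current = -np.inf
    while len(selected) < k_max:
        best_feat, best_auc = None, -np.inf
        for feat in features.columns:
            if feat in selected:
                continue
            auc = cv_auc(features[selected + [feat]], labels, C, seed=seed)
            if auc > best_auc:  # strict: ties keep the first-listed feature
                best_feat, best_auc = feat, auc
        if selected and best_auc - current < min_improvement:
            break
        selected.append(best_feat)
        path_auc.append(best_auc)
        current = best_auc
    return selected, path_auc


def train_candidate(features: pd.DataFrame, labels, subset, C: float, seed: int = 0) -> CandidateModel:
    """Fit a candidate on the full training set and attach its CV AUC."""
    subset = list(subset)
    X = features.loc[:, subset].to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    mu, sd, Z = _standardize(X)[:3]
    coef, intercept = fit_regularized_logistic(Z, y, C)
    return CandidateModel(
        features=tuple(subset),
        C=C,
        coef=tuple(coef),
        intercept=intercept,
        mean=tuple(mu),
        scale=tuple(sd),
        cv_auc=cv_auc(features.loc[:, subset], y, C, seed=seed),
    )


def build_candidates(
    features: pd.DataFrame,
    labels,
    C_grid=DEFAULT_C_GRID,
    k_max: int = 10,
    seed: int = 0,
) -> list[CandidateModel]:
    """Forward-select a path per C; every path prefix becomes a candidate."""
    candidates = []
    for C in C_grid:
        path, _ = forward_select(features, labels, C, k_max=k_max, seed=seed)
        for k in range(1, len(path) + 1):
            candidates.append(train_candidate(features, labels, path[:k], C, seed=seed))
    return candidates


def evaluate_variability(model: CandidateModel, replicates: pd.DataFrame, groups=None) -> float:
    """Analytic variability of a candidate on technical replicates (4*std).

    Each replicate is scored with the *fixed* model (probability x 100),
    scores are mean-centered within biological sample, all centered values
    are pooled, and 4 times the pooled sample SD (ddof=1) is returned.

    `replicates` either carries a MultiIndex whose first level is the
    biological sample, or `groups` supplies the per-row biological ids.
    """
    if groups is None:
        if not isinstance(replicates.index, pd.MultiIndex):
            raise ValueError("supply `groups` or a (biological, replicate) MultiIndex")
        groups = replicates.index.get_level_values(0)
    groups = np.asarray(groups)
    scores = model.decision_scores(replicates)
    centered = pd.Series(scores).groupby(groups).transform(lambda s: s - s.mean())
    sizes = pd.Series(scores).groupby(groups).size()
    if (sizes < 2).all():
        raise ValueError("all biological samples are singletons; SD undefined")
    pooled = centered.to_numpy()
    return float(4.0 * np.std(pooled, ddof=1))


def _with_variability(candidates, replicates, groups=None) -> list[CandidateModel]:
    return [
        replace(m, variability_4std=evaluate_variability(m, replicates, groups))
        for m in candidates
    ]


def select_final_model(
    candidates: list[CandidateModel],
    auc_floor: float = 0.76,
    variability_ceiling: float = 20.0,
) -> CandidateModel:
    """Dual-criterion selection: best CV AUC subject to a variability cap.

    Among candidates with cv_auc >= `auc_floor` and 4*std <=
    `variability_ceiling`, returns the one with maximal CV AUC; ties break
    to smaller variability, then fewer features, then smaller C.  If no
    candidate is feasible the error lists the Pareto front (max AUC / min
    variability trade-offs) to guide threshold revision.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    for m in candidates:
        if m.variability_4std is None:
            raise ValueError(f"candidate {m.features} has no variability score")
    feasible = [
        m for m in candidates
        if m.cv_auc >= auc_floor and m.variability_4std <= variability_ceiling
    ]
    if not feasible:
        front = []
        for m in sorted(candidates, key=lambda m: (-m.cv_auc, m.variability_4std)):
            if not front or m.variability_4std < front[-1].variability_4std:
                front.append(m)
        desc = [
            f"(features={m.features}, cv_auc={m.cv_auc:.3f}, 4*std={m.variability_4std:.2f})"
            for m in front
        ]
        raise ValueError(
            "no model meets criteria "
            f"(AUC >= {auc_floor}, 4*std <= {variability_ceiling}); "
            "Pareto front: " + "; ".join(desc)
        )
    return min(
        feasible,
        key=lambda m: (-m.cv_auc, m.variability_4std, len(m.features), m.C),
    )
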