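"""Bootstrap out-of-bag ensemble scoring: the 0-100 patient score.

Given a fixed feature subset and regularization C, the cohort is resampled
with replacement B times (default 1000).  Each resample trains a logistic
model (coefficients refit per resample, training-statistics
standardization) which then scores the patients *absent* from the
resample; a patient's final score is 100 times the mean out-of-bag
predicted probability of non-progression across the iterations in which
they were out of bag.  Averaging over out-of-bag predictions approximates
performance on unseen patients without holding out a fixed validation
split.

The cohort median of the scores is the default classification threshold:
scores at or below the threshold predict progression (ties go to the
progressor side, so with an odd cohort of distinct scores the median
patient is a predicted progressor), scores above predict non-progression.
Patients are also ranked into quartiles of the score for dose-response
style analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import _standardize, fit_regularized_logistic

__all__ = ["ScoreSet", "bootstrap_oob_scores", "classify", "assign_quartiles"]

logger = logging.getLogger(__name__)


@dataclass
class ScoreSet:
    """Per-patient ensemble scores and their downstream labels.

    `table` is indexed by sample id with columns: score (0-100, NaN when a
    patient was never out of bag), oob_appearances, and — once `classify`
    / `assign_quartiles` have run — predicted_class and quartile.
    `redraws` counts resamples rejected for being single-class.
    """

    table: pd.DataFrame
    B: int
    seed: int
    threshold: float | None = None
    quartile_boundaries: tuple | None = None
    redraws: int = 0

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


def bootstrap_oob_scores(
    features: pd.DataFrame,
    labels,
    model_features,
    C: float,
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 10_000,
) -> ScoreSet:
    """Average out-of-bag logistic probabilities over B bootstrap resamples.

    Per iteration, n patients are drawn with replacement; a single-class
    draw is redrawn (and counted in ``redraws``) so exactly B iterations
    contribute.  Patients never out of bag across all B iterations get a
    missing score with a warning.  One seeded generator drives all draws,
    so results are bitwise reproducible given (seed, B, input order).
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    model_features = list(model_features)
    missing_cols = [f for f in model_features if f not in features.columns]
    if missing_cols:
        raise ValueError(f"model features absent from matrix: {missing_cols}")
    X = features.loc[:, model_features].to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    n = len(y)
    rng = np.random.default_rng(seed)
    score_sum = np.zeros(n)
    appearances = np.zeros(n, dtype=int)
    redraws = 0
    for _ in range(B):
        draw = rng.integers(0, n, size=n)
        while len(np.unique(y[draw])) < 2:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many single-class resamples; check labels")
            draw = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), draw, assume_unique=False)
        if len(oob) == 0:
            continue
        _, _, Ztr, Zoob = _standardize(X[draw], X[oob])
        coef, intercept = fit_regularized_logistic(Ztr, y[draw], C)
        prob = 1.0 / (1.0 + np.exp(-(Zoob @ coef + intercept)))
        score_sum[oob] += prob
        appearances[oob] += 1
    if redraws:
        logger.info("redrew %d single-class resamples", redraws)
    never = appearances == 0
    scores = np.full(n, np.nan)
    scores[~never] = 100.0 * score_sum[~never] / appearances[~never]
    if never.any():
        logger.warning(
            "%d patient(s) never out of bag; scores missing: %s",
            never.sum(), list(features.index[never]),
        )
    table = pd.DataFrame(
        {"score": scores, "oob_appearances": appearances}, index=features.index
    )
    return ScoreSet(table=table, B=B, seed=seed, redraws=redraws)


def classify(score_set: ScoreSet, threshold: float | None = None) -> ScoreSet:
    """Threshold scores into predicted progressors / non-progressors.

    The threshold defaults to the cohort median score.  A score strictly
    above the threshold predicts non-progression; at or below predicts
    progression (the tie goes to the progressor side).
    """
    scores = score_set.scores
    valid = scores.dropna()
    if len(valid) == 0:
        raise ValueError("all scores missing; nothing to classify")
    if len(valid) < 2:
        raise ValueError("need at least 2 scored patients")
    if threshold is None:
        threshold = float(np.median(valid))
    classes = pd.Series(
        np.where(scores > threshold, "non-progressor", "progressor"),
        index=scores.index, dtype=object,
    )
    classes[scores.isna()] = None
    score_set.table["predicted_class"] = classes
    score_set.threshold = float(threshold)
    return score_set


def assign_quartiles(score_set: ScoreSet) -> ScoreSet:
    """Rank patients by score into 4 contiguous groups (larger groups first).

    Group sizes are ceil(n/4) or floor(n/4) with the larger groups taking
    the lowest scores (n=103 gives 26/26/26/25).  Ties are broken by the
    stable input (sample-id) order.  The reported boundaries are the
    lowest score in each of quartiles 2-4.
    """
    scores = score_set.scores
    valid = scores.dropna()
    n = len(valid)
    if n < 4:
        raise ValueError(f"quartiles need >= 4 scored patients, got {n}")
    order = np.argsort(valid.to_numpy(), kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + 1] * rem + [base] * (4 - rem)
    labels = np.empty(n, dtype=int)
    start = 0
    boundaries = []
    for q, size in enumerate(sizes, start=1):
        idx = order[start:start + size]
        labels[idx] = q
        if q > 1:
            boundaries.append(float(valid.to_numpy()[idx[0]]))
        start += size
    quart = pd.Series(np.nan, index=scores.index, dtype=float)
    quart.loc[valid.index] = labels
    score_set.table["quartile"] = quart.astype("Int64")
    score_set.quartile_boundaries = tuple(boundaries)
    return score_set
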