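"""Clinical evaluation of a binary biomarker for disease control.

Everything downstream of a score set lives here: confusion matrices and the
eleven standard diagnostic-test metrics, disease-control / response rates
with Fisher exact tests, relative risk, ROC/AUC, quartile analysis,
head-to-head predictor comparison, Kaplan-Meier / log-rank, and Cox
proportional hazards.

Conventions
-----------
The *positive* class is the **non-progressor** (disease control: CR, PR or
SD); a "positive" prediction asserts the patient will not progress.  Display
rounding is half-up at 2 decimals for metrics and whole percent for rates;
full precision is retained in every returned object.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

__all__ = [
    "ConfusionMatrix",
    "MetricsTable",
    "SurvivalFit",
    "confusion",
    "diagnostic_metrics",
    "reconstruct_confusion",
    "group_rate",
    "fisher_2x2",
    "relative_risk",
    "roc_auc",
    "quartile_dcr",
    "compare_predictors",
    "km_logrank",
    "cox_ph",
    "round_half_up",
]

POSITIVE = "non-progressor"
NEGATIVE = "progressor"


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero-half upward (0.005 -> 0.01 at 2 dp).

    Printed clinical tables are produced by half-up rounding, not banker's
    rounding, so reconstruction arithmetic must use the same rule.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def _as_binary(values, name: str) -> np.ndarray:
    """Coerce class labels to a 0/1 array where 1 = non-progressor."""
    arr = np.asarray(values)
    if arr.dtype.kind in "OUS":
        lowered = np.char.lower(arr.astype(str))
        ok = np.isin(lowered, [POSITIVE, NEGATIVE])
        if not ok.all():
            bad = sorted(set(arr[~ok].tolist()))
            raise ValueError(f"{name}: unrecognized class labels {bad}")
        return (lowered == POSITIVE).astype(int)
    out = arr.astype(int)
    if not np.isin(out, [0, 1]).all():
        raise ValueError(f"{name}: binary labels must be 0/1")
    return out


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with non-progressor (disease control) as positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for nm in ("tp", "fp", "fn", "tn"):
            v = getattr(self, nm)
            if v < 0 or v != int(v):
                raise ValueError(f"{nm} must be a nonnegative integer, got {v}")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=int)


@dataclass(frozen=True)
class MetricsTable:
    """The 11 standard diagnostic metrics; NaN entries are listed in `undefined`."""

    accuracy: float
    sensitivity: float
    specificity: float
    prevalence: float
    fpr: float
    fnr: float
    ppv: float
    npv: float
    lr_plus: float
    lr_minus: float
    dor: float
    undefined: tuple = field(default_factory=tuple)

    _ORDER = (
        "accuracy", "sensitivity", "specificity", "prevalence", "fpr",
        "fnr", "ppv", "npv", "lr_plus", "lr_minus", "dor",
    )

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in self._ORDER})

    def rounded(self, decimals: int = 2) -> pd.Series:
        return self.as_series().map(lambda v: round_half_up(v, decimals))


def confusion(predicted, actual) -> ConfusionMatrix:
    """Cross-tabulate predicted vs actual class (positive = non-progressor)."""
    p = _as_binary(predicted, "predicted")
    a = _as_binary(actual, "actual")
    if len(p) != len(a):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(a)} labels")
    return ConfusionMatrix(
        tp=int(((p == 1) & (a == 1)).sum()),
        fp=int(((p == 1) & (a == 0)).sum()),
        fn=int(((p == 0) & (a == 1)).sum()),
        tn=int(((p == 0) & (a == 0)).sum()),
    )


def _safe_div(num: float, den: float):
    if den == 0:
        return math.nan, True
    return num / den, False


def diagnostic_metrics(cm: ConfusionMatrix) -> MetricsTable:
    """Compute the 11-metric diagnostic table from a confusion matrix.

    Zero denominators yield NaN values flagged in ``undefined`` rather than
    raising; the identities FNR = 1 - sensitivity, FPR = 1 - specificity and
    DOR = (TP*TN)/(FP*FN) hold exactly wherever defined.
    """
    undefined = []
    sens, u = _safe_div(cm.tp, cm.tp + cm.fn)
    if u:
        undefined += ["sensitivity", "fnr"]
    spec, u = _safe_div(cm.tn, cm.tn + cm.fp)
    if u:
        undefined += ["specificity", "fpr"]
    ppv, u = _safe_div(cm.tp, cm.tp + cm.fp)
    if u:
        undefined.append("ppv")
    npv, u = _safe_div(cm.tn, cm.tn + cm.fn)
    if u:
        undefined.append("npv")
    lr_plus, u = _safe_div(sens, 1.0 - spec) if not math.isnan(sens) and not math.isnan(spec) else (math.nan, True)
    if u:
        undefined.append("lr_plus")
    lr_minus, u = _safe_div(1.0 - sens, spec) if not math.isnan(sens) and not math.isnan(spec) else (math.nan, True)
    if u:
        undefined.append("lr_minus")
    dor, u = _safe_div(cm.tp * cm.tn, cm.fp * cm.fn)
    if u:
        undefined.append("dor")
    return MetricsTable(
        accuracy=(cm.tp + cm.tn) / cm.n,
        sensitivity=sens,
        specificity=spec,
        prevalence=(cm.tp + cm.fn) / cm.n,
        fpr=1.0 - spec if not math.isnan(spec) else math.nan,
        fnr=1.0 - sens if not math.isnan(sens) else math.nan,
        ppv=ppv,
        npv=npv,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
        dor=dor,
        undefined=tuple(dict.fromkeys(undefined)),
    )


def reconstruct_confusion(
    n: int,
    prevalence: float,
    sensitivity: float,
    specificity: float,
    decimals: int = 2,
) -> ConfusionMatrix:
    """Recover the unique integer confusion matrix behind a printed metric row.

    Exhaustively searches all (TP, FP, FN, TN) with TP+FP+FN+TN = n whose
    prevalence, sensitivity and specificity round (half-up) to the printed
    values.  Published metric tables usually print only rounded rates; when
    the cohort size is known this inversion is exact and turns a printed
    table back into integer counts suitable for exact re-testing.

    Raises ``ValueError`` if no matrix or more than one matrix matches,
    listing the candidates found.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    factor = 10.0**decimals

    def _hits(total: int, target: float) -> np.ndarray:
        if total == 0:
            return np.array([], dtype=int)
        counts = np.arange(total + 1)
        rounded = np.floor(counts / total * factor + 0.5) / factor
        return counts[rounded == target]

    solutions = []
    for pos in _hits(n, prevalence):
        pos = int(pos)
        neg = n - pos
        for tp, tn in itertools.product(_hits(pos, sensitivity), _hits(neg, specificity)):
            solutions.append(
                ConfusionMatrix(tp=int(tp), fp=neg - int(tn), fn=pos - int(tp), tn=int(tn))
            )
    if not solutions:
        raise ValueError(
            f"no confusion matrix with n={n} rounds to prevalence={prevalence}, "
            f"sensitivity={sensitivity}, specificity={specificity}"
        )
    if len(solutions) > 1:
        raise ValueError(
            f"ambiguous reconstruction: {len(solutions)} matrices match: {solutions}"
        )
    return solutions[0]


def group_rate(outcomes_by_group: dict) -> pd.DataFrame:
    """Success rate per group (e.g. DCR or ORR), counts retained.

    `outcomes_by_group` maps group name -> iterable of 0/1 success flags.
    Empty groups are flagged (`rate` NaN) rather than raising.
    """
    if not outcomes_by_group:
        raise ValueError("no groups supplied")
    rows = []
    for name, flags in outcomes_by_group.items():
        flags = np.asarray(list(flags), dtype=float)
        k, m = int(flags.sum()), len(flags)
        rows.append({
            "group": name,
            "successes": k,
            "size": m,
            "rate": k / m if m else math.nan,
            "empty": m == 0,
        })
    return pd.DataFrame(rows).set_index("group")


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 integer table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be nonnegative integers")
    return float(stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")[1])


def relative_risk(a: int, n1: int, b: int, n2: int, alpha: float = 0.05):
    """Relative risk (a/n1)/(b/n2) with a log-normal Wald CI.

    Returns ``(rr, (lo, hi))``; a zero rate in the reference group yields an
    infinite RR with a NaN interval (flagged, not raised).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups must be nonempty")
    r1, r2 = a / n1, b / n2
    if r2 == 0:
        return math.inf, (math.nan, math.nan)
    rr = r1 / r2
    if a == 0:
        return rr, (math.nan, math.nan)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    return rr, (rr * math.exp(-z * se), rr * math.exp(z * se))


def roc_auc(scores, labels):
    """AUC (Mann-Whitney with ties counted 1/2) and the full ROC curve.

    Returns ``(auc, curve)`` where `curve` is a DataFrame of (threshold,
    fpr, tpr) evaluated at every distinct score, from the strictest
    threshold (nothing called positive) to the loosest.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels, "labels")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    curve = pd.DataFrame({
        "threshold": np.r_[np.inf, s_sorted[distinct]],
        "fpr": np.r_[0.0, fps / n_neg],
        "tpr": np.r_[0.0, tps / n_pos],
    })
    return float(auc), curve


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def quartile_dcr(quartiles, outcomes) -> pd.DataFrame:
    """Per-quartile disease-control rate, each tested against its complement.

    For each quartile a Fisher exact test compares control/progression counts
    inside the quartile against all remaining patients (unadjusted, with
    0.05 / 0.01 / 0.001 significance stars).
    """
    q = np.asarray(quartiles, dtype=int)
    y = _as_binary(outcomes, "outcomes")
    if len(q) != len(y):
        raise ValueError("quartiles and outcomes length mismatch")
    pooled = y.mean()
    rows = []
    for label in sorted(np.unique(q)):
        inside = y[q == label]
        outside = y[q != label]
        table = [
            [int(inside.sum()), int(len(inside) - inside.sum())],
            [int(outside.sum()), int(len(outside) - outside.sum())],
        ]
        p = fisher_2x2(table)
        rows.append({
            "quartile": int(label),
            "successes": int(inside.sum()),
            "size": int(len(inside)),
            "rate": inside.mean(),
            "pooled_rate": pooled,
            "fisher_p": p,
            "stars": _stars(p),
        })
    return pd.DataFrame(rows).set_index("quartile")


def compare_predictors(pred_a, pred_b, actual) -> dict:
    """Head-to-head comparison of two binary predictors on the same samples.

    Reports per-test metric tables, the concordant count, each test's false
    positives/negatives among the discordant samples (each discordant sample
    is an error for exactly one test), and unpaired Fisher tests comparing
    sensitivities (correct/incorrect among actual positives) and
    specificities (among actual negatives).  Note this unpaired construction
    differs from paired approaches (e.g. McNemar) and is reported as such.
    """
    a = _as_binary(pred_a, "pred_a")
    b = _as_binary(pred_b, "pred_b")
    y = _as_binary(actual, "actual")
    if not (len(a) == len(b) == len(y)):
        raise ValueError("predictor and label vectors must have equal length")
    cm_a, cm_b = confusion(a, y), confusion(b, y)
    disc = a != b
    sens_table = [
        [cm_a.tp, cm_a.fn],
        [cm_b.tp, cm_b.fn],
    ]
    spec_table = [
        [cm_a.tn, cm_a.fp],
        [cm_b.tn, cm_b.fp],
    ]
    return {
        "n": len(y),
        "concordant": int((~disc).sum()),
        "discordant": int(disc.sum()),
        "metrics_a": diagnostic_metrics(cm_a),
        "metrics_b": diagnostic_metrics(cm_b),
        "discordant_errors_a": {
            "false_positives": int((disc & (a == 1) & (y == 0)).sum()),
            "false_negatives": int((disc & (a == 0) & (y == 1)).sum()),
        },
        "discordant_errors_b": {
            "false_positives": int((disc & (b == 1) & (y == 0)).sum()),
            "false_negatives": int((disc & (b == 0) & (y == 1)).sum()),
        },
        "sensitivity_fisher_p": fisher_2x2(sens_table),
        "specificity_fisher_p": fisher_2x2(spec_table),
    }


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves per group with the two-group log-rank test."""

    curves: dict            # group -> DataFrame(time, at_risk, survival)
    medians: dict           # group -> median survival (NaN if curve stays > 0.5)
    statistic: float
    p_value: float


def km_logrank(times, events, groups) -> SurvivalFit:
    """Kaplan-Meier product-limit curves per group plus the log-rank test.

    Two groups use the standard log-rank chi-square; more than two fall back
    to the multivariate (k-sample) log-rank statistic.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if (t < 0).any():
        raise ValueError("times must be nonnegative")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be binary 0/1")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    curves, medians = {}, {}
    for lab in labels:
        mask = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        tab = kmf.event_table
        curves[lab] = pd.DataFrame({
            "time": kmf.survival_function_.index.values,
            "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).values,
            "survival": kmf.survival_function_.iloc[:, 0].values,
        })
        medians[lab] = float(kmf.median_survival_time_)
    if len(labels) == 2:
        m0 = g == labels[0]
        res = logrank_test(t[m0], t[~m0], event_observed_A=e[m0], event_observed_B=e[~m0])
    else:
        res = multivariate_logrank_test(t, g, e)
    return SurvivalFit(
        curves=curves,
        medians=medians,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def cox_ph(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron tie handling) via partial likelihood.

    Returns one row per covariate: coefficient, hazard ratio, 95% Wald CI and
    Wald p.  Constant covariates are rejected by name before fitting.
    """
    cov = pd.DataFrame(covariates).copy()
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 1:
        raise ValueError("Cox model requires at least one event")
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    df = cov.reset_index(drop=True)
    df["_time"] = t
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # convergence diagnostics surfaced to caller
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    out = pd.DataFrame({
        "coef": cph.params_,
        "hr": np.exp(cph.params_),
        "hr_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "hr_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
        "p": cph.summary["p"],
    })
    out.index.name = "covariate"
    return out
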