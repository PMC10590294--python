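"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study population the pipeline targets: ~103
patients with a 62-feature immune panel organized into correlated
"cell-type" blocks, a sparse logistic outcome model with disease-control
prevalence near 0.41, exponential/Weibull survival whose hazard falls with
the latent immune score, a technical-replicate design of 6 biological
samples x 9 replicates, a negative-binomial expression layer so the
signature-scoring stage can be exercised end-to-end, and a CPS-like
integer comparator marker correlated with immune activity.

All outputs are deterministic given the spec's seed.  Feature
distributions are stand-ins: no public description of the real panel's
marginals exists, so multivariate normal blocks are used as the simplest
structure carrying the assumed correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "CohortSpec",
    "ReplicateSpec",
    "generate_cohort",
    "generate_replicates",
    "generate_expression_layer",
    "generate_comparator_marker",
]

N_BLOCKS = 8  # correlated "cell-type" blocks; remaining features independent


def _err(fieldname: str, msg: str):
    raise ValueError(f"CohortSpec.{fieldname}: {msg}")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic patient cohort.

    Defaults emulate the target study: n=103 patients, 62 immune features,
    three informative features with log-odds effects, disease-control
    prevalence 0.41, and survival whose log-hazard decreases with the
    latent immune predictor.
    """

    n_patients: int = 103
    n_features: int = 62
    informative_indices: tuple = (0, 1, 2)
    effect_sizes: tuple = (0.5, 0.6, 0.7)
    target_prevalence: float = 0.41
    feature_block_correlation: float = 0.4
    survival_baseline_scale: float = 12.0   # months; median OS scale under null
    survival_score_loghazard: float = 0.35  # log-hazard drop per unit latent score
    censor_rate: float = 0.25
    followup_horizon: float = 48.0          # administrative censoring, months
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            _err("n_patients", f"must be >= 4, got {self.n_patients}")
        if self.n_features < 1:
            _err("n_features", f"must be >= 1, got {self.n_features}")
        idx = tuple(self.informative_indices)
        if any(i < 0 or i >= self.n_features for i in idx):
            _err("informative_indices", f"must lie in [0, {self.n_features}), got {idx}")
        if len(set(idx)) != len(idx):
            _err("informative_indices", "must be unique")
        if len(self.effect_sizes) != len(idx):
            _err("effect_sizes", "must match informative_indices in length")
        if not 0 < self.target_prevalence < 1:
            _err("target_prevalence", f"must be strictly in (0,1), got {self.target_prevalence}")
        if not -1 <= self.feature_block_correlation <= 1:
            _err("feature_block_correlation", "must be in [-1, 1]")
        if self.survival_baseline_scale <= 0:
            _err("survival_baseline_scale", "must be positive")
        if not 0 <= self.censor_rate < 1:
            _err("censor_rate", f"must be in [0, 1), got {self.censor_rate}")
        if self.followup_horizon <= 0:
            _err("followup_horizon", "must be positive")
        if self.weibull_shape <= 0:
            _err("weibull_shape", "must be positive")


@dataclass(frozen=True)
class ReplicateSpec:
    """Technical-replicate design: i.i.d. Gaussian assay noise per feature."""

    n_biological: int = 6
    n_replicates: int = 9
    technical_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_biological < 1 or self.n_replicates < 1:
            raise ValueError("n_biological and n_replicates must be >= 1")
        if self.technical_sd < 0:
            raise ValueError(f"technical_sd must be >= 0, got {self.technical_sd}")


def _block_covariance(n_features: int, rho: float) -> np.ndarray:
    """Block-diagonal equicorrelation: 8 blocks + independent remainder."""
    cov = np.eye(n_features)
    block = n_features // (N_BLOCKS + 1)
    if block >= 2 and rho != 0:
        for b in range(N_BLOCKS):
            lo, hi = b * block, (b + 1) * block
            cov[lo:hi, lo:hi] = rho
            np.fill_diagonal(cov[lo:hi, lo:hi], 1.0)
    return cov


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Bisect the logistic intercept so mean(sigmoid(b0+eta)) = target."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: (samples x features matrix, clinical table).

    Features are multivariate normal with block-equicorrelation structure.
    The outcome is Bernoulli(sigmoid(b0 + x.beta)) where beta is sparse
    (the informative features) and b0 is solved by bisection on the
    realized design so the *expected* disease-control prevalence equals
    the target.  Survival is proportional-hazards Weibull (shape 1 =
    exponential) with log-hazard = baseline - loghazard_coef * centered
    latent predictor, independent exponential censoring calibrated to the
    requested censor rate, and an administrative follow-up cap.

    The clinical table carries: outcome_label (CR/PR/SD for controls, PD
    for progressors), non_progressor flag, os_months, os_event.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features
    cov = _block_covariance(p, spec.feature_block_correlation)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        _err("feature_block_correlation", "covariance not positive definite")
    X = rng.standard_normal((n, p)) @ chol.T

    beta = np.zeros(p)
    beta[list(spec.informative_indices)] = spec.effect_sizes
    eta = X @ beta
    b0 = _solve_intercept(eta, spec.target_prevalence)
    prob = expit(b0 + eta)
    y = rng.random(n) < prob  # True = non-progressor (disease control)

    # CR/PR/SD split within controls: responders (CR+PR) roughly 60% of
    # controls, mirroring an ORR below the DCR.
    labels = np.where(y, "SD", "PD").astype(object)
    controls = np.flatnonzero(y)
    draw = rng.random(len(controls))
    labels[controls[draw < 0.15]] = "CR"
    labels[controls[(draw >= 0.15) & (draw < 0.60)]] = "PR"

    lp = spec.survival_score_loghazard * (eta - eta.mean())
    shape = spec.weibull_shape
    base_events = rng.exponential(1.0, n)
    t_event = spec.survival_baseline_scale * (base_events * np.exp(lp)) ** (1.0 / shape)
    if spec.censor_rate > 0:
        cens_scale = spec.survival_baseline_scale * (1 - spec.censor_rate) / spec.censor_rate
        t_cens = rng.exponential(cens_scale, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, spec.followup_horizon)
    os_months = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    ids = [f"S{i:04d}" for i in range(n)]
    fm = pd.DataFrame(X, index=ids, columns=[f"f{j:02d}" for j in range(p)])
    fm.index.name = "sample_id"
    clinical = pd.DataFrame(
        {
            "outcome_label": labels,
            "non_progressor": y.astype(int),
            "os_months": os_months,
            "os_event": os_event,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return fm, clinical


def generate_replicates(base_features: pd.DataFrame, spec: ReplicateSpec) -> pd.DataFrame:
    """Expand biological samples into technical replicates.

    Each replicate is its base row plus i.i.d. Gaussian noise with SD
    `technical_sd` per feature.  The result carries a (biological,
    replicate) MultiIndex so downstream variability scoring can center
    within biological sample; it has exactly
    n_biological * n_replicates rows.
    """
    if len(base_features) != spec.n_biological:
        raise ValueError(
            f"expected {spec.n_biological} biological rows, got {len(base_features)}"
        )
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for bio_id, row in base_features.iterrows():
        noise = rng.normal(0.0, spec.technical_sd, (spec.n_replicates, len(row)))
        block = pd.DataFrame(
            row.to_numpy() + noise,
            columns=base_features.columns,
            index=pd.MultiIndex.from_product(
                [[bio_id], [f"rep{j}" for j in range(spec.n_replicates)]],
                names=["biological", "replicate"],
            ),
        )
        blocks.append(block)
    return pd.concat(blocks)


def generate_expression_layer(
    feature_matrix: pd.DataFrame,
    genes_per_signature: int = 10,
    dispersion: float = 0.05,
    library_size: int = 1_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Back-fill a count matrix whose signature scores track given features.

    For each feature, `genes_per_signature` member genes receive
    negative-binomial counts whose log2-mean equals the feature value plus
    a per-gene baseline (so log-CPM recovers the feature up to an additive
    constant).  Returns (genes x samples counts, gene sets dict suitable
    for GMT export).
    """
    if genes_per_signature < 1:
        raise ValueError("genes_per_signature must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = np.random.default_rng(seed)
    n_genes = feature_matrix.shape[1] * genes_per_signature
    base_mean = library_size / max(n_genes, 1)
    rows, gene_ids = [], []
    gene_sets: dict[str, list[str]] = {}
    nb_n = 1.0 / dispersion
    for feat in feature_matrix.columns:
        v = feature_matrix[feat].to_numpy(dtype=float)
        members = [f"{feat}_g{j}" for j in range(genes_per_signature)]
        gene_sets[feat] = members
        for g in members:
            mu = base_mean * np.power(2.0, v)
            counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
            rows.append(counts)
            gene_ids.append(g)
    expr = pd.DataFrame(
        np.vstack(rows), index=pd.Index(gene_ids, name="gene_id"),
        columns=feature_matrix.index,
    )
    return expr, gene_sets


def generate_comparator_marker(
    feature_matrix: pd.DataFrame,
    weights,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """A CPS-like integer marker in {0..100} correlated with immune activity.

    The raw signal x.w + Gaussian noise is mapped monotonically onto the
    integer range via its within-cohort rank, mimicking a pathologist
    score: ties in the signal receive identical scores, and the clinical
    categories (marker >= 1, marker >= 20) are derivable downstream.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (feature_matrix.shape[1],):
        raise ValueError(
            f"weights length {w.shape} does not match {feature_matrix.shape[1]} features"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    signal = feature_matrix.to_numpy() @ w
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, len(signal))
    n = len(signal)
    if n == 1 or np.ptp(signal) == 0:
        values = np.zeros(n, dtype=int)
    else:
        ranks = stats.rankdata(signal, method="average")
        values = np.floor(100.0 * (ranks - 1) / (n - 1) + 0.5).astype(int)
    return pd.Series(values, index=feature_matrix.index, name="cps")
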