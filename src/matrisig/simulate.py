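"""Synthetic data generators for the two study regimes.

``simulate_fibroblast`` emulates small-replicate two-condition arrays:
log-normal intensities with planted signed fold changes on chosen
features. ``simulate_cohort`` emulates a tumour cohort in which a latent
centroid-like expression state carries a proportional-hazards effect,
with administrative censoring and independent clinical covariates.

Modelling choices (not claims about the source data): array noise is
log-normal on intensities; survival is Weibull with shape 1 by default
(i.e. exponential, constant baseline hazard) for analytic tractability.
In the cohort, patients without the latent state receive the
opposite-signed expression profile, so the two strata mirror the
positively- and negatively-correlated groups a sign-of-correlation
classifier is meant to separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CASE, CONTROL, ExpressionMatrix
from .signature import Centroid

DEFAULT_PREVALENCES = {
    "er": 0.7,
    "ln": 0.4,
    "age": 0.6,
    "size": 0.45,
    "grade3": 0.35,
}
SUBTYPES = ("LumA", "LumB", "Basal", "Her2", "NormalLike")
SUBTYPE_PROBS = (0.4, 0.2, 0.15, 0.15, 0.1)


@dataclass
class FibroblastSimSpec:
    """Parameters of the two-condition array simulation."""

    n_features: int = 200
    n_case: int = 3
    n_ctrl: int = 3
    planted: list[tuple[int, float]] = field(default_factory=list)
    noise_sigma: float = 0.2
    baseline: float = 8.0  # log2-scale location of gene baselines
    gene_sd: float = 1.0  # spread of per-gene baselines (log2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for feature, fc in self.planted:
            if abs(fc) < 1:
                raise ValueError(f"planted |fold change| must be >= 1, got {fc}")
            if not 0 <= int(feature) < self.n_features:
                raise ValueError(f"planted feature index {feature} out of range")


def simulate_fibroblast(spec: FibroblastSimSpec) -> ExpressionMatrix:
    """Simulate a case/control array matrix with planted fold changes.

    log2 intensity = gene baseline + condition effect + N(0, sigma);
    the condition effect adds sign(fc) * log2|fc| to the case arm of each
    planted feature, so in the noiseless limit the case/control median
    ratio equals the planted fold change exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_case + spec.n_ctrl
    gene_base = rng.normal(spec.baseline, spec.gene_sd, size=spec.n_features)
    log2 = np.tile(gene_base[:, None], (1, n_samples))
    for feature, fc in spec.planted:
        log2[int(feature), : spec.n_case] += np.sign(fc) * np.log2(abs(fc))
    log2 += rng.normal(0.0, spec.noise_sigma, size=log2.shape)

    feature_ids = [f"probe_{i:04d}" for i in range(spec.n_features)]
    sample_ids = [f"case_{i}" for i in range(spec.n_case)] + [
        f"ctrl_{i}" for i in range(spec.n_ctrl)
    ]
    condition = {s: (CASE if s.startswith("case") else CONTROL) for s in sample_ids}
    values = pd.DataFrame(np.exp2(log2), index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(values, scale="linear", condition=condition)


@dataclass
class CohortSimSpec:
    """Parameters of the tumour-cohort simulation."""

    n_patients: int
    centroid: Centroid
    frac_centroid_like: float = 0.4
    hr_true: float = 2.0
    baseline_hazard: float = 0.004  # events per month in the reference stratum
    admin_censor_months: float = 120.0
    covariate_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    seed: int = 0
    signal_scale: float = 2.0  # log2 units along the centroid direction
    noise_sigma: float = 0.5  # log2-scale expression noise
    suppressor_genes: tuple = ()  # genes whose effect opposes their weight sign
    n_noise_genes: int = 0
    weibull_shape: float = 1.0  # 1 = exponential survival
    endpoint: str = "DMFS"
    baseline_log2: float = 8.0  # cohort-wide expression location

    def __post_init__(self) -> None:
        if not 0 <= self.frac_centroid_like <= 1:
            raise ValueError("frac_centroid_like must be in [0, 1]")
        if self.hr_true <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hr_true and baseline_hazard must be > 0")
        if self.centroid is None or len(self.centroid) == 0:
            raise ValueError("centroid must be non-empty")
        bad = {k: v for k, v in self.covariate_prevalences.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"prevalences outside [0, 1]: {bad}")
        unknown = [g for g in self.suppressor_genes
                   if str(g).strip().upper() not in self.centroid.weights.index]
        if unknown:
            raise ValueError(f"suppressor genes not in centroid: {unknown}")


def simulate_cohort(
    spec: CohortSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Simulate an expression cohort with a latent prognostic state.

    Returns ``(expression, clinical, latent)`` where ``latent`` is a
    boolean Series marking centroid-like patients. Latent patients'
    log2 expression runs along the transformed centroid direction
    (suppressor genes flipped); the rest along its negation; both plus
    N(0, noise_sigma). Survival is Weibull (exponential by default) with
    hazard ``baseline_hazard * hr_true**latent`` and administrative
    censoring at ``admin_censor_months``. Covariates are independent
    draws at the stated prevalences.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    latent = rng.random(n) < spec.frac_centroid_like

    t = spec.centroid.transformed()
    direction = t / np.linalg.norm(t.to_numpy())
    flip = [str(g).strip().upper() for g in spec.suppressor_genes]
    direction.loc[[g for g in flip if g in direction.index]] *= -1

    genes = list(direction.index) + [f"NULL{i:03d}" for i in range(spec.n_noise_genes)]
    effect = np.concatenate([direction.to_numpy(), np.zeros(spec.n_noise_genes)])
    signs = np.where(latent, 1.0, -1.0)
    log2 = (
        spec.baseline_log2
        + spec.signal_scale * np.outer(effect, signs)
        + rng.normal(0.0, spec.noise_sigma, size=(len(genes), n))
    )
    sample_ids = [f"P{i:05d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2), index=genes, columns=sample_ids), scale="linear"
    )

    hazard = spec.baseline_hazard * np.where(latent, spec.hr_true, 1.0)
    raw_times = (rng.exponential(1.0, size=n) / hazard) ** (1.0 / spec.weibull_shape)
    event = (raw_times <= spec.admin_censor_months).astype(int)
    times = np.minimum(raw_times, spec.admin_censor_months)
    times = np.maximum(times, 1e-6)  # clinical contract requires time > 0

    prev = {**DEFAULT_PREVALENCES, **spec.covariate_prevalences}
    grade3 = rng.random(n) < prev["grade3"]
    grade = np.where(grade3, 3, rng.choice([1, 2], size=n, p=[0.35, 0.65]))
    clinical = pd.DataFrame(
        {
            "time_months": times,
            "event": event,
            "endpoint": spec.endpoint,
            "er": np.where(rng.random(n) < prev["er"], "pos", "neg"),
            "ln": np.where(rng.random(n) < prev["ln"], "pos", "neg"),
            "grade": grade,
            "age_gt50": rng.random(n) < prev["age"],
            "size_gt20mm": rng.random(n) < prev["size"],
            "subtype": rng.choice(SUBTYPES, size=n, p=SUBTYPE_PROBS),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return expr, clinical, pd.Series(latent, index=sample_ids, name="latent")
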