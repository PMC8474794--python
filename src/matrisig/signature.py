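"""Fold-change centroids and cohort stratification.

A centroid is an ordered gene -> signed fold-change weight vector built
from a DE table. Patients are stratified either by the sign of the
Pearson correlation between their median-centred log2 profile and the
log2-transformed centroid (``classify_by_centroid``) or by a weighted
median-split composite score (``composite_score``).

Normalisation choice (documented deliberately): cohort expression is
log2-transformed and gene-wise median-centred, and centroid weights are
compared on the signed-log2 scale ``sign(w) * log2(|w|)`` — correlating
against raw linear ratios would let the largest fold changes dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

GROUP_POSITIVE = "positive"
GROUP_NEGATIVE = "negative"
GROUP_HIGH = "high"
GROUP_LOW = "low"


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class Centroid:
    """Ordered gene -> signed fold-change weight mapping."""

    weights: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        self.weights.index = [_norm(g) for g in self.weights.index]
        if self.weights.index.duplicated().any():
            raise ValueError("duplicate genes in centroid")
        if (self.weights == 0).any() or not np.isfinite(self.weights).all():
            raise ValueError("centroid weights must be non-zero and finite")

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def transformed(self) -> pd.Series:
        """Signed log2 magnitude of each weight: sign(w) * log2(|w|)."""
        w = self.weights
        return np.sign(w) * np.log2(w.abs())

    def __len__(self) -> int:
        return len(self.weights)


def build_centroid(de: pd.DataFrame, provenance: str = "") -> Centroid:
    """Collapse a DE table to one signed weight per gene.

    The weight is the arithmetic mean of the gene's signed probe fold
    changes (probe averaging for multi-probe genes).
    """
    if de.empty:
        raise ValueError("cannot build a centroid from an empty DE table")
    symbols = de["gene_symbol"].map(_norm)
    means = de["fold_change"].groupby(symbols, sort=False).mean()
    if (means == 0).any():
        zero = list(means.index[means == 0])
        raise ValueError(f"probe fold changes average to zero for {zero}")
    return Centroid(means, provenance=provenance)


def reverse_signs(c: Centroid, genes) -> Centroid:
    """Negate the weights of the listed genes, leaving the rest alone."""
    targets = [_norm(g) for g in genes]
    unknown = [g for g in targets if g not in c.weights.index]
    if unknown:
        raise ValueError(f"genes not in centroid: {unknown}")
    w = c.weights.copy()
    w.loc[targets] *= -1
    note = f"; reversed: {','.join(targets)}" if targets else ""
    return Centroid(w, provenance=c.provenance + note)


def centroid_correlation(profile: pd.Series, c: Centroid) -> float:
    """Pearson r between a patient profile and the transformed centroid.

    ``profile`` holds the patient's gene-wise median-centred log2 values;
    genes missing from the profile are dropped. At least 3 shared genes
    and non-zero variance on both sides are required.
    """
    t = c.transformed()
    shared = [g for g in t.index if g in profile.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared with centroid (need >= 3)")
    x = profile.loc[shared].to_numpy(dtype=float)
    y = t.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in profile or centroid over shared genes")
    return float(np.corrcoef(x, y)[0, 1])


def _centred_log2(cohort: ExpressionMatrix) -> pd.DataFrame:
    log2 = cohort.to_log2().values
    centred = log2.sub(log2.median(axis=1), axis=0)
    centred.index = [_norm(g) for g in centred.index]
    return centred


def _shared_genes(centred: pd.DataFrame, c: Centroid) -> list[str]:
    shared = [g for g in c.genes if g in centred.index]
    dropped = len(c) - len(shared)
    if dropped:
        logger.info("%d of %d centroid genes absent from cohort; dropped", dropped, len(c))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} centroid genes found in cohort (need >= 3)")
    return shared


def classify_by_centroid(
    cohort: ExpressionMatrix, c: Centroid, max_unclassifiable: float = 0.05
) -> pd.DataFrame:
    """Split a cohort by the sign of the per-patient centroid correlation.

    Returns a DataFrame indexed by sample id with ``score`` (Pearson r)
    and ``group`` (``positive`` iff r > 0; r == 0 goes to ``negative``).
    Patients whose correlation cannot be computed are excluded; more than
    ``max_unclassifiable`` of the cohort failing is an error.
    """
    centred = _centred_log2(cohort)
    shared = _shared_genes(centred, c)
    sub = centred.loc[shared]
    scores: dict[str, float] = {}
    failed: list[str] = []
    for sample in sub.columns:
        try:
            scores[sample] = centroid_correlation(sub[sample], c)
        except ValueError:
            failed.append(sample)
    if len(failed) > max_unclassifiable * len(sub.columns):
        raise ValueError(
            f"{len(failed)}/{len(sub.columns)} patients unclassifiable "
            f"(> {max_unclassifiable:.0%})"
        )
    if failed:
        logger.warning("%d patients unclassifiable: %s", len(failed), failed[:5])
    result = pd.DataFrame({"score": pd.Series(scores)})
    result["group"] = np.where(result["score"] > 0, GROUP_POSITIVE, GROUP_NEGATIVE)
    result.index.name = "sample_id"
    result.attrs["n_unclassifiable"] = len(failed)
    return result


def composite_score(cohort: ExpressionMatrix, c: Centroid) -> pd.DataFrame:
    """Weighted median-split stratification.

    Per patient the score is the mean over signature genes of
    ``sign(weight) * centred log2 expression`` (negative weighting for
    good-prognosis genes). Groups split at the cohort median score;
    scores equal to the median go to ``low``.
    """
    centred = _centred_log2(cohort)
    shared = _shared_genes(centred, c)
    signs = np.sign(c.weights.loc[shared]).to_numpy()
    sub = centred.loc[shared]
    scores = (sub.mul(signs, axis=0)).mean(axis=0)
    cut = scores.median()
    result = pd.DataFrame({"score": scores})
    result["group"] = np.where(result["score"] > cut, GROUP_HIGH, GROUP_LOW)
    result.index.name = "sample_id"
    return result


def read_centroid(path) -> Centroid:
    df = pd.read_csv(path, sep="\t")
    return Centroid(
        pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str)),
        provenance=f"loaded from {path}",
    )


def write_centroid(c: Centroid, path) -> None:
    c.weights.rename("weight").rename_axis("gene_symbol").to_csv(path, sep="\t")


def write_stratification(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t")


def read_stratification(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df
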