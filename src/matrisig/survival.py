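"""Survival machinery: follow-up truncation, Kaplan-Meier, log-rank, Cox.

The clinical table is a DataFrame indexed by sample id with columns
``time_months, event, endpoint, er, ln, grade, age_gt50, size_gt20mm,
subtype`` (the last five may hold ``unknown``/NA). Kaplan-Meier and Cox
fitting are delegated to lifelines; the log-rank test is computed
directly from the observed-minus-expected event counts so that the
per-group direction (who fares worse) is available to the screening
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.stats import chi2

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "time_months",
    "event",
    "endpoint",
    "er",
    "ln",
    "grade",
    "age_gt50",
    "size_gt20mm",
    "subtype",
]

def _encode_posneg(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.lower().map({"pos": 1.0, "neg": 0.0})


def _encode_grade3(s: pd.Series) -> pd.Series:
    num = pd.to_numeric(s, errors="coerce")
    return num.eq(3).astype(float).where(num.notna())


def _encode_bool(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.lower().map(
        {"true": 1.0, "false": 0.0, "1": 1.0, "0": 0.0, "1.0": 1.0, "0.0": 0.0}
    )


#: covariate name -> (clinical column, encoder to a 0/1 indicator, label)
COVARIATE_ENCODINGS = {
    "er": ("er", _encode_posneg, "ER_pos"),
    "ln": ("ln", _encode_posneg, "LN_pos"),
    "grade": ("grade", _encode_grade3, "G3"),
    "age": ("age_gt50", _encode_bool, "age_gt50"),
    "size": ("size_gt20mm", _encode_bool, "size_gt20mm"),
}


def validate_clinical(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("time_months", "event") if c not in ct.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    if (ct["time_months"] <= 0).any():
        raise ValueError("follow-up times must be > 0")
    if not ct["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return ct


def read_clinical(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t", index_col=0)
    ct.index = ct.index.astype(str)
    return validate_clinical(ct)


def write_clinical(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index_label="sample_id")


def apply_followup_cutoff(ct: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``cutoff`` months.

    Times strictly greater than the cutoff are truncated to it and their
    events cleared; an event at exactly the cutoff is retained.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = ct.copy()
    beyond = out["time_months"] > cutoff
    out.loc[beyond, "time_months"] = cutoff
    out.loc[beyond, "event"] = 0
    return out


def km_curve(times, events) -> pd.Series:
    """Product-limit survivor function, indexed by time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return kmf.survival_function_.iloc[:, 0]


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    observed: np.ndarray  # events per group
    expected: np.ndarray  # expected events per group
    group_sizes: np.ndarray


def logrank(groups) -> LogrankResult:
    """Log-rank test over two or more ``(times, events)`` samples.

    Returns the chi-square statistic on ``len(groups) - 1`` degrees of
    freedom, its upper-tail p-value, and the per-group observed and
    expected event counts (observed > expected marks the worse arm).
    """
    groups = [
        (np.asarray(t, dtype=float), np.asarray(e, dtype=int)) for t, e in groups
    ]
    if any(t.size == 0 for t, _ in groups):
        raise ValueError("each group must contain at least one subject")
    if sum(int(e.sum()) for _, e in groups) == 0:
        raise ValueError("log-rank test requires at least one event overall")
    k = len(groups)
    event_times = np.unique(
        np.concatenate([t[e == 1] for t, e in groups if (e == 1).any()])
    )
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        n_at_risk = np.array([(gt >= t).sum() for gt, _ in groups], dtype=float)
        d_here = np.array(
            [((gt == t) & (ge == 1)).sum() for gt, ge in groups], dtype=float
        )
        n = n_at_risk.sum()
        d = d_here.sum()
        if n == 0:
            continue
        frac = n_at_risk / n
        O += d_here
        E += d * frac
        if n > 1:
            scale = d * (n - d) / (n - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    cov = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(cov) @ diff) if diff.size else 0.0
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, k - 1))
    sizes = np.array([t.size for t, _ in groups])
    return LogrankResult(stat, p, O, E, sizes)


@dataclass
class SurvivalSummary:
    """Two-group evaluation: log-rank plus a Cox proportional-hazards fit."""

    logrank_statistic: float
    logrank_p: float
    group_sizes: dict
    cox_entries: pd.DataFrame  # index: covariate; columns: hr, ci_low, ci_high, p

    def to_frame(self) -> pd.DataFrame:
        out = self.cox_entries.copy()
        out.attrs["logrank_statistic"] = self.logrank_statistic
        out.attrs["logrank_p"] = self.logrank_p
        return out


def _risk_indicator(groups: pd.DataFrame) -> pd.Series:
    labels = groups["group"]
    high_risk = {"positive", "high"}
    levels = set(labels.unique())
    if not levels <= {"positive", "negative", "high", "low"}:
        raise ValueError(f"unrecognised group labels: {levels}")
    return labels.isin(high_risk).astype(float)


def cox_fit(
    ct: pd.DataFrame,
    groups: pd.DataFrame,
    covariates: tuple[str, ...] = (),
) -> SurvivalSummary:
    """Cox PH fit of the stratification group plus clinical covariates.

    ``groups`` is a stratification result (index sample id, ``group``
    column). Covariates are drawn from ``er, ln, grade, age, size`` and
    encoded as 0/1 indicators (ER-positive, LN-positive, grade 3,
    age > 50, size > 20 mm). Patients with unknown values for any
    requested covariate are dropped listwise (logged). Ties are handled
    with the Efron approximation; reported p-values are Wald.
    """
    unknown = [c for c in covariates if c not in COVARIATE_ENCODINGS]
    if unknown:
        raise ValueError(f"unknown covariates {unknown}; choose from "
                         f"{sorted(COVARIATE_ENCODINGS)}")
    shared = ct.index.intersection(groups.index)
    ct = validate_clinical(ct.loc[shared])
    risk = _risk_indicator(groups.loc[shared])

    df = pd.DataFrame(
        {"time": ct["time_months"].astype(float), "event": ct["event"].astype(int),
         "group": risk}
    )
    for cov in covariates:
        col, encode, label = COVARIATE_ENCODINGS[cov]
        if col not in ct.columns:
            raise ValueError(f"clinical table lacks column {col!r} for covariate {cov}")
        series = ct[col].replace({"unknown": np.nan, "": np.nan})
        df[label] = pd.to_numeric(encode(series), errors="coerce")
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("dropped %d patients with unknown covariates", n_before - len(df))
    for col in df.columns.drop(["time", "event"]):
        if df[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} has a single level after filtering")

    corr = df.drop(columns=["time", "event"]).corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if (corr > 0.999).any().any():
        raise ValueError("collinear covariates detected")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise ValueError(f"Cox fit failed: {exc}") from exc

    summary = cph.summary
    cox_entries = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    cox_entries.index.name = "covariate"

    masks = [risk.loc[df.index] == 1.0, risk.loc[df.index] == 0.0]
    lr = logrank(
        [(df.loc[m, "time"], df.loc[m, "event"]) for m in masks]
    )
    sizes = {"risk": int(masks[0].sum()), "reference": int(masks[1].sum())}
    return SurvivalSummary(lr.statistic, lr.p_value, sizes, cox_entries)
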