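"""Signature refinement: per-gene survival screening across cohort
subgroups, joint Benjamini-Hochberg correction, driver/suppressor
classification and construction of the reversed-sign compact centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .expression import ExpressionMatrix
from .signature import Centroid, reverse_signs
from .survival import logrank

logger = logging.getLogger(__name__)

HIGH_POOR = "high-expression-poor"
LOW_POOR = "low-expression-poor"
DRIVER = "driver"
SUPPRESSOR = "suppressor"
AMBIGUOUS = "ambiguous"

#: default subgroup predicates (column -> required value, ANDed)
DEFAULT_SUBGROUPS: dict[str, dict] = {
    "all": {},
    "er_pos": {"er": "pos"},
    "er_neg": {"er": "neg"},
    "ln_pos": {"ln": "pos"},
    "ln_neg": {"ln": "neg"},
    "er_pos_ln_neg": {"er": "pos", "ln": "neg"},
    "grade_1": {"grade": 1},
    "grade_2": {"grade": 2},
    "grade_3": {"grade": 3},
    "lum_a": {"subtype": "LumA"},
    "lum_b": {"subtype": "LumB"},
    "basal": {"subtype": "Basal"},
    "her2": {"subtype": "Her2"},
    "normal_like": {"subtype": "NormalLike"},
}


def subgroup_mask(ct: pd.DataFrame, predicates: dict) -> pd.Series:
    mask = pd.Series(True, index=ct.index)
    for col, value in predicates.items():
        if col not in ct.columns:
            raise ValueError(f"subgroup predicate on missing column {col!r}")
        if col == "grade":
            mask &= pd.to_numeric(ct[col], errors="coerce") == float(value)
        else:
            mask &= ct[col].astype(str) == str(value)
    return mask


def per_gene_screen(
    cohort: ExpressionMatrix,
    ct: pd.DataFrame,
    genes,
    subgroups: dict[str, dict] | None = None,
    min_patients: int = 20,
    min_events: int = 5,
) -> pd.DataFrame:
    """Median-split log-rank screen of each gene in each subgroup.

    Within each retained subgroup, patients are split at the gene's
    median expression (ties go to the low half) and the two halves are
    compared by log-rank; ``direction`` records which half had the worse
    outcome (more observed than expected events). Subgroups with fewer
    than ``min_patients`` patients or ``min_events`` events are skipped.

    Returns a long-format frame (gene, subgroup, raw_p, adj_p,
    direction) with BH adjustment applied jointly across every computed
    cell; genes absent from the cohort yield missing cells.
    """
    if subgroups is None:
        subgroups = DEFAULT_SUBGROUPS
    expr = cohort.to_log2().values
    expr.index = [str(g).strip().upper() for g in expr.index]
    shared = ct.index.intersection(expr.columns)
    ct = ct.loc[shared]

    kept: dict[str, pd.Index] = {}
    for name, preds in subgroups.items():
        members = ct.index[subgroup_mask(ct, preds)]
        n_events = int(ct.loc[members, "event"].sum())
        if len(members) < min_patients or n_events < min_events:
            logger.info(
                "skipping subgroup %s (%d patients, %d events)",
                name, len(members), n_events,
            )
            continue
        kept[name] = members

    rows = []
    for gene in genes:
        key = str(gene).strip().upper()
        if key not in expr.index:
            logger.warning("gene %s absent from cohort; row left missing", gene)
            for name in kept:
                rows.append((key, name, np.nan, None))
            continue
        for name, members in kept.items():
            values = expr.loc[key, members]
            high = values > values.median()
            sub = ct.loc[members]
            if high.sum() == 0 or (~high).sum() == 0:
                logger.info("degenerate split for %s in %s; skipped", gene, name)
                rows.append((key, name, np.nan, None))
                continue
            lr = logrank(
                [
                    (sub.loc[high.values, "time_months"], sub.loc[high.values, "event"]),
                    (sub.loc[~high.values, "time_months"], sub.loc[~high.values, "event"]),
                ]
            )
            direction = HIGH_POOR if lr.observed[0] > lr.expected[0] else LOW_POOR
            rows.append((key, name, lr.p_value, direction))

    sm = pd.DataFrame(rows, columns=["gene", "subgroup", "raw_p", "direction"])
    sm["adj_p"] = np.nan
    valid = sm["raw_p"].notna()
    if valid.any():
        sm.loc[valid, "adj_p"] = bh_adjust(sm.loc[valid, "raw_p"].to_numpy())
    return sm[["gene", "subgroup", "raw_p", "adj_p", "direction"]]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a flat p-value list."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return false_discovery_control(p, method="bh")


def select_signature(sm: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genes significant (adjusted p < alpha) in at least one subgroup.

    Returns one row per selected gene with its most significant subgroup
    and that cell's adjusted p. Selection is strict (adj_p < alpha), so
    alpha = 0 selects nothing; alpha >= 1 selects every screened gene
    (adjusted p is capped at 1).
    """
    if alpha >= 1:
        hits = sm[sm["adj_p"].notna()]
    else:
        hits = sm[sm["adj_p"] < alpha]
    if hits.empty:
        return pd.DataFrame(columns=["gene", "best_subgroup", "best_adj_p"])
    best = hits.loc[hits.groupby("gene", sort=False)["adj_p"].idxmin()]
    out = best.rename(columns={"subgroup": "best_subgroup", "adj_p": "best_adj_p"})
    return out[["gene", "best_subgroup", "best_adj_p"]].reset_index(drop=True)


@dataclass
class DirectionCall:
    gene: str
    de_direction: str  # up / down in the DE comparison
    prognostic_direction: str | None
    concordance: str  # driver / suppressor / ambiguous


def classify_direction(
    gene: str,
    de_direction: str,
    cells: pd.DataFrame,
    alpha: float = 0.05,
) -> DirectionCall:
    """Classify one selected gene as driver, suppressor or ambiguous.

    ``cells`` holds the gene's screen rows. The prognostic direction is
    taken from the most significant cell; if the gene's significant
    cells disagree on direction it is flagged ambiguous and excluded
    from classification. Concordance (DE direction agrees with the
    poor-prognosis direction) marks a driver; discordance a suppressor.
    """
    if de_direction not in ("up", "down"):
        raise ValueError(f"de_direction must be up/down, got {de_direction!r}")
    sig = cells[(cells["adj_p"] < alpha) & cells["direction"].notna()]
    if sig.empty:
        raise ValueError(f"no significant cells for {gene}")
    directions = set(sig["direction"])
    if len(directions) > 1:
        logger.info("gene %s has conflicting prognostic directions; ambiguous", gene)
        return DirectionCall(gene, de_direction, None, AMBIGUOUS)
    prog = sig.loc[sig["adj_p"].idxmin(), "direction"]
    concordant = (de_direction == "up" and prog == HIGH_POOR) or (
        de_direction == "down" and prog == LOW_POOR
    )
    return DirectionCall(gene, de_direction, prog, DRIVER if concordant else SUPPRESSOR)


def classify_directions(
    sm: pd.DataFrame,
    de_directions: dict[str, str],
    selected: pd.DataFrame,
    alpha: float = 0.05,
) -> list[DirectionCall]:
    """Direction calls for every selected gene (see classify_direction)."""
    calls = []
    for gene in selected["gene"]:
        key = str(gene).strip().upper()
        cells = sm[sm["gene"] == key]
        calls.append(classify_direction(key, de_directions[key], cells, alpha))
    return calls


def build_refined_centroid(c: Centroid, calls) -> Centroid:
    """Restrict the centroid to classified genes, reversing suppressors.

    Ambiguous genes are dropped; the reversal list is recorded in the
    centroid provenance.
    """
    keep = [call.gene for call in calls if call.concordance in (DRIVER, SUPPRESSOR)]
    missing = [g for g in keep if g not in c.weights.index]
    if missing:
        raise ValueError(f"selected genes missing from centroid: {missing}")
    if not keep:
        raise ValueError("no unambiguous genes to build a refined centroid from")
    sub = Centroid(
        c.weights.loc[keep], provenance=c.provenance + "; refined"
    )
    reversals = [call.gene for call in calls if call.concordance == SUPPRESSOR]
    return reverse_signs(sub, reversals)


def write_screen(sm: pd.DataFrame, path) -> None:
    sm.to_csv(path, sep="\t", index=False)


def read_screen(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
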