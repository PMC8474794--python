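"""Two-class rank-product differential expression with permutation p-values.

For each feature, the case/control intensity ratio is computed for every
case x control sample pair (k = n_case * n_ctrl comparisons).  Within each
comparison the ratios are ranked across features (midranks on ties), and
the rank product is the geometric mean of the k ranks: ranking descending
ratios gives ``rp_up`` (small = consistently up-regulated), ascending
gives ``rp_down``.  Significance comes from permuting the condition
labels and pooling the permuted rank products over all features:

    p_dir = (# permuted RP <= observed RP + 1) / (n_features * n_perm + 1)

evaluated separately for each direction. Because a feature is scored on
whichever arm its fold change favours, the reported ``p_value`` is the
two-sided min-p calibration: the statistic min(p_up, p_down) referred
to its own pooled permutation null, which is uniform under the null by
construction. The proportion of false prediction is
``pfp = p_value * n_features / rank`` where ``rank`` is the feature's
position in the observed RP ordering for its direction.
"""

from __future__ import annotations

import itertools
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import CASE, CONTROL, ExpressionMatrix

DE_COLUMNS = [
    "gene_symbol",
    "fold_change",
    "rp_up",
    "rp_down",
    "p_value",
    "pfp",
    "direction",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention for fold changes)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(median_case: float, median_ctrl: float) -> float:
    """Signed fold-change ratio between two condition medians.

    Returns ``max/min`` of the two medians, negated when the control
    median is the larger; magnitude is therefore always >= 1.
    """
    if median_case <= 0 or median_ctrl <= 0:
        raise ValueError(
            "medians must be positive linear-scale intensities, got "
            f"({median_case}, {median_ctrl})"
        )
    if median_ctrl > median_case:
        return -median_ctrl / median_case
    return median_case / median_ctrl


def rank_product(ranks, k: int | None = None) -> float:
    """Geometric mean of a feature's per-comparison ranks."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("rank list is empty")
    if k is None:
        k = ranks.size
    elif k != ranks.size:
        raise ValueError(f"k={k} does not match {ranks.size} ranks")
    if (ranks < 1).any():
        raise ValueError("ranks must be >= 1")
    return float(np.exp(np.mean(np.log(ranks))))


def _pair_log_ratios(log2_values: np.ndarray, case_idx, ctrl_idx) -> np.ndarray:
    """features x (n_case*n_ctrl) matrix of log2 case-minus-control ratios."""
    diffs = [log2_values[:, i] - log2_values[:, j] for i in case_idx for j in ctrl_idx]
    return np.column_stack(diffs)


def _rank_products(log2_values: np.ndarray, case_idx, ctrl_idx):
    """(rp_up, rp_down) over all features for one label assignment."""
    ratios = _pair_log_ratios(log2_values, case_idx, ctrl_idx)
    up_ranks = rankdata(-ratios, axis=0)
    down_ranks = rankdata(ratios, axis=0)
    rp_up = np.exp(np.mean(np.log(up_ranks), axis=1))
    rp_down = np.exp(np.mean(np.log(down_ranks), axis=1))
    return rp_up, rp_down


def rankprod_test(
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Rank-product DE test of case vs control samples.

    Parameters
    ----------
    expr
        Labelled expression matrix with >= 2 samples per arm and strictly
        positive linear intensities.
    n_perm
        Number of random label permutations (>= 100); ignored when
        ``exhaustive`` is set.
    seed
        Seed for the permutation RNG (required unless exhaustive).
    exhaustive
        Enumerate every distinct case/control label assignment instead of
        sampling; exact for small designs.

    Returns
    -------
    DataFrame indexed by probe id with columns ``gene_symbol,
    fold_change, rp_up, rp_down, p_value, pfp, direction``.
    """
    lin = expr.to_linear()
    if (lin.values.to_numpy() <= 0).any():
        raise ValueError("rank-product test requires strictly positive intensities")
    case_samples = lin.samples_in(CASE)
    ctrl_samples = lin.samples_in(CONTROL)
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError(
            f"need >= 2 samples per arm, got {len(case_samples)} case / "
            f"{len(ctrl_samples)} control"
        )
    if not exhaustive:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 (or use exhaustive=True)")
        if seed is None:
            raise ValueError("seed is required for random permutations")

    ordered = case_samples + ctrl_samples
    values = lin.values[ordered].to_numpy(dtype=float)
    log2_values = np.log2(values)
    n_features = values.shape[0]
    n_case = len(case_samples)
    n_total = len(ordered)
    obs_case = list(range(n_case))
    obs_ctrl = list(range(n_case, n_total))

    rp_up_obs, rp_down_obs = _rank_products(log2_values, obs_case, obs_ctrl)

    if exhaustive:
        assignments = [
            (list(c), [i for i in range(n_total) if i not in set(c)])
            for c in itertools.combinations(range(n_total), n_case)
        ]
    else:
        rng = np.random.default_rng(seed)
        assignments = []
        for _ in range(n_perm):
            order = rng.permutation(n_total)
            assignments.append((list(order[:n_case]), list(order[n_case:])))

    null_up = np.empty((len(assignments), n_features))
    null_down = np.empty_like(null_up)
    for a, (ci, xi) in enumerate(assignments):
        null_up[a], null_down[a] = _rank_products(log2_values, ci, xi)

    n_null = n_features * len(assignments)
    pooled_up = np.sort(null_up.ravel())
    pooled_down = np.sort(null_down.ravel())
    # directional tail probabilities of the observed and null rank products
    p_up = np.searchsorted(pooled_up, rp_up_obs, side="right") / n_null
    p_down = np.searchsorted(pooled_down, rp_down_obs, side="right") / n_null
    null_p_up = np.searchsorted(pooled_up, null_up.ravel(), side="right") / n_null
    null_p_down = np.searchsorted(pooled_down, null_down.ravel(), side="right") / n_null
    null_min_p = np.sort(np.minimum(null_p_up, null_p_down))
    s_obs = np.minimum(p_up, p_down)
    p_two = (np.searchsorted(null_min_p, s_obs, side="right") + 1) / (n_null + 1)

    med_case = np.median(values[:, :n_case], axis=1)
    med_ctrl = np.median(values[:, n_case:], axis=1)
    fcs = np.array([fold_change(a, b) for a, b in zip(med_case, med_ctrl)])
    up = fcs > 0

    rank_up = rankdata(rp_up_obs)
    rank_down = rankdata(rp_down_obs)
    p = p_two
    ranks = np.where(up, rank_up, rank_down)
    pfp = p * n_features / ranks

    symbols = [lin.gene_symbols.get(f, f) for f in lin.feature_ids]
    return pd.DataFrame(
        {
            "gene_symbol": symbols,
            "fold_change": fcs,
            "rp_up": rp_up_obs,
            "rp_down": rp_down_obs,
            "p_value": p,
            "pfp": pfp,
            "direction": np.where(up, "up", "down"),
        },
        index=pd.Index(lin.feature_ids, name="probe_id"),
    )


def sort_de(de: pd.DataFrame) -> pd.DataFrame:
    """Order a DE table by decreasing fold change then increasing p."""
    return de.sort_values(
        ["fold_change", "p_value"], ascending=[False, True], kind="mergesort"
    )


def write_de(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out["fold_change"] = [round_half_up(x, 2) for x in out["fold_change"]]
    out.to_csv(path, sep="\t")


def read_de(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", index_col=0)
    de.index = de.index.astype(str)
    return de
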