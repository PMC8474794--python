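import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matrisig import (
    Centroid,
    CohortSimSpec,
    bh_adjust,
    build_refined_centroid,
    classify_direction,
    per_gene_screen,
    select_signature,
    simulate_cohort,
)
from matrisig.refinement import (
    AMBIGUOUS,
    DRIVER,
    HIGH_POOR,
    LOW_POOR,
    SUPPRESSOR,
    classify_directions,
)

# ----------------------------------------------------------------- bh_adjust


def _bh_oracle(pvals):
    """Step-up adjustment written directly from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def test_bh_hand_computed_toy_vector():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])


def test_bh_all_ones():
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
)
@settings(max_examples=100)
def test_bh_matches_independent_oracle(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
)
def test_bh_bounded_and_order_preserving(pvals):
    adj = bh_adjust(pvals)
    assert (np.asarray(adj) <= 1.0 + 1e-12).all()
    assert (np.asarray(adj) >= np.asarray(pvals) - 1e-12).all()
    idx = np.argsort(pvals)
    assert (np.diff(np.asarray(adj)[idx]) >= -1e-12).all()


def test_bh_identity_when_already_step_up_consistent():
    # p_i = i/n exactly meets the step-up bound: adjustment maxes to 1 at the top
    p = [0.25, 0.5, 0.75, 1.0]
    np.testing.assert_allclose(bh_adjust(p), [1.0, 1.0, 1.0, 1.0])
    # spaced p-values whose p*n/rank is already monotone stay put only when
    # each p_i equals its own bound; verify via the oracle instead of a guess
    np.testing.assert_allclose(bh_adjust([0.1, 0.9]), _bh_oracle([0.1, 0.9]))


# ----------------------------------------------------------- select_signature


def _screen_frame(cells):
    return pd.DataFrame(cells, columns=["gene", "subgroup", "raw_p", "adj_p", "direction"])


def test_select_includes_single_significant_cell():
    sm = _screen_frame([("G1", "all", 0.01, 0.04, HIGH_POOR)])
    out = select_signature(sm, alpha=0.05)
    assert list(out["gene"]) == ["G1"]
    assert out["best_subgroup"].iloc[0] == "all"


def test_select_empty_when_nothing_significant():
    sm = _screen_frame([("G1", "all", 0.2, 0.3, HIGH_POOR)])
    assert select_signature(sm, alpha=0.05).empty


def test_select_boundary_alphas():
    sm = _screen_frame(
        [("G1", "all", 0.01, 0.02, HIGH_POOR), ("G2", "all", 0.9, 1.0, LOW_POOR)]
    )
    assert select_signature(sm, alpha=0).empty
    assert set(select_signature(sm, alpha=1)["gene"]) == {"G1", "G2"}


def test_select_monotone_in_alpha():
    rng = np.random.default_rng(0)
    sm = _screen_frame(
        [(f"G{i}", "all", p, p, HIGH_POOR) for i, p in enumerate(rng.random(30))]
    )
    sizes = [len(select_signature(sm, alpha=a)) for a in (0.0, 0.1, 0.5, 0.9, 1.0)]
    assert sizes == sorted(sizes)
    assert sizes[-1] == 30


def test_select_tags_most_significant_subgroup():
    sm = _screen_frame(
        [("G1", "all", 0.01, 0.03, HIGH_POOR), ("G1", "er_pos", 0.001, 0.004, HIGH_POOR)]
    )
    out = select_signature(sm, alpha=0.05)
    assert out["best_subgroup"].iloc[0] == "er_pos"


# --------------------------------------------------------- classify_direction


def test_driver_up_high_poor():
    cells = _screen_frame([("POSTN", "all", 0.001, 0.01, HIGH_POOR)])
    call = classify_direction("POSTN", "up", cells)
    assert call.concordance == DRIVER


def test_suppressor_up_low_poor():
    cells = _screen_frame([("VCAN", "all", 0.001, 0.01, LOW_POOR)])
    call = classify_direction("VCAN", "up", cells)
    assert call.concordance == SUPPRESSOR


def test_driver_down_low_poor():
    cells = _screen_frame([("SFRP1", "all", 0.001, 0.01, LOW_POOR)])
    call = classify_direction("SFRP1", "down", cells)
    assert call.concordance == DRIVER


def test_conflicting_directions_flagged_ambiguous():
    cells = _screen_frame(
        [
            ("G1", "all", 0.001, 0.01, HIGH_POOR),
            ("G1", "er_neg", 0.002, 0.02, LOW_POOR),
        ]
    )
    call = classify_direction("G1", "up", cells)
    assert call.concordance == AMBIGUOUS
    assert call.prognostic_direction is None


def test_direction_from_most_significant_cell():
    cells = _screen_frame(
        [
            ("G1", "all", 0.01, 0.03, HIGH_POOR),
            ("G1", "er_neg", 0.2, 0.4, LOW_POOR),  # not significant: ignored
        ]
    )
    call = classify_direction("G1", "up", cells)
    assert call.prognostic_direction == HIGH_POOR
    assert call.concordance == DRIVER


# ------------------------------------------------------ build_refined_centroid


def test_refined_drivers_only_restriction(small_centroid):
    calls = classify_directions(
        _screen_frame(
            [
                ("GPC1", "all", 0.001, 0.01, HIGH_POOR),
                ("WISP2", "all", 0.001, 0.01, LOW_POOR),
            ]
        ),
        {"GPC1": "up", "WISP2": "down"},
        pd.DataFrame({"gene": ["GPC1", "WISP2"]}),
    )
    refined = build_refined_centroid(small_centroid, calls)
    assert refined.genes == ["GPC1", "WISP2"]
    assert refined.weights["GPC1"] == pytest.approx(3.74)
    assert refined.weights["WISP2"] == pytest.approx(-3.31)


def test_refined_reverses_suppressors(small_centroid):
    calls = classify_directions(
        _screen_frame(
            [
                ("GPC1", "all", 0.001, 0.01, HIGH_POOR),
                ("VCAN", "all", 0.001, 0.01, LOW_POOR),
            ]
        ),
        {"GPC1": "up", "VCAN": "up"},
        pd.DataFrame({"gene": ["GPC1", "VCAN"]}),
    )
    refined = build_refined_centroid(small_centroid, calls)
    assert refined.weights["VCAN"] == pytest.approx(-3.1)
    assert "VCAN" in refined.provenance


def test_refined_missing_gene_errors(small_centroid):
    from matrisig.refinement import DirectionCall

    calls = [DirectionCall("NOPE", "up", HIGH_POOR, DRIVER)]
    with pytest.raises(ValueError, match="missing"):
        build_refined_centroid(small_centroid, calls)


# ------------------------------------------------------------ per_gene_screen


def test_screen_planted_effect_significant(small_centroid):
    spec = CohortSimSpec(
        n_patients=600, centroid=small_centroid, hr_true=3.0, seed=13
    )
    cohort, ct, _ = simulate_cohort(spec)
    sm = per_gene_screen(cohort, ct, ["GPC1"], subgroups={"all": {}})
    cell = sm[(sm["gene"] == "GPC1") & (sm["subgroup"] == "all")].iloc[0]
    assert cell["raw_p"] < 0.01
    assert cell["direction"] == HIGH_POOR  # positive weight, latent = poor


def test_screen_subset_oracle(small_centroid):
    """Each subgroup cell equals a recomputation on manually subset data."""
    spec = CohortSimSpec(
        n_patients=300, centroid=small_centroid, hr_true=2.5, seed=14
    )
    cohort, ct, _ = simulate_cohort(spec)
    subgroups = {"er_pos": {"er": "pos"}, "er_neg": {"er": "neg"}}
    sm = per_gene_screen(cohort, ct, ["VCAN"], subgroups=subgroups)
    from matrisig.survival import logrank

    for name, value in (("er_pos", "pos"), ("er_neg", "neg")):
        members = ct.index[ct["er"] == value]
        values = np.log2(cohort.values.loc["VCAN", members])
        high = values > values.median()
        sub = ct.loc[members]
        expected = logrank(
            [
                (sub.loc[high.values, "time_months"], sub.loc[high.values, "event"]),
                (sub.loc[~high.values, "time_months"], sub.loc[~high.values, "event"]),
            ]
        ).p_value
        cell = sm[(sm["gene"] == "VCAN") & (sm["subgroup"] == name)].iloc[0]
        assert cell["raw_p"] == pytest.approx(expected, rel=1e-9)


def test_screen_constant_gene_skipped_with_missing_cell(small_centroid):
    spec = CohortSimSpec(n_patients=100, centroid=small_centroid, seed=15)
    cohort, ct, _ = simulate_cohort(spec)
    flat = cohort.values.copy()
    flat.loc["GPC1"] = 100.0  # identical in every patient
    from matrisig.expression import ExpressionMatrix

    sm = per_gene_screen(
        ExpressionMatrix(flat), ct, ["GPC1"], subgroups={"all": {}}
    )
    assert sm["raw_p"].isna().all()


def test_screen_absent_gene_row_missing(small_centroid, planted_cohort):
    cohort, ct, _ = planted_cohort
    sm = per_gene_screen(cohort, ct, ["NOT_A_GENE"], subgroups={"all": {}})
    assert sm["raw_p"].isna().all()


def test_screen_small_subgroups_skipped(small_centroid, planted_cohort):
    cohort, ct, _ = planted_cohort
    sm = per_gene_screen(
        cohort, ct, ["GPC1"],
        subgroups={"all": {}, "tiny": {"grade": 1, "er": "neg", "ln": "pos"}},
        min_patients=50,
    )
    assert set(sm["subgroup"]) == {"all"}


def test_screen_adjusted_ge_raw(small_centroid, planted_cohort):
    cohort, ct, _ = planted_cohort
    sm = per_gene_screen(cohort, ct, small_centroid.genes)
    valid = sm.dropna(subset=["raw_p"])
    assert (valid["adj_p"] >= valid["raw_p"] - 1e-12).all()
    assert valid["adj_p"].between(0, 1).all()


# -------------------------------------------------- end-to-end refinement run


def test_recovers_planted_suppressor_set():
    genes = ["D1", "D2", "D3", "D4", "D5", "S1", "S2"]
    weights = pd.Series([3.0, 2.5, -2.0, 2.2, -1.8, 2.8, -2.4], index=genes)
    centroid = Centroid(weights)
    spec = CohortSimSpec(
        n_patients=800,
        centroid=centroid,
        hr_true=3.0,
        suppressor_genes=("S1", "S2"),
        seed=17,
    )
    cohort, ct, _ = simulate_cohort(spec)
    sm = per_gene_screen(cohort, ct, genes)
    selected = select_signature(sm, alpha=0.05)
    directions = {g: ("up" if w > 0 else "down") for g, w in weights.items()}
    calls = classify_directions(sm, directions, selected)
    reversed_set = {c.gene for c in calls if c.concordance == SUPPRESSOR}
    driver_set = {c.gene for c in calls if c.concordance == DRIVER}
    assert reversed_set == {"S1", "S2"}
    assert driver_set == {"D1", "D2", "D3", "D4", "D5"}
    refined = build_refined_centroid(centroid, calls)
    assert refined.weights["S1"] == pytest.approx(-2.8)
    assert refined.weights["S2"] == pytest.approx(2.4)
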