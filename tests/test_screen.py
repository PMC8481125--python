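"""Viability normalisation, IC50 fitting, selectivity matrices,
clustering and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from egfr_groups.screen import (
    ClusterResult,
    SelectivityMatrix,
    build_selectivity_matrix,
    compare_group_selectivity,
    fit_dose_response,
    hierarchical_cluster,
    mutant_wt_ratio,
    normalize_viability,
    welch_anova,
)


# --- normalisation ----------------------------------------------------------


def test_normalize_viability():
    assert normalize_viability([5000.0], [10000.0, 10000.0])[0] == pytest.approx(0.5)
    assert normalize_viability([10000.0], [10000.0])[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        normalize_viability([1.0], [0.0, 0.0])


# --- dose-response fitting --------------------------------------------------

DOSES7 = 10.0 ** np.linspace(0, 3, 7)  # 1 nM .. 1000 nM


def logistic(d, ic50, hill=1.0, top=1.0, bottom=0.0):
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


def test_exact_logistic_recovers_ic50():
    fr = logistic(DOSES7, 100.0)
    fit = fit_dose_response(DOSES7, fr)
    assert not fit.ic50_censored
    assert fit.ic50 == pytest.approx(100.0, rel=1e-4)


def test_resistant_curve_is_censored_at_max_dose():
    fr = np.full(7, 0.95)
    fit = fit_dose_response(DOSES7, fr + np.linspace(0, -0.02, 7))
    assert fit.ic50_censored
    assert fit.censor_direction == "high"
    assert fit.ic50 == pytest.approx(DOSES7.max())


def test_fit_requires_four_distinct_doses():
    with pytest.raises(ValueError):
        fit_dose_response([1.0, 10.0, 100.0], [1.0, 0.5, 0.0])


def test_noisy_curve_ic50_matches_grid_search_oracle(rng):
    doses = DOSES7
    fr = logistic(doses, 60.0, hill=1.3) + rng.normal(0, 0.03, size=7)
    fit = fit_dose_response(doses, fr)
    # oracle: dense grid over the fitted curve, bracket the 0.5 crossing
    grid = np.logspace(0, 3, 20001)
    pred = fit.predict(grid)
    crossing = grid[np.argmin(np.abs(pred - 0.5))]
    assert fit.ic50 == pytest.approx(crossing, rel=1e-3)


def test_ic50_scales_with_doses():
    fr = logistic(DOSES7, 100.0, hill=1.7)
    fit1 = fit_dose_response(DOSES7, fr)
    fit2 = fit_dose_response(DOSES7 * 3.5, fr)
    assert fit2.ic50 == pytest.approx(3.5 * fit1.ic50, rel=1e-6)


def test_replicate_points_are_accepted():
    doses = np.repeat(DOSES7, 3)
    fr = logistic(doses, 40.0)
    fit = fit_dose_response(doses, fr)
    assert fit.ic50 == pytest.approx(40.0, rel=1e-4)


# --- mutant/WT ratio --------------------------------------------------------


def test_mutant_wt_ratio_examples():
    ratio, logr = mutant_wt_ratio(10.0, [100.0, 100.0, 100.0])
    assert (ratio, logr) == (pytest.approx(0.1), pytest.approx(-1.0))
    ratio, logr = mutant_wt_ratio(100.0, [100.0])
    assert (ratio, logr) == (pytest.approx(1.0), pytest.approx(0.0))
    ratio, logr = mutant_wt_ratio(250.0, [100.0, 300.0])
    assert ratio == pytest.approx(1.25)
    assert logr == pytest.approx(0.0969, abs=1e-4)
    with pytest.raises(ValueError):
        mutant_wt_ratio(-1.0, [100.0])
    with pytest.raises(ValueError):
        mutant_wt_ratio(1.0, [])


# --- selectivity matrix -----------------------------------------------------


def _replicates(rows):
    return pd.DataFrame(rows, columns=["cell_line", "drug", "log_ratio", "censored"])


def test_median_conventions():
    df = _replicates(
        [("m", "d", -1.0, False), ("m", "d", -0.5, False), ("m", "d", -0.2, False),
         ("s", "d", -0.7, False),
         ("e", "d", -1.0, False), ("e", "d", 0.0, False)]
    )
    m = build_selectivity_matrix(df)
    assert m.values.loc["m", "d"] == pytest.approx(-0.5)
    assert m.values.loc["s", "d"] == pytest.approx(-0.7)
    assert m.values.loc["e", "d"] == pytest.approx(-0.5)  # even count: mean of middle pair


def test_censor_flag_propagates_with_median_replicate():
    df = _replicates(
        [("m", "d", -1.0, False), ("m", "d", 0.5, True), ("m", "d", 0.5, True),
         ("k", "d", -1.0, False), ("k", "d", -0.8, False), ("k", "d", 0.5, True)]
    )
    m = build_selectivity_matrix(df)
    assert bool(m.censored.loc["m", "d"]) is True
    assert bool(m.censored.loc["k", "d"]) is False


def test_missing_cells_warn_not_imputed():
    df = _replicates([("m1", "d1", 0.0, False), ("m1", "d2", 0.1, False),
                      ("m2", "d1", 0.2, False)])
    with pytest.warns(UserWarning, match="missing"):
        m = build_selectivity_matrix(df)
    assert np.isnan(m.values.loc["m2", "d2"])


def test_duplicate_ids_rejected():
    values = pd.DataFrame([[0.0], [0.1]], index=["m", "m"], columns=["d"])
    with pytest.raises(ValueError):
        SelectivityMatrix(values, None)


# --- hierarchical clustering ------------------------------------------------


def test_identical_rows_merge_first_at_height_zero(toy_matrix):
    values = toy_matrix.values.copy()
    values.loc["m2"] = values.loc["m1"]
    m = SelectivityMatrix(values, None)
    res = hierarchical_cluster(m)
    first = res.linkage[0]
    assert first[2] == pytest.approx(0.0)
    assert {int(first[0]), int(first[1])} == {0, 1}


def test_merge_order_matches_brute_force_nearest_pair(toy_matrix):
    res = hierarchical_cluster(toy_matrix)
    # hand distances: d(m1,m2)=sqrt(.5)=.707, d(m2,m3)=.707, d(m1,m3)=sqrt(2)
    # nearest pair merges first (tie -> scipy merges the first-listed pair)
    first = res.linkage[0]
    assert first[2] == pytest.approx(np.sqrt(0.5))
    assert res.linkage[1][2] == pytest.approx(np.sqrt(2.0))  # complete linkage


def test_permutation_leaves_merge_heights_unchanged(toy_matrix, rng):
    res = hierarchical_cluster(toy_matrix)
    perm = rng.permutation(len(toy_matrix.values))
    shuffled = SelectivityMatrix(toy_matrix.values.iloc[perm], None)
    res2 = hierarchical_cluster(shuffled)
    assert np.allclose(sorted(res.linkage[:, 2]), sorted(res2.linkage[:, 2]))


def test_cluster_needs_two_rows(toy_matrix):
    one = SelectivityMatrix(toy_matrix.values.iloc[:1], None)
    with pytest.raises(ValueError):
        hierarchical_cluster(one)


def test_newick_export_contains_all_leaves(toy_matrix):
    nwk = hierarchical_cluster(toy_matrix).to_newick()
    assert nwk.endswith(";")
    for label in toy_matrix.values.index:
        assert label in nwk


# --- Welch ANOVA + Holm-Sidak -----------------------------------------------


def test_welch_f_matches_hand_computation():
    groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]),
              np.array([5.0, 5.5, 6.5])]
    F, df1, df2, p = welch_anova(groups)
    # hand computation of the Welch formula
    n = np.array([3.0, 3.0, 3.0])
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    w = n / var
    mw = (w * means).sum() / w.sum()
    A = (w * (means - mw) ** 2).sum() / 2
    tmp = ((1 - w / w.sum()) ** 2 / 2).sum()
    B = 1 + 2 * 1 / 8 * tmp
    assert F == pytest.approx(A / B)
    assert df2 == pytest.approx(8 / (3 * tmp))
    assert 0 < p < 1


def test_welch_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    data = {g: rng.normal(loc, 1.0, size=6) for g, loc in [("a", 0), ("b", 0.5), ("c", 2)]}
    F, df1, df2, p = welch_anova(list(data.values()))
    df = pd.DataFrame(
        [{"g": g, "y": v} for g, vals in data.items() for v in vals]
    )
    ref = pingouin.welch_anova(data=df, dv="y", between="g")
    assert F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
    assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-6)
    assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


def test_identical_constant_groups_not_significant():
    res = compare_group_selectivity({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
    assert res.p_value == pytest.approx(1.0)
    assert (res.pairwise["p_adj"] == 1.0).all()


def test_separated_groups_significant():
    eps = [0.001, -0.001, 0.0005]
    res = compare_group_selectivity(
        {"a": np.array([0.0, 0.0, 0.0]) + eps, "b": np.array([1.0, 1.0, 1.0]) + eps}
    )
    assert res.p_value < 1e-3
    assert (res.pairwise["p_adj"] < 1e-3).all()


def test_group_comparison_from_matrix_columns(toy_matrix):
    res = compare_group_selectivity(toy_matrix, {"dA": "first", "dB": "second"})
    assert set(res.group_sizes.index) == {"first", "second"}
    assert res.group_sizes["first"] == 3


def test_small_group_rejected():
    with pytest.raises(ValueError):
        welch_anova([np.array([1.0]), np.array([2.0, 3.0])])
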