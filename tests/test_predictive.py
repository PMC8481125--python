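"""LOO group profiles, Spearman rho pairing, and CART recursive
partitioning, each checked against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from egfr_groups.predictive import (
    CartControl,
    GroupingScheme,
    cart_fit,
    compare_groupings,
    importance_comparison,
    loo_group_profile,
    mutation_rho,
    variable_importance,
)
from egfr_groups.screen import SelectivityMatrix

from conftest import brute_force_spearman


def matrix_from(values, mutations, drugs):
    df = pd.DataFrame(values, index=pd.Index(mutations, name="mutation"),
                      columns=pd.Index(drugs, name="drug"))
    return SelectivityMatrix(df, None)


# --- LOO profiles -----------------------------------------------------------


def test_loo_profile_is_mean_of_others(toy_matrix):
    scheme = GroupingScheme("s", {"m1": "g", "m2": "g", "m3": "g"})
    profile = loo_group_profile(toy_matrix, scheme, "m1")
    # mean of m2, m3 by hand
    assert profile["dA"] == pytest.approx((-0.5 + 0.0) / 2)
    assert profile["dB"] == pytest.approx((0.5 + 1.0) / 2)


def test_loo_profile_two_identical_rows(toy_matrix):
    values = toy_matrix.values.copy()
    values.loc["m2"] = values.loc["m1"]
    m = SelectivityMatrix(values, None)
    scheme = GroupingScheme("s", {"m1": "g", "m2": "g", "m3": "h"})
    profile = loo_group_profile(m, scheme, "m1")
    assert np.allclose(profile, values.loc["m1"])


def test_singleton_category_not_evaluable(toy_matrix):
    scheme = GroupingScheme("s", {"m1": "solo", "m2": "g", "m3": "g"})
    assert loo_group_profile(toy_matrix, scheme, "m1") is None


# --- Spearman rho -----------------------------------------------------------


def test_rho_extremes():
    x = pd.Series([1.0, 2.0, 3.0, 4.0])
    assert mutation_rho(x, x) == pytest.approx(1.0)
    assert mutation_rho(x, x.iloc[::-1].reset_index(drop=True)) == pytest.approx(-1.0)


def test_rho_hand_example():
    assert mutation_rho(pd.Series([1, 2, 3, 4.0]), pd.Series([1, 3, 2, 4.0])) == pytest.approx(0.8)


def test_rho_zero_variance_flagged():
    assert np.isnan(mutation_rho(pd.Series([1.0, 1.0, 1.0]), pd.Series([1, 2, 3.0])))


def test_rho_matches_brute_force_on_all_small_permutations():
    base = np.arange(1.0, 6.0)
    for perm in itertools.permutations(range(5)):
        y = base[list(perm)]
        assert mutation_rho(pd.Series(base), pd.Series(y)) == pytest.approx(
            brute_force_spearman(base, y)
        )


@given(st.lists(st.integers(0, 3), min_size=3, max_size=6),
       st.lists(st.integers(0, 3), min_size=3, max_size=6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_rho_matches_brute_force_with_ties(xs, ys):
    n = min(len(xs), len(ys))
    x, y = np.array(xs[:n], dtype=float), np.array(ys[:n], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return
    assert mutation_rho(pd.Series(x), pd.Series(y)) == pytest.approx(
        brute_force_spearman(x, y)
    )


# --- compare_groupings ------------------------------------------------------


def test_identical_schemes_give_t_zero_p_one(toy_matrix):
    values = np.array([[0.0, 1.0, 2.0], [0.1, 1.1, 1.9], [2.0, 1.0, 0.0],
                       [1.9, 1.2, 0.2]])
    m = matrix_from(values, ["a", "b", "c", "d"], ["d1", "d2", "d3"])
    scheme = GroupingScheme("s", {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
    same = GroupingScheme("t", dict(scheme.mapping))
    res = compare_groupings(m, scheme, same)
    assert res.t_stat == 0.0
    assert res.p_value == 1.0


def test_paired_t_matches_hand_computation():
    rng = np.random.default_rng(5)
    values = np.array(
        [[0.0, 1.0, 2.0, 3.0], [0.2, 1.1, 2.2, 2.9], [3.0, 2.0, 1.0, 0.0],
         [2.8, 2.1, 0.9, 0.3]]
    ) + rng.normal(0, 0.3, size=(4, 4))
    m = matrix_from(values, ["a", "b", "c", "d"], ["d1", "d2", "d3", "d4"])
    good = GroupingScheme("good", {"a": "x", "b": "x", "c": "y", "d": "y"})
    bad = GroupingScheme("bad", {"a": "x", "b": "y", "c": "x", "d": "y"})
    res = compare_groupings(m, good, bad)
    diffs = (res.table["rho_a"] - res.table["rho_b"]).to_numpy()
    t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
    assert res.t_stat == pytest.approx(t_hand)
    assert res.df == len(diffs) - 1


def test_singletons_dropped_and_listed():
    values = np.random.default_rng(1).normal(size=(5, 4))
    m = matrix_from(values, list("abcde"), ["d1", "d2", "d3", "d4"])
    a = GroupingScheme("a", {"a": "g", "b": "g", "c": "g", "d": "g", "e": "solo"})
    b = GroupingScheme("b", {k: "h" for k in "abcde"})
    res = compare_groupings(m, a, b)
    assert res.dropped == ["e"]
    assert len(res.table) == 4


def test_too_few_pairs_rejected(toy_matrix):
    a = GroupingScheme("a", {"m1": "g", "m2": "g", "m3": "solo"})
    b = GroupingScheme("b", {"m1": "h", "m2": "h", "m3": "h"})
    with pytest.raises(ValueError):
        compare_groupings(toy_matrix, a, b)


# --- CART -------------------------------------------------------------------


def test_perfect_binary_split_goodness():
    y = pd.Series([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    X = pd.DataFrame({"flag": [0, 0, 0, 1, 1, 1]})
    tree = cart_fit(y, X, CartControl(min_split=2, cp=0.0, min_bucket=1))
    splits = tree.splits()
    assert len(splits) == 1
    assert splits[0].predictor == "flag"
    assert splits[0].goodness == pytest.approx(1.5)  # total SS 1.5 -> child SS 0
    assert variable_importance(tree)["flag"] == pytest.approx(100.0)


def test_constant_response_root_only():
    y = pd.Series([2.0] * 8)
    X = pd.DataFrame({"a": [0, 1] * 4})
    tree = cart_fit(y, X, CartControl(min_split=2, cp=0.0, min_bucket=1))
    assert tree.root.is_leaf
    assert variable_importance(tree).empty


def _brute_force_best_split(y, X, categorical, min_bucket=1):
    """Exhaustive best first split over all predictors and partitions."""
    y = np.asarray(y, dtype=float)
    ss = lambda v: float(np.sum((v - v.mean()) ** 2)) if v.size else 0.0
    parent = ss(y)
    best = -np.inf
    for col in X.columns:
        x = X[col].to_numpy()
        if col in categorical:
            cats = list(pd.unique(x))
            for r in range(1, len(cats)):
                for left in itertools.combinations(cats, r):
                    mask = np.isin(x, left)
                    if mask.sum() < min_bucket or (~mask).sum() < min_bucket:
                        continue
                    best = max(best, parent - ss(y[mask]) - ss(y[~mask]))
        else:
            for thr in np.unique(x.astype(float))[:-1]:
                mask = x.astype(float) <= thr
                if mask.sum() < min_bucket or (~mask).sum() < min_bucket:
                    continue
                best = max(best, parent - ss(y[mask]) - ss(y[~mask]))
    return best


def test_first_split_matches_exhaustive_search(rng):
    for _ in range(25):
        n = int(rng.integers(6, 15))
        X = pd.DataFrame(
            {
                "cat": rng.choice(list("pqrs"), size=n),
                "num": rng.integers(0, 4, size=n).astype(float),
                "bin": rng.integers(0, 2, size=n),
            }
        )
        y = pd.Series(rng.normal(size=n))
        tree = cart_fit(y, X, CartControl(min_split=2, cp=0.0, min_bucket=1),
                        categorical={"cat"})
        if tree.root.is_leaf:
            continue
        oracle = _brute_force_best_split(y, X, {"cat"})
        assert tree.root.goodness == pytest.approx(oracle, rel=1e-9)


def test_importance_scaling_arithmetic():
    # two splits with goodness 8 and 2 -> shares 80/20
    y = pd.Series([0.0, 0.0, 2.0, 2.0, 2.0, 2.0, 3.0, 3.0])
    X = pd.DataFrame({"a": [0, 0, 1, 1, 1, 1, 1, 1], "b": [0, 1, 0, 0, 1, 1, 0, 0]})
    tree = cart_fit(y, X, CartControl(min_split=2, cp=0.0, min_bucket=1))
    imp = variable_importance(tree)
    raw = {p: sum(s.goodness for s in tree.splits() if s.predictor == p)
           for p in tree.predictors}
    total = sum(raw.values())
    for p in tree.predictors:
        assert imp[p] == pytest.approx(100.0 * raw[p] / total)
    assert imp.sum() == pytest.approx(100.0)


def test_shift_invariance(rng):
    n = 12
    X = pd.DataFrame({"cat": rng.choice(list("xyz"), size=n), "num": rng.normal(size=n)})
    y = pd.Series(rng.normal(size=n))
    control = CartControl(min_split=3, cp=0.01, min_bucket=1)
    t1 = cart_fit(y, X, control, categorical={"cat"})
    t2 = cart_fit(y + 7.5, X, control, categorical={"cat"})
    assert [s.rule() for s in t1.splits()] == [s.rule() for s in t2.splits()]
    if not t1.root.is_leaf:
        pd.testing.assert_series_equal(variable_importance(t1), variable_importance(t2))


def test_shift_invariance_of_rho(rng):
    values = rng.normal(size=(3, 5))
    m = matrix_from(values, ["m1", "m2", "m3"], [f"d{i}" for i in range(5)])
    shifted = SelectivityMatrix(m.values + 3.0, None)
    scheme = GroupingScheme("s", {"m1": "g", "m2": "g", "m3": "g"})
    for mutation in m.values.index:
        r1 = mutation_rho(
            m.values.loc[mutation], loo_group_profile(m, scheme, mutation)
        )
        r2 = mutation_rho(
            shifted.values.loc[mutation], loo_group_profile(shifted, scheme, mutation)
        )
        assert r1 == pytest.approx(r2)


# --- importance comparison --------------------------------------------------


def _group_matrix(rng, sigma):
    groups = {f"m{i}": f"g{i % 3}" for i in range(9)}
    templates = {"g0": [-2.0, 0.0, 1.0, -1.0], "g1": [0.0, -2.0, -1.0, 1.0],
                 "g2": [1.0, 1.0, -2.0, 0.0]}
    values = np.array([templates[groups[m]] for m in groups]) + rng.normal(
        0, sigma, size=(9, 4)
    )
    m = matrix_from(values, list(groups), ["d1", "d2", "d3", "d4"])
    exons = {m_: [18 + i % 4] for i, m_ in enumerate(groups)}
    return m, groups, exons


def test_noiseless_group_templates_give_structure_importance_100(rng):
    m, groups, exons = _group_matrix(rng, sigma=0.0)
    res = importance_comparison(m, groups, exons, CartControl(min_split=2, cp=0.01, min_bucket=1))
    assert (res.table["imp_structure"] == 100.0).all()
    assert (res.table["imp_exon"] == 0.0).all()
    assert res.table["structure_in_first_two"].all()


def test_noisy_group_templates_favour_structure(rng):
    wins = 0
    for seed in range(20):
        m, groups, exons = _group_matrix(np.random.default_rng(seed), sigma=0.3)
        res = importance_comparison(
            m, groups, exons, CartControl(min_split=2, cp=0.01, min_bucket=1)
        )
        if res.table["imp_structure"].mean() > res.table["imp_exon"].mean():
            wins += 1
    assert wins >= 18


def test_permuted_response_gives_no_strong_signal():
    rng = np.random.default_rng(99)
    m, groups, exons = _group_matrix(rng, sigma=0.0)
    perm = rng.permutation(m.values.index.to_list())
    permuted = SelectivityMatrix(
        pd.DataFrame(m.values.to_numpy(), index=perm, columns=m.values.columns), None
    )
    res = importance_comparison(
        permuted, groups, exons, CartControl(min_split=2, cp=0.01, min_bucket=1)
    )
    # after permuting mutation labels the structure predictor should not
    # dominate every tree
    assert not (res.table["imp_structure"] == 100.0).all()
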