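"""Do structure-function groups predict drug selectivity better than
exon-based groups?

Two complementary procedures quantify this on a selectivity matrix:

* a leave-one-out correlation: each mutation's per-drug selectivity
  profile is Spearman-correlated with the mean profile of its category
  (structure group, or exon) computed *without* that mutation, and the
  paired per-mutation rho vectors under the two grouping schemes are
  compared by a two-sided paired t-test;

* CART regression trees, one per drug, using the structure group (one
  unordered categorical) and four exon indicators as predictors.
  Variable importance is the rpart convention: the sum of the goodness
  of split (the split's reduction in within-node sum of squares) over
  each predictor's splits, scaled to total 100 per tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import SelectivityMatrix

__all__ = [
    "GroupingScheme",
    "loo_group_profile",
    "mutation_rho",
    "RhoComparison",
    "compare_groupings",
    "CartControl",
    "CartNode",
    "RegressionTree",
    "cart_fit",
    "variable_importance",
    "ImportanceComparison",
    "importance_comparison",
]


@dataclass(frozen=True)
class GroupingScheme:
    """A named mapping from matrix row (mutation id) to category label."""

    name: str
    mapping: Mapping[str, object]

    def category(self, mutation: str):
        return self.mapping[mutation]

    def members(self, category, universe: Iterable[str]) -> list[str]:
        return [m for m in universe if self.mapping.get(m) == category]

    def small_categories(self, universe: Iterable[str]) -> list:
        """Categories with fewer than two members (not LOO-evaluable)."""
        counts = pd.Series([self.mapping[m] for m in universe]).value_counts()
        return sorted(counts.index[counts < 2].tolist(), key=str)


def loo_group_profile(
    matrix: SelectivityMatrix, scheme: GroupingScheme, mutation: str
) -> Optional[pd.Series]:
    """Per-drug mean profile of the mutation's category, excluding it.

    Returns ``None`` when the category has no other member (singleton
    categories are flagged not-evaluable, never an exception).
    """
    category = scheme.category(mutation)
    others = [m for m in scheme.members(category, matrix.mutations) if m != mutation]
    if not others:
        return None
    return matrix.values.loc[others].mean(axis=0)


def mutation_rho(profile_self: pd.Series, profile_group: pd.Series) -> float:
    """Spearman rank correlation (average-rank ties); NaN when a vector
    has zero variance (undefined, flagged by the caller)."""
    x = np.asarray(profile_self, dtype=float)
    y = np.asarray(profile_group, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("profiles must align over >=3 drugs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass
class RhoComparison:
    """Paired per-mutation LOO rho under two grouping schemes."""

    scheme_a: str
    scheme_b: str
    table: pd.DataFrame  # index mutation; columns rho_a, rho_b
    dropped: list  # mutations not evaluable under both schemes
    t_stat: float
    df: int
    p_value: float

    @property
    def mean_rho(self) -> pd.Series:
        return self.table.mean().rename({"rho_a": self.scheme_a, "rho_b": self.scheme_b})

    @property
    def median_rho(self) -> pd.Series:
        return self.table.median().rename({"rho_a": self.scheme_a, "rho_b": self.scheme_b})

    def summary(self) -> str:
        m, md = self.mean_rho, self.median_rho
        return (
            f"LOO Spearman rho over {len(self.table)} mutations "
            f"({len(self.dropped)} dropped as not evaluable)\n"
            f"  {self.scheme_a}: mean rho = {m[self.scheme_a]:.4f}, median = {md[self.scheme_a]:.4f}\n"
            f"  {self.scheme_b}: mean rho = {m[self.scheme_b]:.4f}, median = {md[self.scheme_b]:.4f}\n"
            f"  paired two-sided t({self.df}) = {self.t_stat:.4f}, p = {self.p_value:.3g}"
        )


def compare_groupings(
    matrix: SelectivityMatrix, scheme_a: GroupingScheme, scheme_b: GroupingScheme
) -> RhoComparison:
    """Pair each evaluable mutation's LOO rho under the two schemes and
    run a paired two-sided t-test on the rho vectors.

    Mutations evaluable under only one scheme (singleton category, or a
    zero-variance profile making rho undefined) are dropped from the
    pairing and listed in ``dropped``.
    """
    rows = {}
    dropped = []
    for mutation in matrix.mutations:
        rhos = []
        for scheme in (scheme_a, scheme_b):
            profile = loo_group_profile(matrix, scheme, mutation)
            if profile is None:
                rhos.append(None)
                continue
            rho = mutation_rho(matrix.values.loc[mutation], profile)
            rhos.append(None if np.isnan(rho) else rho)
        if rhos[0] is None or rhos[1] is None:
            dropped.append(mutation)
        else:
            rows[mutation] = {"rho_a": rhos[0], "rho_b": rhos[1]}
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} mutations evaluable under both schemes; need >=3")
    table = pd.DataFrame.from_dict(rows, orient="index")

    diffs = table["rho_a"] - table["rho_b"]
    n = len(diffs)
    if np.allclose(diffs, 0):
        t, p = 0.0, 1.0
    elif diffs.std(ddof=1) == 0:
        t, p = float(np.sign(diffs.iloc[0]) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(table["rho_a"], table["rho_b"])
    return RhoComparison(
        scheme_a.name, scheme_b.name, table, dropped, float(t), n - 1, float(p)
    )


# --------------------------------------------------------------------------
# CART


@dataclass(frozen=True)
class CartControl:
    """Stopping rules for recursive partitioning.

    ``min_split``: smallest node that may be split; ``min_bucket``:
    smallest allowed child (default ``max(1, min_split // 3)``);
    ``cp``: a split must reduce the root sum of squares by at least
    ``cp * SS(root)``.
    """

    min_split: int = 20
    cp: float = 0.01
    min_bucket: Optional[int] = None

    @property
    def bucket(self) -> int:
        return self.min_bucket if self.min_bucket is not None else max(1, self.min_split // 3)


@dataclass
class CartNode:
    n: int
    mean: float
    ss: float
    predictor: Optional[str] = None
    threshold: Optional[float] = None  # numeric split: x <= threshold goes left
    left_categories: Optional[frozenset] = None  # categorical split
    goodness: float = 0.0
    left: Optional["CartNode"] = None
    right: Optional["CartNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None

    def rule(self) -> str:
        if self.is_leaf:
            return f"leaf(n={self.n}, mean={self.mean:.3g})"
        if self.left_categories is not None:
            cats = ",".join(sorted(map(str, self.left_categories)))
            return f"{self.predictor} in {{{cats}}}"
        return f"{self.predictor} <= {self.threshold:.4g}"


@dataclass
class RegressionTree:
    root: CartNode
    predictors: list[str]
    control: CartControl
    response_name: Optional[str] = None

    def nodes(self) -> list[CartNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.extend([node.right, node.left])
        return out

    def splits(self) -> list[CartNode]:
        return [n for n in self.nodes() if not n.is_leaf]

    def split_sequence(self) -> list[str]:
        """Predictors used at the first and subsequent split levels
        (breadth-first order)."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            if not node.is_leaf:
                out.append(node.predictor)
                queue.extend([node.left, node.right])
        return out

    def predict(self, x: Mapping[str, object]) -> float:
        node = self.root
        while not node.is_leaf:
            value = x[node.predictor]
            if node.left_categories is not None:
                node = node.left if value in node.left_categories else node.right
            else:
                node = node.left if value <= node.threshold else node.right
        return node.mean


def _node_ss(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _best_split_for_predictor(
    y: np.ndarray, x: np.ndarray, categorical: bool, bucket: int
) -> Optional[tuple[float, Optional[float], Optional[frozenset]]]:
    """Best (goodness, threshold, left_categories) for one predictor, or None."""
    ss_parent = _node_ss(y)
    best = None
    if categorical:
        cats = pd.unique(x)
        if len(cats) < 2:
            return None
        means = {c: y[x == c].mean() for c in cats}
        # rpart's reduction: order categories by mean response, then scan
        # ordered prefix splits (optimal for a single-split SS criterion)
        ordered = sorted(cats, key=lambda c: (means[c], str(c)))
        for cut in range(1, len(ordered)):
            left_set = frozenset(ordered[:cut])
            mask = np.isin(x, list(left_set))
            nl, nr = mask.sum(), (~mask).sum()
            if nl < bucket or nr < bucket:
                continue
            goodness = ss_parent - _node_ss(y[mask]) - _node_ss(y[~mask])
            if best is None or goodness > best[0]:
                best = (goodness, None, left_set)
    else:
        xv = np.asarray(x, dtype=float)
        uniq = np.unique(xv)
        if uniq.size < 2:
            return None
        for i in range(uniq.size - 1):
            thr = 0.5 * (uniq[i] + uniq[i + 1])
            mask = xv <= thr
            nl, nr = mask.sum(), (~mask).sum()
            if nl < bucket or nr < bucket:
                continue
            goodness = ss_parent - _node_ss(y[mask]) - _node_ss(y[~mask])
            # ties broken toward the lower split value (first hit wins)
            if best is None or goodness > best[0]:
                best = (goodness, float(thr), None)
    return best


def cart_fit(
    response: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    control: CartControl = CartControl(),
    categorical: Optional[set[str]] = None,
) -> RegressionTree:
    """Greedy recursive binary partitioning minimising within-node SS.

    Categorical predictors (object/category dtype by default) are split
    by ordering categories by their mean response; the goodness of a
    split is ``SS(parent) - SS(left) - SS(right)``.  Splitting stops at
    ``min_split`` observations or when the best split's goodness falls
    below ``cp * SS(root)``.  Ties go to the earlier-listed predictor
    and the lower split value, so fits are deterministic.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.reset_index(drop=True)
    if y.size != len(X):
        raise ValueError("response and predictors must align")
    if categorical is None:
        categorical = {
            c for c in X.columns
            if X[c].dtype == object or isinstance(X[c].dtype, pd.CategoricalDtype)
        }
    ss_root = _node_ss(y)
    threshold_ss = control.cp * ss_root

    def grow(idx: np.ndarray) -> CartNode:
        yv = y[idx]
        node = CartNode(n=idx.size, mean=float(yv.mean()), ss=_node_ss(yv))
        if idx.size < control.min_split or node.ss == 0:
            return node
        best = None  # (goodness, col_order, threshold, left_cats, predictor)
        for col_i, col in enumerate(X.columns):
            xv = X[col].to_numpy()[idx]
            cand = _best_split_for_predictor(yv, xv, col in categorical, control.bucket)
            if cand is None:
                continue
            goodness, thr, cats = cand
            # strict > keeps the earlier-listed predictor on ties
            if best is None or goodness > best[0] + 1e-12:
                best = (goodness, col_i, thr, cats, col)
        if best is None or best[0] < threshold_ss or best[0] <= 0:
            return node
        goodness, _, thr, cats, col = best
        if cats is not None:
            mask = np.isin(X[col].to_numpy()[idx], list(cats))
        else:
            mask = X[col].to_numpy(dtype=float)[idx] <= thr
        node.predictor = col
        node.threshold = thr
        node.left_categories = cats
        node.goodness = float(goodness)
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    root = grow(np.arange(y.size))
    name = response.name if isinstance(response, pd.Series) else None
    return RegressionTree(root, list(X.columns), control, response_name=name)


def variable_importance(tree: RegressionTree) -> pd.Series:
    """Per-predictor sum of split goodness, scaled to total 100.

    A root-only tree has no splits and yields an empty Series;
    predictors never used in a split score 0.
    """
    splits = tree.splits()
    if not splits:
        return pd.Series(dtype=float)
    raw = pd.Series(0.0, index=tree.predictors)
    for node in splits:
        raw[node.predictor] += node.goodness
    return 100.0 * raw / raw.sum()


# --------------------------------------------------------------------------
# Importance comparison across drugs


@dataclass
class ImportanceComparison:
    """Per-drug CART importances: structure group vs summed exon indicators."""

    table: pd.DataFrame  # index drug; imp_structure, imp_exon, structure_in_first_two
    trees: dict
    t_stat: float
    df: int
    p_value: float

    @property
    def mean_importance(self) -> pd.Series:
        return self.table[["imp_structure", "imp_exon"]].mean()

    def summary(self) -> str:
        m = self.mean_importance
        frac = self.table["structure_in_first_two"].mean()
        return (
            f"CART variable importance over {len(self.table)} drugs\n"
            f"  structure group: mean {m['imp_structure']:.1f}; "
            f"exon indicators (summed): mean {m['imp_exon']:.1f}\n"
            f"  structure predictor in first/second split: {100 * frac:.0f}% of trees\n"
            f"  paired two-sided t({self.df}) = {self.t_stat:.4g}, p = {self.p_value:.3g}"
        )


def encode_predictors(
    mutations: Sequence[str],
    structure_groups: Mapping[str, str],
    exon_indicators: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Design matrix: one categorical structure-group column plus four
    0/1 exon indicators (a variant spanning two exons may set two)."""
    rows = []
    for m in mutations:
        row = {"sf_group": structure_groups[m]}
        exons = set(exon_indicators[m])
        for e in (18, 19, 20, 21):
            row[f"exon{e}"] = int(e in exons)
        rows.append(row)
    return pd.DataFrame(rows, index=list(mutations))


def importance_comparison(
    matrix: SelectivityMatrix,
    structure_groups: Mapping[str, str],
    exon_indicators: Mapping[str, Sequence[int]],
    control: CartControl = CartControl(),
) -> ImportanceComparison:
    """One CART tree per drug; compare the structure-group importance to
    the summed exon-indicator importance with a paired two-sided t-test.

    Also records, per tree, whether the structure predictor appears in
    the first or second split.
    """
    if len(matrix.drugs) < 2:
        raise ValueError("need >=2 drugs")
    X = encode_predictors(list(matrix.mutations), structure_groups, exon_indicators)
    exon_cols = [c for c in X.columns if c.startswith("exon")]

    rows = {}
    trees = {}
    for drug in matrix.drugs:
        y = matrix.values[drug]
        tree = cart_fit(y, X, control, categorical={"sf_group"})
        trees[drug] = tree
        imp = variable_importance(tree)
        if imp.empty:
            continue
        seq = tree.split_sequence()
        rows[drug] = {
            "imp_structure": float(imp.get("sf_group", 0.0)),
            "imp_exon": float(sum(imp.get(c, 0.0) for c in exon_cols)),
            "structure_in_first_two": "sf_group" in seq[:2],
        }
    if not rows:
        raise ValueError("all trees are root-only; no splits to compare")
    table = pd.DataFrame.from_dict(rows, orient="index")
    skipped = [d for d in matrix.drugs if d not in rows]
    if skipped:
        warnings.warn(f"root-only trees skipped for drugs: {skipped}")

    diffs = table["imp_structure"] - table["imp_exon"]
    if np.allclose(diffs, diffs.iloc[0]):
        if np.isclose(diffs.iloc[0], 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(diffs.iloc[0]) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(table["imp_structure"], table["imp_exon"])
    return ImportanceComparison(table, trees, float(t), len(table) - 1, float(p))
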