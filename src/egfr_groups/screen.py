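"""Dose-response screens: viability normalisation, 4-parameter logistic
IC50 fits, mutant/WT selectivity ratios, the median log-selectivity
matrix, hierarchical clustering and per-group comparisons.

The screening model follows the Ba/F3 convention: raw bioluminescence is
normalised to the mean DMSO control, a variable-slope logistic is fitted
per (cell line, drug), and the IC50 is the interpolated concentration at
50% inhibition relative to DMSO (absolute, not relative to the fitted
asymptotes).  Selectivity is the ratio of the mutant IC50 to the mean
wild-type IC50 for the same drug, summarised as the median log10 ratio
over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DoseResponse",
    "FitError",
    "normalize_viability",
    "fit_dose_response",
    "mutant_wt_ratio",
    "SelectivityMatrix",
    "build_selectivity_matrix",
    "ClusterResult",
    "hierarchical_cluster",
    "welch_anova",
    "GroupComparison",
    "compare_group_selectivity",
]


class FitError(RuntimeError):
    """Dose-response fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def normalize_viability(raw, dmso) -> np.ndarray:
    """Fraction-of-DMSO viability: ``raw / mean(dmso)``."""
    dmso = np.asarray(dmso, dtype=float)
    mean = dmso.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"non-positive DMSO control mean ({mean})")
    return np.asarray(raw, dtype=float) / mean


def _logistic(logx: np.ndarray, top: float, bottom: float, hill: float, log_ic: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ic)))


@dataclass
class DoseResponse:
    """Fitted variable-slope logistic for one (cell line, drug) curve."""

    concentrations: np.ndarray
    viabilities: np.ndarray
    top: float
    bottom: float
    hill: float
    inflection: float  # concentration at the curve midpoint
    ic50: float
    ic50_censored: bool
    censor_direction: Optional[str] = None  # "high" | "low" | None
    sse: float = float("nan")
    drug: Optional[str] = None
    cell_line: Optional[str] = None

    def predict(self, concentration) -> np.ndarray:
        logx = np.log10(np.asarray(concentration, dtype=float))
        return _logistic(logx, self.top, self.bottom, self.hill, np.log10(self.inflection))

    def summary(self) -> str:
        cens = f" (censored {self.censor_direction})" if self.ic50_censored else ""
        return (
            f"DoseResponse[{self.cell_line or '?'} x {self.drug or '?'}]: "
            f"IC50={self.ic50:.4g}{cens}, top={self.top:.3f}, bottom={self.bottom:.3f}, "
            f"hill={self.hill:.3f}, SSE={self.sse:.3g}"
        )


def fit_dose_response(
    doses: Sequence[float],
    fractions: Sequence[float],
    *,
    bottom_bounds: tuple[float, float] = (0.0, 0.5),
    top_bounds: tuple[float, float] = (0.5, 1.2),
    hill_bounds: tuple[float, float] = (1e-2, 20.0),
    drug: Optional[str] = None,
    cell_line: Optional[str] = None,
) -> DoseResponse:
    """Least-squares variable-slope logistic fit and absolute IC50.

    ``doses`` and ``fractions`` are parallel (repeat doses for
    replicates).  The IC50 is the dose where the fitted curve crosses
    0.5 of the DMSO level; a curve that never reaches 0.5 within the
    tested range is censored at the nearest tested dose and flagged.
    The asymptote bounds (bottom in [0, 0.5], top in [0.5, 1.2])
    stabilise 7-point fits.
    """
    doses = np.asarray(doses, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if doses.shape != fractions.shape:
        raise ValueError("doses and fractions must be parallel arrays")
    if not np.all(np.isfinite(fractions)) or not np.all(doses > 0):
        raise ValueError("doses must be positive and fractions finite")
    distinct = np.unique(doses)
    if distinct.size < 4:
        raise ValueError(f"need >=4 distinct dose levels, got {distinct.size}")

    logx = np.log10(doses)
    lo, hi = logx.min(), logx.max()

    top0 = float(np.clip(np.median(fractions[logx == lo]), *top_bounds))
    bot0 = float(np.clip(np.median(fractions[logx == hi]), *bottom_bounds))
    mid_guess = logx[np.argmin(np.abs(fractions - 0.5))]
    p0 = [top0, bot0, 1.0, float(mid_guess)]
    bounds = (
        [top_bounds[0], bottom_bounds[0], hill_bounds[0], lo - 3.0],
        [top_bounds[1], bottom_bounds[1], hill_bounds[1], hi + 3.0],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _logistic, logx, fractions, p0=p0, bounds=bounds, maxfev=20000
            )
    except RuntimeError as exc:
        raise FitError(
            f"dose-response fit did not converge for {cell_line}/{drug}",
            {"p0": p0, "n_points": doses.size, "error": str(exc)},
        ) from exc
    top, bottom, hillslope, log_ic = (float(x) for x in popt)
    sse = float(np.sum((_logistic(logx, *popt) - fractions) ** 2))

    ic50, censored, direction = _absolute_ic50(top, bottom, hillslope, log_ic, lo, hi)
    return DoseResponse(
        concentrations=distinct,
        viabilities=fractions,
        top=top,
        bottom=bottom,
        hill=hillslope,
        inflection=10.0 ** log_ic,
        ic50=ic50,
        ic50_censored=censored,
        censor_direction=direction,
        sse=sse,
        drug=drug,
        cell_line=cell_line,
    )


def _absolute_ic50(
    top: float, bottom: float, hillslope: float, log_ic: float, lo: float, hi: float
) -> tuple[float, bool, Optional[str]]:
    # solve bottom + (top-bottom)/(1+10^(h(l-l0))) = 0.5
    if top <= 0.5 or bottom >= 0.5:
        # curve never crosses 0.5: flat-resistant (top side) or always-below
        if bottom >= 0.5 or _logistic(np.array([hi]), top, bottom, hillslope, log_ic)[0] > 0.5:
            return 10.0 ** hi, True, "high"
        return 10.0 ** lo, True, "low"
    log_x50 = log_ic + np.log10((top - 0.5) / (0.5 - bottom)) / hillslope
    if log_x50 > hi:
        return 10.0 ** hi, True, "high"
    if log_x50 < lo:
        return 10.0 ** lo, True, "low"
    return float(10.0 ** log_x50), False, None


def mutant_wt_ratio(
    ic50_mut: float, wt_ic50s: Sequence[float], log_base: float = 10.0
) -> tuple[float, float]:
    """Selectivity ratio and its log: mutant IC50 over the mean WT IC50."""
    wt = np.asarray(wt_ic50s, dtype=float)
    if wt.size == 0:
        raise ValueError("need at least one WT IC50")
    if ic50_mut <= 0 or np.any(wt <= 0):
        raise ValueError("IC50 values must be positive")
    ratio = float(ic50_mut / wt.mean())
    return ratio, float(np.log(ratio) / np.log(log_base))


# --------------------------------------------------------------------------
# Selectivity matrix


@dataclass
class SelectivityMatrix:
    """Mutations x drugs matrix of median log10(mutant/WT IC50).

    ``values`` is a DataFrame (rows: mutation/cell-line ids, columns:
    drug ids); ``censored`` marks cells whose median replicate was
    IC50-censored (the value is then the ratio at the censor bound).
    ``row_groups``/``row_exons`` and ``col_classes`` carry the
    structure-function / exon annotation of rows and the drug class of
    columns.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    row_groups: pd.Series = None
    row_exons: pd.Series = None
    col_classes: pd.Series = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row/column ids must be unique")
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def mutations(self) -> pd.Index:
        return self.values.index

    @property
    def drugs(self) -> pd.Index:
        return self.values.columns

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("log_ratio").reset_index()
        long.columns = ["mutation", "drug", "log_ratio"]
        long["censored"] = self.censored.stack().to_numpy()
        if self.row_groups is not None:
            long["group"] = long["mutation"].map(self.row_groups)
        if self.row_exons is not None:
            long["exon"] = long["mutation"].map(self.row_exons)
        if self.col_classes is not None:
            long["drug_class"] = long["drug"].map(self.col_classes)
        return long

    def plot(self, ax=None):
        """Quick heat map of the selectivity matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(0.45 * len(self.drugs) + 2, 0.3 * len(self.mutations) + 2))
        vmax = np.nanmax(np.abs(self.values.to_numpy())) or 1.0
        im = ax.imshow(self.values.to_numpy(), cmap="RdYlGn_r", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xticks(range(len(self.drugs)), self.drugs, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.mutations)), self.mutations, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="median log10(Mut/WT)")
        return ax


def _median_with_censor(values: np.ndarray, censored: np.ndarray) -> tuple[float, bool]:
    order = np.argsort(values, kind="stable")
    v = values[order]
    c = censored[order]
    n = v.size
    if n % 2:
        mid = n // 2
        return float(v[mid]), bool(c[mid])
    m1, m2 = n // 2 - 1, n // 2
    return float(0.5 * (v[m1] + v[m2])), bool(c[m1] or c[m2])


def build_selectivity_matrix(
    replicates: pd.DataFrame,
    *,
    mutation_col: str = "cell_line",
    drug_col: str = "drug",
    value_col: str = "log_ratio",
    censor_col: str = "censored",
    row_groups: Optional[pd.Series] = None,
    row_exons: Optional[pd.Series] = None,
    col_classes: Optional[pd.Series] = None,
) -> SelectivityMatrix:
    """Median-over-replicates selectivity matrix from per-replicate log ratios.

    The median of an even replicate count is the mean of the middle
    pair.  A cell's censor flag propagates when the median replicate is
    itself censored.  (Mutation, drug) pairs absent from ``replicates``
    are reported via a warning, never imputed.
    """
    if replicates.empty:
        raise ValueError("no replicate data")
    df = replicates.copy()
    if censor_col not in df.columns:
        df[censor_col] = False

    rows = pd.Index(pd.unique(df[mutation_col]), name="mutation")
    cols = pd.Index(pd.unique(df[drug_col]), name="drug")
    values = pd.DataFrame(np.nan, index=rows, columns=cols)
    censored = pd.DataFrame(False, index=rows, columns=cols)
    for (mut, drug), sub in df.groupby([mutation_col, drug_col], sort=False):
        med, cens = _median_with_censor(
            sub[value_col].to_numpy(dtype=float), sub[censor_col].to_numpy(dtype=bool)
        )
        values.loc[mut, drug] = med
        censored.loc[mut, drug] = cens

    missing = values.isna()
    if missing.to_numpy().any():
        cells = [(m, d) for m in rows for d in cols if missing.loc[m, d]]
        warnings.warn(f"missing (mutation, drug) cells, not imputed: {cells}")

    if col_classes is None and "drug_class" in df.columns:
        col_classes = df.drop_duplicates(drug_col).set_index(drug_col)["drug_class"]
    return SelectivityMatrix(values, censored, row_groups, row_exons, col_classes)


# --------------------------------------------------------------------------
# Hierarchical clustering


@dataclass
class ClusterResult:
    """Agglomerative clustering of matrix rows or columns."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    order: list[int]  # leaf order (indices into labels)

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: SelectivityMatrix | pd.DataFrame,
    axis: str = "rows",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering under Euclidean distance.

    Censored cells already sit at their censor-bound value, keeping the
    matrix finite.  Complete linkage by default; scipy's deterministic
    ordering provides the tie-break.
    """
    values = matrix.values if isinstance(matrix, SelectivityMatrix) else matrix
    data = values if axis == "rows" else values.T
    if data.shape[0] < 2:
        raise ValueError("need at least two observations to cluster")
    if data.isna().to_numpy().any():
        raise ValueError("clustered axis contains missing values")
    Z = hierarchy.linkage(data.to_numpy(), method=method, metric="euclidean")
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(Z, list(data.index), order)


# --------------------------------------------------------------------------
# Group comparisons (Welch ANOVA + Holm-Sidak pairwise)


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, df1, df2, p)``.  Each group needs n >= 2.  If every
    group is an identical constant the test degenerates to F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >=2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs >=2 observations")
    k = len(arrays)
    n = np.array([g.size for g in arrays], dtype=float)
    means = np.array([g.mean() for g in arrays])
    var = np.array([g.var(ddof=1) for g in arrays])

    if np.all(var == 0):
        if np.allclose(means, means[0]):
            return 0.0, float(k - 1), float("inf"), 1.0
        return float("inf"), float(k - 1), float("inf"), 0.0
    if np.any(var == 0):
        raise ValueError("a group has zero variance; Welch weights undefined")

    w = n / var
    W = w.sum()
    mw = (w * means).sum() / W
    A = (w * (means - mw) ** 2).sum() / (k - 1)
    tmp = ((1 - w / W) ** 2 / (n - 1)).sum()
    B = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    F = float(A / B)
    df1 = float(k - 1)
    df2 = float((k**2 - 1) / (3 * tmp))
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


@dataclass
class GroupComparison:
    """Welch ANOVA plus Holm-Sidak-adjusted pairwise Welch t-tests."""

    f_stat: float
    df1: float
    df2: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_adj
    group_sizes: pd.Series

    def summary(self) -> str:
        lines = [
            f"Welch one-way ANOVA: F({self.df1:.0f}, {self.df2:.1f}) = "
            f"{self.f_stat:.4g}, p = {self.p_value:.3g}",
            self.pairwise.to_string(index=False),
        ]
        return "\n".join(lines)


def compare_group_selectivity(
    data: dict | pd.DataFrame | SelectivityMatrix,
    grouping: Optional[pd.Series | dict | str] = None,
    *,
    value_col: str = "log_ratio",
    axis: str = "columns",
) -> GroupComparison:
    """Compare selectivity between groups of drugs (or mutations).

    ``data`` may be a mapping of group -> observations, a long DataFrame
    (``grouping`` names its group column), or a
    :class:`SelectivityMatrix` whose columns (``axis="columns"``) or
    rows are grouped by the ``grouping`` mapping.  Welch's ANOVA across
    groups is followed by all pairwise Welch t-tests with Holm-Sidak
    adjustment.
    """
    if isinstance(data, SelectivityMatrix):
        long = data.to_long()
        key = "drug" if axis == "columns" else "mutation"
        long["_grp"] = long[key].map(pd.Series(grouping))
        long = long.dropna(subset=["_grp"])
        samples = {g: sub[value_col].to_numpy() for g, sub in long.groupby("_grp")}
    elif isinstance(data, pd.DataFrame):
        samples = {g: sub[value_col].to_numpy() for g, sub in data.groupby(grouping)}
    else:
        samples = {g: np.asarray(v, dtype=float) for g, v in data.items()}

    names = sorted(samples)
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    F, df1, df2, p = welch_anova([samples[g] for g in names])

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = samples[names[i]], samples[names[j]]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                t, praw = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
            else:
                t, praw = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"group_a": names[i], "group_b": names[j], "t": float(t), "p_raw": float(praw)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="holm-sidak")[1]
    sizes = pd.Series({g: samples[g].size for g in names}, name="n")
    return GroupComparison(F, df1, df2, p, pairwise, sizes)
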