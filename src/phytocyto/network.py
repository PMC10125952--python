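"""Group statistics, time-course regression and the banded
correlation network.

The network is built in two steps.  Step 1 screens each trait for a
control-vs-kinetin difference (Mann-Whitney U as the primary test,
Student's t reported alongside) at a significance threshold ``alpha``.
Step 2 computes pairwise Pearson coefficients among the surviving
traits and classifies each |r| into strength bands:

* none     : |r| < 0.3
* moderate : 0.3 <= |r| <= 0.8
* strong   : |r| > 0.8

Edges with band "none" are dropped; surviving edges carry the signed r,
its sign and its band.  No multiple-testing correction is applied
across pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "compare_groups",
    "fit_window_regression",
    "pairwise_correlations",
    "band_classify",
    "significance_screen",
    "build_network",
    "write_graphml",
    "BAND_CUTS",
    "EXACT_MW_MAX_N",
]

BAND_CUTS = (0.3, 0.8)
#: Largest combined sample size for which the Mann-Whitney P value is
#: computed by exact enumeration over label assignments.
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    u_stat: float
    p_u: float
    t_stat: float
    p_t: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class RegressionResult:
    trait: str
    window: tuple[float, float]
    model: str
    coefficients: dict
    r_squared: dict
    u_stat: float | None = None
    p_u: float | None = None
    t_stat: float | None = None
    p_t: float | None = None


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_mw_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact P by enumeration of all C(n, n1) label
    assignments; two-sidedness is distance of U from its null mean.
    Tie-tolerant (U computed from midranks)."""
    ranks = _midranks(pooled)
    n = pooled.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    d_obs = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
    return count / comb(n, n1)


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Mann-Whitney U and Student's t comparison of groups.

    U is the statistic of group *a* (number of (a, b) pairs with
    a > b, ties counted half).  The Mann-Whitney P is exact by
    enumeration for combined n <= 12 and uses the tie-corrected normal
    approximation (with continuity correction) otherwise.  Degenerate
    input (every value identical) yields P = 1 with a warning.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size

    ranks = _midranks(pooled)
    u_stat = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; P set to 1")
        return GroupComparison(u_stat=u_stat, p_u=1.0, t_stat=0.0, p_t=1.0,
                               method="degenerate")

    if n1 + n2 <= EXACT_MW_MAX_N:
        p_u = _exact_mw_p(pooled, n1, u_stat)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p_u = float(res.pvalue)
        method = "asymptotic"

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # equal-variance zero case with different means: t undefined
        t_stat, p_t = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
    else:
        tres = stats.ttest_ind(a, b)
        t_stat, p_t = float(tres.statistic), float(tres.pvalue)
    return GroupComparison(u_stat=u_stat, p_u=float(p_u),
                           t_stat=t_stat, p_t=p_t, method=method)


def _fit_poly(days: np.ndarray, values: np.ndarray, degree: int):
    """Least-squares polynomial fit; returns (coefficients, R^2).
    Constant data (zero total variance) is reported as R^2 = 0."""
    coef = np.polyfit(days, values, degree)
    pred = np.polyval(coef, days)
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0:
        return tuple(coef), 0.0
    ss_res = float(np.sum((values - pred) ** 2))
    return tuple(coef), max(1.0 - ss_res / ss_tot, 0.0)


def fit_window_regression(table: pd.DataFrame, trait: str,
                          window: tuple[float, float] = (4.0, 7.0),
                          model: str = "linear",
                          group_col: str = "group",
                          day_col: str = "timepoint_d") -> RegressionResult:
    """Per-group regression of a trait over a day window, plus a
    between-group comparison of the window values.

    ``model`` is "linear" or "quadratic".  Each group present in the
    table gets its own least-squares fit and R^2; when exactly two
    groups are present the window values are additionally compared via
    :func:`compare_groups`.  At least 3 points per group are required.
    """
    if model not in ("linear", "quadratic"):
        raise ValueError(f"unknown model {model!r}")
    degree = 1 if model == "linear" else 2
    lo, hi = float(window[0]), float(window[1])
    sub = table[(table[day_col] >= lo) & (table[day_col] <= hi)]
    if sub.empty:
        raise ValueError(f"no data in window {window}")

    coefficients, r_squared, group_values = {}, {}, {}
    for grp, gdf in sub.groupby(group_col, sort=True):
        days = gdf[day_col].to_numpy(dtype=float)
        vals = gdf[trait].to_numpy(dtype=float)
        if vals.size < 3:
            raise ValueError(
                f"group {grp!r} has {vals.size} points in window; need >= 3"
            )
        coefficients[grp], r_squared[grp] = _fit_poly(days, vals, degree)
        group_values[grp] = vals

    cmp = None
    if len(group_values) == 2:
        (va, vb) = group_values.values()
        cmp = compare_groups(va, vb)
    return RegressionResult(
        trait=trait, window=(lo, hi), model=model,
        coefficients=coefficients, r_squared=r_squared,
        u_stat=cmp.u_stat if cmp else None,
        p_u=cmp.p_u if cmp else None,
        t_stat=cmp.t_stat if cmp else None,
        p_t=cmp.p_t if cmp else None,
    )


def pairwise_correlations(table: pd.DataFrame,
                          traits=None) -> pd.DataFrame:
    """Symmetric Pearson r matrix over trait columns.

    Missing values are handled by pairwise deletion; pairs with fewer
    than 3 complete rows, or involving a zero-variance trait, are NaN.
    """
    if traits is None:
        traits = [c for c in table.columns
                  if pd.api.types.is_numeric_dtype(table[c])]
    data = table[list(traits)].astype(float)
    r = data.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)
    # pandas leaves r = NaN for zero-variance traits, which is the
    # flagged-missing convention required here
    return r


def band_classify(r: float) -> str:
    """Correlation-strength band of a coefficient.

    none if |r| < 0.3; moderate if 0.3 <= |r| <= 0.8; strong if
    |r| > 0.8.
    """
    if np.isnan(r):
        raise ValueError("cannot band-classify a missing correlation")
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| = {a} exceeds 1")
    lo, hi = BAND_CUTS
    if a < lo:
        return "none"
    if a <= hi:
        return "moderate"
    return "strong"


def significance_screen(table: pd.DataFrame, traits=None,
                        group_col: str = "group",
                        alpha: float = 0.05) -> pd.DataFrame:
    """Step-1 per-trait screen: control-vs-kinetin difference.

    Returns a frame indexed by trait with columns u_stat, p_u, t_stat,
    p_t and ``significant`` (Mann-Whitney P <= alpha; the t-test is
    reported alongside).
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, found {groups}")
    if traits is None:
        traits = [c for c in table.columns
                  if pd.api.types.is_numeric_dtype(table[c]) and c != group_col]
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    rows = []
    for t in traits:
        cmp = compare_groups(ga[t].dropna(), gb[t].dropna())
        rows.append(dict(trait=t, u_stat=cmp.u_stat, p_u=cmp.p_u,
                         t_stat=cmp.t_stat, p_t=cmp.p_t,
                         significant=cmp.p_u <= alpha))
    return pd.DataFrame(rows).set_index("trait")


def build_network(r: pd.DataFrame, significant, alpha: float = 0.05) -> nx.Graph:
    """Assemble the banded correlation network.

    Nodes are the traits flagged significant in step 1 (lexicographic
    order); edges connect pairs whose |r| reaches at least the moderate
    band, attributed with r, sign and band.  An empty node set yields
    an empty graph with a warning.
    """
    if isinstance(significant, pd.DataFrame):
        significant = significant["significant"]
    sig = pd.Series(significant)
    nodes = sorted(t for t in r.columns if bool(sig.get(t, False)))
    g = nx.Graph(alpha=float(alpha),
                 band_cuts=f"{BAND_CUTS[0]},{BAND_CUTS[1]}")
    if not nodes:
        warnings.warn("no trait passed the step-1 significance screen")
        return g
    g.add_nodes_from(nodes)
    for a, b in combinations(nodes, 2):
        rv = r.loc[a, b]
        if pd.isna(rv):
            continue
        band = band_classify(rv)
        if band == "none":
            continue
        g.add_edge(a, b, r=float(rv),
                   sign="positive" if rv >= 0 else "negative", band=band)
    return g


def write_graphml(g: nx.Graph, path) -> None:
    """Deterministic GraphML export (nodes/edges in insertion order,
    which :func:`build_network` makes lexicographic)."""
    nx.write_graphml(g, path)
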