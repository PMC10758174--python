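"""Associations of cultural distance with internalization and stigma.

This is the inferential layer: hierarchical polynomial correlations of
continuous log distance with each outcome, a quartile trend ANOVA with
orthogonal linear/nonlinear decomposition and eta (the correlation
ratio, sqrt(SS_between / SS_total)), Tukey post-hoc contrasts of the
culturally distal quartile, a median-centred Levene test of variance
heterogeneity, and the dichotomised influential-item count.

A summary-statistics ANOVA oracle is included: it computes the identical
decomposition purely from per-group (mean, s.d., n) rows, so published
tables of quartile summaries can be checked for internal consistency
without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ratings import RatingsMatrix

__all__ = [
    "GroupSummary",
    "TrendANOVAResults",
    "polynomial_trend_regression",
    "quartile_trend_anova",
    "summary_stat_anova",
    "posthoc_distal",
    "variance_heterogeneity",
    "influential_item_count",
]

QUARTILE_LEVELS = (1, 2, 3, 4)


@dataclass
class GroupSummary:
    """Per-group mean, standard deviation and size (one ANOVA cell)."""

    label: object
    mean: float
    sd: float
    n: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass
class TrendANOVAResults:
    """One-way trend ANOVA across ordered groups (distance quartiles).

    The between-groups sum of squares is split into a linear component
    (orthogonal polynomial contrast, weighted generalisation for unequal
    n) and the nonlinear remainder; ``eta`` is sqrt(SS_between/SS_total).
    """

    groups: pd.DataFrame  # columns: mean, sd, n; index: ordered labels
    ss_between: float
    ss_within: float
    ss_linear: float
    f_overall: float
    f_linear: float
    f_nonlinear: float
    p_overall: float
    p_linear: float
    p_nonlinear: float
    eta: float
    df_between: int
    df_within: float
    outcome: str = ""

    @property
    def ss_nonlinear(self) -> float:
        return self.ss_between - self.ss_linear

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def eta_squared(self) -> float:
        return self.eta**2

    def summary(self) -> str:
        name = self.outcome or "outcome"
        lines = [
            f"Quartile trend ANOVA: {name}",
            "=" * 48,
            f"{'group':<10}{'mean':>8}{'sd':>8}{'n':>8}",
        ]
        for label, row in self.groups.iterrows():
            lines.append(
                f"{label!s:<10}{row['mean']:>8.1f}{row['sd']:>8.1f}{row['n']:>8.6g}"
            )
        lines += [
            "",
            f"Overall F (df {self.df_between},{self.df_within:g})   = "
            f"{self.f_overall:.1f}   p = {self.p_overall:.3f}",
            f"Linear F (df 1,{self.df_within:g})    = "
            f"{self.f_linear:.1f}   p = {self.p_linear:.3f}",
            f"Nonlinear F (df 2,{self.df_within:g}) = "
            f"{self.f_nonlinear:.1f}   p = {self.p_nonlinear:.3f}",
            f"eta = {self.eta:.4f}",
        ]
        return "\n".join(lines)


def _trend_from_moments(
    labels: np.ndarray, means: np.ndarray, sds: np.ndarray, ns: np.ndarray,
    outcome: str = "",
) -> TrendANOVAResults:
    k = len(labels)
    if k < 3:
        raise ValueError("trend ANOVA needs at least 3 ordered groups")
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, float(total_n - k)
    ms_within = ss_within / df_w
    # linear contrast: centred group scores 1..k, weighted for unequal n
    # (reduces to the classical (-3,-1,1,3) coefficients when balanced)
    x = np.arange(1, k + 1, dtype=float)
    c = x - (ns * x).sum() / total_n
    ss_linear = float((ns * c * means).sum() ** 2 / (ns * c**2).sum())
    ss_nonlinear = max(ss_between - ss_linear, 0.0)
    f_overall = (ss_between / df_b) / ms_within
    f_linear = ss_linear / ms_within
    f_nonlinear = (ss_nonlinear / (df_b - 1)) / ms_within
    eta = float(np.sqrt(ss_between / (ss_between + ss_within)))
    groups = pd.DataFrame({"mean": means, "sd": sds, "n": ns},
                          index=pd.Index(labels, name="group"))
    return TrendANOVAResults(
        groups=groups,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_linear=ss_linear,
        f_overall=float(f_overall),
        f_linear=float(f_linear),
        f_nonlinear=float(f_nonlinear),
        p_overall=float(stats.f.sf(f_overall, df_b, df_w)),
        p_linear=float(stats.f.sf(f_linear, 1, df_w)),
        p_nonlinear=float(stats.f.sf(f_nonlinear, df_b - 1, df_w)),
        eta=eta,
        df_between=df_b,
        df_within=df_w,
        outcome=outcome,
    )


def _split_groups(y: pd.Series, quartile: pd.Series) -> list[np.ndarray]:
    frame = pd.DataFrame({"y": y, "q": quartile}).dropna()
    levels = sorted(frame["q"].unique())
    groups = [frame.loc[frame["q"] == lvl, "y"].to_numpy() for lvl in levels]
    if any(len(g) < 2 for g in groups):
        bad = [lvl for lvl, g in zip(levels, groups) if len(g) < 2]
        raise ValueError(f"groups with fewer than 2 observations: {bad}")
    return groups


def quartile_trend_anova(
    y: pd.Series, quartile: pd.Series, outcome: str = ""
) -> TrendANOVAResults:
    """One-way trend ANOVA of an outcome across distance quartiles.

    Linear effect via the orthogonal polynomial contrast (−3, −1, 1, 3)
    (weighted generalisation under unequal n); the nonlinear effect is the
    between-groups remainder on 2 df; eta = sqrt(SS_between/SS_total).
    """
    frame = pd.DataFrame({"y": y, "q": quartile}).dropna()
    groups = _split_groups(frame["y"], frame["q"])
    labels = np.array(sorted(frame["q"].unique()))
    means = np.array([g.mean() for g in groups])
    sds = np.array([g.std(ddof=1) for g in groups])
    ns = np.array([len(g) for g in groups], dtype=float)
    return _trend_from_moments(labels, means, sds, ns, outcome)


def summary_stat_anova(
    groups: list[GroupSummary] | pd.DataFrame, outcome: str = ""
) -> TrendANOVAResults:
    """Trend ANOVA computed purely from per-group summary statistics.

    Accepts a list of :class:`GroupSummary` or a frame with columns
    ``mean``, ``sd``, ``n`` (and optionally ``label``).  Exactly equals
    the raw-data ANOVA when the summaries are exact, which makes it an
    oracle for checking published quartile tables.
    """
    if isinstance(groups, pd.DataFrame):
        frame = groups.reset_index() if "label" not in groups.columns else groups
        label_col = "label" if "label" in frame.columns else frame.columns[0]
        groups = [
            GroupSummary(row[label_col], float(row["mean"]), float(row["sd"]),
                         float(row["n"]))
            for _, row in frame.iterrows()
        ]
    labels = np.array([g.label for g in groups])
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    ns = np.array([g.n for g in groups], dtype=float)
    return _trend_from_moments(labels, means, sds, ns, outcome)


def polynomial_trend_regression(
    x: pd.Series | np.ndarray, y: pd.Series | np.ndarray, max_degree: int = 3
) -> pd.DataFrame:
    """Hierarchical polynomial regression of an outcome on log distance.

    Fits centred orthogonal polynomials of degree 1..``max_degree`` and
    reports, per added degree, the cumulative R-squared, the increment
    over the previous degree, and the F-change test of that increment.
    The degree-1 row also carries the plain linear correlation r.
    """
    frame = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float)})
    frame = frame.dropna()
    n = len(frame)
    if n <= max_degree + 1:
        raise ValueError("need more observations than parameters")
    xv, yv = frame["x"].to_numpy(), frame["y"].to_numpy()
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor: polynomial trend undefined")
    xc = xv - xv.mean()
    # orthonormal polynomial basis (constant + degrees 1..max) via QR
    basis, _ = np.linalg.qr(np.vander(xc, max_degree + 1, increasing=True))
    yc = yv - yv.mean()
    ss_total = float(yc @ yc)
    rows = []
    if np.ptp(yv) == 0 or ss_total == 0:
        # constant outcome: every correlation and increment is zero
        for d in range(1, max_degree + 1):
            rows.append({"degree": d, "r_squared": 0.0, "delta_r_squared": 0.0,
                         "f_change": 0.0, "p_change": 1.0})
        out = pd.DataFrame(rows).set_index("degree")
        out.insert(0, "r", 0.0)
        return out
    proj = basis.T @ yc  # projections; column 0 is the constant
    ss_by_degree = proj[1:] ** 2  # SS uniquely attributed to each degree
    cum = np.cumsum(ss_by_degree)
    prev_r2 = 0.0
    for d in range(1, max_degree + 1):
        r2 = float(cum[d - 1] / ss_total)
        delta = r2 - prev_r2
        df_resid = n - d - 1
        f_change = (delta / 1) / ((1 - r2) / df_resid) if r2 < 1 else np.inf
        rows.append({
            "degree": d,
            "r_squared": r2,
            "delta_r_squared": delta,
            "f_change": float(f_change),
            "p_change": float(stats.f.sf(f_change, 1, df_resid)),
        })
        prev_r2 = r2
    out = pd.DataFrame(rows).set_index("degree")
    r = float(np.corrcoef(xv, yv)[0, 1])
    out.insert(0, "r", [r] + [np.nan] * (max_degree - 1))
    return out


def posthoc_distal(
    y: pd.Series, quartile: pd.Series, alpha: float = 0.05,
    method: str = "tukey",
) -> pd.DataFrame:
    """Post-hoc contrasts of the culturally distal quartile (4) vs 1–3.

    Tukey HSD by default (Scheffé optionally); returns one row per
    comparison with the mean difference (distal minus other), p-value,
    and whether the distal quartile is *significantly lower*.
    """
    groups = _split_groups(y, quartile)
    levels = sorted(pd.DataFrame({"y": y, "q": quartile}).dropna()["q"].unique())
    k = len(groups)
    distal_idx = k - 1
    means = [g.mean() for g in groups]
    rows = []
    if method == "tukey":
        res = stats.tukey_hsd(*groups)
        pvals = {j: res.pvalue[distal_idx, j] for j in range(k - 1)}
    elif method == "scheffe":
        ns = np.array([len(g) for g in groups], dtype=float)
        df_w = ns.sum() - k
        ss_w = sum((len(g) - 1) * g.var(ddof=1) for g in groups)
        ms_w = ss_w / df_w
        pvals = {}
        for j in range(k - 1):
            diff = means[distal_idx] - means[j]
            f_s = diff**2 / (ms_w * (1 / ns[distal_idx] + 1 / ns[j])) / (k - 1)
            pvals[j] = float(stats.f.sf(f_s, k - 1, df_w))
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    for j in range(k - 1):
        diff = means[distal_idx] - means[j]
        p = float(pvals[j])
        rows.append({
            "comparison": f"{levels[distal_idx]} vs {levels[j]}",
            "mean_diff": diff,
            "p_value": p,
            "distal_lower": bool(p < alpha and diff < 0),
        })
    return pd.DataFrame(rows).set_index("comparison")


def variance_heterogeneity(
    y: pd.Series, quartile: pd.Series
) -> tuple[float, float, pd.Series]:
    """Median-centred Levene test of equal variances across quartiles.

    Returns (statistic, p-value, per-group variances); the variance
    Series' ``idxmax()`` names the most variable group.
    """
    groups = _split_groups(y, quartile)
    levels = sorted(pd.DataFrame({"y": y, "q": quartile}).dropna()["q"].unique())
    stat, p = stats.levene(*groups, center="median")
    variances = pd.Series([g.var(ddof=1) for g in groups], index=levels,
                          name="variance")
    return float(stat), float(p), variances


def influential_item_count(
    ratings: RatingsMatrix, quartile: pd.Series | None = None
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Number of items each informant rates as influential (code 3 or 4).

    Dichotomises the 1–4 codes at 3 and counts per informant; with
    quartile labels supplied, also returns the per-quartile mean counts.
    """
    counts = (ratings.values >= 3).sum(axis=1).rename("influential_items")
    if quartile is None:
        return counts
    aligned = quartile.reindex(counts.index)
    means = counts.groupby(aligned).mean().rename("mean_influential_items")
    return counts, means
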