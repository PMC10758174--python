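"""R-mode internalization scales.

The treatment group's risk-factor ratings are factored (principal
components of the item correlation matrix, varimax rotation, scree-elbow
retention) and items loading past a threshold are summed into scales.
In the study's terms the two recovered scales are the *Internalized
Psychosocial Model of Risk* (IPSMR, 17 items, range 17–68) and the
*Internalized Experiential Model of Risk* (IEMR, 5 items, range 5–20);
scale reliability is reported as Cronbach's alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratings import RatingsMatrix
from .reliability import cronbach_alpha

__all__ = [
    "varimax",
    "select_factors_scree",
    "assign_items",
    "score_scale",
    "cronbach_alpha",
    "InternalizationModel",
    "FactorResults",
]

DEFAULT_LOADING_THRESHOLD = 0.40


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Kaiser varimax rotation of a loading matrix (orthogonal).

    Maximises the variance of squared loadings within factors; per-item
    communalities are invariant under the rotation.
    """
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ rot


def select_factors_scree(eigenvalues: np.ndarray) -> int:
    """Number of factors before the scree-plot elbow.

    The elbow is the eigenvalue at which the curve's discrete acceleration
    (second difference) is maximal; the retained count is the number of
    eigenvalues *before* it.  A flat spectrum has no elbow and returns 1
    with a warning.  The retention rule is overridable via the model's
    ``n_factors`` argument.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if e.size < 3:
        raise ValueError("scree selection needs at least 3 eigenvalues")
    accel = e[:-2] - 2 * e[1:-1] + e[2:]  # acceleration at positions 2..k-1
    if np.allclose(accel, accel[0]):
        warnings.warn("flat eigenvalue spectrum: no scree elbow; retaining 1",
                      stacklevel=2)
        return 1
    elbow = int(np.argmax(accel)) + 1  # 0-based index of the elbow eigenvalue
    return max(elbow, 1)


def assign_items(
    loadings: pd.DataFrame, threshold: float = DEFAULT_LOADING_THRESHOLD
) -> dict[str, list[str]]:
    """Threshold assignment of items to factors.

    An item joins the factor where its |loading| meets the threshold; if
    several factors qualify it joins the one with the largest |loading|.
    Items below threshold everywhere are reported under ``"unassigned"``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sets: dict[str, list[str]] = {c: [] for c in loadings.columns}
    sets["unassigned"] = []
    absload = loadings.abs()
    for item in loadings.index:
        row = absload.loc[item]
        if (row >= threshold).any():
            sets[row.idxmax()].append(item)
        else:
            sets["unassigned"].append(item)
    return sets


def score_scale(ratings: RatingsMatrix, item_set: list[str]) -> pd.Series:
    """Plain sum of the 1–4 ratings over an item set, per informant.

    Informants missing any item of the set get a missing (NaN) score — no
    imputation.
    """
    missing_items = [i for i in item_set if i not in ratings.values.columns]
    if missing_items:
        raise KeyError(f"items not in catalogue: {missing_items}")
    sub = ratings.values[list(item_set)]
    scores = sub.sum(axis=1)
    scores[sub.isna().any(axis=1)] = np.nan
    return scores


@dataclass
class FactorResults:
    """Varimax-rotated principal-components solution with summed scales."""

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    n_factors: int
    variance_explained: float
    item_sets: dict[str, list[str]]
    alphas: dict[str, float]
    scores: pd.DataFrame
    threshold: float
    model: "InternalizationModel" = field(repr=False)

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def summary(self) -> str:
        lines = [
            "R-mode internalization scales",
            "=" * 46,
            f"Factors retained (scree): {self.n_factors}",
            f"Variance explained:       {self.variance_explained:.1%}",
            f"Loading threshold:        {self.threshold:.2f}",
            "",
            f"{'scale':<12}{'items':>6}{'alpha':>8}",
        ]
        for name, items in self.item_sets.items():
            if name == "unassigned":
                lines.append(f"{name:<12}{len(items):>6}{'':>8}")
            else:
                a = self.alphas.get(name, float("nan"))
                lines.append(f"{name:<12}{len(items):>6}{a:>8.3f}")
        return "\n".join(lines)

    def loadings_tsv(self, path) -> None:
        self.loadings.round(3).to_csv(path, sep="\t")


class InternalizationModel:
    """Exploratory factoring of one group's ratings into internalized scales.

    PCA is run on the item Pearson-correlation matrix (items share a 1–4
    scale, but standardisation matches standard EFA practice for skewed
    ratings); retained components are varimax-rotated and sign-aligned so
    each factor's largest |loading| is positive.

    Parameters
    ----------
    ratings
        Typically the TG subset.
    n_factors
        Retained components; ``None`` (default) uses the scree elbow.
    threshold
        |loading| cutoff for item assignment (default 0.40).
    scale_names
        Labels for the factor scales in retention order; defaults to
        ("IPSMR", "IEMR") for a two-factor solution, else factor1, ...
    """

    def __init__(
        self,
        ratings: RatingsMatrix,
        n_factors: int | None = None,
        threshold: float = DEFAULT_LOADING_THRESHOLD,
        scale_names: tuple[str, ...] | None = None,
    ) -> None:
        self.ratings = ratings
        self.n_factors = n_factors
        self.threshold = threshold
        self.scale_names = scale_names

    def fit(self) -> FactorResults:
        values = self.ratings.values
        if values.shape[1] < 2:
            raise ValueError("factoring needs at least 2 items")
        corr = values.corr()
        bad = corr.columns[corr.isna().any()].tolist()
        if bad:
            raise ValueError(
                f"singular correlation matrix; offending items: {bad}"
            )
        evals, evecs = np.linalg.eigh(corr.to_numpy())
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        m = self.n_factors or select_factors_scree(evals)
        if m >= values.shape[0]:
            raise ValueError("more factors than informants")
        raw_load = evecs[:, :m] * np.sqrt(np.clip(evals[:m], 0, None))
        rotated = varimax(raw_load) if m > 1 else raw_load.copy()
        # order rotated factors by explained variance, align signs
        ssq = (rotated**2).sum(axis=0)
        rotated = rotated[:, np.argsort(ssq)[::-1]]
        for j in range(m):
            if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
                rotated[:, j] = -rotated[:, j]
        if self.scale_names is not None:
            names = list(self.scale_names)
        elif m == 2:
            names = ["IPSMR", "IEMR"]
        else:
            names = [f"factor{j+1}" for j in range(m)]
        loadings = pd.DataFrame(rotated, index=values.columns, columns=names)
        item_sets = assign_items(loadings, self.threshold)
        alphas, scores = {}, {}
        for name in names:
            items = item_sets[name]
            if len(items) >= 2:
                sub = values[items].dropna()
                alphas[name] = cronbach_alpha(sub.to_numpy())
            if items:
                scores[name] = score_scale(self.ratings, items)
        return FactorResults(
            loadings=loadings,
            eigenvalues=evals,
            n_factors=m,
            variance_explained=float(evals[:m].sum() / evals.sum()),
            item_sets=item_sets,
            alphas=alphas,
            scores=pd.DataFrame(scores),
            threshold=self.threshold,
            model=self,
        )
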