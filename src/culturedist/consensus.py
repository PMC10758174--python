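"""Cultural consensus foundations.

Given an informant-by-item table of ordinal influence ratings, this module
estimates how much of a shared "answer key" the informants hold in common:

* the informant-by-informant **agreement matrix** (Pearson correlation of
  rating profiles across items, treating the 1–4 codes as interval);
* a minimum-residual single-factor fit of that matrix, whose first-factor
  loadings are the per-informant **cultural competences** and whose
  eigenvalue ratio supports the conventional 3:1 consensus rule;
* the competence-weighted **answer key** (the group's most likely rating
  of each item);
* **respondent reliability** — Cronbach's alpha computed with informants
  as parallel measures of the key (the internal-consistency consensus
  model for rating data);
* **residual agreement** — structured agreement left after removing the
  consensus factor, evidence of subgroups emphasising different parts of
  the shared model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratings import RatingsMatrix
from .reliability import cronbach_alpha

__all__ = [
    "informant_agreement",
    "CulturalConsensusModel",
    "ConsensusResults",
    "ResidualAgreementResults",
    "respondent_reliability",
    "consensus_answer_key",
]

#: Conventional first-to-second eigenvalue ratio required to declare consensus.
EIG_RATIO_RULE = 3.0
#: How negative a competence may be before it counts as a model violation.
NEGATIVE_COMPETENCE_TOL = 0.1


def informant_agreement(
    ratings: RatingsMatrix | pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Informant-by-informant agreement matrix.

    Entry (i, j) is the Pearson correlation of informants i and j across
    items (pairwise-complete under missing ratings); ``method="match"``
    instead gives the chance-corrected proportion of exactly matching
    codes, (m - 1/L)/(1 - 1/L) with L = 4 response options — the classic
    consensus-theory coefficient for categorical answers, which does not
    treat the codes as interval.  The diagonal is 1.  An informant with
    zero rating variance has undefined correlations; the corresponding
    entries are NaN and a warning is issued.
    """
    values = ratings.values if isinstance(ratings, RatingsMatrix) else ratings
    if values.shape[0] < 3 or values.shape[1] < 3:
        raise ValueError("agreement needs at least 3 informants and 3 items")
    if method == "pearson":
        agree = values.T.corr(method="pearson")  # pairwise-complete
        flat = values.std(axis=1, ddof=0) == 0
        if flat.any():
            warnings.warn(
                "informants with zero rating variance have undefined "
                f"agreement: {list(values.index[flat])}",
                stacklevel=2,
            )
    elif method == "match":
        arr = values.to_numpy()
        n = arr.shape[0]
        agree = pd.DataFrame(np.eye(n), index=values.index, columns=values.index)
        n_options = 4
        for i in range(n):
            for j in range(i + 1, n):
                both = ~np.isnan(arr[i]) & ~np.isnan(arr[j])
                if both.any():
                    m = np.mean(arr[i, both] == arr[j, both])
                    p = (m - 1 / n_options) / (1 - 1 / n_options)
                else:
                    p = np.nan
                agree.iloc[i, j] = agree.iloc[j, i] = p
    else:
        raise ValueError(f"unknown agreement method {method!r}")
    np.fill_diagonal(agree.values, 1.0)
    return agree


def _minres_single_factor(
    agreement: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Minimum-residual single-factor fit of a symmetric agreement matrix.

    Iterates communalities on the diagonal (starting from each row's
    largest absolute off-diagonal entry), extracting the leading
    eigenvector at each step.  Returns the loading vector and the
    first-to-second eigenvalue ratio of the final communality-adjusted
    matrix.
    """
    a = np.array(agreement, dtype=float)
    n = a.shape[0]
    off = a - np.diag(np.diag(a))
    comm = np.abs(off).max(axis=1)
    loadings = None
    for _ in range(max_iter):
        np.fill_diagonal(a, comm)
        evals, evecs = np.linalg.eigh(a)
        lam1 = evals[-1]
        v = evecs[:, -1]
        new_loadings = np.sqrt(max(lam1, 0.0)) * v
        if new_loadings.sum() < 0:
            new_loadings = -new_loadings
        new_comm = np.minimum(new_loadings**2, 1.0)
        delta = np.abs(new_comm - comm).max()
        comm, loadings = new_comm, new_loadings
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"minres factoring did not converge within {max_iter} iterations "
            f"(tolerance {tol:g})"
        )
    np.fill_diagonal(a, comm)
    evals = np.linalg.eigvalsh(a)
    lam1, lam2 = evals[-1], evals[-2]
    eig_ratio = float(lam1 / lam2) if lam2 > 1e-12 else float("inf")
    return loadings, eig_ratio


def consensus_answer_key(
    ratings: RatingsMatrix, competences: pd.Series
) -> pd.DataFrame:
    """Competence-weighted consensus answer key.

    Negative competences are clipped to zero for weighting (consensus
    theory treats them as model violation, not information); items use
    whichever informants actually rated them.  Returns a frame with the
    unrounded weighted mean and the key rounded to the 1–4 scale.
    """
    w = competences.reindex(ratings.values.index).clip(lower=0).to_numpy()
    if not np.any(w > 0):
        raise ValueError("no informative informants: all competences are zero")
    vals = ratings.values.to_numpy()
    mask = ~np.isnan(vals)
    weighted = np.where(mask, vals, 0.0) * w[:, None]
    denom = (mask * w[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        unrounded = weighted.sum(axis=0) / denom
    key = np.clip(np.floor(unrounded + 0.5), 1, 4)
    return pd.DataFrame(
        {"unrounded": unrounded, "key": key}, index=ratings.values.columns
    )


def respondent_reliability(ratings: RatingsMatrix) -> float:
    """Reliability of the aggregate answer key under the internal-consistency
    consensus model: Cronbach's alpha over the *transposed* rating matrix
    (informants as parallel measures, items as cases)."""
    if ratings.n_informants < 3:
        raise ValueError("respondent reliability needs at least 3 informants")
    return cronbach_alpha(ratings.values.to_numpy().T)


@dataclass
class ResidualAgreementResults:
    """Agreement structure left after removing the consensus factor."""

    residual: pd.DataFrame
    subgroup_labels: pd.Series
    subgroup_strength: float
    degenerate: bool

    def n_subgroups(self) -> int:
        return int(self.subgroup_labels.nunique())


@dataclass
class ConsensusResults:
    """Fitted cultural-consensus solution for one sample of informants."""

    agreement: pd.DataFrame
    competences: pd.Series
    eig_ratio: float
    answer_key: pd.DataFrame
    respondent_reliability: float
    consensus: bool
    model: "CulturalConsensusModel" = field(repr=False)

    def residual_agreement(
        self, split_ratio: float = 2.0, degenerate_tol: float = 0.1
    ) -> ResidualAgreementResults:
        """Subgroup structure in the agreement left over after the consensus
        factor is removed.

        The consensus component (outer product of the competence loadings)
        is subtracted from the agreement matrix; informants are partitioned
        by the sign of their loading on the residual's leading eigenvector.
        A split is only declared when that leading eigenvalue dominates the
        second by ``split_ratio`` — noise residuals have a flat spectrum —
        and when the residual is not degenerate (all entries within
        ``degenerate_tol`` of zero).
        """
        lam = self.competences.to_numpy()
        resid = self.agreement.to_numpy() - np.outer(lam, lam)
        np.fill_diagonal(resid, 0.0)
        resid_df = pd.DataFrame(
            resid, index=self.agreement.index, columns=self.agreement.columns
        )
        idx = self.agreement.index
        evals, evecs = np.linalg.eigh(resid)
        lam1, lam2 = evals[-1], max(evals[-2], 1e-12)
        degenerate = bool(np.abs(resid).max() < degenerate_tol)
        if degenerate or lam1 / lam2 < split_ratio:
            labels = pd.Series(1, index=idx)
            strength = 0.0 if degenerate else float(
                lam1 / np.sum(np.clip(evals, 0, None))
            )
            return ResidualAgreementResults(resid_df, labels, strength, degenerate)
        v = evecs[:, -1]
        labels = pd.Series(np.where(v >= 0, 1, 2), index=idx)
        strength = float(lam1 / np.sum(np.clip(evals, 0, None)))
        return ResidualAgreementResults(resid_df, labels, strength, degenerate)

    def summary(self) -> str:
        lines = [
            "Cultural consensus analysis",
            "=" * 40,
            f"Informants:              {len(self.competences)}",
            f"Items:                   {self.answer_key.shape[0]}",
            f"Eigenvalue ratio:        {self.eig_ratio:.2f}",
            f"Consensus (>= {EIG_RATIO_RULE:.0f}:1):     {self.consensus}",
            f"Mean competence:         {self.competences.mean():.3f}",
            f"Min/max competence:      "
            f"{self.competences.min():.3f} / {self.competences.max():.3f}",
            f"Respondent reliability:  {self.respondent_reliability:.3f}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "eig_ratio": self.eig_ratio,
                "consensus": self.consensus,
                "respondent_reliability": self.respondent_reliability,
                "competences": {
                    str(k): float(v) for k, v in self.competences.items()
                },
                "answer_key": {
                    str(k): float(v) for k, v in self.answer_key["key"].items()
                },
            },
            indent=2,
        )

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"competence": self.competences})
        out.to_csv(path, sep="\t")


class CulturalConsensusModel:
    """Single-culture consensus model for ordinal rating data.

    Parameters
    ----------
    ratings
        The informant-by-item table (one group; pooling GPS and TG here
        would conflate two populations).
    agreement_method
        "pearson" (default; ratings treated as interval) or "match".
    eig_ratio_rule, negative_tol
        The consensus declaration rule: first/second eigenvalue ratio at
        least ``eig_ratio_rule`` and no competence below ``-negative_tol``.
    """

    def __init__(
        self,
        ratings: RatingsMatrix,
        agreement_method: str = "pearson",
        eig_ratio_rule: float = EIG_RATIO_RULE,
        negative_tol: float = NEGATIVE_COMPETENCE_TOL,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> None:
        self.ratings = ratings
        self.agreement_method = agreement_method
        self.eig_ratio_rule = eig_ratio_rule
        self.negative_tol = negative_tol
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> ConsensusResults:
        agreement = informant_agreement(self.ratings, self.agreement_method)
        a = agreement.to_numpy().copy()
        # pairwise-undefined entries cannot enter the factoring
        if np.isnan(a).any():
            a = np.where(np.isnan(a), 0.0, a)
        loadings, eig_ratio = _minres_single_factor(a, self.max_iter, self.tol)
        competences = pd.Series(loadings, index=agreement.index, name="competence")
        consensus = bool(
            eig_ratio >= self.eig_ratio_rule
            and competences.min() >= -self.negative_tol
        )
        key = consensus_answer_key(self.ratings, competences)
        reliability = respondent_reliability(self.ratings)
        return ConsensusResults(
            agreement=agreement,
            competences=competences,
            eig_ratio=eig_ratio,
            answer_key=key,
            respondent_reliability=reliability,
            consensus=consensus,
            model=self,
        )
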