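"""Q-mode cultural distance.

The pooled GPS + TG rating profiles are turned into a full symmetric
matrix of profile dissimilarities (1 − Pearson correlation between two
informants' profiles, so individual differences in rating *magnitude* are
ignored in favour of pattern), embedded with nonmetric multidimensional
scaling, and each treatment-group member's squared Euclidean distance
from the general-population centroid is the **cultural distance**:

    distance_i = sum over dims of (TG coord_i,d − GPS centroid_d)^2

Raw distances are right-skewed, so a natural-log transform is applied
and the sample is split into quartiles of distance (1 = most proximate,
4 = most distal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .ratings import RatingsMatrix

__all__ = [
    "profile_dissimilarity",
    "nonmetric_mds",
    "kruskal_stress",
    "gps_centroid",
    "cultural_distance",
    "log_and_quartile",
    "CulturalDistanceModel",
    "DistanceResults",
    "MDSResult",
]


def profile_dissimilarity(
    pooled: RatingsMatrix, metric: str = "correlation"
) -> pd.DataFrame:
    """Full symmetric matrix of profile dissimilarities.

    ``metric="correlation"`` (default) gives d(i,j) = 1 − Pearson r of the
    two rating profiles, range [0, 2]: elevation-free, shape-only.
    ``metric="sqeuclidean"`` keeps magnitude differences, offered for
    sensitivity analysis.  Zero-variance informants have no defined
    correlation profile and are dropped with a warning.
    """
    values = pooled.values
    if metric == "correlation":
        flat = values.std(axis=1, ddof=0) == 0
        if flat.any():
            warnings.warn(
                "dropping zero-variance informants from dissimilarity: "
                f"{list(values.index[flat])}",
                stacklevel=2,
            )
            values = values.loc[~flat]
        d = 1.0 - values.T.corr().to_numpy()
    elif metric == "sqeuclidean":
        d = squareform(pdist(values.to_numpy(), metric="sqeuclidean"))
    else:
        raise ValueError(f"unknown dissimilarity metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def kruskal_stress(dissimilarity: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities are the least-squares monotone (isotonic) regression of the
    configuration's inter-point distances on the dissimilarities; stress-1
    is sqrt(sum (d − dhat)^2 / sum d^2) over the upper triangle.
    """
    dvec = squareform(np.asarray(dissimilarity, dtype=float), checks=False)
    dist = pdist(coordinates)
    disparities = IsotonicRegression(increasing=True).fit_transform(dvec, dist)
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disparities) ** 2) / denom))


@dataclass
class MDSResult:
    """A nonmetric MDS configuration.

    The configuration is identified only up to rotation, reflection and
    translation; every downstream quantity in this package depends on
    inter-point distances only.
    """

    coordinates: pd.DataFrame
    stress: float
    n_dims: int
    seed: int
    n_starts: int


def nonmetric_mds(
    dissimilarity: pd.DataFrame,
    n_dims: int = 2,
    seed: int = 0,
    n_starts: int = 20,
) -> MDSResult:
    """Best-of-``n_starts`` nonmetric (Kruskal) multidimensional scaling.

    Minimises stress via SMACOF with monotone-regression disparities; the
    reported stress is Kruskal stress-1 recomputed from the final
    configuration.
    """
    n = dissimilarity.shape[0]
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if n_dims >= n:
        raise ValueError(f"n_dims={n_dims} must be smaller than the number "
                         f"of points ({n})")
    coords, _ = smacof(
        dissimilarity.to_numpy(),
        metric=False,
        n_components=n_dims,
        n_init=n_starts,
        max_iter=300,
        eps=1e-6,
        random_state=seed,
        normalized_stress=True,
    )
    stress = kruskal_stress(dissimilarity.to_numpy(), coords)
    frame = pd.DataFrame(
        coords,
        index=dissimilarity.index,
        columns=[f"dim{k+1}" for k in range(n_dims)],
    )
    return MDSResult(frame, stress, n_dims, seed, n_starts)


def gps_centroid(mds: MDSResult, groups: pd.Series) -> np.ndarray:
    """Arithmetic mean of the GPS members' coordinates (the cultural core)."""
    mask = groups.reindex(mds.coordinates.index) == "GPS"
    if not mask.any():
        raise ValueError("no GPS-labelled informants; centroid undefined")
    return mds.coordinates.loc[mask].mean(axis=0).to_numpy()


def cultural_distance(
    mds: MDSResult, centroid: np.ndarray, groups: pd.Series
) -> pd.Series:
    """Squared Euclidean distance of each TG member from the GPS centroid."""
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape[0] != mds.n_dims:
        raise ValueError("centroid dimension does not match the MDS solution")
    mask = groups.reindex(mds.coordinates.index) == "TG"
    diffs = mds.coordinates.loc[mask].to_numpy() - centroid
    return pd.Series(
        (diffs**2).sum(axis=1), index=mds.coordinates.index[mask],
        name="raw_distance",
    )


def log_and_quartile(raw: pd.Series, n_groups: int = 4) -> pd.DataFrame:
    """Natural-log distance and rank-based quartile (1 = most proximate).

    Zero distances are offset by half the smallest positive distance
    before the log.  Quartile sizes are as equal as possible, with extra
    members assigned to the lower (more proximate) quartiles first.
    """
    raw = raw.astype(float)
    if raw.nunique() <= 1:
        raise ValueError("degenerate quartiles: all distances identical")
    positive = raw[raw > 0]
    offset = positive.min() / 2.0 if (raw <= 0).any() else 0.0
    log_d = np.log(raw + offset)
    order = log_d.rank(method="first").astype(int) - 1  # stable split
    n = len(raw)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
    bounds = np.cumsum(sizes)
    quart = pd.Series(np.searchsorted(bounds, order.to_numpy(), side="right") + 1,
                      index=raw.index, name="quartile")
    return pd.DataFrame({"raw_distance": raw, "log_distance": log_d,
                         "quartile": quart})


@dataclass
class DistanceResults:
    """Cultural distance of every TG member from the GPS cultural core."""

    mds: MDSResult
    centroid: np.ndarray
    table: pd.DataFrame  # index: TG informants; raw/log distance, quartile
    model: "CulturalDistanceModel" = field(repr=False)

    @property
    def raw_distance(self) -> pd.Series:
        return self.table["raw_distance"]

    @property
    def log_distance(self) -> pd.Series:
        return self.table["log_distance"]

    @property
    def quartile(self) -> pd.Series:
        return self.table["quartile"]

    def summary(self) -> str:
        q = self.table.groupby("quartile")["log_distance"]
        lines = [
            "Cultural distance (Q-mode)",
            "=" * 40,
            f"MDS dimensions:   {self.mds.n_dims}",
            f"Kruskal stress-1: {self.mds.stress:.3f}",
            f"TG members:       {len(self.table)}",
            f"log distance:     {self.log_distance.mean():.2f} "
            f"(+/- {self.log_distance.std(ddof=1):.2f})",
            "",
            "quartile   n    mean log distance",
        ]
        for g, s in q:
            lines.append(f"{g:>8} {s.size:>4}   {s.mean():>8.2f}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


class CulturalDistanceModel:
    """End-to-end Q-mode model: pooled profiles -> MDS -> distance quartiles.

    Parameters
    ----------
    pooled
        GPS + TG ratings on the same item catalogue.
    metric
        Profile dissimilarity ("correlation" or "sqeuclidean").
    n_dims, n_starts, seed
        Nonmetric MDS controls (2 dimensions, 20 random starts by default).
    """

    def __init__(
        self,
        pooled: RatingsMatrix,
        metric: str = "correlation",
        n_dims: int = 2,
        n_starts: int = 20,
        seed: int = 0,
    ) -> None:
        self.pooled = pooled
        self.metric = metric
        self.n_dims = n_dims
        self.n_starts = n_starts
        self.seed = seed

    def fit(self) -> DistanceResults:
        d = profile_dissimilarity(self.pooled, self.metric)
        mds = nonmetric_mds(d, self.n_dims, self.seed, self.n_starts)
        groups = self.pooled.group
        centroid = gps_centroid(mds, groups)
        raw = cultural_distance(mds, centroid, groups)
        table = log_and_quartile(raw)
        return DistanceResults(mds=mds, centroid=centroid, table=table, model=self)
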