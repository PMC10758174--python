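"""Informant-by-item rating matrices.

The core data container of the package: a table of 1–4 influence ratings
(29 substance-use risk factors by default), one row per informant, with a
group label distinguishing the general population sample (``GPS``) from
the treatment group (``TG``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import RISK_FACTORS

__all__ = ["RatingsMatrix", "read_ratings", "RatingsValidationError"]

VALID_GROUPS = ("GPS", "TG")
RATING_MIN, RATING_MAX = 1, 4


class RatingsValidationError(ValueError):
    """A ratings table violated the schema (codes, IDs, or layout)."""


@dataclass
class RatingsMatrix:
    """Informant-by-item grid of ordinal influence ratings.

    Parameters
    ----------
    values
        DataFrame indexed by informant ID, one column per item; entries in
        {1, 2, 3, 4} or NaN for missing.
    group
        Series aligned to ``values.index`` with labels ``GPS`` or ``TG``.
    """

    values: pd.DataFrame
    group: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.group = self.group.reindex(self.values.index)
        self._validate()

    def _validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise RatingsValidationError(f"duplicate informant IDs: {dupes}")
        if self.group.isna().any():
            missing = idx[self.group.isna()].tolist()
            raise RatingsValidationError(f"missing group label for: {missing}")
        bad_groups = set(self.group.unique()) - set(VALID_GROUPS)
        if bad_groups:
            raise RatingsValidationError(
                f"unknown group labels {sorted(bad_groups)}; expected {VALID_GROUPS}"
            )
        arr = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(arr) & (
                (arr < RATING_MIN) | (arr > RATING_MAX) | (arr != np.round(arr))
            )
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise RatingsValidationError(
                f"rating out of range 1-4 at informant {idx[i]!r}, "
                f"item {self.values.columns[j]!r}: {arr[i, j]!r}"
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        group: str | list[str],
        informant_ids: list[str] | None = None,
        items: list[str] | None = None,
    ) -> "RatingsMatrix":
        """Build from a plain array plus a scalar or per-informant group."""
        values = np.asarray(values, dtype=float)
        n, k = values.shape
        if items is None:
            items = list(RISK_FACTORS[:k]) if k <= len(RISK_FACTORS) else [
                f"item{j+1}" for j in range(k)
            ]
        if informant_ids is None:
            informant_ids = [f"R{i+1:03d}" for i in range(n)]
        frame = pd.DataFrame(values, index=pd.Index(informant_ids, name="informant"),
                             columns=items)
        if isinstance(group, str):
            grp = pd.Series(group, index=frame.index)
        else:
            grp = pd.Series(list(group), index=frame.index)
        return cls(frame, grp)

    # -- views -------------------------------------------------------------

    @property
    def informant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_informants(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset(self, which: str) -> "RatingsMatrix":
        """Restrict to one group (``GPS`` or ``TG``)."""
        mask = self.group == which
        return RatingsMatrix(self.values.loc[mask], self.group.loc[mask])

    def pool(self, other: "RatingsMatrix") -> "RatingsMatrix":
        """Stack two matrices sharing the same item catalogue."""
        if list(other.values.columns) != list(self.values.columns):
            raise RatingsValidationError("item catalogues differ; cannot pool")
        return RatingsMatrix(
            pd.concat([self.values, other.values]),
            pd.concat([self.group, other.group]),
        )

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path, sep: str = ",") -> None:
        out = self.values.copy()
        out.insert(0, "group", self.group)
        out.to_csv(path, sep=sep)

    def __eq__(self, other: object) -> bool:  # exact content equality
        if not isinstance(other, RatingsMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.group.equals(other.group)


def read_ratings(path, sep: str | None = None) -> RatingsMatrix:
    """Read a ratings table from CSV/TSV.

    Layout: first column informant ID, second column group (GPS/TG),
    remaining columns one per item with the header row carrying item
    labels.  Blank cells become missing ratings; any other malformed code
    raises :class:`RatingsValidationError` naming the offending cell.
    """
    if sep is None:
        name = getattr(path, "name", str(path))
        sep = "\t" if str(name).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype={1: str})
    if frame.columns[0].lower() != "group":
        raise RatingsValidationError(
            f"second column must be 'group', found {frame.columns[0]!r}"
        )
    group = frame.iloc[:, 0].astype(str)
    values = frame.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    # any non-blank cell that failed numeric conversion is a malformed code
    raw = frame.iloc[:, 1:]
    stripped = raw.astype(str).apply(lambda col: col.str.strip())
    bad = values.isna() & raw.notna() & (stripped != "")
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise RatingsValidationError(
            f"malformed rating at informant {frame.index[i]!r}, "
            f"item {values.columns[j]!r}: {raw.iloc[i, j]!r}"
        )
    return RatingsMatrix(values, group)


def write_ratings(matrix: RatingsMatrix, path, sep: str = ",") -> None:
    matrix.to_csv(path, sep=sep)


def round_trip_equal(matrix: RatingsMatrix) -> bool:
    """True if a write-then-read cycle reproduces the matrix exactly."""
    buf = io.StringIO()
    matrix.to_csv(buf)
    buf.seek(0)
    return read_ratings(buf, sep=",") == matrix
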