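"""Stigma instrument scoring.

Two instruments are scored:

* **Perceived stigma** — a 14-item scale mixing 6 dichotomous items
  (coded 0/1) with 8 items on a 4-point rating scale (1–4); the total is
  the plain sum, range 8–38 under this coding.  The coding itself is a
  package default chosen so the published sample mean (19.1) is interior
  to the feasible range; it is configurable.
* **Self-stigma** — an adaptation of the Internalized Stigma of Mental
  Illness (ISMI) scale with "alcohol or drug use" substituted for
  "mental illness"; k four-point items (default 29, the original ISMI
  length), plain sum with reverse-coded items honoured via a config list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StigmaResponses",
    "score_perceived_stigma",
    "score_self_stigma",
    "PERCEIVED_N_BINARY",
    "PERCEIVED_N_RATED",
    "SELF_STIGMA_N_ITEMS",
]

PERCEIVED_N_BINARY = 6
PERCEIVED_N_RATED = 8
SELF_STIGMA_N_ITEMS = 29


def _check_range(frame: pd.DataFrame, lo: int, hi: int, label: str) -> None:
    arr = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(arr) & ((arr < lo) | (arr > hi) | (arr != np.round(arr)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{label} item {frame.columns[j]!r} out of range [{lo}, {hi}] for "
            f"respondent {frame.index[i]!r}: {arr[i, j]!r}"
        )


@dataclass
class StigmaResponses:
    """Item-level responses to the two stigma instruments.

    Parameters
    ----------
    perceived_binary
        Respondent-by-item frame of the 6 dichotomous perceived-stigma
        items, coded 0/1.
    perceived_rated
        The 8 four-point perceived-stigma items, coded 1–4.
    self_stigma
        The adapted ISMI items, coded 1–4 (item count configurable).
    reverse_coded
        Self-stigma item labels scored reversed (x -> 5 - x).
    """

    perceived_binary: pd.DataFrame
    perceived_rated: pd.DataFrame
    self_stigma: pd.DataFrame
    reverse_coded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.perceived_binary.shape[1] != PERCEIVED_N_BINARY:
            raise ValueError(
                f"expected {PERCEIVED_N_BINARY} dichotomous perceived-stigma items"
            )
        if self.perceived_rated.shape[1] != PERCEIVED_N_RATED:
            raise ValueError(
                f"expected {PERCEIVED_N_RATED} rated perceived-stigma items"
            )
        _check_range(self.perceived_binary, 0, 1, "perceived (dichotomous)")
        _check_range(self.perceived_rated, 1, 4, "perceived (rated)")
        _check_range(self.self_stigma, 1, 4, "self-stigma")
        unknown = set(self.reverse_coded) - set(self.self_stigma.columns)
        if unknown:
            raise ValueError(f"reverse-coded items not found: {sorted(unknown)}")


def score_perceived_stigma(responses: StigmaResponses) -> pd.Series:
    """Total perceived stigma: sum of 0/1 binaries plus 1–4 rated items.

    Range [8, 38] under the default coding.  A respondent missing any of
    the 14 items gets a missing total.
    """
    both = pd.concat([responses.perceived_binary, responses.perceived_rated],
                     axis=1)
    total = both.sum(axis=1)
    total[both.isna().any(axis=1)] = np.nan
    return total.rename("perceived_stigma")


def score_self_stigma(responses: StigmaResponses) -> pd.Series:
    """Total self-stigma: plain sum of the 1–4 codes after reversing the
    configured reverse-coded items (x -> 5 - x)."""
    items = responses.self_stigma.copy()
    for col in responses.reverse_coded:
        items[col] = 5 - items[col]
    total = items.sum(axis=1)
    total[items.isna().any(axis=1)] = np.nan
    return total.rename("self_stigma")
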