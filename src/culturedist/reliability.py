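"""Internal-consistency (Cronbach's alpha) reliability.

Alpha is used twice in this package with two different orientations:

* conventionally, on a cases-by-items score table, to report the
  reliability of a summed scale (the R-mode internalisation scales and
  the stigma instruments); and
* transposed, with *informants* playing the role of scale items and the
  rated domain items playing the role of cases — the internal-consistency
  model of cultural consensus, where alpha is the *respondent
  reliability* of the group's aggregate answer key.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cronbach_alpha"]


def cronbach_alpha(data: np.ndarray) -> float:
    """Cronbach's alpha of a cases-by-items table.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the sum),
    with k the number of items (columns).  Variances are computed with
    denominator n-1 across cases (rows).

    Raises
    ------
    ValueError
        If fewer than 2 items, fewer than 2 cases, or the summed score has
        zero variance (alpha undefined).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("alpha requires a 2-D table with at least 2 items")
    if x.shape[0] < 2:
        raise ValueError("alpha requires at least 2 cases")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))
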