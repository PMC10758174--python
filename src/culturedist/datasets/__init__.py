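"""Packaged reference tables from the published urban-Brazil study of
cultural models of substance-use risk.

These are the study's *printed* summary tables, not raw data (the raw
informant ratings were never deposited).  They serve two purposes:

* the varimax loading table drives the worked item-assignment example
  (17-item psychosocial set, 5-item experiential set);
* the quartile means/s.d. table feeds the summary-statistics ANOVA
  oracle that reconstructs the printed F-ratios and eta coefficients.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_risk_factor_loadings",
    "load_quartile_summaries",
    "load_sample_descriptives",
    "RISK_FACTORS",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__name__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_risk_factor_loadings() -> pd.DataFrame:
    """Two-factor varimax loadings of the 29 risk factors (treatment group).

    Returns a frame indexed by item label with columns ``factor1``
    (psychosocial model of risk) and ``factor2`` (experiential model).
    """
    return _read("risk_factor_loadings.csv").set_index("item")


def load_quartile_summaries() -> pd.DataFrame:
    """Published quartile-of-cultural-distance means and s.d.s per scale.

    Columns: ``scale`` (IPSMR, IEMR, self_stigma, perceived_stigma),
    ``quartile`` (1 = most proximate .. 4 = most distal), ``mean``, ``sd``.

    .. note::
       The printed self-stigma quartile-2 s.d. (2.5) is inconsistent with
       the printed F-ratios for that scale and is carried here verbatim;
       reconstructions of the self-stigma row should be read with caution.
    """
    return _read("quartile_summaries.csv")


def load_sample_descriptives() -> pd.DataFrame:
    """Published whole-sample descriptive statistics (n = 133)."""
    return _read("sample_descriptives.csv").set_index("variable")


#: The 29-item risk-factor catalogue, in the loading table's order.
RISK_FACTORS: tuple[str, ...] = tuple(load_risk_factor_loadings().index)
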