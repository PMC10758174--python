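"""End-to-end pipeline driver.

Sequences the five analysis stages — consensus foundations, Q-mode
cultural distance, R-mode internalization scales, stigma scoring, and
the distance-outcome associations — over a pair of rating matrices plus
outcome scores, and writes the table-shaped outputs and a JSON run
manifest (seed, parameters, config hash) so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    influential_item_count,
    posthoc_distal,
    quartile_trend_anova,
    variance_heterogeneity,
)
from .consensus import CulturalConsensusModel
from .distance import CulturalDistanceModel
from .factors import InternalizationModel
from .ratings import RatingsMatrix, read_ratings
from .simulate import StudyData, SyntheticConfig, generate_study

logger = logging.getLogger("culturedist")

__all__ = ["PipelineConfig", "PipelineResults", "run_pipeline"]

STAGES = ("consensus", "distance", "factors", "stigma", "association")


@dataclass
class PipelineConfig:
    """Everything a full run needs; all randomness flows from ``seed``."""

    ratings_path: str | None = None  # CSV with GPS+TG rows; None -> synthetic
    outcomes_path: str | None = None  # CSV of outcome totals keyed by ID
    dissimilarity: str = "correlation"
    n_dims: int = 2
    n_starts: int = 20
    loading_threshold: float = 0.40
    n_factors: int | None = 2
    posthoc: str = "tukey"
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResults:
    """Bundle of fitted stage results plus the run manifest."""

    consensus: object
    distance: object
    factors: object
    outcomes: pd.DataFrame
    anovas: dict[str, object]
    posthoc: dict[str, pd.DataFrame]
    levene: dict[str, tuple]
    influential: tuple[pd.Series, pd.Series]
    manifest: dict
    study: StudyData | None = field(default=None, repr=False)

    def summary(self) -> str:
        parts = [self.consensus.summary(), "", self.distance.summary(), "",
                 self.factors.summary(), ""]
        for name, res in self.anovas.items():
            parts += [res.summary(), ""]
        return "\n".join(parts)


def _load_inputs(config: PipelineConfig) -> tuple[RatingsMatrix, pd.DataFrame,
                                                  StudyData | None]:
    if config.ratings_path is None:
        study = generate_study(SyntheticConfig(seed=config.seed))
        return study.pooled, study.outcomes, study
    pooled = read_ratings(config.ratings_path)
    if config.outcomes_path is None:
        raise ValueError("outcomes_path is required with observed ratings")
    outcomes = pd.read_csv(config.outcomes_path, index_col=0)
    return pooled, outcomes, None


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run consensus -> distance -> factors -> stigma -> association.

    Any stage failure is re-raised with the stage name attached.  With
    ``out_dir`` set, writes per-stage TSV tables and ``manifest.json``.
    """
    pooled, outcomes, study = _load_inputs(config)
    completed: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            completed.append(name)
            logger.info("stage %s complete", name)
            return out
        return deco

    gps = pooled.subset("GPS")
    tg = pooled.subset("TG")

    consensus = stage("consensus")(
        lambda: CulturalConsensusModel(gps).fit()
    )
    distance = stage("distance")(
        lambda: CulturalDistanceModel(
            pooled, metric=config.dissimilarity, n_dims=config.n_dims,
            n_starts=config.n_starts, seed=config.seed,
        ).fit()
    )
    factors = stage("factors")(
        lambda: InternalizationModel(
            tg, n_factors=config.n_factors, threshold=config.loading_threshold
        ).fit()
    )
    outcome_table = stage("stigma")(
        lambda: pd.concat([factors.scores, outcomes], axis=1)
        .reindex(distance.table.index)
    )

    def associations():
        quart = distance.quartile
        anovas, post, lev = {}, {}, {}
        for col in outcome_table.columns:
            y = outcome_table[col]
            anovas[col] = quartile_trend_anova(y, quart, outcome=col)
            post[col] = posthoc_distal(y, quart, method=config.posthoc)
            lev[col] = variance_heterogeneity(y, quart)
        counts = influential_item_count(tg, quart)
        return anovas, post, lev, counts

    anovas, post, lev, counts = stage("association")(associations)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages_completed": completed,
        "n_gps": gps.n_informants,
        "n_tg": tg.n_informants,
        "mds_stress": distance.mds.stress,
    }
    results = PipelineResults(
        consensus=consensus, distance=distance, factors=factors,
        outcomes=outcome_table, anovas=anovas, posthoc=post, levene=lev,
        influential=counts, manifest=manifest, study=study,
    )
    if config.out_dir is not None:
        _write_outputs(results, config)
    return results


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def _write_outputs(results: PipelineResults, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={config.seed} config_hash={config.config_hash()}\n"

    def write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", float_format="%.10g")

    write(pd.DataFrame({"competence": results.consensus.competences}),
          "competences.tsv")
    write(results.distance.table, "distance.tsv")
    write(results.distance.mds.coordinates, "coordinates.tsv")
    write(results.factors.loadings.round(3), "loadings.tsv")
    write(results.outcomes, "scores.tsv")
    rows = []
    for name, res in results.anovas.items():
        for q, g in res.groups.iterrows():
            rows.append({"outcome": name, "quartile": q, "mean": g["mean"],
                         "sd": g["sd"], "n": g["n"]})
        rows.append({"outcome": name, "quartile": "F_overall",
                     "mean": res.f_overall, "sd": res.p_overall,
                     "n": res.eta})
    write(pd.DataFrame(rows).set_index("outcome"), "quartile_anova.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(results.manifest, fh, indent=2, default=str)
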