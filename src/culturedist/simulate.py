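"""Synthetic study generator.

Emulates the statistical structure the analysis assumes, so every stage
of the pipeline is testable without the (non-deposited) raw data:

* a **GPS cohort** whose members answer each item with a shared,
  skewed-high answer key with probability equal to their own cultural
  competence, and otherwise draw from a skewed categorical — the
  consensus-theory generative process;
* a **TG cohort** in four distance classes.  Each member holds a personal
  key that equals the GPS key on an "influential inventory" of items and
  is down-rated (1–2) elsewhere; the inventory shrinks and the adherence
  drops with class distance, so distal members make more distinctions and
  rate fewer items as influential;
* **stigma outcomes** with an inverted-U (cubic-capable) relation of
  self-stigma to distance class and a flat (null) perceived-stigma
  profile, drawn truncated-normal around per-class targets.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config; identical config + seed reproduces every matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratings import RatingsMatrix

__all__ = [
    "TGClass",
    "OutcomeModel",
    "SyntheticConfig",
    "generate_answer_key",
    "generate_gps",
    "generate_tg",
    "generate_outcomes",
    "generate_subgroups",
    "generate_study",
    "StudyData",
]


@dataclass
class TGClass:
    """One TG distance class: cohort size, key adherence, inventory size."""

    size: int
    adherence: float
    inventory: int

    def __post_init__(self) -> None:
        if not 0 <= self.adherence <= 1:
            raise ValueError("adherence must be in [0, 1]")


@dataclass
class OutcomeModel:
    """Per-class stigma outcome targets (means, s.d.s, scale bounds)."""

    self_stigma_means: tuple[float, ...] = (39.1, 43.9, 43.2, 37.6)
    self_stigma_sds: tuple[float, ...] = (9.7, 10.0, 10.1, 10.9)
    #: hard scale bounds for the generated totals, or None for unbounded.
    #: The published distal-class moments (37.6 +/- 10.9) are unrealisable
    #: under ANY normal truncated at the 29-item sum floor of 29 — the
    #: s.d. exceeds the distance to the floor — so no floor is imposed by
    #: default; set e.g. (29, 116) to activate moment-matched truncation.
    self_stigma_range: tuple[float, float] | None = None
    perceived_mean: float = 19.1
    perceived_sd: float = 4.1
    perceived_range: tuple[float, float] | None = (8, 38)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the published study: 48 GPS raters with competences
    uniform on (0.5, 0.9) sharing a skewed-high key (22 of 29 items keyed
    influential), and 133 TG members in four classes of graded deviation
    whose influential-item inventories target roughly 22/23/21/14 items.
    """

    n_gps: int = 48
    n_tg: int = 133
    n_items: int = 29
    n_influential: int = 22  # items keyed 3-4 in the shared answer key
    competence_range: tuple[float, float] = (0.5, 0.9)
    #: rating probabilities for codes 1..4 when an informant misses the key
    noise_probs: tuple[float, ...] = (0.05, 0.15, 0.45, 0.35)
    #: "stratified": each informant matches the key on exactly a fraction
    #: `competence` of items (randomly placed; competence is the realised
    #: share of key agreement).  "bernoulli": independent per-item matching
    #: with probability `competence` (adds binomial noise to the realised
    #: share, which blurs parameter recovery at 29 items).
    adherence_mode: str = "stratified"
    answer_key: np.ndarray | None = None
    tg_classes: tuple[TGClass, ...] = (
        TGClass(34, 0.99, 22),
        TGClass(33, 0.87, 23),
        TGClass(33, 0.80, 20),
        TGClass(33, 0.92, 14),
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(c.size for c in self.tg_classes) != self.n_tg:
            raise ValueError("TG class sizes must sum to n_tg")
        if not np.isclose(sum(self.noise_probs), 1.0):
            raise ValueError("noise_probs must sum to 1")

    @classmethod
    def reliability_calibration(cls, seed: int = 0) -> "SyntheticConfig":
        """GPS conditions calibrated to the published respondent reliability.

        The study's general-population rating data showed *substantial but
        weak* pairwise agreement: formal consensus analysis found no
        consensus, while the internal-consistency model gave respondent
        reliability 0.871 — which at 48 informants implies a mean
        inter-informant correlation near 0.12, i.e. mean competences
        around 0.35.  This preset lowers the competence range accordingly;
        the default (0.5, 0.9) range describes a strongly consensual
        cohort instead and yields reliabilities near 1.
        """
        return cls(competence_range=(0.25, 0.45), seed=seed)

    def key(self) -> np.ndarray:
        if self.answer_key is not None:
            key = np.asarray(self.answer_key, dtype=float)
            if key.shape != (self.n_items,):
                raise ValueError("answer_key length must equal n_items")
            return key
        return generate_answer_key(self.n_items, self.n_influential)


def generate_answer_key(n_items: int = 29, n_influential: int = 22) -> np.ndarray:
    """Deterministic skewed-high answer key.

    The first ``n_influential`` items alternate 4, 3 (keyed influential);
    the remainder alternate 2, 1 — most risk factors are held to have at
    least some influence, a few none.
    """
    key = np.empty(n_items)
    key[:n_influential] = [4 if i % 2 == 0 else 3 for i in range(n_influential)]
    rest = n_items - n_influential
    key[n_influential:] = [2 if i % 2 == 0 else 1 for i in range(rest)]
    return key


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _answer_rows(
    keys: np.ndarray, adherence: np.ndarray, noise_probs: np.ndarray,
    rng: np.random.Generator, mode: str = "stratified",
) -> np.ndarray:
    """Each informant reports the key on a share `adherence` of items,
    drawing the rest from the skewed noise distribution.

    "stratified" fixes the matched-item count at adherence * n_items
    (randomised rounding, random placement) so the realised key agreement
    equals the competence parameter; "bernoulli" matches each item
    independently.
    """
    n, k = keys.shape
    if mode == "bernoulli":
        hit = rng.random((n, k)) < adherence[:, None]
    elif mode == "stratified":
        target = adherence * k
        count = np.floor(target).astype(int)
        count += rng.random(n) < (target - count)  # unbiased rounding
        hit = np.zeros((n, k), dtype=bool)
        for i in range(n):
            hit[i, rng.choice(k, size=count[i], replace=False)] = True
    else:
        raise ValueError(f"unknown adherence mode {mode!r}")
    noise = rng.choice([1, 2, 3, 4], size=(n, k), p=noise_probs)
    return np.where(hit, keys, noise)


def generate_gps(config: SyntheticConfig) -> RatingsMatrix:
    """GPS cohort: shared key, per-informant competence, skewed noise."""
    rng = _rng(config, 1)
    lo, hi = config.competence_range
    competences = rng.uniform(lo, hi, config.n_gps)
    keys = np.tile(config.key(), (config.n_gps, 1))
    values = _answer_rows(keys, competences, np.asarray(config.noise_probs),
                          rng, config.adherence_mode)
    m = RatingsMatrix.from_arrays(
        values, "GPS",
        informant_ids=[f"GPS{i+1:03d}" for i in range(config.n_gps)],
    )
    m.true_competence = pd.Series(competences, index=m.values.index)
    return m


def generate_tg(config: SyntheticConfig) -> tuple[RatingsMatrix, pd.Series]:
    """TG cohort with graded deviation; returns (ratings, true class labels).

    Per class, each informant's personal key keeps the GPS key on an
    inventory of items and down-rates (1–2) the rest.  The inventory is
    drawn per informant: influential key items first (all of them if the
    inventory is large enough, a random subset otherwise), topped up with
    random non-influential items when the inventory exceeds the key's own
    influential set — so a full-inventory class reproduces the GPS key
    exactly and distal classes make more distinctions.
    """
    rng = _rng(config, 2)
    key = config.key()
    influential = np.flatnonzero(key >= 3)
    other = np.flatnonzero(key < 3)
    rows, labels, ids = [], [], []
    i = 0
    for cls_num, cls in enumerate(config.tg_classes, start=1):
        for _ in range(cls.size):
            inv = min(cls.inventory, config.n_items)
            if inv >= len(influential):
                chosen = set(influential) | set(
                    rng.choice(other, size=inv - len(influential), replace=False)
                )
            else:
                chosen = set(rng.choice(influential, size=inv, replace=False))
            personal = np.where(
                [j in chosen for j in range(config.n_items)],
                np.maximum(key, 3),  # influential per the shared key (3-4)
                np.minimum(key, 2),  # down-rated elsewhere (1-2)
            )
            rows.append(personal)
            labels.append(cls_num)
            ids.append(f"TG{i+1:03d}")
            i += 1
    keys = np.asarray(rows, dtype=float)
    adherence = np.repeat(
        [c.adherence for c in config.tg_classes],
        [c.size for c in config.tg_classes],
    )
    values = _answer_rows(keys, adherence, np.asarray(config.noise_probs),
                          rng, config.adherence_mode)
    m = RatingsMatrix.from_arrays(values, "TG", informant_ids=ids)
    true_class = pd.Series(labels, index=m.values.index, name="true_class")
    return m, true_class


def generate_outcomes(
    true_class: pd.Series, config: SyntheticConfig
) -> pd.DataFrame:
    """Stigma outcome totals per TG member, seeded and truncated to range.

    Self-stigma follows per-class targets (inverted-U by default);
    perceived stigma is flat across classes.  Out-of-range draws are
    redrawn (not clipped) to avoid point masses at the scale bounds.
    """
    rng = _rng(config, 3)
    om = config.outcome_model
    cls = true_class.to_numpy()
    means = np.array([om.self_stigma_means[c - 1] for c in cls])
    sds = np.array([om.self_stigma_sds[c - 1] for c in cls])
    self_st = _truncated_normal(means, sds, om.self_stigma_range, rng)
    perceived = _truncated_normal(
        np.full(len(cls), om.perceived_mean),
        np.full(len(cls), om.perceived_sd),
        om.perceived_range,
        rng,
    )
    return pd.DataFrame(
        {"self_stigma": self_st, "perceived_stigma": perceived},
        index=true_class.index,
    )


def _match_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncated normal has the
    target mean and s.d.

    Naive truncation would bias the realised moments (the self-stigma
    floor sits less than one s.d. below the published class means, so a
    plain redraw shifts means upward by several points and flattens the
    planted inverted-U); moment matching keeps the class targets exact.
    """
    from scipy import optimize, stats

    def residual(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(
        residual, [mean - sd / 2, np.log(sd * 1.2)],
        bounds=([lo - 10 * sd, np.log(sd / 10)],
                [hi + 10 * sd, np.log(sd * 10)]),
        xtol=1e-12, ftol=1e-12,
    )
    resid = np.abs(sol.fun).max()
    if resid > 0.05:
        raise ValueError(
            f"cannot match mean={mean}, sd={sd} on [{lo}, {hi}] "
            f"(residual {resid:.3g})"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncated_normal(
    means: np.ndarray, sds: np.ndarray, bounds: tuple[float, float] | None,
    rng: np.random.Generator, max_rounds: int = 100,
) -> np.ndarray:
    if np.all(sds == 0):
        return means.astype(float).copy()
    if bounds is None:
        return rng.normal(means, sds)
    lo, hi = bounds
    # moment-matched underlying parameters per distinct (mean, sd) target
    mu = np.empty_like(means, dtype=float)
    sigma = np.empty_like(sds, dtype=float)
    for m, s in set(zip(means.tolist(), sds.tolist())):
        mask = (means == m) & (sds == s)
        mu[mask], sigma[mask] = _match_truncnorm_params(m, s, lo, hi)
    out = rng.normal(mu, sigma)
    for _ in range(max_rounds):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mu[bad], sigma[bad])
    return np.clip(out, lo, hi)


def generate_subgroups(
    config: SyntheticConfig,
    n_per_group: int = 20,
    emphasis_size: int = 6,
    adherence: float = 0.85,
) -> tuple[RatingsMatrix, pd.Series]:
    """Two planted subgroups sharing the key but with opposed emphases.

    Both groups follow the shared answer key, but group 1 up-rates one
    block of items (and down-rates a second block) while group 2 does the
    opposite — consensus plus structured residual agreement, for testing
    residual-subgroup recovery.
    """
    rng = _rng(config, 4)
    key = config.key()
    block_a = np.arange(emphasis_size)
    block_b = np.arange(emphasis_size, 2 * emphasis_size)
    rows, labels = [], []
    for grp, (up, down) in enumerate([(block_a, block_b), (block_b, block_a)],
                                     start=1):
        personal = key.copy()
        personal[up] = np.minimum(personal[up] + 1, 4)
        personal[down] = np.maximum(personal[down] - 1, 1)
        keys = np.tile(personal, (n_per_group, 1))
        adh = np.full(n_per_group, adherence)
        rows.append(_answer_rows(keys, adh, np.asarray(config.noise_probs),
                                 rng, config.adherence_mode))
        labels += [grp] * n_per_group
    values = np.vstack(rows)
    m = RatingsMatrix.from_arrays(values, "GPS")
    return m, pd.Series(labels, index=m.values.index, name="subgroup")


def generate_two_factor_ratings(
    n_informants: int = 200,
    item_groups: tuple[int, int, int] = (17, 5, 7),
    within_corr: float = 0.3,
    seed: int = 0,
) -> tuple[RatingsMatrix, dict[str, list[str]]]:
    """Ratings driven by two orthogonal latent factors, for factor-recovery
    tests.

    ``item_groups`` gives the number of items loading on factor 1, on
    factor 2, and pure-noise items.  Items within a factor share latent
    correlation ``within_corr``; continuous scores are discretised to the
    1–4 scale at skewed cut points.  Returns the matrix and the planted
    item assignment.
    """
    rng = np.random.default_rng([seed, 5])
    k1, k2, k0 = item_groups
    n_items = k1 + k2 + k0
    lam = np.sqrt(within_corr)
    z = rng.standard_normal((n_informants, 2))
    eps = rng.standard_normal((n_informants, n_items))
    latent = np.empty((n_informants, n_items))
    latent[:, :k1] = lam * z[:, [0]] + np.sqrt(1 - lam**2) * eps[:, :k1]
    latent[:, k1:k1 + k2] = (lam * z[:, [1]]
                             + np.sqrt(1 - lam**2) * eps[:, k1:k1 + k2])
    latent[:, k1 + k2:] = eps[:, k1 + k2:]
    # skewed-high discretisation: most mass on codes 3-4, as in the study
    cuts = np.quantile(rng.standard_normal(100_000), [0.10, 0.30, 0.60])
    values = np.digitize(latent, cuts) + 1
    m = RatingsMatrix.from_arrays(values.astype(float), "TG")
    items = m.items
    planted = {"factor1": items[:k1], "factor2": items[k1:k1 + k2],
               "noise": items[k1 + k2:]}
    return m, planted


@dataclass
class StudyData:
    """One synthetic study: cohorts, truth, and outcomes."""

    gps: RatingsMatrix
    tg: RatingsMatrix
    true_class: pd.Series
    outcomes: pd.DataFrame
    config: SyntheticConfig

    @property
    def pooled(self) -> RatingsMatrix:
        return self.gps.pool(self.tg)


def generate_study(config: SyntheticConfig | None = None, seed: int | None = None
                   ) -> StudyData:
    """Generate a full synthetic study under the default (or given) conditions."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    gps = generate_gps(config)
    tg, true_class = generate_tg(config)
    outcomes = generate_outcomes(true_class, config)
    return StudyData(gps=gps, tg=tg, true_class=true_class, outcomes=outcomes,
                     config=config)
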