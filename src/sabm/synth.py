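"""Synthetic two-wave school panels with known ground-truth parameters.

Real adolescent friendship surveys of this design are access-restricted, so
every other module is exercised on generated panels that emulate their
structure: directed nominations, sparse networks with reciprocity and
transitivity excess, attribute homophily, and integer-coded behaviors with
school-like marginals.  Wave 1 is drawn from an independent-dyad homophily
model with a reciprocity boost (a deliberate simplification of a full
exponential-family graph model: simple, seed-stable, and sufficient to give
the SABM homophily structure to explain).  Wave 2 is the endpoint of a
recorded ministep simulation from wave 1 under the ground-truth parameters,
so generated panels come with the true data-generating process attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import build_context
from .datatypes import (
    ActorTable,
    BehaviorPanel,
    ConfigError,
    EffectParameterSet,
    GenerationError,
    NetworkPanel,
)
from .simulate import SimulationTrace, simulate_period


@dataclass
class BehaviorConfig:
    """Wave-1 distribution of one integer-coded behavior.

    ``distribution`` is one of ``rounded_normal`` (params: mean, sd),
    ``truncated_geometric`` (params: p) or ``categorical`` (params:
    probability per level) — matching BMI-like, screen-time-like and
    sports-score-like marginals respectively.
    """

    name: str
    z_min: int
    z_max: int
    distribution: str = "rounded_normal"
    params: tuple = (22.6, 4.4)


@dataclass
class SchoolConfig:
    """Everything needed to generate one synthetic two-wave school panel."""

    n_actors: int
    # attribute marginals
    male_prop: float = 0.5
    grades: tuple[int, ...] = (9, 10, 11)
    grade_probs: tuple[float, ...] | None = None
    black_prop: float = 0.0
    hispanic_prop: float = 0.0
    age_mean: float = 16.0
    age_sd: float = 1.0
    income_mean: float = 40.0
    income_sd: float = 20.0
    income_missing_rate: float = 0.2
    # behavior
    behavior: BehaviorConfig = field(
        default_factory=lambda: BehaviorConfig("bmi", 14, 44)
    )
    # wave-1 tie model
    target_mean_outdegree: float = 3.0
    baseline_logit: float | None = None  # overrides calibration when given
    reciprocity_boost: float = 2.0
    homophily_weights: dict = field(default_factory=dict)  # same_sex, same_grade,
    # same_black, same_hispanic, age_sim, income_sim (log-odds contributions)
    # wave-1 -> wave-2 evolution
    ground_truth: EffectParameterSet = field(default_factory=EffectParameterSet)
    nomination_cap: bool = False
    # realism bands on wave-2 change counts (None bound = unchecked)
    net_change_band: tuple[int | None, int | None] = (None, None)
    beh_change_band: tuple[int | None, int | None] = (None, None)
    max_retries: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("male_prop", "black_prop", "hispanic_prop", "income_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.n_actors < 10:
            raise ConfigError("n_actors must be >= 10")
        if self.behavior.z_min >= self.behavior.z_max:
            raise ConfigError("behavior bounds must satisfy z_min < z_max")


@dataclass
class SyntheticPanel:
    """A generated panel plus its ground truth and provenance."""

    actors: ActorTable
    network: NetworkPanel
    behavior: BehaviorPanel
    ground_truth: EffectParameterSet
    seed: int | None
    trace: SimulationTrace
    config: SchoolConfig


def generate_actors(config: SchoolConfig, rng: np.random.Generator) -> ActorTable:
    """Draw the fixed covariates; missing incomes are mean-imputed and flagged."""
    n = config.n_actors
    sex = (rng.random(n) < config.male_prop).astype(int)
    probs = config.grade_probs
    if probs is None:
        probs = tuple(1.0 / len(config.grades) for _ in config.grades)
    grade = rng.choice(config.grades, size=n, p=probs)
    black = (rng.random(n) < config.black_prop).astype(int)
    hispanic = (rng.random(n) < config.hispanic_prop).astype(int)
    age = np.round(rng.normal(config.age_mean, config.age_sd, size=n), 1)
    income = np.maximum(0.0, rng.normal(config.income_mean, config.income_sd, size=n))
    missing = rng.random(n) < config.income_missing_rate
    if missing.all():
        income_mean_obs = config.income_mean
    else:
        income_mean_obs = income[~missing].mean()
    income[missing] = income_mean_obs

    table = ActorTable(
        pd.DataFrame(
            {
                "sex": sex,
                "grade": grade,
                "black": black,
                "hispanic": hispanic,
                "age": age,
                "income": np.round(income, 1),
                "income_imputed": missing,
            }
        )
    )
    for attr in ("black", "hispanic"):
        if table.is_constant(attr):
            warnings.warn(
                f"attribute {attr!r} is constant in the generated school; the "
                f"corresponding homophily effect is not identifiable",
                stacklevel=2,
            )
    return table


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _tie_logits(actors: ActorTable, config: SchoolConfig) -> np.ndarray:
    """Baseline-free log-odds of each directed tie from homophily weights."""
    n = actors.n_actors
    w = config.homophily_weights
    logits = np.zeros((n, n))
    for key, attr in (
        ("same_sex", "sex"),
        ("same_grade", "grade"),
        ("same_black", "black"),
        ("same_hispanic", "hispanic"),
    ):
        if w.get(key):
            a = actors.column(attr)
            logits += w[key] * (a[:, None] == a[None, :])
    for key, attr in (("age_sim", "age"), ("income_sim", "income")):
        if w.get(key):
            v = actors.column(attr).astype(float)
            span = float(v.max() - v.min()) or 1.0
            logits += w[key] * (1.0 - np.abs(v[:, None] - v[None, :]) / span)
    np.fill_diagonal(logits, -np.inf)
    return logits


def _expected_mean_outdegree(b: float, logits: np.ndarray, rb: float) -> float:
    """Expected mean out-degree of the sequential dyad model at baseline b."""
    n = logits.shape[0]
    p = _sigmoid(b + logits)
    np.fill_diagonal(p, 0.0)
    # first direction drawn marginally; second direction conditions on it
    iu = np.triu_indices(n, k=1)
    p_ij = p[iu]
    l_ji = (b + logits.T)[iu]
    p_ji = p_ij * _sigmoid(l_ji + rb) + (1 - p_ij) * _sigmoid(l_ji)
    return float((p_ij.sum() + p_ji.sum()) / n)


def calibrate_baseline_logit(
    actors: ActorTable, config: SchoolConfig
) -> float:
    """Bisection on the baseline log-odds to hit the target mean out-degree."""
    logits = _tie_logits(actors, config)
    target = config.target_mean_outdegree
    lo, hi = -20.0, 5.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_mean_outdegree(mid, logits, config.reciprocity_boost) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_wave1(
    actors: ActorTable, config: SchoolConfig, rng: np.random.Generator
):
    """Wave-1 network and behavior draw.

    Ties: per unordered pair, the i->j direction is Bernoulli with log-odds
    ``baseline + homophily terms``; the j->i direction gets an additional
    ``reciprocity_boost`` if i->j realized.  Behavior: per the configured
    integer distribution, truncated to bounds.
    """
    n = actors.n_actors
    logits = _tie_logits(actors, config)
    b = config.baseline_logit
    if b is None:
        b = calibrate_baseline_logit(actors, config)

    x = np.zeros((n, n), dtype=np.int8)
    iu, ju = np.triu_indices(n, k=1)
    u1 = rng.random(len(iu))
    x[iu, ju] = (u1 < _sigmoid(b + logits[iu, ju])).astype(np.int8)
    u2 = rng.random(len(iu))
    boost = config.reciprocity_boost * x[iu, ju]
    x[ju, iu] = (u2 < _sigmoid(b + logits[ju, iu] + boost)).astype(np.int8)

    beh = config.behavior
    if beh.distribution == "rounded_normal":
        mean, sd = beh.params
        raw = rng.normal(mean, sd, size=n)
        # integer coding: round half away from zero
        z = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
    elif beh.distribution == "truncated_geometric":
        (p,) = beh.params
        z = rng.geometric(p, size=n) - 1
    elif beh.distribution == "categorical":
        levels = np.arange(beh.z_min, beh.z_max + 1)
        z = rng.choice(levels, size=n, p=np.asarray(beh.params, dtype=float))
    else:
        raise ConfigError(f"unknown behavior distribution {beh.distribution!r}")
    z = np.clip(np.asarray(z, dtype=np.int64), beh.z_min, beh.z_max)
    return x, z


def _in_band(value: int, band: tuple[int | None, int | None]) -> bool:
    lo, hi = band
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def generate_panel(config: SchoolConfig, seed: int | None = None) -> SyntheticPanel:
    """Generate a complete synthetic panel under the ground-truth parameters.

    Wave 2 is simulated from wave 1; panels whose realized change counts
    fall outside the configured bands are redrawn (fresh wave-2 simulation)
    up to ``max_retries`` times, after which a :class:`GenerationError`
    reports the realized counts.
    """
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    actor_seq, wave1_seq, *wave2_seqs = root.spawn(2 + config.max_retries + 1)

    rng = np.random.default_rng(actor_seq)
    actors = generate_actors(config, rng)
    x0, z0 = generate_wave1(actors, config, np.random.default_rng(wave1_seq))

    beh_cfg = config.behavior
    beh_w1 = BehaviorPanel(beh_cfg.name, z0[None, :], beh_cfg.z_min, beh_cfg.z_max)
    ctx = build_context(actors, beh_w1)

    realized = None
    for attempt, seq in enumerate(wave2_seqs):
        trace = simulate_period(
            x0, z0, actors, config.ground_truth, ctx,
            np.random.default_rng(seq),
            nomination_cap=config.nomination_cap,
        )
        net_changes = int(np.sum(trace.x1 != x0))
        beh_changes = int(np.sum(np.abs(trace.z1 - z0)))
        realized = (net_changes, beh_changes)
        if _in_band(net_changes, config.net_change_band) and _in_band(
            beh_changes, config.beh_change_band
        ):
            network = NetworkPanel([x0, trace.x1])
            behavior = BehaviorPanel(
                beh_cfg.name,
                np.stack([z0, trace.z1]),
                beh_cfg.z_min,
                beh_cfg.z_max,
            )
            return SyntheticPanel(
                actors, network, behavior, config.ground_truth, seed, trace, config
            )
    raise GenerationError(
        f"wave-2 change counts {realized} outside bands "
        f"net={config.net_change_band}, beh={config.beh_change_band} "
        f"after {config.max_retries + 1} attempts"
    )


# ---------------------------------------------------------------------------
# named presets emulating the two study schools (scaled down by default)

def jefferson_like(
    n_actors: int = 120, behavior: str = "bmi", seed: int | None = None
) -> SchoolConfig:
    """Rural, racially homogeneous school: denser network, grades 9-11."""
    from .published import published_parameters

    behaviors = {
        "bmi": BehaviorConfig("bmi", 14, 44, "rounded_normal", (22.6, 4.4)),
        "screen_time": BehaviorConfig("screen_time", 0, 9, "truncated_geometric", (0.45,)),
        "sports": BehaviorConfig("sports", 0, 3, "categorical", (0.25, 0.3, 0.25, 0.2)),
    }
    return SchoolConfig(
        n_actors=n_actors,
        male_prop=0.474,
        grades=(9, 10, 11),
        black_prop=0.0,
        hispanic_prop=0.008,
        age_mean=16.1,
        age_sd=1.1,
        income_mean=45.2,
        income_sd=26.7,
        income_missing_rate=0.17,
        behavior=behaviors[behavior],
        target_mean_outdegree=3.5,
        reciprocity_boost=2.2,
        homophily_weights={"same_sex": 0.4, "same_grade": 1.0, "age_sim": 1.0},
        ground_truth=published_parameters("jefferson", behavior),
        net_change_band=(1, None),
        seed=seed,
    )


def sunshine_like(
    n_actors: int = 200, behavior: str = "bmi", seed: int | None = None
) -> SchoolConfig:
    """Urban, diverse school: sparser network, race/ethnicity mixture."""
    from .published import published_parameters

    behaviors = {
        "bmi": BehaviorConfig("bmi", 16, 51, "rounded_normal", (23.3, 4.7)),
        "screen_time": BehaviorConfig("screen_time", 0, 9, "truncated_geometric", (0.38,)),
        "sports": BehaviorConfig("sports", 0, 3, "categorical", (0.3, 0.3, 0.22, 0.18)),
    }
    return SchoolConfig(
        n_actors=n_actors,
        male_prop=0.499,
        grades=(10, 11),
        black_prop=0.213,
        hispanic_prop=0.406,
        age_mean=16.5,
        age_sd=0.9,
        income_mean=33.7,
        income_sd=18.8,
        income_missing_rate=0.39,
        behavior=behaviors[behavior],
        target_mean_outdegree=1.8,
        reciprocity_boost=1.8,
        homophily_weights={
            "same_sex": 0.5,
            "same_grade": 0.9,
            "same_black": 0.8,
            "same_hispanic": 0.9,
            "age_sim": 1.0,
        },
        ground_truth=published_parameters("sunshine", behavior),
        net_change_band=(1, None),
        seed=seed,
    )

PRESETS = {"jefferson_like": jefferson_like, "sunshine_like": sunshine_like}
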