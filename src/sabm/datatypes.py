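"""Domain types for stochastic actor-based co-evolution models.

The model operates on a fixed set of N actors observed at two (or more)
waves.  A :class:`NetworkPanel` holds the directed friendship adjacency
matrix at each wave, a :class:`BehaviorPanel` the integer-coded behavior
(BMI, screen-time decile, active-sports score) of every actor at each wave,
and an :class:`ActorTable` the fixed covariates (sex, grade, race,
ethnicity, age, household income).  :class:`EffectParameterSet` collects the
objective-function weights (betas) and the basic rate parameters that drive
the ministep process.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class SabmError(Exception):
    """Base class for model errors."""


class InvalidStateError(SabmError):
    """A network/behavior state violates a structural invariant."""


class InvalidContextError(SabmError):
    """A similarity context is unusable (e.g. non-positive range)."""


class InvalidChoiceError(SabmError):
    """A candidate action is outside the legal candidate set."""


class ConfigError(SabmError):
    """Invalid configuration."""


class EstimationError(SabmError):
    """Estimation failure (singular derivative, degenerate targets, ...)."""


class GenerationError(SabmError):
    """Synthetic panel generation failed its realism bands."""


ACTOR_COLUMNS = ("sex", "grade", "black", "hispanic", "age", "income", "income_imputed")


@dataclass
class ActorTable:
    """Fixed actor covariates, indexed by contiguous actor ids 0..N-1.

    ``sex``, ``black``, ``hispanic`` are 0/1 categories, ``grade`` an
    ordinal category, ``age`` in years, ``income`` in $1k units.
    ``income_imputed`` flags actors whose raw income was missing and was
    replaced by the school mean.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in ACTOR_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidStateError(f"actor table missing columns: {missing}")
        if not np.array_equal(df.index.to_numpy(), np.arange(len(df))):
            raise InvalidStateError("actor_ids must be unique and contiguous from 0")
        for col in ("age", "income"):
            if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
                raise InvalidStateError(f"non-finite values in {col!r}")

    @property
    def n_actors(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def is_constant(self, name: str) -> bool:
        """True when an attribute takes a single value across the school."""
        col = self.frame[name].to_numpy()
        return bool(np.all(col == col[0]))


@dataclass
class NetworkPanel:
    """Directed friendship adjacency matrices, one per wave.

    Entries are 0/1; self-ties are structurally forbidden.
    """

    waves: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.waves:
            raise InvalidStateError("network panel needs at least one wave")
        n = self.waves[0].shape[0]
        cleaned = []
        for w, x in enumerate(self.waves):
            x = np.asarray(x)
            if x.shape != (n, n):
                raise InvalidStateError(f"wave {w}: expected shape {(n, n)}, got {x.shape}")
            if not np.isin(x, (0, 1)).all():
                raise InvalidStateError(f"wave {w}: ties must be 0/1")
            if np.trace(x) != 0:
                raise InvalidStateError(f"wave {w}: self-ties present")
            cleaned.append(x.astype(np.int8))
        self.waves = cleaned

    @property
    def n_actors(self) -> int:
        return self.waves[0].shape[0]

    @property
    def n_waves(self) -> int:
        return len(self.waves)


@dataclass
class SimilarityContext:
    """Scaling and centering constants for a dyadic similarity measure.

    ``sim(v_i, v_j) = 1 - |v_i - v_j| / range_used``, centered by
    subtracting ``sim_avg`` (the mean dyadic similarity in the data).
    """

    name: str
    range_used: float
    sim_avg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.range_used > 0):
            raise InvalidContextError(
                f"similarity context {self.name!r}: range_used must be > 0, "
                f"got {self.range_used}"
            )
        if not (0.0 <= self.sim_avg <= 1.0):
            raise InvalidContextError(
                f"similarity context {self.name!r}: sim_avg must lie in [0, 1]"
            )


@dataclass
class BehaviorPanel:
    """Integer-coded behavior per actor per wave, plus its model context.

    ``z_avg`` centers the behavior in shape effects; ``range_used`` and
    ``sim_avg`` parameterize the behavior similarity measure.  By default
    all three are pooled over every actor and wave; each can be overridden,
    which is how constants backed out from published worked examples are
    injected.
    """

    name: str
    values: np.ndarray  # shape (n_waves, n_actors), integer
    z_min: int
    z_max: int
    z_avg: float | None = None
    range_used: float | None = None
    sim_avg: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise InvalidStateError("behavior values must be (n_waves, n_actors)")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.round(vals)):
                raise InvalidStateError("behavior values must be integers")
            vals = vals.astype(np.int64)
        if vals.min() < self.z_min or vals.max() > self.z_max:
            raise InvalidStateError(
                f"behavior {self.name!r}: values outside [{self.z_min}, {self.z_max}]"
            )
        self.values = vals
        if self.z_avg is None:
            self.z_avg = float(vals.mean())
        if self.range_used is None:
            # pooled observed span; falls back to the coding bounds when the
            # observed values are constant
            span = float(vals.max() - vals.min())
            self.range_used = span if span > 0 else float(self.z_max - self.z_min)
        if self.range_used <= 0:
            raise InvalidContextError(f"behavior {self.name!r}: range_used must be > 0")
        if self.sim_avg is None:
            self.sim_avg = float(_mean_dyadic_similarity(vals, self.range_used))
        if not (0.0 <= self.sim_avg <= 1.0):
            raise InvalidContextError(f"behavior {self.name!r}: sim_avg outside [0, 1]")

    @property
    def n_actors(self) -> int:
        return self.values.shape[1]

    @property
    def context(self) -> SimilarityContext:
        return SimilarityContext(self.name, self.range_used, self.sim_avg)


def _mean_dyadic_similarity(values: np.ndarray, range_used: float) -> float:
    # mean of 1 - |z_i - z_j|/range over all ordered pairs i != j, pooled
    # over waves; O(n^2) per wave is fine at school scale
    sims = []
    for wave in values:
        diff = np.abs(wave[:, None] - wave[None, :]) / range_used
        n = len(wave)
        off = ~np.eye(n, dtype=bool)
        sims.append(1.0 - diff[off])
    return float(np.concatenate(sims).mean())


# canonical ordering of the 12 network effects and 3 behavior effects
NETWORK_EFFECTS = (
    "outdegree",
    "reciprocity",
    "transitive_triplets",
    "same_sex",
    "same_grade",
    "same_black",
    "same_hispanic",
    "age_similarity",
    "income_similarity",
    "behavior_ego",
    "behavior_alter",
    "behavior_similarity",
)
BEHAVIOR_EFFECTS = ("linear_shape", "quadratic_shape", "average_similarity")
RATE_PARAMETERS = ("rate_net", "rate_beh")

_EFFECT_TO_FIELD = {
    "outdegree": "beta_deg",
    "reciprocity": "beta_rec",
    "transitive_triplets": "beta_ttip",
    "same_sex": "beta_same_sex",
    "same_grade": "beta_same_grade",
    "same_black": "beta_same_black",
    "same_hispanic": "beta_same_hisp",
    "age_similarity": "beta_age_sim",
    "income_similarity": "beta_inc_sim",
    "behavior_ego": "beta_beh_ego",
    "behavior_alter": "beta_beh_alter",
    "behavior_similarity": "beta_beh_sim",
    "linear_shape": "beta_lin",
    "quadratic_shape": "beta_quad",
    "average_similarity": "beta_avsim",
    "rate_net": "rate_net",
    "rate_beh": "rate_beh",
}
FIELD_TO_EFFECT = {v: k for k, v in _EFFECT_TO_FIELD.items()}


@dataclass
class EffectParameterSet:
    """Objective-function weights and basic rate parameters.

    Network function betas follow the canonical 12-effect ordering of
    :data:`NETWORK_EFFECTS`; the behavior function has linear/quadratic
    shape and the average-similarity (peer influence) effect.  Rates are
    expected change opportunities per actor per period and must be > 0.
    """

    beta_deg: float = 0.0
    beta_rec: float = 0.0
    beta_ttip: float = 0.0
    beta_same_sex: float = 0.0
    beta_same_grade: float = 0.0
    beta_same_black: float = 0.0
    beta_same_hisp: float = 0.0
    beta_age_sim: float = 0.0
    beta_inc_sim: float = 0.0
    beta_beh_ego: float = 0.0
    beta_beh_alter: float = 0.0
    beta_beh_sim: float = 0.0
    beta_lin: float = 0.0
    beta_quad: float = 0.0
    beta_avsim: float = 0.0
    rate_net: float = 1.0
    rate_beh: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ConfigError(f"parameter {f.name} must be finite, got {v}")
        if self.rate_net <= 0 or self.rate_beh <= 0:
            raise ConfigError("rate parameters must be strictly positive")

    def network_betas(self) -> np.ndarray:
        """Betas in :data:`NETWORK_EFFECTS` order."""
        return np.array([getattr(self, _EFFECT_TO_FIELD[e]) for e in NETWORK_EFFECTS])

    def behavior_betas(self) -> np.ndarray:
        return np.array([self.beta_lin, self.beta_quad, self.beta_avsim])

    def get(self, effect: str) -> float:
        return float(getattr(self, _EFFECT_TO_FIELD[effect]))

    def replace(self, **updates: float) -> "EffectParameterSet":
        by_field = {
            _EFFECT_TO_FIELD.get(k, k): v for k, v in updates.items()
        }
        return dataclasses.replace(self, **by_field)

    def to_dict(self) -> dict[str, float]:
        """Parameters keyed by effect name (the JSON interchange layout)."""
        out = {e: self.get(e) for e in NETWORK_EFFECTS + BEHAVIOR_EFFECTS}
        out["rate_net"] = self.rate_net
        out["rate_beh"] = self.rate_beh
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "EffectParameterSet":
        kwargs = {}
        for k, v in d.items():
            if k in _EFFECT_TO_FIELD:
                kwargs[_EFFECT_TO_FIELD[k]] = float(v)
            elif k in FIELD_TO_EFFECT:
                kwargs[k] = float(v)
            else:
                raise ConfigError(f"unknown effect/parameter name {k!r}")
        return cls(**kwargs)


@dataclass
class ChoiceDistribution:
    """Discrete distribution over the candidate actions of one ministep."""

    actions: Sequence
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(self.actions) != len(p):
            raise InvalidStateError("actions and probabilities differ in length")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise InvalidStateError("probabilities must be >= 0 and sum to 1")
        self.probabilities = p

    def prob(self, action) -> float:
        for a, p in zip(self.actions, self.probabilities):
            if a == action:
                return float(p)
        raise KeyError(action)

    def as_dict(self) -> dict:
        return {a: float(p) for a, p in zip(self.actions, self.probabilities)}
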