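"""Published parameter sets and worked-example constants for two schools.

The fitted SABM parameters reported for the two large Add-Health-style high
schools — "Jefferson High" (rural, racially homogeneous, N = 624) and
"Sunshine High" (urban, diverse, N = 1151) — are reproduced here as plain
data so that influence probability tables and worked choice scenarios can
be recomputed without access to the restricted survey data.

Some constants needed to evaluate the objective functions (the behavior
similarity denominator and centering mean) were not reported directly; they
are backed out from the printed objective values of the worked BMI
scenarios (:func:`backout_worked_constants`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import EffectParameterSet

# ---------------------------------------------------------------------------
# fitted parameters (structural + homophily effects common to all behaviors,
# plus per-behavior network and behavior-function effects)

_JEFFERSON_STRUCTURAL = dict(
    outdegree=-3.56,
    reciprocity=2.26,
    transitive_triplets=0.48,
    same_sex=0.18,
    same_grade=0.49,
    age_similarity=0.91,
    income_similarity=0.060,
)
_SUNSHINE_STRUCTURAL = dict(
    outdegree=-5.97,
    reciprocity=2.48,
    transitive_triplets=0.67,
    same_sex=0.47,
    same_grade=0.51,
    same_black=0.83,
    same_hispanic=0.91,
    age_similarity=1.18,
    income_similarity=0.56,
)

_BEHAVIOR_BLOCKS = {
    ("jefferson", "bmi"): dict(
        rate_net=12.87, rate_beh=4.17,
        behavior_alter=-0.007, behavior_ego=0.014, behavior_similarity=0.54,
        linear_shape=0.16, quadratic_shape=0.015, average_similarity=14.10,
    ),
    ("jefferson", "screen_time"): dict(
        rate_net=12.87, rate_beh=3.97,
        behavior_alter=-0.017, behavior_ego=0.023, behavior_similarity=0.17,
        linear_shape=-0.46, quadratic_shape=0.070, average_similarity=5.04,
    ),
    ("jefferson", "sports"): dict(
        rate_net=12.87, rate_beh=3.84,
        behavior_alter=0.082, behavior_ego=0.021, behavior_similarity=0.59,
        linear_shape=-0.20, quadratic_shape=0.33, average_similarity=1.74,
    ),
    ("sunshine", "bmi"): dict(
        rate_net=6.77, rate_beh=5.20,
        behavior_alter=-0.009, behavior_ego=0.017, behavior_similarity=1.30,
        linear_shape=0.10, quadratic_shape=0.006, average_similarity=10.57,
    ),
    ("sunshine", "screen_time"): dict(
        rate_net=6.77, rate_beh=7.39,
        behavior_alter=-0.043, behavior_ego=-0.066, behavior_similarity=-0.89,
        linear_shape=-0.36, quadratic_shape=0.012, average_similarity=-0.47,
    ),
    ("sunshine", "sports"): dict(
        rate_net=6.77, rate_beh=3.77,
        behavior_alter=0.061, behavior_ego=-0.061, behavior_similarity=0.28,
        linear_shape=-0.33, quadratic_shape=0.23, average_similarity=1.30,
    ),
}


def published_parameters(school: str, behavior: str) -> EffectParameterSet:
    """Fitted parameter set for one of the 6 school x behavior models."""
    structural = {"jefferson": _JEFFERSON_STRUCTURAL, "sunshine": _SUNSHINE_STRUCTURAL}[
        school
    ]
    block = _BEHAVIOR_BLOCKS[(school, behavior)]
    return EffectParameterSet.from_dict({**structural, **block})


@dataclass(frozen=True)
class BehaviorSpec:
    """Coding and centering constants of one behavior in one school."""

    name: str
    z_min: int
    z_max: int
    z_avg: float
    range_used: float


# BMI is integer-coded; the similarity denominator implied by the worked
# scenarios (~33.1, see backout_worked_constants) is used for probability
# tables, while the observed span at Jefferson was 13.8-44.3.
def behavior_specs(school: str = "jefferson") -> dict[str, BehaviorSpec]:
    consts = backout_worked_constants()
    if school == "jefferson":
        return {
            "bmi": BehaviorSpec("bmi", 14, 44, 22.6, consts.range_used),
            # screen time in 10 h/wk categories 0-9; mean 14.9 h/wk -> 1.49
            "screen_time": BehaviorSpec("screen_time", 0, 9, 1.49, 9.0),
            # sports frequency score 0-3; school mean 1.5
            "sports": BehaviorSpec("sports", 0, 3, 1.5, 3.0),
        }
    return {
        "bmi": BehaviorSpec("bmi", 16, 51, 23.3, 51 - 16),
        "screen_time": BehaviorSpec("screen_time", 0, 9, 1.86, 9.0),
        "sports": BehaviorSpec("sports", 0, 3, 1.3, 3.0),
    }


# ---------------------------------------------------------------------------
# worked-example scenario values (Jefferson BMI model)

# objective values of the four candidate actions in the worked network
# scenario: keep the network, drop the reciprocating alter, drop the
# non-reciprocating alter, add the reciprocating obese alter
WORKED_NETWORK_OBJECTIVES = {
    "keep": -2.77,
    "drop_reciprocated": -2.52,
    "drop_nonreciprocated": -0.26,
    "add_reciprocating": -3.18,
}
WORKED_NETWORK_PROBABILITIES = {
    "keep": 0.065,
    "drop_reciprocated": 0.084,
    "drop_nonreciprocated": 0.807,
    "add_reciprocating": 0.043,
}

# behavior objective triples (down one unit, stay, up one unit) for an ego
# at BMI 23: friendless, and with two alters at BMI 30
WORKED_BEHAVIOR_OBJECTIVES_ISOLATE = (-0.093, 0.0689, 0.260)
WORKED_BEHAVIOR_OBJECTIVES_TWO_ALTERS_30 = (-1.608, -1.019, -0.402)
WORKED_BEHAVIOR_PROBABILITIES_ISOLATE = (0.278, 0.327, 0.395)
WORKED_BEHAVIOR_PROBABILITIES_TWO_ALTERS_30 = (0.163, 0.293, 0.544)
WORKED_REVERSED_PROBABILITIES = {"down": 0.351, "up": 0.319}

WORKED_EGO_BMI = 23
WORKED_ALTER_BMI = 30
WORKED_BMI_MEAN = 22.6


@dataclass(frozen=True)
class WorkedConstants:
    """Behavior-similarity constants recovered from the worked scenarios."""

    centered_similarities: tuple[float, float, float]
    per_unit_increment: float
    range_used: float
    sim_avg: float


def backout_worked_constants() -> WorkedConstants:
    """Recover the BMI similarity scaling from the printed objective values.

    The two-alter scenario's objectives differ from the friendless
    scenario's purely through ``beta_avsim * (sim - sim_avg)``, so the three
    centered similarities follow by subtraction and division.  Consecutive
    candidates change |ego - alter| by one unit, so the similarity increment
    per BMI unit is ``1 / range_used``; with the alters 7 units away at the
    stay-same candidate, ``sim_avg`` follows from the middle similarity.
    """
    params = published_parameters("jefferson", "bmi")
    iso = np.array(WORKED_BEHAVIOR_OBJECTIVES_ISOLATE)
    two = np.array(WORKED_BEHAVIOR_OBJECTIVES_TWO_ALTERS_30)
    s = (two - iso) / params.beta_avsim
    increment = float((s[2] - s[0]) / 2.0)
    range_used = 1.0 / increment
    gap = abs(WORKED_EGO_BMI - WORKED_ALTER_BMI)  # 7 at the stay-same candidate
    sim_avg = float((1.0 - gap * increment) - s[1])
    return WorkedConstants(tuple(map(float, s)), increment, range_used, sim_avg)
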