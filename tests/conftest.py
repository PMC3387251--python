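"""Shared fixtures: toy actor tables, brute-force oracles, recovery setup."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sabm import (
    ActorTable,
    BehaviorPanel,
    EffectParameterSet,
    ModelContext,
    SimilarityContext,
)
from sabm.synth import BehaviorConfig, SchoolConfig


def make_actors(
    sex, grade=None, black=None, hispanic=None, age=None, income=None
) -> ActorTable:
    """Small actor table with sensible defaults for unspecified columns."""
    n = len(sex)
    return ActorTable(
        pd.DataFrame(
            {
                "sex": list(sex),
                "grade": list(grade) if grade is not None else [10] * n,
                "black": list(black) if black is not None else [0] * n,
                "hispanic": list(hispanic) if hispanic is not None else [0] * n,
                "age": list(age) if age is not None else [16.0] * n,
                "income": list(income) if income is not None else [40.0] * n,
                "income_imputed": [False] * n,
            }
        )
    )


def random_scenario(rng, n=None):
    """Random small network + attributes + behavior + parameters + context."""
    if n is None:
        n = int(rng.integers(2, 7))
    x = rng.integers(0, 2, size=(n, n)).astype(np.int8)
    np.fill_diagonal(x, 0)
    attrs = make_actors(
        sex=rng.integers(0, 2, n),
        grade=rng.integers(9, 12, n),
        black=rng.integers(0, 2, n),
        hispanic=rng.integers(0, 2, n),
        age=np.round(rng.uniform(14, 19, n), 1),
        income=np.round(rng.uniform(10, 90, n), 1),
    )
    z = rng.integers(0, 7, n)
    ctx = ModelContext(
        age=SimilarityContext("age", 5.0, float(rng.uniform(0, 1))),
        income=SimilarityContext("income", 80.0, float(rng.uniform(0, 1))),
        behavior=SimilarityContext("beh", 6.0, float(rng.uniform(0, 1))),
        z_avg=float(rng.uniform(2, 4)),
        z_min=0,
        z_max=6,
    )
    betas = {name: float(rng.normal(0, 0.8)) for name in (
        "outdegree", "reciprocity", "transitive_triplets", "same_sex",
        "same_grade", "same_black", "same_hispanic", "age_similarity",
        "income_similarity", "behavior_ego", "behavior_alter",
        "behavior_similarity",
    )}
    params = EffectParameterSet.from_dict(betas)
    return x, attrs, z, params, ctx


# ---------------------------------------------------------------------------
# independent brute-force oracles (explicit loops over ordered pairs/triples)

def brute_effect_statistics(i, x, attrs, z, ctx):
    n = x.shape[0]
    sex, grade = attrs.column("sex"), attrs.column("grade")
    black, hisp = attrs.column("black"), attrs.column("hispanic")
    age, inc = attrs.column("age").astype(float), attrs.column("income").astype(float)

    outdeg = sum(x[i, j] for j in range(n))
    rec = sum(x[i, j] * x[j, i] for j in range(n))
    ttip = sum(
        x[i, h] * x[i, j] * x[j, h] for j in range(n) for h in range(n)
    )
    same = lambda a: sum(x[i, j] * (a[i] == a[j]) for j in range(n))
    simsum = lambda v, c: sum(
        x[i, j] * ((1 - abs(v[i] - v[j]) / c.range_used) - c.sim_avg)
        for j in range(n)
    )
    beh_ego = outdeg * (z[i] - ctx.z_avg)
    beh_alter = sum(x[i, j] * (z[j] - ctx.z_avg) for j in range(n))
    beh_sim = simsum(z.astype(float), ctx.behavior)
    return np.array(
        [
            outdeg, rec, ttip,
            same(sex), same(grade), same(black), same(hisp),
            simsum(age, ctx.age), simsum(inc, ctx.income),
            beh_ego, beh_alter, beh_sim,
        ],
        dtype=float,
    )


def brute_network_choice(i, x, attrs, z, params, ctx):
    """Exhaustive candidate enumeration: actual toggled matrices, full stats."""
    n = x.shape[0]
    betas = params.network_betas()
    actions, objectives = ["keep"], [
        float(betas @ brute_effect_statistics(i, x, attrs, z, ctx))
    ]
    for k in range(n):
        if k == i:
            continue
        cand = x.copy()
        cand[i, k] ^= 1
        actions.append(k)
        objectives.append(float(betas @ brute_effect_statistics(i, cand, attrs, z, ctx)))
    v = np.array(objectives)
    e = np.exp(v - v.max())
    return actions, v, e / e.sum()


# ---------------------------------------------------------------------------
# the parameter-recovery simulation study conditions

RECOVERY_EFFECTS = [
    "rate_net", "rate_beh", "outdegree", "reciprocity",
    "behavior_similarity", "average_similarity",
]


def recovery_school(kind: str, n_actors: int = 60) -> SchoolConfig:
    """Synthetic school with either a homophily-only or influence-only truth."""
    truth = EffectParameterSet(
        beta_deg=-2.5,
        beta_rec=2.0,
        rate_net=3.0,
        rate_beh=2.0,
        beta_beh_sim=3.0 if kind == "homophily" else 0.0,
        beta_avsim=3.0 if kind == "influence" else 0.0,
    )
    return SchoolConfig(
        n_actors=n_actors,
        behavior=BehaviorConfig("index", 0, 6, "rounded_normal", (3.0, 1.5)),
        target_mean_outdegree=3.0,
        reciprocity_boost=1.5,
        homophily_weights={"same_sex": 0.3},
        ground_truth=truth,
        net_change_band=(1, None),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
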