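"""Continuous-time ministep simulation of network/behavior co-evolution.

Between two observation waves the process unfolds as a sequence of
ministeps.  Opportunities arrive with total intensity
``N * (rate_net + rate_beh)`` over a unit-length period, so the number of
events is Poisson with that mean; each event picks an actor uniformly and is
a network opportunity with probability ``rate_net / (rate_net + rate_beh)``.
The chosen actor then samples one action from its multinomial choice
distribution (see :mod:`sabm.core`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    KEEP,
    ModelContext,
    behavior_candidate_objectives,
    make_eval_cache,
    network_toggle_deltas,
    softmax,
)
from .datatypes import (
    ActorTable,
    ConfigError,
    EffectParameterSet,
    InvalidStateError,
)


@dataclass
class Ministep:
    """One elementary change opportunity and the action taken."""

    index: int
    actor: int
    change_type: str  # "network" | "behavior"
    action: object  # alter id or KEEP for network; delta in {-1, 0, +1} for behavior


@dataclass
class SimulationTrace:
    """A full simulation run: initial state, ministeps, final state, seed.

    Replaying the ministeps from the initial state reproduces the final
    state exactly (see :func:`replay`).
    """

    x0: np.ndarray
    z0: np.ndarray
    ministeps: list[Ministep]
    x1: np.ndarray
    z1: np.ndarray
    seed: object = None

    @property
    def n_steps(self) -> int:
        return len(self.ministeps)


def _check_rates(params: EffectParameterSet) -> float:
    if params.rate_net <= 0 or params.rate_beh <= 0:
        raise ConfigError("rate parameters must be strictly positive")
    return params.rate_net + params.rate_beh


def draw_event_count(params: EffectParameterSet, n_actors: int, rng) -> int:
    """Number of ministeps in a unit period: Poisson(N * (rate_net + rate_beh))."""
    total = _check_rates(params)
    return int(rng.poisson(n_actors * total))


def draw_next_event(params: EffectParameterSet, n_actors: int, rng):
    """Actor (uniform) and change type (by rate ratio) of the next ministep."""
    total = _check_rates(params)
    actor = int(rng.integers(n_actors))
    change_type = "network" if rng.random() < params.rate_net / total else "behavior"
    return actor, change_type


def allowed_creation_mask(
    net: np.ndarray,
    sex: np.ndarray,
    ego: int,
    max_total: int = 10,
    max_per_sex: int = 5,
) -> np.ndarray:
    """Nomination cap: which tie creations remain available to the ego.

    Mirrors a name-up-to-10-friends instrument with at most 5 of each sex:
    once the ego has ``max_total`` out-ties no creation is offered, and once
    it has ``max_per_sex`` out-ties to one sex no further alters of that sex
    are offered.  Deletions and keep-same are never restricted.
    """
    row = net[ego]
    allowed = np.ones(len(row), dtype=bool)
    if row.sum() >= max_total:
        allowed[:] = False
        return allowed
    for s in np.unique(sex):
        if row[sex == s].sum() >= max_per_sex:
            allowed[sex == s] = False
    return allowed


def _validate_state(x: np.ndarray, z: np.ndarray, ctx: ModelContext) -> None:
    if np.trace(x) != 0:
        raise InvalidStateError("initial network has self-ties")
    if not np.isin(x, (0, 1)).all():
        raise InvalidStateError("initial network must be binary")
    if z.min() < ctx.z_min or z.max() > ctx.z_max:
        raise InvalidStateError("initial behavior outside coding bounds")


def simulate_period(
    x0: np.ndarray,
    z0: np.ndarray,
    attrs: ActorTable,
    params: EffectParameterSet,
    ctx: ModelContext,
    rng: np.random.Generator | int,
    nomination_cap: bool = False,
    max_total: int = 10,
    max_per_sex: int = 5,
    n_steps: int | None = None,
    record_steps: bool = True,
) -> SimulationTrace:
    """Simulate one between-wave period of joint network/behavior change.

    ``rng`` may be a Generator or an integer seed (recorded in the trace).
    ``n_steps`` overrides the Poisson-drawn event count (used by tests and
    by conditional experiments).  With ``record_steps=False`` the ministep
    list is left empty, which saves memory in estimation loops.
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)

    _check_rates(params)
    x = np.array(x0, dtype=np.int8, copy=True)
    z = np.array(z0, dtype=np.int64, copy=True)
    _validate_state(x, z, ctx)
    n = x.shape[0]
    sex = attrs.column("sex")

    if n_steps is None:
        n_steps = draw_event_count(params, n, rng)

    cache = make_eval_cache(attrs, params, ctx)
    p_net = params.rate_net / (params.rate_net + params.rate_beh)

    steps: list[Ministep] = []
    for k in range(n_steps):
        actor = int(rng.integers(n))
        change_type = "network" if rng.random() < p_net else "behavior"
        if change_type == "network":
            delta = network_toggle_deltas(actor, x, z, ctx, cache)
            if nomination_cap:
                allowed = allowed_creation_mask(x, sex, actor, max_total, max_per_sex)
                delta[(x[actor] == 0) & ~allowed] = -np.inf
            # candidate 0 is keep-same (objective 0), candidate j+1 toggles j
            probs = softmax(np.concatenate(([0.0], delta)))
            idx = int(np.searchsorted(np.cumsum(probs), rng.random()))
            if idx == 0:
                action = KEEP
            else:
                action = idx - 1
                x[actor, action] ^= 1
        else:
            deltas, objs = behavior_candidate_objectives(actor, x, z, params, ctx)
            probs = softmax(objs)
            idx = int(np.searchsorted(np.cumsum(probs), rng.random()))
            action = int(deltas[idx])
            z[actor] += action
        if record_steps:
            steps.append(Ministep(k, actor, change_type, action))

    return SimulationTrace(np.array(x0, dtype=np.int8), np.array(z0, dtype=np.int64),
                           steps, x, z, seed=seed)


def replay(trace: SimulationTrace):
    """Re-apply a trace's ministeps to its initial state; returns (x, z)."""
    x = np.array(trace.x0, copy=True)
    z = np.array(trace.z0, copy=True)
    for step in trace.ministeps:
        if step.change_type == "network":
            if step.action != KEEP:
                x[step.actor, step.action] ^= 1
        else:
            z[step.actor] += step.action
    return x, z
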