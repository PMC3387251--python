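"""Effect statistics, objective functions and the multinomial choice rule.

An actor ("ego") who receives a change opportunity evaluates an objective
function — a linear combination of effect statistics — for every candidate
state it can reach in one ministep, and chooses among candidates with
probabilities proportional to the exponentiated objective values.

Network ministeps: the candidate set is the current network plus the N-1
states reachable by toggling a single outgoing tie (self-ties are never
candidates).  Behavior ministeps: move the integer behavior down one unit,
keep it, or move it up one unit, truncated at the coding bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ActorTable,
    BehaviorPanel,
    ChoiceDistribution,
    EffectParameterSet,
    InvalidChoiceError,
    InvalidStateError,
    NETWORK_EFFECTS,
    SimilarityContext,
)

KEEP = "keep"  # label of the no-change candidate in a network ministep


def softmax(values: np.ndarray) -> np.ndarray:
    """Exponentiate-and-normalize, guarded against overflow by max-subtraction."""
    v = np.asarray(values, dtype=float)
    e = np.exp(v - v.max())
    return e / e.sum()


def choice_probabilities_from_objectives(actions, objectives) -> ChoiceDistribution:
    """Multinomial choice distribution over candidate objective values."""
    return ChoiceDistribution(list(actions), softmax(objectives))


def similarity(v_i: float, v_j: float, ctx: SimilarityContext) -> float:
    """Centered dyadic similarity ``(1 - |v_i - v_j|/range_used) - sim_avg``.

    The uncentered value lies in [0, 1] when the dyad's values lie within
    the context's range: 1 means identical values, 0 maximal difference.
    """
    return (1.0 - abs(v_i - v_j) / ctx.range_used) - ctx.sim_avg


@dataclass
class ModelContext:
    """Similarity scalings/centerings and behavior coding used by the model.

    Bundles the dyadic similarity contexts for age, income and the behavior,
    the behavior centering mean ``z_avg`` and the behavior coding bounds.
    """

    age: SimilarityContext
    income: SimilarityContext
    behavior: SimilarityContext
    z_avg: float
    z_min: int
    z_max: int


def build_context(attrs: ActorTable, beh: BehaviorPanel) -> ModelContext:
    """Pooled-data context: ranges and mean similarities from the observed data.

    Age and income ranges are the observed spans in the school; mean
    similarities are averaged over all ordered dyads.  Behavior constants
    come from the :class:`BehaviorPanel` (pooled over waves unless
    overridden there).
    """
    ctxs = {}
    for name in ("age", "income"):
        col = attrs.column(name).astype(float)
        span = float(col.max() - col.min())
        if span <= 0:
            span = 1.0  # constant attribute: similarity is identically 1
        diff = np.abs(col[:, None] - col[None, :]) / span
        off = ~np.eye(len(col), dtype=bool)
        ctxs[name] = SimilarityContext(name, span, float((1.0 - diff[off]).mean()))
    return ModelContext(
        age=ctxs["age"],
        income=ctxs["income"],
        behavior=beh.context,
        z_avg=beh.z_avg,
        z_min=beh.z_min,
        z_max=beh.z_max,
    )


def _check_dims(net: np.ndarray, attrs: ActorTable, z: np.ndarray) -> int:
    n = net.shape[0]
    if net.shape != (n, n):
        raise InvalidStateError("adjacency matrix must be square")
    if attrs.n_actors != n or len(z) != n:
        raise InvalidStateError(
            f"dimension mismatch: network {n}, attributes {attrs.n_actors}, "
            f"behavior {len(z)}"
        )
    return n


def effect_statistics(
    actor: int,
    net: np.ndarray,
    attrs: ActorTable,
    z: np.ndarray,
    ctx: ModelContext,
) -> np.ndarray:
    """Per-ego network-effect statistics, in :data:`NETWORK_EFFECTS` order.

    Returns the 12-vector (outdegree, reciprocity, transitive triplets,
    same-sex/grade/black/hispanic tie counts, centered age and income
    similarity sums, behavior-ego, behavior-alter, behavior-similarity).
    Behavior values enter the ego and alter statistics centered by
    ``ctx.z_avg``.
    """
    n = _check_dims(net, attrs, z)
    if np.trace(net) != 0:
        raise InvalidStateError("self-ties present")
    i = actor
    row = net[i].astype(float)
    col = net[:, i].astype(float)
    zc = np.asarray(z, dtype=float) - ctx.z_avg

    outdeg = row.sum()
    rec = float(row @ col)
    # ordered alter pairs (j, h) with i->j, i->h and j->h
    ttip = float(row @ (net.astype(float) @ row))

    stats = [outdeg, rec, ttip]
    for name in ("sex", "grade", "black", "hispanic"):
        a = attrs.column(name)
        stats.append(float(row @ (a == a[i])))
    for name, sctx in (("age", ctx.age), ("income", ctx.income)):
        v = attrs.column(name).astype(float)
        sims = (1.0 - np.abs(v - v[i]) / sctx.range_used) - sctx.sim_avg
        stats.append(float(row @ sims))
    stats.append(outdeg * zc[i])          # behavior ego (sociability)
    stats.append(float(row @ zc))         # behavior alter (attraction)
    bsims = (1.0 - np.abs(z - z[i]) / ctx.behavior.range_used) - ctx.behavior.sim_avg
    stats.append(float(row @ bsims))      # behavior similarity (homophily)
    return np.array(stats)


def network_objective(
    actor: int,
    candidate_net: np.ndarray,
    attrs: ActorTable,
    z: np.ndarray,
    params: EffectParameterSet,
    ctx: ModelContext,
) -> float:
    """Network objective value: betas dotted with the candidate's statistics."""
    return float(
        params.network_betas() @ effect_statistics(actor, candidate_net, attrs, z, ctx)
    )


@dataclass
class EvalCache:
    """Precomputed ministep-invariant pieces of the network objective.

    The homophily contributions (same-attribute indicators, centered age and
    income similarities) depend only on fixed covariates, so simulation
    loops precompute their combined weighted matrix once.
    """

    static: np.ndarray  # (N, N) combined dyadic homophily contribution
    b_deg: float
    b_rec: float
    b_ttip: float
    b_beh_ego: float
    b_beh_alter: float
    b_beh_sim: float


def make_eval_cache(
    attrs: ActorTable, params: EffectParameterSet, ctx: ModelContext
) -> EvalCache:
    n = attrs.n_actors
    b = dict(zip(NETWORK_EFFECTS, params.network_betas()))
    static = np.zeros((n, n))
    for name, key in (
        ("sex", "same_sex"),
        ("grade", "same_grade"),
        ("black", "same_black"),
        ("hispanic", "same_hispanic"),
    ):
        if b[key] != 0.0:
            a = attrs.column(name)
            static += b[key] * (a[:, None] == a[None, :])
    for name, key, sctx in (
        ("age", "age_similarity", ctx.age),
        ("income", "income_similarity", ctx.income),
    ):
        if b[key] != 0.0:
            v = attrs.column(name).astype(float)
            static += b[key] * (
                (1.0 - np.abs(v[:, None] - v[None, :]) / sctx.range_used) - sctx.sim_avg
            )
    return EvalCache(
        static,
        b["outdegree"],
        b["reciprocity"],
        b["transitive_triplets"],
        b["behavior_ego"],
        b["behavior_alter"],
        b["behavior_similarity"],
    )


def network_toggle_deltas(
    actor: int,
    net: np.ndarray,
    z: np.ndarray,
    ctx: ModelContext,
    cache: EvalCache,
) -> np.ndarray:
    """Objective change from toggling the ego's out-tie to each actor.

    Entry k is ``f(x with i->k toggled) - f(x)``; the self entry is ``-inf``
    (a self-tie is never a candidate).  The hot path of the simulator.
    """
    i = actor
    x = net.astype(float)
    row = x[i]
    zc = np.asarray(z, dtype=float) - ctx.z_avg

    contrib = cache.static[i] + cache.b_deg
    contrib = contrib + cache.b_rec * x[:, i]
    if cache.b_ttip != 0.0:
        # toggling i->k changes ego i's triplet count by
        # sum_h x_ih x_kh  (k as middle alter)  +  sum_j x_ij x_jk
        contrib = contrib + cache.b_ttip * (x @ row + row @ x)
    if cache.b_beh_ego != 0.0:
        contrib = contrib + cache.b_beh_ego * zc[i]
    if cache.b_beh_alter != 0.0:
        contrib = contrib + cache.b_beh_alter * zc
    if cache.b_beh_sim != 0.0:
        contrib = contrib + cache.b_beh_sim * (
            (1.0 - np.abs(z - z[i]) / ctx.behavior.range_used) - ctx.behavior.sim_avg
        )

    delta = (1.0 - 2.0 * row) * contrib  # sign: create +1, delete -1
    delta[i] = -np.inf
    return delta


def network_candidate_objectives(
    actor: int,
    net: np.ndarray,
    attrs: ActorTable,
    z: np.ndarray,
    params: EffectParameterSet,
    ctx: ModelContext,
    allowed: np.ndarray | None = None,
    cache: EvalCache | None = None,
):
    """Candidate actions and objective values for a network ministep.

    Candidates are ``KEEP`` plus each alter id whose out-tie the ego may
    toggle.  ``allowed`` (boolean over actors) restricts which *creations*
    are offered — used by the nomination cap; deletions are always offered.
    Objectives are reported relative to the current state (the choice rule
    is invariant to that shift).
    """
    n = _check_dims(net, attrs, z)
    if cache is None:
        cache = make_eval_cache(attrs, params, ctx)
    delta = network_toggle_deltas(actor, net, z, ctx, cache)
    row = net[actor]
    candidates = [k for k in range(n) if k != actor]
    if allowed is not None:
        candidates = [k for k in candidates if row[k] == 1 or allowed[k]]
    actions = [KEEP] + candidates
    objectives = np.concatenate(([0.0], delta[candidates]))
    return actions, objectives


def network_choice_probabilities(
    actor: int,
    net: np.ndarray,
    attrs: ActorTable,
    z: np.ndarray,
    params: EffectParameterSet,
    ctx: ModelContext,
    allowed: np.ndarray | None = None,
) -> ChoiceDistribution:
    """Choice distribution of a network ministep (keep + single-tie toggles)."""
    actions, objectives = network_candidate_objectives(
        actor, net, attrs, z, params, ctx, allowed
    )
    return choice_probabilities_from_objectives(actions, objectives)


def average_similarity(
    actor: int, z_actor: float, net: np.ndarray, z: np.ndarray, ctx: ModelContext
) -> float:
    """Mean centered behavior similarity between the ego and its alters.

    Defined as 0 for isolates (no alters): an ego without friends receives
    no peer-influence contribution, so only the shape terms drive its
    behavior choices.
    """
    row = net[actor]
    deg = row.sum()
    if deg == 0:
        return 0.0
    sims = (
        1.0 - np.abs(np.asarray(z, dtype=float) - z_actor) / ctx.behavior.range_used
    ) - ctx.behavior.sim_avg
    return float(row @ sims) / float(deg)


def behavior_objective(
    actor: int,
    z_candidate: int,
    net: np.ndarray,
    z: np.ndarray,
    params: EffectParameterSet,
    ctx: ModelContext,
) -> float:
    """Behavior objective: linear + quadratic shape plus average similarity.

    ``beta_lin*(z - z_avg) + beta_quad*(z - z_avg)^2 + beta_avsim * avsim``
    where ``avsim`` is the ego's mean centered similarity with its alters
    at the candidate value.
    """
    if not (ctx.z_min <= z_candidate <= ctx.z_max):
        raise InvalidChoiceError(
            f"behavior candidate {z_candidate} outside [{ctx.z_min}, {ctx.z_max}]"
        )
    zc = z_candidate - ctx.z_avg
    obj = params.beta_lin * zc + params.beta_quad * zc**2
    if params.beta_avsim != 0.0:
        obj += params.beta_avsim * average_similarity(actor, z_candidate, net, z, ctx)
    return float(obj)


def behavior_candidate_objectives(
    actor: int,
    net: np.ndarray,
    z: np.ndarray,
    params: EffectParameterSet,
    ctx: ModelContext,
):
    """Feasible behavior deltas (-1/0/+1 truncated at bounds) and objectives."""
    zi = int(z[actor])
    deltas = [d for d in (-1, 0, 1) if ctx.z_min <= zi + d <= ctx.z_max]
    objs = np.array(
        [behavior_objective(actor, zi + d, net, z, params, ctx) for d in deltas]
    )
    return deltas, objs


def behavior_choice_probabilities(
    actor: int,
    net: np.ndarray,
    z: np.ndarray,
    params: EffectParameterSet,
    ctx: ModelContext,
) -> ChoiceDistribution:
    """Choice distribution over the 2 or 3 feasible behavior moves."""
    deltas, objs = behavior_candidate_objectives(actor, net, z, params, ctx)
    return choice_probabilities_from_objectives(deltas, objs)
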