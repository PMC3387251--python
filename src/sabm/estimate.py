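"""Method-of-moments estimation by Robbins-Monro stochastic approximation.

The estimator matches observed target statistics (computed from the wave-2
state of a two-wave panel) to their simulated expectations under the model
started from wave 1.  Parameters are adjusted in three phases:

1. a crude derivative matrix D of expected targets with respect to the
   parameters, from finite differences with common random numbers;
2. iterative updates ``theta <- theta - a * diag(D)^-1 (simulated -
   observed)`` over subphases with geometrically decreasing gain, clipped
   steps, a derivative refresh at each subphase, and Polyak averaging of
   each subphase's tail (the diagonal update is far more robust to
   Monte-Carlo noise in D than the full Newton step);
3. evaluation runs at the final estimate, yielding convergence t-ratios
   (mean deviation / sd of simulated targets) and Monte-Carlo
   delta-method standard errors from the full finite-difference D.

Rate parameters are matched to Hamming-distance targets (number of tie
variables changed between waves; sum of absolute behavior changes); each
objective-function effect is matched to the wave-2 sum of its per-ego
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ModelContext, average_similarity, build_context, effect_statistics
from .datatypes import (
    ActorTable,
    BEHAVIOR_EFFECTS,
    BehaviorPanel,
    ConfigError,
    EffectParameterSet,
    EstimationError,
    InvalidStateError,
    NETWORK_EFFECTS,
    NetworkPanel,
    RATE_PARAMETERS,
)
from .simulate import simulate_period

ALL_EFFECTS = RATE_PARAMETERS + NETWORK_EFFECTS + BEHAVIOR_EFFECTS

# effects whose target degenerates when the underlying attribute is constant
_HOMOGENEITY_SENSITIVE = {
    "same_sex": "sex",
    "same_grade": "grade",
    "same_black": "black",
    "same_hispanic": "hispanic",
}


def total_network_statistics(
    net: np.ndarray, attrs: ActorTable, z: np.ndarray, ctx: ModelContext
) -> np.ndarray:
    """Sum of per-ego network effect statistics over all egos (vectorized)."""
    x = net.astype(float)
    n = x.shape[0]
    zc = np.asarray(z, dtype=float) - ctx.z_avg
    outdeg = x.sum(axis=1)

    stats = [x.sum(), (x * x.T).sum(), (x * (x @ x)).sum()]
    for name in ("sex", "grade", "black", "hispanic"):
        a = attrs.column(name)
        stats.append((x * (a[:, None] == a[None, :])).sum())
    for name, sctx in (("age", ctx.age), ("income", ctx.income)):
        v = attrs.column(name).astype(float)
        sims = (1.0 - np.abs(v[:, None] - v[None, :]) / sctx.range_used) - sctx.sim_avg
        stats.append((x * sims).sum())
    stats.append(float(outdeg @ zc))
    stats.append(float(x.sum(axis=0) @ zc))
    zz = np.asarray(z, dtype=float)
    bsims = (
        1.0 - np.abs(zz[:, None] - zz[None, :]) / ctx.behavior.range_used
    ) - ctx.behavior.sim_avg
    stats.append((x * bsims).sum())
    return np.array(stats)


def state_targets(
    effects: list[str],
    x1: np.ndarray,
    z1: np.ndarray,
    x0: np.ndarray,
    z0: np.ndarray,
    attrs: ActorTable,
    ctx: ModelContext,
) -> np.ndarray:
    """Target statistic vector for an end-of-period state ``(x1, z1)``.

    Rate targets are distances from the start-of-period state; effect
    targets are functions of the end state alone.
    """
    net_stats = None
    out = []
    for e in effects:
        if e == "rate_net":
            out.append(float(np.sum(x1 != x0)))
        elif e == "rate_beh":
            out.append(float(np.sum(np.abs(z1.astype(int) - z0.astype(int)))))
        elif e in NETWORK_EFFECTS:
            if net_stats is None:
                net_stats = total_network_statistics(x1, attrs, z1, ctx)
            out.append(float(net_stats[NETWORK_EFFECTS.index(e)]))
        elif e == "linear_shape":
            out.append(float(np.sum(z1 - ctx.z_avg)))
        elif e == "quadratic_shape":
            out.append(float(np.sum((z1 - ctx.z_avg) ** 2)))
        elif e == "average_similarity":
            out.append(
                float(
                    sum(
                        average_similarity(i, z1[i], x1, z1, ctx)
                        for i in range(x1.shape[0])
                    )
                )
            )
        else:
            raise ConfigError(f"unknown effect {e!r}")
    return np.array(out)


def observed_targets(
    net: NetworkPanel,
    beh: BehaviorPanel,
    attrs: ActorTable,
    effects: list[str],
    ctx: ModelContext | None = None,
) -> np.ndarray:
    """Observed target statistics of a two-wave panel, one per effect."""
    if net.n_waves != 2 or beh.values.shape[0] != 2:
        raise InvalidStateError("method-of-moments targets need exactly two waves")
    if ctx is None:
        ctx = build_context(attrs, beh)
    return state_targets(
        effects, net.waves[1], beh.values[1], net.waves[0], beh.values[0], attrs, ctx
    )


@dataclass
class FitConfig:
    """Tuning knobs of the three-phase stochastic approximation.

    Defaults suit a school-sized panel; the reduced settings used for
    simulation studies shrink every phase proportionally.
    """

    phase1_sims_per_side: int = 5
    fd_delta_beta: float = 0.75
    fd_delta_rate_frac: float = 0.2
    gain_a0: float = 0.2
    gain_halving: float = 2.0  # gain divided by this at each new subphase
    step_limit: float = 0.3  # per-iteration |step| cap, relative to 1 + |theta|
    phase2_iterations: tuple[int, ...] = (30, 60, 90, 120)
    phase3_sims: int = 500
    phase3_fd_sims_per_side: int = 4
    t_threshold: float = 0.15
    max_restarts: int = 1
    min_rate: float = 0.05

    def reduced(self) -> "FitConfig":
        """Desk-scale settings for replicate simulation studies."""
        return FitConfig(
            phase1_sims_per_side=4,
            phase2_iterations=(20, 40, 60, 90),
            phase3_sims=120,
            phase3_fd_sims_per_side=3,
            max_restarts=3,
        )


@dataclass
class EstimationResult:
    """Point estimates with convergence diagnostics and Monte-Carlo SEs."""

    effects: list[str]
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    t_ratios: dict[str, float]
    converged: bool
    observed: dict[str, float]
    simulated_means: dict[str, float]
    n_phase3: int
    seed: object
    dropped_effects: list[str] = field(default_factory=list)
    history: list[np.ndarray] = field(default_factory=list)
    deviation_history: list[np.ndarray] = field(default_factory=list)
    se_method: str = "monte_carlo_delta"

    def parameters(self) -> EffectParameterSet:
        known = {e: v for e, v in self.estimates.items()}
        return EffectParameterSet.from_dict(known)

    def to_dict(self) -> dict:
        """JSON-ready layout: effect name, estimate, SE, 95% CI, t-ratio."""
        rows = []
        for e in self.effects:
            est, se = self.estimates[e], self.standard_errors[e]
            rows.append(
                {
                    "effect": e,
                    "estimate": est,
                    "standard_error": se,
                    "ci95": [est - 1.96 * se, est + 1.96 * se],
                    "convergence_t_ratio": self.t_ratios[e],
                }
            )
        return {
            "effects": rows,
            "converged": self.converged,
            "n_phase3_simulations": self.n_phase3,
            "se_method": self.se_method,
            "dropped_effects": self.dropped_effects,
            "seed": self.seed,
        }


def _theta_to_params(
    effects: list[str], theta: np.ndarray, base: EffectParameterSet
) -> EffectParameterSet:
    return base.replace(**dict(zip(effects, theta)))


def drop_degenerate_effects(effects: list[str], attrs: ActorTable) -> tuple[list[str], list[str]]:
    """Remove homophily effects whose attribute is constant in the school.

    When everyone shares an attribute value the matching-tie statistic
    equals the out-degree in every state, so the effect is not separately
    identifiable (e.g. race homophily in a racially homogeneous school).
    """
    kept, dropped = [], []
    for e in effects:
        attr = _HOMOGENEITY_SENSITIVE.get(e)
        if attr is not None and attrs.is_constant(attr):
            dropped.append(e)
            warnings.warn(
                f"effect {e!r} dropped: attribute {attr!r} is constant in this "
                f"school, its statistic is collinear with outdegree",
                stacklevel=3,
            )
        else:
            kept.append(e)
    return kept, dropped


def _initial_theta(
    effects: list[str],
    obs_changes_net: float,
    obs_changes_beh: float,
    n: int,
    base: EffectParameterSet,
) -> np.ndarray:
    theta = []
    for e in effects:
        if e == "rate_net":
            theta.append(max(0.5, 1.5 * obs_changes_net / n))
        elif e == "rate_beh":
            theta.append(max(0.5, 1.5 * obs_changes_beh / n))
        elif e == "outdegree":
            theta.append(-1.0)
        else:
            theta.append(base.get(e))
    return np.array(theta)


def _fd_derivative(
    simulate_targets,
    effects: list[str],
    theta: np.ndarray,
    config: FitConfig,
    sims_per_side: int,
    seed_source: np.random.Generator,
) -> np.ndarray:
    """Finite-difference derivative of expected targets w.r.t. parameters.

    Common random numbers: the same seeds are used at theta+delta and
    theta-delta, so Monte-Carlo noise largely cancels in the difference.
    """
    p = len(effects)
    D = np.zeros((p, p))
    for k, e in enumerate(effects):
        if e in RATE_PARAMETERS:
            delta = max(config.fd_delta_rate_frac * abs(theta[k]), 0.1)
        else:
            delta = config.fd_delta_beta
        lo = np.array(theta)
        hi = np.array(theta)
        lo[k] -= delta
        hi[k] += delta
        if e in RATE_PARAMETERS:
            lo[k] = max(lo[k], config.min_rate)
        seeds = seed_source.integers(2**31, size=sims_per_side)
        plus = np.mean([simulate_targets(hi, int(s)) for s in seeds], axis=0)
        minus = np.mean([simulate_targets(lo, int(s)) for s in seeds], axis=0)
        D[:, k] = (plus - minus) / (hi[k] - lo[k])
    return D


def _solve(D: np.ndarray, v: np.ndarray, effects: list[str]) -> np.ndarray:
    if not np.all(np.isfinite(D)):
        raise EstimationError("derivative matrix contains non-finite entries")
    cond = np.linalg.cond(D)
    if not np.isfinite(cond) or cond > 1e10:
        # name the effects spanning the (near-)null space
        _, _, vt = np.linalg.svd(D)
        weights = np.abs(vt[-1])
        suspects = [effects[i] for i in np.argsort(weights)[::-1][:2]]
        raise EstimationError(
            f"derivative matrix is singular; collinear effects: {suspects}"
        )
    return np.linalg.solve(D, v)


def mc_standard_errors(
    phase3_targets: np.ndarray,
    derivative: np.ndarray,
    effects: list[str] | None = None,
) -> np.ndarray:
    """Monte-Carlo delta-method standard errors.

    ``phase3_targets`` is the (n_sims, p) array of simulated target vectors
    at the estimate; ``derivative`` the finite-difference matrix D.  The
    estimator covariance is ``D^-1 Sigma D^-T`` with Sigma the simulated
    target covariance (the observation is a single panel realization).
    """
    sims = np.asarray(phase3_targets, dtype=float)
    if sims.ndim != 2:
        raise EstimationError("phase-3 simulations must be a 2-D array")
    n3, p = sims.shape
    if effects is None:
        effects = [f"effect_{i}" for i in range(p)]
    if n3 < 100:
        raise EstimationError(
            f"phase-3 needs >= 100 simulations for standard errors, got {n3}"
        )
    variances = sims.var(axis=0, ddof=1)
    dead = [effects[i] for i in range(p) if variances[i] == 0.0]
    if dead:
        raise EstimationError(
            f"zero simulated-target variance for {dead}; the statistic does not "
            f"vary across simulated states"
        )
    sigma = np.cov(sims.T)
    if p == 1:
        sigma = sigma.reshape(1, 1)
    Dinv_sigma = _solve(derivative, sigma, effects)
    cov = _solve(derivative, Dinv_sigma.T, effects).T
    return np.sqrt(np.abs(np.diag(cov)))


def robbins_monro_fit(
    net: NetworkPanel,
    beh: BehaviorPanel,
    attrs: ActorTable,
    effects: list[str],
    config: FitConfig | None = None,
    rng: np.random.Generator | int = 0,
    init: EffectParameterSet | None = None,
    nomination_cap: bool = False,
) -> EstimationResult:
    """Fit the free effects of a two-wave panel by method of moments.

    ``effects`` lists the free parameters by canonical name (rates plus any
    network/behavior effects).  Returns point estimates, convergence
    t-ratios (flagged, not silent, when above threshold) and Monte-Carlo
    standard errors.  Seed-reproducible end to end.
    """
    if config is None:
        config = FitConfig()
    seed = rng if not isinstance(rng, np.random.Generator) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    unknown = [e for e in effects if e not in ALL_EFFECTS]
    if unknown:
        raise ConfigError(f"unknown effects: {unknown}")
    effects, dropped = drop_degenerate_effects(list(effects), attrs)

    ctx = build_context(attrs, beh)
    obs = observed_targets(net, beh, attrs, effects, ctx)
    x0, z0 = net.waves[0], beh.values[0]

    base = init if init is not None else EffectParameterSet()
    theta = _initial_theta(
        effects,
        float(np.sum(net.waves[1] != x0)),
        float(np.sum(np.abs(beh.values[1].astype(int) - z0.astype(int)))),
        net.n_actors,
        base,
    )
    rate_idx = [i for i, e in enumerate(effects) if e in RATE_PARAMETERS]

    def simulate_targets(th: np.ndarray, sim_seed: int) -> np.ndarray:
        params = _theta_to_params(effects, th, base)
        trace = simulate_period(
            x0, z0, attrs, params, ctx,
            np.random.default_rng(sim_seed),
            nomination_cap=nomination_cap, record_steps=False,
        )
        return state_targets(effects, trace.x1, trace.z1, x0, z0, attrs, ctx)

    history = [theta.copy()]
    deviation_history: list[np.ndarray] = []
    diag_history: list[np.ndarray] = []

    def run_phase2(theta: np.ndarray, iterations, subphase_offset: int) -> np.ndarray:
        # Robbins-Monro with a diagonal derivative: each target is matched
        # through its own parameter, which is robust to Monte-Carlo noise in
        # the off-diagonal derivative entries.  The diagonal is re-estimated
        # at each subphase and pooled across subphases to tame noise in
        # weakly-responding targets.  The gain is constant within a subphase
        # and halved across subphases (restarts continue the halving);
        # per-iteration steps are clipped, each subphase ends on a Polyak
        # average of its tail, and the final subphase averages its full path.
        for k, n_iter in enumerate(iterations):
            D = _fd_derivative(
                simulate_targets, effects, theta, config,
                config.phase1_sims_per_side, rng,
            )
            diag_history.append(np.abs(np.diag(D)))
            diag = np.mean(diag_history, axis=0)
            if np.any(diag < 1e-12):
                dead = [effects[i] for i in np.nonzero(diag < 1e-12)[0]]
                raise EstimationError(
                    f"targets do not respond to their own parameters: {dead}"
                )
            a = config.gain_a0 / config.gain_halving ** (subphase_offset + k)
            tail: list[np.ndarray] = []
            for _ in range(n_iter):
                sim = simulate_targets(theta, int(rng.integers(2**31)))
                deviation_history.append(sim - obs)
                step = a * (sim - obs) / diag
                lim = config.step_limit * (1.0 + np.abs(theta))
                theta = theta - np.clip(step, -lim, lim)
                for i in rate_idx:
                    theta[i] = max(theta[i], config.min_rate)
                history.append(theta.copy())
                tail.append(theta.copy())
            cut = 0 if k == len(iterations) - 1 else len(tail) // 2
            theta = np.mean(tail[cut:], axis=0)
        return theta

    iterations = config.phase2_iterations
    subphase_offset = 0
    for attempt in range(config.max_restarts + 1):
        theta = run_phase2(theta, iterations, subphase_offset)

        # phase 3: evaluation at the candidate estimate
        sims = np.array(
            [
                simulate_targets(theta, int(s))
                for s in rng.integers(2**31, size=config.phase3_sims)
            ]
        )
        dev = sims - obs
        sd = dev.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_ratios = np.where(sd > 0, dev.mean(axis=0) / sd, np.inf)
        converged = bool(np.all(np.abs(t_ratios) < config.t_threshold))
        if converged or attempt == config.max_restarts:
            break
        # not converged: continue with a shorter phase 2 from this point,
        # at gains that keep decreasing where the last subphase left off
        subphase_offset += len(iterations)
        iterations = tuple(max(10, it // 2) for it in iterations)

    D3 = _fd_derivative(
        simulate_targets, effects, theta, config, config.phase3_fd_sims_per_side, rng
    )
    ses = mc_standard_errors(sims, D3, effects)

    if not converged:
        warnings.warn(
            f"estimation not converged: max |t| = {np.max(np.abs(t_ratios)):.3f} "
            f"exceeds {config.t_threshold}",
            stacklevel=2,
        )

    return EstimationResult(
        effects=effects,
        estimates=dict(zip(effects, map(float, theta))),
        standard_errors=dict(zip(effects, map(float, ses))),
        t_ratios=dict(zip(effects, map(float, t_ratios))),
        converged=converged,
        observed=dict(zip(effects, map(float, obs))),
        simulated_means=dict(zip(effects, map(float, sims.mean(axis=0)))),
        n_phase3=config.phase3_sims,
        seed=seed,
        dropped_effects=dropped,
        history=history,
        deviation_history=deviation_history,
    )
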