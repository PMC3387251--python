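"""Fit a co-evolution model to a synthetic panel with known ground truth.

Generates a two-wave panel in which peer influence (average similarity) is
the only behavior mechanism, fits the model by method of moments, and
compares estimates with the generating parameters.  Takes a couple of
minutes at the reduced phase lengths.
"""

import warnings

from sabm import generate_panel, robbins_monro_fit
from sabm.estimate import FitConfig
from sabm.synth import BehaviorConfig, SchoolConfig
from sabm import EffectParameterSet

truth = EffectParameterSet(
    beta_deg=-2.5, beta_rec=2.0, beta_avsim=3.0, rate_net=3.0, rate_beh=2.0
)
config = SchoolConfig(
    n_actors=60,
    behavior=BehaviorConfig("index", 0, 6, "rounded_normal", (3.0, 1.5)),
    target_mean_outdegree=3.0,
    reciprocity_boost=1.5,
    homophily_weights={"same_sex": 0.3},
    ground_truth=truth,
    net_change_band=(1, None),
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    panel = generate_panel(config, seed=7)

effects = ["rate_net", "rate_beh", "outdegree", "reciprocity",
           "behavior_similarity", "average_similarity"]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = robbins_monro_fit(
        panel.network, panel.behavior, panel.actors, effects,
        FitConfig().reduced(), rng=1,
    )

print(f"converged: {result.converged} "
      f"(max |t| = {max(abs(t) for t in result.t_ratios.values()):.3f})\n")
print(f"{'effect':24s}{'truth':>8s}{'estimate':>10s}{'SE':>8s}")
for e in effects:
    print(f"{e:24s}{truth.get(e):8.2f}{result.estimates[e]:10.2f}"
          f"{result.standard_errors[e]:8.2f}")
print("\nA convergence t-ratio near 0 means the simulated moment matches the")
print("observed target; influence is recovered while homophily stays near 0.")
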