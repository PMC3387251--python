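"""Generate a synthetic two-wave school panel and summarize it.

The generator emulates a rural, racially homogeneous high school: directed
friendship nominations with reciprocity and homophily, an integer-coded BMI
behavior, and a second wave simulated one period forward under the
published parameter set (which ships with the panel as its ground truth).
"""

import numpy as np

from sabm import describe_panel, generate_panel, jefferson_like

panel = generate_panel(jefferson_like(n_actors=120), seed=42)
d = describe_panel(panel.actors, panel.network, panel.behavior)

print(f"N = {d.n_actors} students")
print(f"mean out-degree      {d.mean_outdegree:.2f} (sd {d.sd_outdegree:.2f})")
print(f"total ties (wave 1)  {d.total_ties}")
print(f"reciprocated ties    {d.mean_reciprocated_ties:.2f} per student")
print(f"transitive triplets  {d.mean_transitive_triplets:.2f} per student")
print(f"BMI mean {d.behavior_mean:.1f}, range {d.behavior_range}")
print(f"centered BMI avg. similarity {d.mean_average_similarity:+.3f} (near 0 by construction)")

x0, x1 = panel.network.waves
print(f"\nwave 1 -> wave 2: {int(np.sum(x1 != x0))} tie variables changed, "
      f"{int(np.abs(panel.behavior.values[1] - panel.behavior.values[0]).sum())} "
      f"behavior units moved")
print(f"ground-truth friendship rate: {panel.ground_truth.rate_net}")
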