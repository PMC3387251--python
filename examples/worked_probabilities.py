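"""Recompute the worked friendship-choice and BMI-change scenarios.

A student with two friends weighs four options (keep the network, drop
either tie, add a reciprocating heavier alter); a student at BMI 23 weighs
moving one unit down, staying, or moving one unit up — friendless, and with
two friends at BMI 30.  Probabilities come from exponentiating each
option's objective value and normalizing.
"""

from sabm import worked_examples

report = worked_examples()

print("Network ministep (4 candidates):")
for action, p in report["network"]["probabilities"].items():
    print(f"  {action:22s} p = {p:.3f}")
print("Most likely: drop the unreciprocated tie (p ~ 0.807).\n")

for key, label in (
    ("behavior_isolate", "BMI 23, no friends"),
    ("behavior_two_alters", "BMI 23, two friends at BMI 30"),
):
    block = report[key]
    print(f"Behavior ministep ({label}):")
    for d in (-1, 0, 1):
        print(
            f"  move {d:+d}: objective {float(block['objectives'][d]):7.3f}"
            f"  p = {float(block['probabilities_recomputed'][d]):.3f}"
        )
    print()

rev = report["behavior_reversed"]
print(
    "Reversed scenario (BMI 30, friends at 23): "
    f"p(down) = {rev['p_down']:.3f}, p(up) = {rev['p_up']:.3f}"
)
print("Heavier alters pull the ego up more strongly than leaner alters pull it down.")
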