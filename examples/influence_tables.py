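"""Predicted behavior-change probabilities by ego and alter levels.

For each behavior, every cell gives the probability that an ego at the row
level moves down one unit, stays, or moves up one unit when all of its
friends sit at the column level — computed from the published school
parameters.  "na" marks moves that are impossible at the coding bounds.
"""

from sabm import standard_influence_tables

for name, table in standard_influence_tables("jefferson").items():
    print(f"\n=== {name} ===")
    print(table.to_dataframe().to_string(index=False, na_rep="na"))

print(
    "\nReading: a student who played sports once or twice last week has a "
    "~75% chance\nof playing less if their friends play none — peer behavior "
    "pulls the ego toward it."
)
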