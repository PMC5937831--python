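"""Growth-trait percent-change contrasts.

Reproduces the published seedling-growth arithmetic: high temperature
suppresses every trait, and spraying spermidine recovers most of the
loss (half-up rounding to two decimals, the table convention).
"""

import pandas as pd

from spidmir.growth import GrowthTable

TABLE = [
    # treatment, plant height (cm), stem diameter (mm), leaf area (cm^2),
    # shoot fresh weight (g), dry weight (g)
    ("CW", 11.60, 5.93, 82.23, 14.99, 1.17),
    ("CS", 12.49, 6.31, 91.99, 16.58, 1.30),
    ("HW", 8.36, 5.41, 53.13, 11.83, 0.95),
    ("HS", 9.79, 5.87, 68.37, 13.56, 1.08),
]
TRAITS = ["height", "stem", "leaf_area", "fresh_weight", "dry_weight"]

rows = [
    {"treatment": t, "trait": trait, "mean": v, "sd": 0.0, "n": 8, "letter": ""}
    for t, *means in TABLE
    for trait, v in zip(TRAITS, means)
]
gt = GrowthTable(pd.DataFrame(rows))

print("effect of high temperature (CW -> HW):")
print(gt.contrast("CW", "HW").to_string())
print("\nrecovery by spermidine under heat (HW -> HS):")
print(gt.contrast("HW", "HS").to_string())
print("\nnegative = suppression by heat; positive = recovery after spraying.")
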