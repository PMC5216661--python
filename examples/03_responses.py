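"""Build the three response variables with the false-absence correction.

A patch is deemed unoccupied on an occasion only when two consecutive
surveys recorded zero individuals; an isolated zero between positive
counts is treated as a detection failure and kept occupied.
"""

import pandas as pd

from patchmeta import build_response_table, correct_false_absences

for counts in ([2, 0, 3], [2, 0, 0, 3], [0, 0, 0]):
    marks = ["occ" if o else "abs" for o in correct_false_absences(counts)]
    print(f"counts {counts} -> {marks}")

surveys = pd.DataFrame({
    "patch_id": "p1", "year": [1, 2, 3], "generation": "summer",
    "count": [0, 10, 20], "surveyed": True,
})
table = build_response_table(surveys, pd.DataFrame({"patch_id": ["p1"]}))
row = table.iloc[0]
print(f"\nsummer counts [0, 10, 20]:")
print(f"  occupancy fraction = {row['occupancy_fraction']:.2f} "
      "(the isolated zero is kept occupied)")
print(f"  mean abundance     = {row['mean_abundance']:.1f}")
print(f"  CV of abundance    = {row['cv_abundance']:.2f} "
      "(sample SD 10 over mean 10)")
print(f"  log(mean + 0.1)    = {row['log_mean']:.4f}")
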