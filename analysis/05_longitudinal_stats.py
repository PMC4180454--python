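#!/usr/bin/env python
"""Fit the three longitudinal model layers and report the headline findings.

* Joint bilateral volume mixed model (quadratic age, side contrasts b3-b5,
  side-specific variances) plus interval percent changes.
* Per-band functional models of length/radius/area with permutation global
  tests.
* Per-vertex directional shape models with BH-FDR maps, and the
  left-minus-flipped-right asymmetry analysis.

Writes volume_model.csv, interval_changes.csv, functional_*.csv,
shape_q_*.vtk, asymmetry_*.{vtk,csv} into the run directory.
"""

import pandas as pd

from common import get_config, stage

cfg = get_config()
stage("stats", cfg)
out = cfg.out_dir
print("== volume model (normalized scales) ==")
print(pd.read_csv(f"{out}/volume_model.csv").round(4).to_string(index=False))
print("\n== interval volume changes ==")
print(pd.read_csv(f"{out}/interval_changes.csv").round(2).to_string(index=False))
print("\n== functional global tests ==")
print(pd.read_csv(f"{out}/functional_global.csv").round(4).to_string(index=False))
print("\n== per-vertex shape effects ==")
print(pd.read_csv(f"{out}/shape_summary.csv").to_string(index=False))
print("\n== left - flipped-right asymmetry ==")
print(pd.read_csv(f"{out}/asymmetry_summary.csv").to_string(index=False))
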