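#!/usr/bin/env python
"""Compute mean-latitude-axis profiles (length, radius, area per band).

The medial curve of each corresponded surface is the chain of per-band mean
points over 100 equal-width colatitude bands, anterior tip first.  Writes
results/run/profiles.csv (tidy: one row per surface x band).
"""

import pandas as pd

from common import get_config, stage

cfg = get_config()
stage("morphometry", cfg)
prof = pd.read_csv(f"{cfg.out_dir}/profiles.csv")
total_len = prof.groupby(["age_days", "side"])["length"].sum().unstack()
print("mean total medial length (mm) by age:")
print((total_len / prof.groupby(["age_days", "side"])["subject"].nunique().unstack())
      .round(1).to_string())
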