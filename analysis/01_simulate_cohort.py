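#!/usr/bin/env python
"""Generate the default synthetic longitudinal cohort.

24 subjects, visits at 2 weeks then every 3 months in year one and every 6
months in year two, ~12 % missed visits, 1 mm isotropic masks for both
sides.  Writes NIfTI masks, the covariate table, and the ground-truth table
under results/run/masks/.
"""

from common import get_config, stage

cfg = get_config()
files = stage("simulate", cfg)
print("cohort written:")
for f in files:
    print("  ", f)
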