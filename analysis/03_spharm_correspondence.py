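#!/usr/bin/env python
"""Establish SPHARM-PDM correspondence across all surfaces.

Right-side masks are mirrored across the mid-sagittal plane first, every
surface is spherically parameterized (area-preserving map), expanded in real
spherical harmonics to degree 12, aligned by its first-order ellipsoid and
rigid Procrustes, and sampled at the shared 1002-site icosahedral grid.
Writes spharm_coeffs.json and pdm.npz into the run directory.
"""

import json
from pathlib import Path

from common import get_config, stage

cfg = get_config()
stage("spharm", cfg)
payload = json.loads((Path(cfg.out_dir) / "spharm_coeffs.json").read_text())
print(f"{len(payload['surfaces'])} surfaces corresponded at degree "
      f"{payload['degree']} (subdivision {cfg.subdivision}, "
      f"{10 * cfg.subdivision**2 + 2} points each)")
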