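"""Shared driver configuration for the numbered analysis scripts.

All scripts operate on one run directory (default ``results/run``) with one
global seed, so the whole analysis is reproduced by running the scripts in
order.  Pass ``--out`` / ``--seed`` / ``--subjects`` to override.
"""

from __future__ import annotations

import argparse

from lvshape.pipeline import RunConfig, run_pipeline


def get_config() -> RunConfig:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/run")
    ap.add_argument("--seed", type=int, default=20140929)
    ap.add_argument("--subjects", type=int, default=24)
    args = ap.parse_args()
    return RunConfig(out_dir=args.out, seed=args.seed, n_subjects=args.subjects)


def stage(name: str, cfg: RunConfig):
    run_pipeline(cfg, [name])
    import json
    from pathlib import Path

    manifest = json.loads((Path(cfg.out_dir) / "manifest.json").read_text())
    return sorted(manifest["stages"][name]["artifacts"])
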