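"""End-to-end pipeline orchestration.

Stages: ``simulate`` (or load user masks) -> ``preprocess`` -> ``spharm`` ->
``morphometry`` -> ``stats`` -> ``growth``.  Each stage reads its inputs from
the run directory and writes its artifacts back there, so any stage can be
re-run from cached upstream outputs.  A manifest (JSON) records the
configuration, per-stage seeds and SHA-256 checksums of every artifact.

One global seed fans out to per-stage seeds through ``numpy.random
.SeedSequence(seed).spawn``; ages are stored in days everywhere, months
appear only in presentation-level outputs (growth rates).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .correspondence import align
from .growth import growth_directions, render_growth_ellipsoids
from .harmonics import SpharmCoeffs, fit_spharm, icosphere_design, sample_pdm
from .masks import LabelMask, load_mask, regularize, resample_isotropic, save_mask
from .medial import mean_latitude_axis
from .meshing import extract_surface, mirror_sagittal
from .sphere import spherical_parameterize
from .stats import (
    fit_functional_model,
    fit_shape_lmm,
    fit_volume_model,
    interval_change,
    left_right_difference,
)
from .synthetic import CohortDesign, PopulationParams, generate_cohort
from .vtkio import write_vtk_polydata

STAGES = ("simulate", "preprocess", "spharm", "morphometry", "stats", "growth")


class PipelineError(RuntimeError):
    """Stage failure with the offending stage and item named."""


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str
    mode: str = "synthetic"  # or "masks"
    masks_csv: Optional[str] = None  # covariate table for mode="masks"
    # synthetic cohort
    n_subjects: int = 24
    visit_ages: Sequence[float] = (14, 91, 182, 274, 365, 548, 730)
    missingness_rate: float = 0.12
    voxel_spacing: float = 1.0
    # correspondence
    degree: int = 12
    subdivision: int = 10
    morph_subdivision: int = 36
    param_max_iter: int = 800
    anterior_axis: Sequence[float] = (0.0, 1.0, 0.0)
    superior_axis: Sequence[float] = (0.0, 0.0, 1.0)
    # statistics
    n_bands: int = 100
    fdr_q: float = 0.05
    n_permutations: int = 999
    target_spacing: float = 1.0
    seed: int = 20140929

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visit_ages"] = list(self.visit_ages)
        d["anterior_axis"] = list(self.anterior_axis)
        d["superior_axis"] = list(self.superior_axis)
        return d

    def stage_seed(self, stage: str) -> int:
        i = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[i]
        return int(child.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, run_dir: Path, config: RunConfig):
        self.path = run_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config": config.to_dict(), "stages": {}}
            self.data["config"] = config.to_dict()

    def record(self, stage: str, files: list, seed: int, elapsed: float) -> None:
        self.data["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(elapsed, 2),
            "artifacts": {
                str(Path(f).name): _sha256(Path(f)) for f in files if Path(f).exists()
            },
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _log(run_dir: Path, stage: str, message: str, **extra) -> None:
    entry = {"t": round(time.time(), 2), "stage": stage, "msg": message, **extra}
    with open(run_dir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> list:
    run_dir = Path(config.out_dir)
    mask_dir = run_dir / "masks"
    design = CohortDesign(
        n_subjects=config.n_subjects,
        visit_ages=tuple(config.visit_ages),
        missingness_rate=config.missingness_rate,
        voxel_spacing=config.voxel_spacing,
        seed=config.stage_seed("simulate"),
    )
    generate_cohort(design, PopulationParams(), out_dir=mask_dir)
    _log(run_dir, "simulate", "cohort generated", n_subjects=design.n_subjects)
    return [mask_dir / "covariates.csv", mask_dir / "truth.json",
            mask_dir / "missingness_draws.csv"]


def _covariates(config: RunConfig) -> pd.DataFrame:
    if config.mode == "synthetic":
        path = Path(config.out_dir) / "masks" / "covariates.csv"
    else:
        if not config.masks_csv or not Path(config.masks_csv).exists():
            raise PipelineError(f"preprocess: covariate table not found: {config.masks_csv}")
        path = Path(config.masks_csv)
    if not path.exists():
        raise PipelineError(f"preprocess: missing covariates table {path}")
    return pd.read_csv(path)


def stage_preprocess(config: RunConfig) -> list:
    run_dir = Path(config.out_dir)
    out = run_dir / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    cov = _covariates(config)
    rows = []
    for _, row in cov.iterrows():
        src = Path(row["path"])
        if not src.exists():
            raise PipelineError(f"preprocess: mask file missing: {src}")
        try:
            mask = load_mask(src)
            mask = resample_isotropic(mask, config.target_spacing)
            mask = regularize(mask)
        except Exception as exc:
            raise PipelineError(f"preprocess failed on {src.name}: {exc}") from exc
        dst = out / src.name
        save_mask(mask, dst)
        rows.append(
            dict(subject=row["subject"], age_days=row["visit_age_days"],
                 gender=row["gender"], side=row["side"],
                 volume_mm3=mask.volume_mm3, path=str(dst))
        )
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "volumes.csv", index=False)
    _log(run_dir, "preprocess", "masks regularized", n=len(table))
    return [run_dir / "volumes.csv"]


def stage_spharm(config: RunConfig) -> list:
    run_dir = Path(config.out_dir)
    table = pd.read_csv(run_dir / "volumes.csv")
    coeffs_list, meta = [], []
    for _, row in table.iterrows():
        src = Path(row["path"])
        try:
            mask = load_mask(src)
            if row["side"] == "right":
                # mirror across mid-sagittal plane BEFORE parameterization so
                # left and flipped-right share one correspondence
                mask = mirror_sagittal(mask)
            mesh = extract_surface(mask)
            param = spherical_parameterize(mesh, max_iter=config.param_max_iter)
            c = fit_spharm(mesh, param, config.degree)
        except Exception as exc:
            raise PipelineError(f"spharm failed on {src.name}: {exc}") from exc
        c.provenance = dict(subject=row["subject"], age_days=float(row["age_days"]),
                            gender=row["gender"], side=row["side"])
        coeffs_list.append(c)
        meta.append(c.provenance)
        _log(run_dir, "spharm", "parameterized", item=src.name,
             iterations=param.iterations, max_ratio=round(param.max_area_ratio, 3))
    aligned = align(
        coeffs_list,
        anterior_axis=np.asarray(config.anterior_axis, dtype=float),
        superior_axis=np.asarray(config.superior_axis, dtype=float),
        sample_subdivision=config.subdivision,
    )
    payload = {"degree": config.degree,
               "surfaces": [c.to_json_dict() for c in aligned]}
    (run_dir / "spharm_coeffs.json").write_text(json.dumps(payload))

    # sampled PDMs per side
    theta, phi, faces, _, _ = icosphere_design(config.subdivision, config.degree)
    arrays = {"theta": theta, "phi": phi, "faces": faces}
    cov_rows = {"left": [], "right": []}
    pdms = {"left": [], "right": []}
    for c, m in zip(aligned, meta):
        pdms[m["side"]].append(sample_pdm(c, config.subdivision).points)
        cov_rows[m["side"]].append(m)
    for side in ("left", "right"):
        arrays[f"W_{side}"] = np.stack(pdms[side])
        pd.DataFrame(cov_rows[side]).to_csv(run_dir / f"pdm_cov_{side}.csv", index=False)
    np.savez_compressed(run_dir / "pdm.npz", **arrays)
    return [run_dir / "spharm_coeffs.json", run_dir / "pdm.npz",
            run_dir / "pdm_cov_left.csv", run_dir / "pdm_cov_right.csv"]


def _load_aligned(run_dir: Path):
    payload = json.loads((run_dir / "spharm_coeffs.json").read_text())
    return [SpharmCoeffs.from_json_dict(d) for d in payload["surfaces"]]


def stage_morphometry(config: RunConfig) -> list:
    run_dir = Path(config.out_dir)
    aligned = _load_aligned(run_dir)
    frames = []
    for c in aligned:
        surf = sample_pdm(c, config.morph_subdivision)
        try:
            prof = mean_latitude_axis(surf, n_bands=config.n_bands)
        except Exception as exc:
            raise PipelineError(
                f"morphometry failed on {c.provenance}: {exc}"
            ) from exc
        df = prof.to_frame()
        for k in ("subject", "age_days", "gender", "side"):
            df[k] = c.provenance[k]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    cols = ["subject", "age_days", "gender", "side", "band", "position",
            "length", "radius", "area"]
    table[cols].to_csv(run_dir / "profiles.csv", index=False)
    _log(run_dir, "morphometry", "profiles computed", n_surfaces=len(aligned))
    return [run_dir / "profiles.csv"]


def stage_stats(config: RunConfig) -> list:
    run_dir = Path(config.out_dir)
    seed = config.stage_seed("stats")
    rng = np.random.default_rng(seed)
    outputs = []

    volumes = pd.read_csv(run_dir / "volumes.csv")
    vfit = fit_volume_model(volumes)
    vtab = vfit.to_frame()
    vtab.to_csv(run_dir / "volume_model.csv", index=False)
    (run_dir / "volume_model_meta.json").write_text(json.dumps({
        "random_intercept_var": vfit.random_intercept_var,
        "residual_var": vfit.residual_var,
        "loglik": vfit.loglik,
        "volume_mean": vfit.volume_mean,
        "volume_sd": vfit.volume_sd,
        "age_min": vfit.age_normalization.age_min,
        "age_max": vfit.age_normalization.age_max,
    }, indent=1))
    outputs += [run_dir / "volume_model.csv", run_dir / "volume_model_meta.json"]

    ages = sorted(config.visit_ages)
    a12 = min(ages, key=lambda a: abs(a - 365.0))  # visit nearest 12 months
    pairs = list(dict.fromkeys(
        [(ages[0], a12), (a12, ages[-1]), (ages[0], ages[1])]
    ))
    frames = []
    for t1, t2 in pairs:
        if t1 == t2:
            continue
        try:
            frames.append(interval_change(volumes, t1, t2))
        except Exception as exc:
            _log(run_dir, "stats", "interval change skipped",
                 t1=t1, t2=t2, reason=str(exc))
    if frames:
        ichanges = pd.concat(frames, ignore_index=True)
    else:
        ichanges = pd.DataFrame(
            columns=["side", "t1", "t2", "n", "mean_pct", "sd_pct", "t", "p"]
        )
    ichanges.to_csv(run_dir / "interval_changes.csv", index=False)
    outputs.append(run_dir / "interval_changes.csv")

    profiles = pd.read_csv(run_dir / "profiles.csv")
    func_rows, regional_frames = [], []
    for side in ("left", "right"):
        sub = profiles[profiles["side"] == side]
        for measure in ("length", "radius", "area"):
            ff = fit_functional_model(
                sub.dropna(subset=[measure]), measure,
                knots=np.asarray(ages, dtype=float),
                n_permutations=config.n_permutations,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            func_rows.append(dict(side=side, measure=measure,
                                  global_stat=ff.global_stat, global_p=ff.global_p))
            reg = ff.regional.copy()
            reg.insert(0, "side", side)
            reg.insert(1, "measure", measure)
            regional_frames.append(reg)
    pd.DataFrame(func_rows).to_csv(run_dir / "functional_global.csv", index=False)
    pd.concat(regional_frames, ignore_index=True).to_csv(
        run_dir / "functional_regional.csv", index=False
    )
    outputs += [run_dir / "functional_global.csv", run_dir / "functional_regional.csv"]

    pdm = np.load(run_dir / "pdm.npz")
    faces = pdm["faces"]
    shape_summary = []
    for side in ("left", "right"):
        W = pdm[f"W_{side}"]
        cov = pd.read_csv(run_dir / f"pdm_cov_{side}.csv")
        res = fit_shape_lmm(W, cov, fdr_q=config.fdr_q)
        mean_pts = W.mean(axis=0)
        point_data = {}
        for contrast in res.contrasts:
            qj = res.qvalues_joint[contrast]
            point_data[f"neglog10_q_{contrast}_joint"] = -np.log10(
                np.clip(qj, 1e-300, 1.0)
            )
            for k, d in enumerate("xyz"):
                qd = res.qvalues_direction[contrast][:, k]
                point_data[f"neglog10_q_{contrast}_{d}"] = -np.log10(
                    np.clip(qd, 1e-300, 1.0)
                )
            shape_summary.append(dict(
                side=side, contrast=contrast,
                n_vertices=len(qj),
                n_sig_joint=int((qj <= config.fdr_q).sum()),
                min_q=float(np.nanmin(qj)),
            ))
        write_vtk_polydata(run_dir / f"shape_q_{side}.vtk", mean_pts, faces, point_data)
        outputs.append(run_dir / f"shape_q_{side}.vtk")
    pd.DataFrame(shape_summary).to_csv(run_dir / "shape_summary.csv", index=False)
    outputs.append(run_dir / "shape_summary.csv")

    # left - flipped right asymmetry (right was mirrored before correspondence)
    cov_l = pd.read_csv(run_dir / "pdm_cov_left.csv")
    cov_r = pd.read_csv(run_dir / "pdm_cov_right.csv")
    res, used, n_excl = left_right_difference(
        pdm["W_left"], pdm["W_right"], cov_l, cov_r, fdr_q=config.fdr_q
    )
    _log(run_dir, "stats", "asymmetry analysis", n_pairs=len(used), excluded=n_excl)
    qj = res.qvalues_joint["age"]
    point_data = {"neglog10_q_age_joint": -np.log10(np.clip(qj, 1e-300, 1.0))}
    for k, d in enumerate("xyz"):
        qd = res.qvalues_direction["age"][:, k]
        point_data[f"neglog10_q_age_{d}"] = -np.log10(np.clip(qd, 1e-300, 1.0))
    write_vtk_polydata(
        run_dir / "asymmetry_q.vtk", pdm["W_left"].mean(axis=0), faces, point_data
    )
    asym = pd.DataFrame([dict(
        n_pairs=len(used), n_excluded=n_excl,
        n_sig_joint=int((qj <= config.fdr_q).sum()),
        min_q=float(np.nanmin(qj)),
    )])
    asym.to_csv(run_dir / "asymmetry_summary.csv", index=False)
    outputs += [run_dir / "asymmetry_q.vtk", run_dir / "asymmetry_summary.csv"]
    return outputs


def stage_growth(config: RunConfig) -> list:
    run_dir = Path(config.out_dir)
    pdm = np.load(run_dir / "pdm.npz")
    theta = pdm["theta"]
    outputs = []
    horn_frac = 0.15  # colatitude fraction at either pole counted as "horn"
    horn = (theta < horn_frac * np.pi) | (theta > (1 - horn_frac) * np.pi)
    rows = []
    for side in ("left", "right"):
        W = pdm[f"W_{side}"]
        cov = pd.read_csv(run_dir / f"pdm_cov_{side}.csv")
        field = growth_directions(W, cov)
        mean_pts = W.mean(axis=0)
        write_vtk_polydata(
            run_dir / f"growth_{side}.vtk", mean_pts, pdm["faces"],
            {"growth_rate": field.growth_rate,
             "principal_direction": field.principal_direction,
             "sv1": field.singular_values[:, 0],
             "sv2": field.singular_values[:, 1],
             "sv3": field.singular_values[:, 2]},
        )
        gv, gf, gr = render_growth_ellipsoids(field, mean_pts, subsample=10, scale=2.0)
        write_vtk_polydata(run_dir / f"growth_glyphs_{side}.vtk", gv, gf,
                           {"growth_rate": gr})
        rows.append(dict(
            side=side,
            horn_mean_rate=float(field.growth_rate[horn].mean()),
            midbody_mean_rate=float(field.growth_rate[~horn].mean()),
            n_vectors=field.n_vectors,
        ))
        outputs += [run_dir / f"growth_{side}.vtk", run_dir / f"growth_glyphs_{side}.vtk"]
    pd.DataFrame(rows).to_csv(run_dir / "growth_summary.csv", index=False)
    outputs.append(run_dir / "growth_summary.csv")
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "spharm": stage_spharm,
    "morphometry": stage_morphometry,
    "stats": stage_stats,
    "growth": stage_growth,
}


def run_pipeline(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Run the requested stages (default: all applicable) and return run dir."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES) if config.mode == "synthetic" else list(STAGES[1:])
    manifest = Manifest(run_dir, config)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage {stage!r}")
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, files, config.stage_seed(stage), time.time() - t0)
    return run_dir
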