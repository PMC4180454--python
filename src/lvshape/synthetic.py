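"""Synthetic longitudinal cohort of ventricle-like binary masks.

Each shape is a curved tube (a C-shaped arc mimicking a lateral-ventricle
body with anterior and posterior horns) with:

* a biphasic growth law, quadratic in age with its vertex at ``peak_age``,
  so volume rises over the first year and falls during the second — the
  growth law is conjugate to the quadratic-age fixed effects fitted by the
  statistical models;
* anterior-weighted lengthening (local length grows faster in the anterior
  half of the arc);
* posterior-weighted radius growth (a linear ramp over normalized arc
  position);
* a left > right size asymmetry (uniform scale factor on the left side);
* a gender effect as a bounded radius bump on the anterior 20 % of the arc
  of the *left* side only;
* smooth boundary jitter with standard deviation ``noise_sd`` mm.

Everything is deterministic given the declared seeds; regenerating with the
same configuration reproduces masks bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .masks import LabelMask, save_mask


class SyntheticError(ValueError):
    """Raised for degenerate generator configurations (e.g. self-intersection)."""


#: Nominal visit schedule in days: 2 weeks, then every 3 months in year one
#: and every 6 months in year two.
DEFAULT_VISIT_AGES = (14, 91, 182, 274, 365, 548, 730)

#: Total bend of the C-shaped centerline arc, radians.
ARC_ANGLE = 2.0

_ARC_SAMPLES = 400


def default_radius_profile(n: int = 40) -> np.ndarray:
    """Baseline tube radius (mm) over normalized arc position in [0, 1].

    Tapers toward both tips (horns) with a thicker mid-body.
    """
    s = np.linspace(0.0, 1.0, n)
    return 1.2 + 2.1 * np.sin(np.pi * s) ** 0.7


@dataclass
class GrowthTruth:
    """Ground-truth growth parameters for one subject/side."""

    subject_id: str
    side: str  # {"left", "right"}
    gender: str  # {"M", "F"}
    baseline_length: float = 40.0  # mm
    baseline_radius_profile: np.ndarray = field(default_factory=default_radius_profile)
    length_growth_amplitude: float = 0.32
    radius_growth_amplitude: float = 0.36
    peak_age: float = 450.0  # days; maximal volume age
    asymmetry_factor: float = 1.05  # left/right uniform scale
    gender_effect: float = 0.8  # mm radius bump, anterior 20 %, left side, gender M
    noise_sd: float = 0.25  # mm boundary jitter
    cross_section_ratio: float = 0.75  # left-right semi-axis / in-plane semi-axis
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_radius_profile = np.asarray(
            self.baseline_radius_profile, dtype=float
        )
        if self.side not in ("left", "right"):
            raise SyntheticError(f"side must be left/right, got {self.side!r}")
        if self.gender not in ("M", "F"):
            raise SyntheticError(f"gender must be M/F, got {self.gender!r}")
        if (self.baseline_radius_profile <= 0).any():
            raise SyntheticError("baseline_radius_profile must be strictly positive")
        if self.peak_age <= 0:
            raise SyntheticError("peak_age must be positive")
        if not 0.2 <= self.cross_section_ratio <= 1.0:
            raise SyntheticError("cross_section_ratio must be in [0.2, 1]")

    def growth_factor(self, age_days: float) -> float:
        """Biphasic multiplier q(age) in [0, 1]: 0 at age 0, 1 at peak_age."""
        return max(0.0, 1.0 - ((age_days - self.peak_age) / self.peak_age) ** 2)

    def scale(self) -> float:
        """Side-specific uniform scale (asymmetry applied to the left)."""
        return self.asymmetry_factor if self.side == "left" else 1.0

    # -- analytic geometry ------------------------------------------------

    def arc_length(self, age_days: float) -> float:
        return (
            self.baseline_length
            * (1.0 + self.length_growth_amplitude * self.growth_factor(age_days))
            * self.scale()
        )

    def _length_density(self, s: np.ndarray, age_days: float) -> np.ndarray:
        """Relative local-length growth density: anterior-weighted ramp, mean 1."""
        q = self.growth_factor(age_days)
        w = 1.6 - 1.2 * s  # anterior (s=0) grows fastest; mean over [0,1] is 1
        return (1.0 + self.length_growth_amplitude * q * w) / (
            1.0 + self.length_growth_amplitude * q
        )

    def radius_at(self, s: np.ndarray, age_days: float) -> np.ndarray:
        """Tube radius r(s, age) in mm, posterior-weighted growth plus gender bump."""
        s = np.asarray(s, dtype=float)
        grid = np.linspace(0.0, 1.0, len(self.baseline_radius_profile))
        r0 = np.interp(s, grid, self.baseline_radius_profile)
        q = self.growth_factor(age_days)
        w = 0.4 + 1.2 * s  # posterior ramp, mean 1 over [0, 1]
        r = r0 * (1.0 + self.radius_growth_amplitude * q * w)
        if self.side == "left" and self.gender == "M" and self.gender_effect != 0.0:
            r = r + self.gender_effect * np.exp(-(((s - 0.10) / 0.06) ** 2))
        return r * self.scale()

    def centerline(self, age_days: float, n: int = _ARC_SAMPLES):
        """Centerline points (n, 3) in mm and arc positions s in [0, 1].

        The arc lies in a parasagittal plane at |x| = 10 mm (left at x < 0 in
        RAS), bowing superiorly; s = 0 is the anterior tip (+y), s = 1 the
        posterior tip (-y).
        """
        L = self.arc_length(age_days)
        R_arc = L / ARC_ANGLE
        s = np.linspace(0.0, 1.0, n)
        dens = self._length_density(s, age_days)
        u = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(s))])
        u = u / u[-1]  # warped arc fraction, anterior-weighted in time
        alpha = ARC_ANGLE * (0.5 - u)
        x = np.full(n, -10.0 if self.side == "left" else 10.0) * self.scale()
        y = R_arc * np.sin(alpha)
        z = R_arc * (np.cos(alpha) - np.cos(ARC_ANGLE / 2.0))
        rmax = float(self.radius_at(s, age_days).max())
        if rmax >= 0.85 * R_arc:
            raise SyntheticError(
                f"degenerate geometry: max tube radius {rmax:.2f} mm reaches the "
                f"centerline bend radius {R_arc:.2f} mm (self-intersection)"
            )
        return np.column_stack([x, y, z]), s

    def predicted_band_profiles(self, age_days: float, n_bands: int = 100) -> dict:
        """Analytic radius/area/length profiles in mean-latitude band coordinates.

        An area-preserving spherical parameterization assigns colatitude so
        that the spherical-cap area fraction F(theta) = (1 - cos theta)/2
        matches the cumulative surface-area fraction along the tube.  Equal-
        width colatitude bands therefore correspond to windows of the arc
        whose boundaries sit at fixed cumulative-area fractions; this method
        evaluates the generator's ground-truth geometry in exactly those
        coordinates, giving the profile the morphometry stage *should*
        measure (up to voxelization and jitter).
        """
        n = 4000
        s = np.linspace(0.0, 1.0, n)
        pts, _ = self.centerline(age_days, n=n)
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        r = self.radius_at(s, age_days)
        r_mid = 0.5 * (r[1:] + r[:-1])
        a_dens = r_mid * dl  # lateral-area density per segment
        F = np.concatenate([[0.0], np.cumsum(a_dens)])
        F /= F[-1]
        arc = np.concatenate([[0.0], np.cumsum(dl)])
        theta_edges = np.linspace(0.0, np.pi, n_bands + 1)
        F_edges = 0.5 * (1.0 - np.cos(theta_edges))
        s_edges = np.interp(F_edges, F, s)
        arc_edges = np.interp(F_edges, F, arc)
        s_centers = 0.5 * (s_edges[:-1] + s_edges[1:])
        r_band = self.radius_at(s_centers, age_days)
        return {
            "radius": r_band,
            "area": np.pi * self.cross_section_ratio * r_band**2,
            "length": np.diff(arc_edges),
        }

    def analytic_volume(self, age_days: float) -> float:
        """Tube volume integral pi * r(s)^2 dl along the centerline, mm^3."""
        pts, s = self.centerline(age_days, n=2000)
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        r = self.radius_at(s, age_days)
        r2mid = 0.5 * (r[1:] ** 2 + r[:-1] ** 2)
        return float(np.pi * self.cross_section_ratio * (r2mid * dl).sum())


@dataclass
class CohortDesign:
    """Design of the longitudinal cohort."""

    n_subjects: int = 24
    visit_ages: Sequence[float] = DEFAULT_VISIT_AGES
    missingness_rate: float = 0.12
    voxel_spacing: float = 1.0
    seed: int = 20140929

    def __post_init__(self) -> None:
        ages = np.asarray(self.visit_ages, dtype=float)
        if not (np.diff(ages) > 0).all():
            raise SyntheticError("visit_ages must be strictly increasing")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise SyntheticError("missingness_rate must be in [0, 1)")
        if self.voxel_spacing <= 0:
            raise SyntheticError("voxel_spacing must be positive")
        self.visit_ages = tuple(float(a) for a in ages)


@dataclass
class PopulationParams:
    """Between-subject variability of the growth parameters."""

    baseline_length_mean: float = 40.0
    baseline_length_sd: float = 3.0
    length_amplitude_mean: float = 0.32
    radius_amplitude_mean: float = 0.36
    amplitude_rel_sd: float = 0.20
    peak_age_mean: float = 450.0
    peak_age_sd: float = 30.0
    asymmetry_mean: float = 1.05
    asymmetry_sd: float = 0.02
    gender_effect: float = 0.8
    noise_sd: float = 0.25


def _noise_field(truth: GrowthTruth, age_days: float, s: np.ndarray) -> np.ndarray:
    """Smooth radius jitter (mm) along arc position; deterministic per (truth, age)."""
    if truth.noise_sd == 0.0:
        return np.zeros_like(s)
    rng = np.random.default_rng(
        [truth.seed, int(round(age_days)), 0 if truth.side == "left" else 1]
    )
    raw = rng.standard_normal(64)
    smooth = gaussian_filter1d(raw, sigma=3.0, mode="wrap")
    smooth -= smooth.mean()  # jitter must not shift mean radius
    smooth *= truth.noise_sd / smooth.std()
    return np.interp(s, np.linspace(0, 1, 64), smooth)


def generate_shape(
    truth: GrowthTruth, age_days: float, voxel_spacing: float = 1.0
) -> LabelMask:
    """Voxelize the ventricle-like tube for one subject/side at one age.

    Deterministic given (truth, age): two calls return bit-identical masks.
    The voxel grid is symmetric about the mid-sagittal plane x = 0 so that
    mirroring is exact at the voxel level.
    """
    if age_days < 0:
        raise SyntheticError("age must be nonnegative")
    pts, s = truth.centerline(age_days)
    r = truth.radius_at(s, age_days) + _noise_field(truth, age_days, s)
    if (r <= 0).any():
        raise SyntheticError("noise drove tube radius nonpositive")
    margin = float(r.max()) + 2.0 * voxel_spacing
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    # snap grid so that voxel centers sit at (i + 1/2) * spacing offsets from 0,
    # symmetric under x -> -x
    lo = (np.floor(lo / voxel_spacing - 0.5) + 0.5) * voxel_spacing
    n_vox = np.ceil((hi - lo) / voxel_spacing).astype(int) + 1
    axes = [lo[d] + voxel_spacing * np.arange(n_vox[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(pts)
    dist, idx = tree.query(grid, workers=-1)
    # elliptical cross-section: narrower along x (left-right) than in-plane
    dvec = grid - pts[idx]
    dx2 = dvec[:, 0] ** 2
    dperp2 = np.maximum(dist**2 - dx2, 0.0)
    cr = truth.cross_section_ratio
    inside = dx2 / (cr * r[idx]) ** 2 + dperp2 / r[idx] ** 2 <= 1.0
    vox = inside.reshape(tuple(n_vox))
    if not vox.any():
        raise SyntheticError("voxelization produced an empty mask")
    affine = np.eye(4)
    affine[:3, :3] *= voxel_spacing
    affine[:3, 3] = lo
    return LabelMask(vox, affine)


# ---------------------------------------------------------------------------
# Model-level panel simulators (for estimator calibration at known truth)
# ---------------------------------------------------------------------------


def _panel_index(n_subjects, visit_ages, missingness, rng):
    subjects, ages = [], []
    for i in range(n_subjects):
        for a in visit_ages:
            if missingness > 0 and rng.random() < missingness:
                continue
            subjects.append(f"S{i + 1:03d}")
            ages.append(float(a))
    return np.asarray(subjects), np.asarray(ages)


def simulate_volume_panel(
    beta=(0.0, 3.0, -2.0, -0.3, -0.2, 0.3),
    sigma_b=(0.6, 0.5),
    sigma_e=(0.35, 0.30),
    n_subjects: int = 24,
    visit_ages=DEFAULT_VISIT_AGES,
    missingness: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate bilateral volumes from the joint quadratic-age mixed model.

    ``beta`` = (b0, b1, b2, b3, b4, b5) on the normalized-age scale (age
    mapped to [0, 1] over the visit range); ``sigma_b``/``sigma_e`` are
    (left, right) random-intercept and residual SDs.  Returns a tidy frame
    with columns ``subject, age_days, side, volume_mm3``.
    """
    rng = rng or np.random.default_rng(0)
    beta = np.asarray(beta, dtype=float)
    lo, hi = min(visit_ages), max(visit_ages)
    rows = []
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        b_side = {"left": rng.normal(0, sigma_b[0]), "right": rng.normal(0, sigma_b[1])}
        for a in visit_ages:
            if missingness > 0 and rng.random() < missingness:
                continue
            an = (a - lo) / (hi - lo)
            for si, side in enumerate(("left", "right")):
                mean = beta[0] + beta[1] * an + beta[2] * an**2 + si * (
                    beta[3] + beta[4] * an + beta[5] * an**2
                )
                v = mean + b_side[side] + rng.normal(0, sigma_e[si])
                rows.append(dict(subject=sid, age_days=float(a), side=side, volume_mm3=v))
    return pd.DataFrame(rows)


def simulate_profile_panel(
    n_subjects: int = 24,
    visit_ages=DEFAULT_VISIT_AGES,
    n_bands: int = 100,
    effect=None,
    sigma_b: float = 1.0,
    sigma_e: float = 0.5,
    measure: str = "length",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate per-band medial-profile measurements with a random intercept.

    ``effect(position, age_days)`` (vectorized over positions) adds a fixed
    age-by-location signal; ``effect=None`` simulates the null.  Returns a
    tidy frame ``subject, age_days, band, <measure>``.
    """
    rng = rng or np.random.default_rng(0)
    subjects, ages = _panel_index(n_subjects, visit_ages, 0.0, rng)
    pos = np.arange(n_bands) / max(n_bands - 1, 1)
    frames = []
    for sid in np.unique(subjects):
        sel = subjects == sid
        b = rng.normal(0, sigma_b)
        for a in ages[sel]:
            val = b + rng.normal(0, sigma_e, n_bands)
            if effect is not None:
                val = val + effect(pos, a)
            frames.append(
                pd.DataFrame(
                    {"subject": sid, "age_days": a, "band": np.arange(n_bands),
                     measure: val}
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_shape_panel(
    n_subjects: int = 24,
    visit_ages=DEFAULT_VISIT_AGES,
    n_vertices: int = 162,
    sigma_b: float = 0.5,
    sigma_e: float = 0.3,
    age_slope: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate vertex coordinate stacks W (n_obs, V, 3) with random intercepts.

    Under the null (``age_slope=None``) no vertex moves with age or gender;
    otherwise ``age_slope`` (V, 3) adds a linear normalized-age displacement.
    Returns ``(W, covariates)``.
    """
    rng = rng or np.random.default_rng(0)
    subjects, ages = _panel_index(n_subjects, visit_ages, 0.0, rng)
    lo, hi = min(visit_ages), max(visit_ages)
    an = (ages - lo) / (hi - lo)
    n_obs = len(subjects)
    uniq = np.unique(subjects)
    b = {s: rng.normal(0, sigma_b, (n_vertices, 3)) for s in uniq}
    W = np.empty((n_obs, n_vertices, 3))
    for i in range(n_obs):
        W[i] = b[subjects[i]] + rng.normal(0, sigma_e, (n_vertices, 3))
        if age_slope is not None:
            W[i] += an[i] * np.asarray(age_slope)
    genders = {s: ("M" if rng.random() < 0.5 else "F") for s in uniq}
    cov = pd.DataFrame(
        dict(subject=subjects, age_days=ages,
             gender=[genders[s] for s in subjects])
    )
    return W, cov


def _truth_to_json(t: GrowthTruth) -> dict:
    d = asdict(t)
    d["baseline_radius_profile"] = list(map(float, t.baseline_radius_profile))
    return d


def generate_cohort(
    design: CohortDesign,
    population: Optional[PopulationParams] = None,
    out_dir=None,
):
    """Generate masks, a covariate table, and a ground-truth table.

    Returns ``(covariates, truths, retained_draws)`` where *covariates* is a
    DataFrame with columns ``subject, visit_age_days, gender, side, path``
    (path empty if ``out_dir`` is None, in which case masks are kept in
    memory in the extra column ``mask``), *truths* maps (subject, side) ->
    :class:`GrowthTruth`, and *retained_draws* records the Bernoulli
    missingness draws per (subject, visit) for exact replay.

    When ``out_dir`` is given, one NIfTI per subject/visit/side is written
    plus ``covariates.csv`` and ``truth.json``.
    """
    population = population or PopulationParams()
    rng = np.random.default_rng(design.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise SyntheticError(f"cannot create output directory {out_dir}: {exc}")

    truths: dict[tuple[str, str], GrowthTruth] = {}
    rows = []
    draw_records = []
    for i in range(design.n_subjects):
        sid = f"S{i + 1:03d}"
        gender = "M" if rng.random() < 0.5 else "F"
        base_len = rng.normal(population.baseline_length_mean, population.baseline_length_sd)
        amp_l = population.length_amplitude_mean * (
            1.0 + population.amplitude_rel_sd * rng.standard_normal()
        )
        amp_r = population.radius_amplitude_mean * (
            1.0 + population.amplitude_rel_sd * rng.standard_normal()
        )
        peak = rng.normal(population.peak_age_mean, population.peak_age_sd)
        asym = rng.normal(population.asymmetry_mean, population.asymmetry_sd)
        subj_seed = int(rng.integers(0, 2**31 - 1))
        for side in ("left", "right"):
            truths[(sid, side)] = GrowthTruth(
                subject_id=sid,
                side=side,
                gender=gender,
                baseline_length=float(np.clip(base_len, 25.0, 60.0)),
                length_growth_amplitude=float(max(amp_l, 0.0)),
                radius_growth_amplitude=float(max(amp_r, 0.0)),
                peak_age=float(np.clip(peak, design.visit_ages[1], design.visit_ages[-1])),
                asymmetry_factor=float(max(asym, 0.9)),
                gender_effect=population.gender_effect,
                noise_sd=population.noise_sd,
                seed=subj_seed,
            )
        # missingness draws are per subject/visit (a missed appointment drops
        # both sides), recorded so a re-run replays the exact same panel
        for age in design.visit_ages:
            draw = float(rng.random())
            missing = draw < design.missingness_rate
            draw_records.append(
                {"subject": sid, "visit_age_days": age, "draw": draw, "missing": missing}
            )
            if missing:
                continue
            for side in ("left", "right"):
                truth = truths[(sid, side)]
                mask = generate_shape(truth, age, design.voxel_spacing)
                if out_dir is not None:
                    path = out_dir / f"{sid}_{int(age):04d}d_{side}.nii.gz"
                    save_mask(mask, path)
                    rows.append(
                        dict(subject=sid, visit_age_days=age, gender=gender,
                             side=side, path=str(path))
                    )
                else:
                    rows.append(
                        dict(subject=sid, visit_age_days=age, gender=gender,
                             side=side, path="", mask=mask)
                    )
    covariates = pd.DataFrame(rows)
    draws = pd.DataFrame(draw_records)
    if out_dir is not None:
        covariates.to_csv(out_dir / "covariates.csv", index=False)
        truth_payload = {
            "design": {
                "n_subjects": design.n_subjects,
                "visit_ages": list(design.visit_ages),
                "missingness_rate": design.missingness_rate,
                "voxel_spacing": design.voxel_spacing,
                "seed": design.seed,
            },
            "subjects": {f"{k[0]}_{k[1]}": _truth_to_json(v) for k, v in truths.items()},
        }
        (out_dir / "truth.json").write_text(json.dumps(truth_payload, indent=1))
        draws.to_csv(out_dir / "missingness_draws.csv", index=False)
    return covariates, truths, draws
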