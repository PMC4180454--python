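"""Longitudinal statistical layers.

Three models mirror the analysis design:

1. **Joint bilateral volume model.**  With side coded 0 (left) / 1 (right)
   and normalized age ``a``,

       V_ij = b0 + b1 a + b2 a^2 + b3 side + b4 side*a + b5 side*a^2
              + u_i^(side) + e_ij^(side),

   where the random-intercept and residual variances are side-specific.
   Since random effects and residuals are independent across sides and each
   side has its own fixed-effect combination, the joint maximum likelihood
   factorizes into the two per-side fits; the b3..b5 contrasts and their
   standard errors are assembled exactly from those.

2. **Point-wise functional model of medial profiles.**  Per colatitude band,
   a random-intercept model with a piecewise-linear age basis (one slope per
   inter-visit interval, knots at the nominal visit ages).  Regional tests
   are per-band per-interval Wald tests; the global test per measure is a
   sup-Wald statistic over bands computed from the within-subject
   (subject-demeaned) estimator, calibrated by permuting observed ages
   within subject — exchangeable under the null of no age effect.

3. **Per-vertex directional shape model.**  For each corresponded vertex and
   direction k in {x, y, z},

       W_ijk = mu_k + g1k Gender + g2k Age + g3k Age^2 + g4k Gender*Age
               + b_ik + e_ijk,

   with direction-specific random-intercept and residual variances; W is
   centered per vertex/direction and age (in days) normalized before
   fitting.  Direction-agnostic tests combine the per-direction Wald
   chi-squares (the directions are independent channels); vertex-wise
   p-values are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lmm import LMMError, LMMFit, fit_random_intercept


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, adjusted)`` where adjusted values are the usual
    monotone step-up q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise StatsError("bh_fdr: empty p-value list")
    if not 0.0 < q < 1.0:
        raise StatsError(f"bh_fdr: q must be in (0, 1), got {q}")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise StatsError("bh_fdr: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= q
    return reject.reshape(np.shape(pvalues)), adjusted.reshape(np.shape(pvalues))


# ---------------------------------------------------------------------------
# Normalization helpers
# ---------------------------------------------------------------------------


@dataclass
class AgeNormalization:
    """Affine map of age in days onto [0, 1] over the observed range."""

    age_min: float
    age_max: float

    @classmethod
    def from_ages(cls, ages) -> "AgeNormalization":
        ages = np.asarray(ages, dtype=float)
        return cls(float(ages.min()), float(ages.max()))

    def __call__(self, ages) -> np.ndarray:
        span = max(self.age_max - self.age_min, 1e-12)
        return (np.asarray(ages, dtype=float) - self.age_min) / span


# ---------------------------------------------------------------------------
# 1. Joint bilateral volume model
# ---------------------------------------------------------------------------

VOLUME_TERMS = ("intercept", "age", "age2", "side", "side_age", "side_age2")


@dataclass
class VolumeModelFit:
    """Joint bilateral volumetric mixed-model fit (normalized scales)."""

    beta: np.ndarray  # (6,) b0..b5
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    random_intercept_var: dict  # side -> sigma_b^2
    residual_var: dict  # side -> sigma_e^2
    loglik: float
    age_normalization: AgeNormalization
    volume_mean: float
    volume_sd: float
    n_obs: int
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(term=VOLUME_TERMS, beta=self.beta, se=self.se,
                 z=self.zvalues, p=self.pvalues)
        )

    @property
    def beta_raw(self) -> np.ndarray:
        """Coefficients mapped back to the input volume scale (age stays
        normalized): undoes the z-scoring of the response."""
        b = self.beta * self.volume_sd
        b[0] += self.volume_mean
        return b

    @property
    def se_raw(self) -> np.ndarray:
        return self.se * self.volume_sd


def _side_design(age_n: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(age_n), age_n, age_n**2])


def fit_volume_model(cohort: pd.DataFrame) -> VolumeModelFit:
    """Fit the joint bilateral volume model.

    ``cohort`` needs columns ``subject, age_days, side, volume_mm3`` with
    side in {"left", "right"}.  Age is normalized to [0, 1] over the observed
    range and volume z-scored before fitting (recorded in the result).
    """
    required = {"subject", "age_days", "side", "volume_mm3"}
    if not required.issubset(cohort.columns):
        raise StatsError(f"cohort table needs columns {sorted(required)}")
    sides = set(cohort["side"])
    if sides != {"left", "right"}:
        raise StatsError(f"both sides required, got {sorted(sides)}")
    if cohort["subject"].nunique() < 2:
        raise StatsError("volume model needs at least two subjects")
    norm = AgeNormalization.from_ages(cohort["age_days"])
    vmean = float(cohort["volume_mm3"].mean())
    vsd = float(cohort["volume_mm3"].std(ddof=0))
    if vsd == 0:
        raise StatsError("volumes have zero variance")

    per_side: dict[str, LMMFit] = {}
    for side in ("left", "right"):
        sub = cohort[cohort["side"] == side]
        if sub["subject"].nunique() < 2:
            raise StatsError(f"side {side!r} observed in fewer than two subjects")
        X = _side_design(norm(sub["age_days"]))
        y = (sub["volume_mm3"].to_numpy() - vmean) / vsd
        per_side[side] = fit_random_intercept(X, sub["subject"].to_numpy(), y)

    bl = per_side["left"].beta[0]
    br = per_side["right"].beta[0]
    vl = np.diag(per_side["left"].cov[0])
    vr = np.diag(per_side["right"].cov[0])
    beta = np.concatenate([bl, br - bl])
    var = np.concatenate([vl, vr + vl])
    se = np.sqrt(var)
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return VolumeModelFit(
        beta=beta,
        se=se,
        zvalues=z,
        pvalues=p,
        random_intercept_var={s: float(per_side[s].sigma_b2[0]) for s in per_side},
        residual_var={s: float(per_side[s].sigma_e2[0]) for s in per_side},
        loglik=float(sum(f.loglik[0] for f in per_side.values())),
        age_normalization=norm,
        volume_mean=vmean,
        volume_sd=vsd,
        n_obs=len(cohort),
        n_subjects=cohort["subject"].nunique(),
    )


def interval_change(
    cohort: pd.DataFrame, t1: float, t2: float, tol_days: float = 45.0
) -> pd.DataFrame:
    """Per-side percent volume change between two nominal visit ages.

    Per subject: 100 * (V(t2) - V(t1)) / V(t1), using the visit nearest each
    nominal age within ``tol_days``.  Returns one row per side with mean, sd,
    n and a two-sided one-sample t test of the changes against zero.
    """
    rows = []
    for side, sub in cohort.groupby("side"):
        changes = []
        for _, s in sub.groupby("subject"):
            ages = s["age_days"].to_numpy(dtype=float)
            i1 = np.abs(ages - t1).argmin()
            i2 = np.abs(ages - t2).argmin()
            if abs(ages[i1] - t1) > tol_days or abs(ages[i2] - t2) > tol_days:
                continue
            v1 = float(s["volume_mm3"].to_numpy()[i1])
            v2 = float(s["volume_mm3"].to_numpy()[i2])
            changes.append(100.0 * (v2 - v1) / v1)
        if len(changes) < 3:
            raise StatsError(
                f"side {side!r}: fewer than 3 subjects observed at both "
                f"{t1} and {t2} days"
            )
        changes = np.asarray(changes)
        sd = float(changes.std(ddof=1))
        if sd == 0.0:
            stat, p = 0.0 if changes.mean() == 0 else np.inf, 1.0 if changes.mean() == 0 else 0.0
        else:
            stat, p = sps.ttest_1samp(changes, 0.0)
        rows.append(
            dict(side=side, t1=t1, t2=t2, n=len(changes),
                 mean_pct=float(changes.mean()), sd_pct=sd,
                 t=float(stat), p=float(p))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2. Functional (point-wise) model of medial profiles
# ---------------------------------------------------------------------------


def piecewise_age_basis(ages_days, knots) -> np.ndarray:
    """Design [1, s_1, ..., s_K]: accumulated time within each knot interval.

    The coefficient of column k is the growth slope (per day) between knots
    k-1 and k.
    """
    ages = np.asarray(ages_days, dtype=float)
    knots = np.asarray(knots, dtype=float)
    cols = [np.ones_like(ages)]
    for k in range(len(knots) - 1):
        cols.append(np.clip(ages - knots[k], 0.0, knots[k + 1] - knots[k]))
    return np.column_stack(cols)


@dataclass
class FunctionalFit:
    """Per-band piecewise-linear mixed model plus permutation global test."""

    measure: str
    knots: np.ndarray
    regional: pd.DataFrame  # columns: band, interval, coef, se, p
    global_stat: float
    global_p: float
    n_permutations: int
    skipped_bands: np.ndarray
    band_fit: LMMFit


def _demean_by_group(M: np.ndarray, g_idx: np.ndarray, G: int) -> np.ndarray:
    sums = np.zeros((G,) + M.shape[1:])
    np.add.at(sums, g_idx, M)
    counts = np.bincount(g_idx, minlength=G).astype(float)
    return M - (sums / counts[(slice(None),) + (None,) * (M.ndim - 1)])[g_idx]


def _supwald_stat(Xd: np.ndarray, Yd: np.ndarray) -> float:
    """Sup-over-columns Wald statistic from demeaned OLS, X shared."""
    n, p = Xd.shape
    XtX = Xd.T @ Xd
    XtY = Xd.T @ Yd
    beta = np.linalg.solve(XtX, XtY)  # (p, V)
    resid = Yd - Xd @ beta
    dof = max(n - p, 1)
    s2 = (resid**2).sum(axis=0) / dof  # (V,)
    XtX_inv = np.linalg.inv(XtX)
    # Wald: beta' (s2 * XtX_inv)^-1 beta = beta' XtX beta / s2 per column
    quad = np.einsum("pv,pq,qv->v", beta, XtX, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = quad / s2
    return float(np.nanmax(w))


def fit_functional_model(
    profiles: pd.DataFrame,
    measure: str,
    knots: Optional[Sequence[float]] = None,
    n_permutations: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> FunctionalFit:
    """Fit the per-band mixed model and the permutation global test.

    ``profiles`` is a tidy table with columns ``subject, age_days, band`` and
    the measure column (``length``, ``radius`` or ``area``).  Bands with
    all-identical values are skipped and flagged.
    """
    if measure not in profiles.columns:
        raise StatsError(f"measure column {measure!r} missing from profiles")
    df = profiles.dropna(subset=[measure])
    n_visits = df.groupby("subject")["age_days"].nunique()
    if (n_visits >= 2).sum() < 2:
        raise StatsError("functional model needs >= 2 subjects with >= 2 visits")
    df = df[df["subject"].isin(n_visits[n_visits >= 2].index)]
    if knots is None:
        knots = np.sort(df["age_days"].unique())
    knots = np.asarray(knots, dtype=float)

    wide = df.pivot_table(
        index=["subject", "age_days"], columns="band", values=measure
    ).sort_index()
    Y = wide.to_numpy()
    if np.isnan(Y).any():
        raise StatsError("profiles are not complete per (subject, visit)")
    subjects = wide.index.get_level_values("subject").to_numpy()
    ages = wide.index.get_level_values("age_days").to_numpy(dtype=float)
    bands = wide.columns.to_numpy()

    active = Y.std(axis=0) > 1e-12
    skipped = bands[~active]
    X = piecewise_age_basis(ages, knots)
    fit = fit_random_intercept(X, subjects, Y[:, active])

    n_int = X.shape[1] - 1
    rows = []
    act_bands = bands[active]
    for j in range(n_int):
        for bi, band in enumerate(act_bands):
            rows.append(
                dict(
                    band=int(band),
                    interval=j,
                    t_start=knots[j],
                    t_end=knots[j + 1],
                    coef=fit.beta[bi, j + 1],
                    se=fit.se[bi, j + 1],
                    p=fit.pvalues[bi, j + 1],
                )
            )
    regional = pd.DataFrame(rows)

    # global permutation test on the within-subject estimator
    rng = rng or np.random.default_rng(0)
    _, g_idx = np.unique(subjects, return_inverse=True)
    G = g_idx.max() + 1
    Yd = _demean_by_group(Y[:, active], g_idx, G)

    def stat_for(ages_perm):
        Xp = piecewise_age_basis(ages_perm, knots)[:, 1:]
        Xd = _demean_by_group(Xp, g_idx, G)
        return _supwald_stat(Xd, Yd)

    observed = stat_for(ages)
    null = np.empty(n_permutations)
    ages_work = ages.copy()
    for b in range(n_permutations):
        perm = ages.copy()
        for g in range(G):
            sel = np.flatnonzero(g_idx == g)
            perm[sel] = perm[rng.permutation(sel)]
        null[b] = stat_for(perm)
    global_p = float((1 + (null >= observed).sum()) / (1 + n_permutations))
    return FunctionalFit(
        measure=measure,
        knots=knots,
        regional=regional,
        global_stat=observed,
        global_p=global_p,
        n_permutations=n_permutations,
        skipped_bands=skipped,
        band_fit=fit,
    )


# ---------------------------------------------------------------------------
# 3. Per-vertex directional shape model
# ---------------------------------------------------------------------------

SHAPE_TERMS = ("intercept", "gender", "age", "age2", "gender_age")
DIRECTIONS = ("x", "y", "z")


@dataclass
class ShapeLMMResult:
    """Vertex-wise multivariate (x, y, z) mixed-model results."""

    beta: np.ndarray  # (V, 3, p) per vertex, direction, term
    se: np.ndarray  # (V, 3, p)
    pvalues_direction: dict  # contrast -> (V, 3)
    qvalues_direction: dict  # contrast -> (V, 3)
    pvalues_joint: dict  # contrast -> (V,)
    qvalues_joint: dict  # contrast -> (V,)
    sigma_b2: np.ndarray  # (V, 3)
    sigma_e2: np.ndarray  # (V, 3)
    excluded: np.ndarray  # (V,) bool, zero-variance vertices
    terms: tuple = SHAPE_TERMS
    contrasts: dict = field(
        default_factory=lambda: {"age": (2, 3), "gender": (1, 4)}
    )
    fdr_q: float = 0.05


def _shape_design(age_n: np.ndarray, gender01: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(age_n), gender01, age_n, age_n**2, gender01 * age_n]
    )


def fit_shape_lmm(
    W: np.ndarray,
    covariates: pd.DataFrame,
    fdr_q: float = 0.05,
    design: str = "full",
) -> ShapeLMMResult:
    """Fit the per-vertex directional model to corresponded coordinates.

    ``W`` has shape (n_obs, V, 3): for each observation (subject at a visit)
    the aligned coordinates of the V corresponded vertices.  ``covariates``
    needs ``subject, age_days`` and (for the full design) ``gender``.
    ``design="age_only"`` drops the gender terms — used for the left-right
    difference analysis.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 3 or W.shape[2] != 3:
        raise StatsError(f"W must be (n_obs, V, 3), got {W.shape}")
    n_obs, V, _ = W.shape
    if len(covariates) != n_obs:
        raise StatsError("covariate rows do not match observations")
    age_n = AgeNormalization.from_ages(covariates["age_days"])(covariates["age_days"])
    if design == "full":
        gender01 = (covariates["gender"].to_numpy() == "M").astype(float)
        if gender01.std() == 0:  # single-gender cohort: gender unidentifiable
            design = "age_only"
    if design == "full":
        X = _shape_design(age_n, gender01)
        contrasts = {"age": (2, 3), "gender": (1, 4)}
        terms = SHAPE_TERMS
    elif design == "age_only":
        X = np.column_stack([np.ones_like(age_n), age_n, age_n**2])
        contrasts = {"age": (1, 2)}
        terms = ("intercept", "age", "age2")
    else:
        raise StatsError(f"unknown design {design!r}")

    Y = W.reshape(n_obs, V * 3)
    Y = Y - Y.mean(axis=0, keepdims=True)  # center W per vertex/direction
    excluded = (Y.std(axis=0).reshape(V, 3) <= 1e-12).any(axis=1)

    fit = fit_random_intercept(X, covariates["subject"].to_numpy(), Y)
    p = X.shape[1]
    beta = fit.beta.reshape(V, 3, p)
    se = fit.se.reshape(V, 3, p)

    keep = ~excluded
    pvalues_direction, qvalues_direction = {}, {}
    pvalues_joint, qvalues_joint = {}, {}
    for name, idx in contrasts.items():
        stat, pv = fit.wald_joint(list(idx))
        stat = stat.reshape(V, 3)
        # per-direction test of this contrast (df = len(idx) each)
        pdir = sps.chi2.sf(stat, df=len(idx))
        # direction-agnostic: directions are independent channels -> sum
        pjoint = sps.chi2.sf(stat.sum(axis=1), df=3 * len(idx))
        qdir = np.full_like(pdir, np.nan)
        qjoint = np.full(V, np.nan)
        if keep.any():
            for k in range(3):
                _, qdir[keep, k] = bh_fdr(pdir[keep, k], fdr_q)
            _, qjoint[keep] = bh_fdr(pjoint[keep], fdr_q)
        pvalues_direction[name] = pdir
        qvalues_direction[name] = qdir
        pvalues_joint[name] = pjoint
        qvalues_joint[name] = qjoint
    return ShapeLMMResult(
        beta=beta,
        se=se,
        pvalues_direction=pvalues_direction,
        qvalues_direction=qvalues_direction,
        pvalues_joint=pvalues_joint,
        qvalues_joint=qvalues_joint,
        sigma_b2=fit.sigma_b2.reshape(V, 3),
        sigma_e2=fit.sigma_e2.reshape(V, 3),
        excluded=excluded,
        terms=terms,
        contrasts=contrasts,
        fdr_q=fdr_q,
    )


def left_right_difference(
    W_left: np.ndarray,
    W_right_flipped: np.ndarray,
    covariates_left: pd.DataFrame,
    covariates_right: pd.DataFrame,
    fdr_q: float = 0.05,
):
    """Per-vertex left minus flipped-right difference analysis.

    Both coordinate stacks must come from one joint correspondence in which
    right surfaces were mirrored across the mid-sagittal plane *before*
    parameterization and alignment.  Visits lacking a contralateral side are
    excluded (and reported).  Returns ``(result, used, n_excluded)`` where
    ``result`` is the age-only :class:`ShapeLMMResult` on the differences.
    """
    key_l = list(zip(covariates_left["subject"], covariates_left["age_days"]))
    key_r = list(zip(covariates_right["subject"], covariates_right["age_days"]))
    common = sorted(set(key_l) & set(key_r))
    n_excluded = (len(key_l) - len(common)) + (len(key_r) - len(common))
    if len(common) < 4:
        raise StatsError("too few subject/visit pairs with both sides")
    il = [key_l.index(k) for k in common]
    ir = [key_r.index(k) for k in common]
    D = W_left[il] - W_right_flipped[ir]
    cov = covariates_left.iloc[il].reset_index(drop=True)
    result = fit_shape_lmm(D, cov, fdr_q=fdr_q, design="age_only")
    return result, cov, n_excluded
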