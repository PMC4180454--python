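"""Vectorized maximum-likelihood random-intercept linear mixed models.

The longitudinal models used throughout the package share one structure: a
fixed-effect design ``X`` common to all response channels, a subject random
intercept, and channel-specific variance components,

    y_v = X beta_v + Z b_v + e_v,   b_iv ~ N(0, sigma_b2_v),  e_v ~ N(0, sigma_e2_v I),

fitted independently per response column v (a vertex direction, a medial
band, a replicate, a side).  Because the random effect is a single intercept,
the profile log-likelihood depends on one scalar ratio
``lambda = sigma_b2 / sigma_e2`` per column: for fixed lambda, GLS gives beta
and sigma_e2 in closed form via Woodbury block inverses.  The engine
maximizes the profile likelihood by golden-section search on log(lambda),
batched across all columns at once, which is what makes vertex-wise maps and
Monte-Carlo acceptance simulations cheap.

Estimation is plain ML (not REML) so Wald tests on fixed effects are
comparable across models; Wald p-values use the normal reference, as lme4
does by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class LMMError(ValueError):
    """Raised for singular or underdetermined mixed-model fits."""


@dataclass
class LMMFit:
    """Batched fit results; leading axis indexes response columns."""

    beta: np.ndarray  # (V, p)
    se: np.ndarray  # (V, p)
    cov: np.ndarray  # (V, p, p)
    sigma_b2: np.ndarray  # (V,)
    sigma_e2: np.ndarray  # (V,)
    loglik: np.ndarray  # (V,)
    valid: np.ndarray  # (V,) bool; False for zero-variance columns
    n_obs: int = 0
    n_groups: int = 0

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def wald_joint(self, idx) -> tuple[np.ndarray, np.ndarray]:
        """Joint Wald chi-square test of the coefficients in ``idx`` per column."""
        idx = np.asarray(idx, dtype=int)
        b = self.beta[:, idx]
        C = self.cov[:, idx[:, None], idx[None, :]].copy()
        # zero-variance columns have a singular covariance block; report NaN
        bad = ~self.valid | ~np.isfinite(C.reshape(len(C), -1)).all(axis=1)
        with np.errstate(invalid="ignore"):
            det = np.linalg.det(C)
        bad |= ~(det > 0)
        C[bad] = np.eye(len(idx))
        stat = np.einsum("vi,vi->v", b, np.linalg.solve(C, b[..., None])[..., 0])
        stat[bad] = np.nan
        p = stats.chi2.sf(stat, df=len(idx))
        return stat, p


class _Sufficient:
    """Per-design sufficient statistics reused across likelihood evaluations."""

    def __init__(self, X: np.ndarray, groups: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        groups = np.asarray(groups)
        _, self.g_idx = np.unique(groups, return_inverse=True)
        self.n, self.p = X.shape
        self.V = Y.shape[1]
        self.G = self.g_idx.max() + 1
        if self.n != len(Y) or self.n != len(groups):
            raise LMMError("X, Y, groups length mismatch")
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.yty = (Y**2).sum(axis=0)
        self.n_i = np.bincount(self.g_idx).astype(float)
        self.Sx = np.zeros((self.G, self.p))
        np.add.at(self.Sx, self.g_idx, X)
        self.Sy = np.zeros((self.G, self.V))
        np.add.at(self.Sy, self.g_idx, Y)

    def profile(self, lam: np.ndarray, want_fit: bool = False):
        """Profile log-likelihood at ratio ``lam`` (one value per column)."""
        c = lam[None, :] / (1.0 + self.n_i[:, None] * lam[None, :])  # (G, V)
        A = self.XtX[None] - np.einsum("gv,gp,gq->vpq", c, self.Sx, self.Sx)
        b = self.XtY.T - np.einsum("gp,gv->vp", self.Sx, c * self.Sy)
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]  # (V, p)
        except np.linalg.LinAlgError as exc:
            raise LMMError(f"singular GLS system: {exc}") from exc
        quad = self.yty - (c * self.Sy**2).sum(axis=0) - np.einsum("vp,vp->v", beta, b)
        quad = np.maximum(quad, 0.0)
        sigma_e2 = quad / self.n
        logdet = np.log1p(self.n_i[:, None] * lam[None, :]).sum(axis=0)
        with np.errstate(divide="ignore"):
            ll = -0.5 * (
                self.n * np.log(2.0 * np.pi * sigma_e2) + self.n + logdet
            )
        if not want_fit:
            return ll
        cov = np.linalg.inv(A) * sigma_e2[:, None, None]
        return ll, beta, cov, sigma_e2


def fit_random_intercept(
    X: np.ndarray,
    groups: np.ndarray,
    Y: np.ndarray,
    log_lambda_bounds: tuple[float, float] = (-12.0, 10.0),
    n_golden: int = 60,
) -> LMMFit:
    """ML fit of the random-intercept model for every column of ``Y``."""
    suf = _Sufficient(X, groups, Y)
    if suf.G < 2:
        raise LMMError("mixed model needs at least two subjects (groups)")
    if suf.n <= suf.p:
        raise LMMError(f"{suf.n} observations cannot identify {suf.p} fixed effects")
    lo = np.full(suf.V, log_lambda_bounds[0])
    hi = np.full(suf.V, log_lambda_bounds[1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c_ = hi - invphi * (hi - lo)
    d_ = lo + invphi * (hi - lo)
    with np.errstate(invalid="ignore"):
        fc = suf.profile(np.exp(c_))
        fd = suf.profile(np.exp(d_))
        for _ in range(n_golden):
            take = fc > fd
            hi = np.where(take, d_, hi)
            lo = np.where(take, lo, c_)
            c_ = hi - invphi * (hi - lo)
            d_ = lo + invphi * (hi - lo)
            fc = suf.profile(np.exp(c_))
            fd = suf.profile(np.exp(d_))
        lam = np.exp(0.5 * (lo + hi))
        # shrink exactly-zero variance ratio when the boundary is optimal
        at_floor = lo <= log_lambda_bounds[0] + 1e-9
        lam = np.where(at_floor, 0.0, lam)
        ll, beta, cov, sigma_e2 = suf.profile(lam, want_fit=True)
    valid = np.isfinite(ll) & (sigma_e2 > 0)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return LMMFit(
        beta=beta,
        se=se,
        cov=cov,
        sigma_b2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=ll,
        valid=valid,
        n_obs=suf.n,
        n_groups=suf.G,
    )
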