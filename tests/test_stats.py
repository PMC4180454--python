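"""Longitudinal statistics: FDR, volume model, functional model, shape model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lvshape.stats import (
    StatsError,
    bh_fdr,
    fit_functional_model,
    fit_shape_lmm,
    fit_volume_model,
    interval_change,
    left_right_difference,
    piecewise_age_basis,
)
from lvshape.synthetic import (
    simulate_profile_panel,
    simulate_shape_panel,
    simulate_volume_panel,
)


def brute_force_bh(p, q):
    """Independent step-up oracle: largest k with p_(k) <= k/m*q rejected."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * q:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestBHFDR:
    def test_hand_computed_step_up(self):
        reject, adj = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()  # rank-4: 0.04 <= 4/4 * 0.05

    def test_none_rejected(self):
        reject, _ = bh_fdr([0.5, 0.6, 0.9], q=0.05)
        assert not reject.any()

    def test_boundary_single_p(self):
        reject, adj = bh_fdr([0.05], q=0.05)
        assert reject.all()
        assert adj[0] == pytest.approx(0.05)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        _, adj = bh_fdr(p, 0.1)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(StatsError):
            bh_fdr([], 0.05)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**30), st.integers(1, 60))
    def test_matches_brute_force_and_statsmodels(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(m)
        q = 0.05 + 0.3 * rng.random()
        reject, adj = bh_fdr(p, q)
        assert np.array_equal(reject, brute_force_bh(p, q))
        sm_rej, sm_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
        assert np.array_equal(reject, sm_rej)
        assert np.allclose(adj, sm_adj)


class TestVolumeModel:
    TRUTH = np.array([0.0, 3.0, -2.0, -0.3, -0.2, 0.3])

    def test_recovers_known_coefficients(self):
        df = simulate_volume_panel(beta=self.TRUTH, sigma_b=(0.05, 0.05),
                                   sigma_e=(0.02, 0.02),
                                   rng=np.random.default_rng(8))
        fit = fit_volume_model(df)
        assert np.abs(fit.beta_raw - self.TRUTH).max() < 0.05

    def test_side_specific_variances_estimated(self):
        df = simulate_volume_panel(beta=self.TRUTH, sigma_b=(1.0, 0.2),
                                   sigma_e=(0.6, 0.1), n_subjects=60,
                                   rng=np.random.default_rng(9))
        fit = fit_volume_model(df)
        assert fit.random_intercept_var["left"] > fit.random_intercept_var["right"]
        assert fit.residual_var["left"] > fit.residual_var["right"]

    def test_single_subject_rejected(self):
        df = simulate_volume_panel(n_subjects=1, rng=np.random.default_rng(0))
        with pytest.raises(StatsError):
            fit_volume_model(df)

    def test_missing_side_rejected(self):
        df = simulate_volume_panel(rng=np.random.default_rng(0))
        with pytest.raises(StatsError, match="side"):
            fit_volume_model(df[df["side"] == "left"])

    def test_normalization_reported(self):
        df = simulate_volume_panel(rng=np.random.default_rng(1))
        fit = fit_volume_model(df)
        assert fit.age_normalization.age_min == 14.0
        assert fit.age_normalization.age_max == 730.0
        assert fit.volume_sd > 0


class TestIntervalChange:
    def _frame(self, v1, v2, n=5):
        rows = []
        for i in range(n):
            for side in ("left", "right"):
                rows.append(dict(subject=f"S{i}", age_days=14.0, side=side,
                                 volume_mm3=v1[i]))
                rows.append(dict(subject=f"S{i}", age_days=365.0, side=side,
                                 volume_mm3=v2[i]))
        return pd.DataFrame(rows)

    def test_no_change_gives_zero_and_p_one(self):
        v = np.full(5, 100.0)
        out = interval_change(self._frame(v, v), 14, 365)
        assert np.allclose(out["mean_pct"], 0.0)
        assert np.allclose(out["sd_pct"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_exact_doubling(self):
        v = np.array([80.0, 90, 100, 110, 120])
        out = interval_change(self._frame(v, 2 * v), 14, 365)
        assert np.allclose(out["mean_pct"], 100.0)
        assert np.allclose(out["sd_pct"], 0.0)

    def test_too_few_subjects_rejected(self):
        v = np.full(2, 10.0)
        with pytest.raises(StatsError):
            interval_change(self._frame(v, v, n=2), 14, 365)


class TestFunctionalModel:
    def test_piecewise_basis_geometry(self):
        X = piecewise_age_basis([14, 91, 365], [14, 91, 365])
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 1], [0, 77, 77])
        assert np.allclose(X[:, 2], [0, 0, 274])

    def test_programmed_signal_localized(self):
        def effect(pos, age):
            bump = ((pos >= 0.10) & (pos <= 0.40)).astype(float)
            return bump * 3.0 * min(age, 91.0) / 91.0

        prof = simulate_profile_panel(n_bands=100, effect=effect, sigma_e=0.4,
                                      rng=np.random.default_rng(2))
        ff = fit_functional_model(prof, "length", n_permutations=299,
                                  rng=np.random.default_rng(3))
        assert ff.global_p < 0.05
        first = ff.regional[ff.regional["interval"] == 0]
        top = first.nsmallest(10, "p")["band"]
        assert top.between(10, 40).all()

    def test_constant_band_skipped(self):
        prof = simulate_profile_panel(n_bands=10, rng=np.random.default_rng(4))
        prof.loc[prof["band"] == 3, "length"] = 7.0
        ff = fit_functional_model(prof, "length", n_permutations=99,
                                  rng=np.random.default_rng(0))
        assert 3 in ff.skipped_bands
        assert 3 not in set(ff.regional["band"])

    def test_single_subject_rejected(self):
        prof = simulate_profile_panel(n_subjects=1, n_bands=5,
                                      rng=np.random.default_rng(5))
        with pytest.raises(StatsError):
            fit_functional_model(prof, "length", n_permutations=19)


class TestShapeLMM:
    def test_noiseless_growth_along_y_only(self):
        V = 42
        slope = np.zeros((V, 3))
        moving = np.arange(10)
        slope[moving, 1] = 2.0  # growth purely along y
        W, cov = simulate_shape_panel(n_vertices=V, sigma_e=0.01, sigma_b=0.05,
                                      age_slope=slope,
                                      rng=np.random.default_rng(6))
        res = fit_shape_lmm(W, cov)
        q = res.qvalues_direction["age"]
        assert (q[moving, 1] < 0.05).all()  # y direction significant
        assert (q[moving, 0] > 0.05).all()  # x null
        assert (q[moving, 2] > 0.05).all()  # z null

    def test_zero_variance_vertex_flagged(self):
        W, cov = simulate_shape_panel(n_vertices=10, rng=np.random.default_rng(7))
        W[:, 4, :] = 1.0
        res = fit_shape_lmm(W, cov)
        assert res.excluded[4]
        assert np.isnan(res.qvalues_joint["age"][4])

    def test_gender_contrast_detects_programmed_bump(self):
        rng = np.random.default_rng(8)
        V = 42
        W, cov = simulate_shape_panel(n_vertices=V, sigma_e=0.1, sigma_b=0.1,
                                      rng=rng)
        male = (cov["gender"] == "M").to_numpy()
        W[male, :8, 0] += 2.0  # strong gender offset at anterior vertices, x
        res = fit_shape_lmm(W, cov)
        q = res.qvalues_joint["gender"]
        assert (q[:8] < 0.05).all()
        assert q[12:].min() > 0.05


class TestLeftRightDifference:
    def test_symmetric_cohort_no_discoveries(self):
        W, cov = simulate_shape_panel(n_vertices=30, rng=np.random.default_rng(9))
        res, used, n_excl = left_right_difference(W, W.copy(), cov, cov)
        # identical sides -> zero differences everywhere -> excluded vertices
        assert res.excluded.all()
        assert n_excl == 0

    def test_age_growing_asymmetry_detected(self):
        rng = np.random.default_rng(10)
        W, cov = simulate_shape_panel(n_vertices=30, sigma_e=0.05, sigma_b=0.05,
                                      rng=rng)
        Wr = W + rng.normal(0, 0.05, W.shape)  # independent contralateral noise
        an = (cov["age_days"].to_numpy() - 14) / (730 - 14)
        Wl = W + rng.normal(0, 0.05, W.shape)
        Wl[:, :5, 1] += (2.0 * an)[:, None]  # asymmetry grows with age
        res, used, _ = left_right_difference(Wl, Wr, cov, cov)
        q = res.qvalues_joint["age"]
        assert (q[:5] < 0.05).all()

    def test_unmatched_visits_excluded(self):
        W, cov = simulate_shape_panel(n_vertices=12, rng=np.random.default_rng(11))
        res, used, n_excl = left_right_difference(
            W + np.random.default_rng(0).normal(0, 0.1, W.shape),
            W[:-2], cov, cov.iloc[:-2]
        )
        assert n_excl == 2
        assert len(used) == len(cov) - 2
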