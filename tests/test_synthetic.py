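"""Synthetic cohort generator: determinism, growth law, symmetry, cohort layout."""

import numpy as np
import pandas as pd
import pytest

from lvshape.synthetic import (
    CohortDesign,
    GrowthTruth,
    PopulationParams,
    SyntheticError,
    generate_cohort,
    generate_shape,
)


def _truth(**kw):
    base = dict(subject_id="S1", side="right", gender="F", noise_sd=0.0, seed=5)
    base.update(kw)
    return GrowthTruth(**base)


class TestGenerateShape:
    def test_zero_growth_is_age_independent(self):
        t = _truth(length_growth_amplitude=0.0, radius_growth_amplitude=0.0)
        m1 = generate_shape(t, 14)
        m2 = generate_shape(t, 540)
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_deterministic_given_truth_and_age(self):
        t = _truth(noise_sd=0.3)
        m1 = generate_shape(t, 182)
        m2 = generate_shape(t, 182)
        assert np.array_equal(m1.voxels, m2.voxels)
        assert np.allclose(m1.affine, m2.affine)

    def test_voxel_count_tracks_analytic_volume_ratio(self):
        t = _truth()
        v_peak = generate_shape(t, t.peak_age).voxels.sum()
        v_base = generate_shape(t, 0).voxels.sum()
        measured = v_peak / v_base
        analytic = t.analytic_volume(t.peak_age) / t.analytic_volume(0)
        assert abs(measured - analytic) / analytic < 0.05

    def test_volume_trajectory_biphasic(self):
        t = _truth()
        vols = {a: generate_shape(t, a).voxels.sum() for a in (14, 365, 730)}
        assert vols[365] > vols[14]  # year-1 rise
        assert vols[730] < vols[365]  # year-2 fall

    def test_mirror_symmetry_without_asymmetry_or_noise(self):
        kw = dict(asymmetry_factor=1.0, noise_sd=0.0, gender="F")
        left = generate_shape(_truth(side="left", **kw), 182)
        right = generate_shape(_truth(side="right", **kw), 182)

        def centers(m):
            idx = np.argwhere(m.voxels)
            return (m.affine[:3, :3] @ idx.T).T + m.affine[:3, 3]

        cl = centers(left)
        cr = centers(right)
        cr[:, 0] *= -1
        assert np.allclose(
            cl[np.lexsort(cl.T)], cr[np.lexsort(cr.T)], atol=1e-9
        )

    def test_degenerate_geometry_rejected(self):
        t = _truth(baseline_radius_profile=np.full(20, 14.0), baseline_length=30.0)
        with pytest.raises(SyntheticError, match="self-intersection"):
            generate_shape(t, 14)

    def test_negative_age_rejected(self):
        with pytest.raises(SyntheticError):
            generate_shape(_truth(), -1)


class TestTruthValidation:
    def test_nonpositive_radius_profile(self):
        with pytest.raises(SyntheticError):
            _truth(baseline_radius_profile=np.array([1.0, 0.0, 1.0]))

    def test_bad_side_and_gender(self):
        with pytest.raises(SyntheticError):
            _truth(side="up")
        with pytest.raises(SyntheticError):
            _truth(gender="X")


class TestCohortDesign:
    def test_nonincreasing_ages_rejected(self):
        with pytest.raises(SyntheticError):
            CohortDesign(visit_ages=(14, 14, 91))

    def test_bad_missingness(self):
        with pytest.raises(SyntheticError):
            CohortDesign(missingness_rate=1.0)


class TestGenerateCohort:
    def test_complete_cohort_counts(self, tmp_path):
        design = CohortDesign(n_subjects=2, visit_ages=(14, 91, 182, 274, 365, 548, 730),
                              missingness_rate=0.0, seed=1)
        cov, truths, draws = generate_cohort(design, out_dir=tmp_path / "c")
        assert len(cov) == 2 * 7 * 2
        assert len(truths) == 4
        assert (~draws["missing"]).all()
        assert (tmp_path / "c" / "covariates.csv").exists()
        assert (tmp_path / "c" / "truth.json").exists()

    def test_missingness_replay_and_determinism(self, tmp_path):
        design = CohortDesign(n_subjects=6, missingness_rate=0.3, seed=42,
                              visit_ages=(14, 91, 182))
        cov1, _, draws1 = generate_cohort(design, out_dir=tmp_path / "a")
        cov2, _, draws2 = generate_cohort(design, out_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(draws1, draws2)
        n_retained_visits = int((~draws1["missing"]).sum())
        assert len(cov1) == 2 * n_retained_visits  # two sides per retained visit
        assert list(cov1["subject"]) == list(cov2["subject"])
        # masks byte-identical across runs
        import hashlib

        for f in sorted((tmp_path / "a").glob("*.nii.gz")):
            g = tmp_path / "b" / f.name
            assert hashlib.sha256(f.read_bytes()).hexdigest()[:16] == \
                hashlib.sha256(g.read_bytes()).hexdigest()[:16]

    def test_in_memory_mode(self):
        design = CohortDesign(n_subjects=1, visit_ages=(14, 91),
                              missingness_rate=0.0, seed=3)
        cov, truths, _ = generate_cohort(design)
        assert "mask" in cov.columns
        assert len(cov) == 4


def test_growth_factor_shape():
    t = _truth(peak_age=450.0)
    assert t.growth_factor(0) == 0.0
    assert t.growth_factor(450) == 1.0
    assert 0.0 < t.growth_factor(730) < 1.0
    assert t.growth_factor(900) == t.growth_factor(0)  # symmetric, floored at 0
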