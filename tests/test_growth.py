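"""SVD growth fields: rank-1 oracle, isotropy, equivariance, glyphs."""

import numpy as np
import pandas as pd
import pytest

from lvshape.growth import (
    DAYS_PER_MONTH,
    GrowthError,
    growth_directions,
    render_growth_ellipsoids,
)


def _cov(subjects, ages):
    return pd.DataFrame(dict(subject=subjects, age_days=ages))


def _panel(n_subj=5, visits=(14.0, 365.0, 730.0), V=20, rng=None, disp=None):
    """Coordinates with per-vertex displacement field disp(age_months) added."""
    rng = rng or np.random.default_rng(0)
    base = rng.standard_normal((V, 3)) * 10
    rows, subjects, ages = [], [], []
    for i in range(n_subj):
        for a in visits:
            W = base.copy()
            if disp is not None:
                W = W + disp(a)
            rows.append(W)
            subjects.append(f"S{i}")
            ages.append(a)
    return np.stack(rows), _cov(subjects, ages)


def test_static_surfaces_give_zero_field():
    W, cov = _panel()
    field = growth_directions(W, cov)
    assert np.allclose(field.singular_values, 0.0)
    assert np.allclose(field.growth_rate, 0.0)


def test_rank_one_displacement_exact():
    g = 0.7  # mm per month along +y

    def disp(age):
        months = (age - 14.0) / DAYS_PER_MONTH
        return np.array([0.0, g * months, 0.0])

    W, cov = _panel(disp=disp)
    field = growth_directions(W, cov)
    assert np.allclose(np.abs(field.principal_direction[:, 1]), 1.0, atol=1e-12)
    assert np.allclose(field.principal_direction[:, 1], 1.0)  # sign convention
    assert np.allclose(field.growth_rate, g, atol=1e-9)
    assert np.allclose(field.singular_values[:, 1:], 0.0, atol=1e-9)


def test_isotropic_noise_gives_flat_spectrum():
    rng = np.random.default_rng(1)
    m = 500
    subjects = np.repeat([f"S{i}" for i in range(m)], 2)
    ages = np.tile([14.0, 365.0], m)
    V = 5
    W = np.zeros((2 * m, V, 3))
    W[1::2] = rng.standard_normal((m, V, 3))  # later visit displaced isotropically
    field = growth_directions(W, _cov(subjects, ages))
    ratio = field.singular_values[:, 0] / field.singular_values[:, 2]
    assert (ratio < 1.3).all()


def test_rotation_equivariance():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(2)
    W, cov = _panel(rng=rng, disp=lambda a: rng.standard_normal(3) * 0)
    W = W + rng.standard_normal(W.shape) * 0.5
    R = Rotation.from_euler("xyz", [33, -20, 71], degrees=True).as_matrix()
    f1 = growth_directions(W, cov)
    f2 = growth_directions(W @ R.T, cov)
    # directions rotate with R (up to sign fixed by the mean projection, which
    # is also equivariant)
    assert np.allclose(f2.principal_direction, f1.principal_direction @ R.T,
                       atol=1e-8)
    assert np.allclose(f2.growth_rate, f1.growth_rate, atol=1e-8)
    assert np.allclose(f2.singular_values, f1.singular_values, atol=1e-8)


def test_stack_order_invariance():
    rng = np.random.default_rng(3)
    W, cov = _panel(rng=rng)
    W = W + rng.standard_normal(W.shape)
    perm = rng.permutation(len(cov))
    f1 = growth_directions(W, cov)
    f2 = growth_directions(W[perm], cov.iloc[perm].reset_index(drop=True))
    assert np.allclose(np.abs(f1.principal_direction), np.abs(f2.principal_direction), atol=1e-9)
    assert np.allclose(f1.growth_rate, f2.growth_rate, atol=1e-9)


def test_consecutive_reference_mode():
    g = 1.0

    def disp(age):
        months = (age - 14.0) / DAYS_PER_MONTH
        return np.array([0.0, g * months, 0.0])

    W, cov = _panel(disp=disp)
    field = growth_directions(W, cov, reference="consecutive")
    assert np.allclose(field.growth_rate, g, atol=1e-9)


def test_no_repeat_visits_rejected():
    W, cov = _panel(visits=(14.0,))
    with pytest.raises(GrowthError):
        growth_directions(W, cov)


class TestGlyphs:
    def test_rank_one_needles(self):
        def disp(age):
            return np.array([0.0, 0.1 * (age - 14.0), 0.0])

        W, cov = _panel(disp=disp, V=4)
        field = growth_directions(W, cov)
        verts, faces, rates = render_growth_ellipsoids(field, W.mean(0), scale=2.0)
        # needle glyphs: extent along y >> x, z
        v0 = verts[:42] - W.mean(0)[0]
        ext = v0.max(0) - v0.min(0)
        assert ext[1] > 50 * max(ext[0], ext[2])

    def test_zero_field_zero_size(self):
        W, cov = _panel(V=3)
        field = growth_directions(W, cov)
        verts, _, rates = render_growth_ellipsoids(field, W.mean(0))
        assert np.allclose(verts[:42], W.mean(0)[0], atol=1e-12)
        assert np.allclose(rates, 0.0)

    def test_horn_weighted_rates_ordered(self):
        def disp(age):
            months = (age - 14.0) / DAYS_PER_MONTH
            out = np.zeros((6, 3))
            out[:2, 1] = 1.0 * months  # "horn" vertices grow fast
            out[2:, 1] = 0.2 * months
            return out

        W, cov = _panel(V=6, disp=disp)
        field = growth_directions(W, cov)
        _, _, rates = render_growth_ellipsoids(field, W.mean(0))
        horn_rates = rates[: 2 * 42]
        body_rates = rates[2 * 42:]
        assert horn_rates.min() > body_rates.max()
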