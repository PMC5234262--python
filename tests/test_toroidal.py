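import math

import numpy as np
import pytest

from torusseg import (
    CoordinateGrids,
    DegenerateLevelError,
    FrequencyField,
    InvalidImageError,
    InvalidParameterError,
    TorusConfig,
    make_grids,
    thd,
    toroidal_operators,
    tvd,
)

R100 = TorusConfig(R=100.0)


def scalar_thd(u, f, R):
    """Independent plain-math evaluation of the horizontal decomposition."""
    return (R + math.cos(2 * math.pi * f * u)) * math.cos(2 * math.pi * math.atan(f))


def scalar_tvd(v, f, R):
    return (R + math.cos(2 * math.pi * f * v)) * math.sin(2 * math.pi * math.atan(f))


def field(values):
    arr = np.atleast_2d(np.asarray(values, dtype=np.float64))
    return FrequencyField(values=arr, r=1.0)


def grids_like(u=0.0, v=0.0, shape=(1, 1)):
    return CoordinateGrids(
        u=np.full(shape, u, dtype=np.float64),
        v=np.full(shape, v, dtype=np.float64),
    )


class TestGrids:
    def test_two_point_ramp(self):
        g = make_grids(1, 2)
        np.testing.assert_allclose(g.u, [[-0.5, 0.5]])

    def test_odd_width_includes_zero(self):
        g = make_grids(1, 3)
        np.testing.assert_allclose(g.u, [[-2 / 3, 0.0, 2 / 3]], atol=1e-15)

    def test_single_pixel_degenerates_to_zero(self):
        g = make_grids(1, 1)
        assert g.u[0, 0] == 0.0 and g.v[0, 0] == 0.0

    def test_u_and_v_are_transpose_patterns(self):
        g = make_grids(5, 7)
        # u constant down each column, v constant along each row
        assert np.all(g.u == g.u[0:1, :])
        assert np.all(g.v == g.v[:, 0:1])
        np.testing.assert_allclose(g.u[0], -g.u[0][::-1], atol=1e-15)
        np.testing.assert_allclose(g.v[:, 0], -g.v[::-1, 0], atol=1e-15)
        assert np.abs(g.u).max() <= 1 and np.abs(g.v).max() <= 1

    @pytest.mark.parametrize("h, w", [(0, 5), (5, 0), (-1, 3)])
    def test_nonpositive_dimensions_rejected(self, h, w):
        with pytest.raises(InvalidParameterError):
            make_grids(h, w)


class TestDecompositions:
    def test_thd_frozen_value(self):
        # 30-digit evaluation of the formula at u=0.25, f=1, R=100
        out = thd(grids_like(u=0.25), field(1.0), R100)
        assert out[0, 0] == pytest.approx(22.0584040749698, abs=1e-10)

    def test_tvd_frozen_value(self):
        out = tvd(grids_like(v=0.0), field(1.0), R100)
        assert out[0, 0] == pytest.approx(-98.5121651804468, abs=1e-10)

    def test_low_frequency_limits(self):
        # f -> 0+ at u = v = 0: THD -> R + 1, TVD -> 0
        f = field(1e-12)
        assert thd(grids_like(), f, R100)[0, 0] == pytest.approx(101.0, abs=1e-9)
        assert tvd(grids_like(), f, R100)[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_thd_periodic_in_u_with_period_one_over_f(self):
        f = 0.7
        u = np.linspace(-0.5, 0.5, 11)[np.newaxis, :]
        ff = field(np.full(u.shape, f))
        a = thd(CoordinateGrids(u=u, v=np.zeros_like(u)), ff, R100)
        b = thd(CoordinateGrids(u=u + 1 / f, v=np.zeros_like(u)), ff, R100)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_elementwise_against_scalar_oracle(self, rng):
        n = 1000
        amp = rng.uniform(1, 256, n)
        u = rng.uniform(-1, 1, n)
        v = rng.uniform(-1, 1, n)
        r = rng.uniform(0.001, 1.0, n)
        R = 100.0
        f = amp ** (-r)
        g = CoordinateGrids(u=u[np.newaxis, :], v=v[np.newaxis, :])
        ff = FrequencyField(values=f[np.newaxis, :], r=float("nan"))
        h = thd(g, ff, R100)[0]
        w = tvd(g, ff, R100)[0]
        for k in range(n):
            assert h[k] == pytest.approx(scalar_thd(u[k], f[k], R), abs=1e-9)
            assert w[k] == pytest.approx(scalar_tvd(v[k], f[k], R), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidImageError):
            thd(grids_like(shape=(2, 2)), field(np.ones((3, 3))), R100)


class TestOperators:
    def test_single_pixel_matches_stepwise_scalar_evaluation(self):
        # stored amplitude 1, offset 1 -> shifted 2; r = 1 -> f = 0.5; u=v=0
        gray = np.array([[1.0]])
        ff = FrequencyField(values=np.array([[0.5]]), r=1.0)
        level = toroidal_operators(gray, grids_like(), ff, R100)
        # scalar chain: T_a = 2 (tvd + thd); normalization by |T_a| gives 1
        t_a = 2 * (scalar_tvd(0, 0.5, 100) + scalar_thd(0, 0.5, 100))
        assert t_a == pytest.approx(-151.015194271864, abs=1e-9)
        assert level.t_a_norm[0, 0] == 1.0
        assert level.t_p_norm[0, 0] == 1.0

    def test_operators_match_scalar_chain_elementwise(self, rng):
        n = 200
        stored = rng.uniform(0, 255, (1, n))
        u = rng.uniform(-1, 1, (1, n))
        v = rng.uniform(-1, 1, (1, n))
        r = 0.3
        shifted = stored + 1.0
        f = shifted ** (-r)
        g = CoordinateGrids(u=u, v=v)
        ff = FrequencyField(values=f, r=r)
        level = toroidal_operators(stored, g, ff, R100)
        t_a = np.empty(n)
        t_p = np.empty(n)
        for k in range(n):
            h = scalar_thd(u[0, k], f[0, k], 100.0)
            w = scalar_tvd(v[0, k], f[0, k], 100.0)
            t_a[k] = shifted[0, k] * (w + h)
            t_p[k] = shifted[0, k] ** 2 * (w * h)
        np.testing.assert_allclose(
            level.t_a_norm[0], np.abs(t_a) / np.abs(t_a).max(), atol=1e-9
        )
        np.testing.assert_allclose(
            level.t_p_norm[0], np.abs(t_p) / np.abs(t_p).max(), atol=1e-9
        )

    def test_normalized_operators_attain_unit_maximum(self, rng):
        gray = rng.uniform(0, 255, (16, 16))
        g = make_grids(16, 16)
        ff = FrequencyField(values=(gray + 1) ** -0.014, r=0.014)
        level = toroidal_operators(gray, g, ff, R100)
        for t in (level.t_a_norm, level.t_p_norm):
            assert t.min() >= 0 and t.max() == 1.0

    def test_zero_amplitude_with_zero_offset_is_degenerate(self):
        gray = np.zeros((4, 4))
        g = make_grids(4, 4)
        ff = FrequencyField(values=np.ones((4, 4)), r=1.0)
        with pytest.raises(DegenerateLevelError):
            toroidal_operators(gray, g, ff, R100, amplitude_offset=0.0)

    def test_elementwise_locality_under_pixel_permutation(self, rng):
        # jointly permuting (A, u, v) permutes outputs identically:
        # no neighbourhood coupling anywhere in the decomposition
        n = 64
        gray = rng.uniform(0, 255, (1, n))
        u = rng.uniform(-1, 1, (1, n))
        v = rng.uniform(-1, 1, (1, n))
        f = (gray + 1) ** -0.5
        perm = rng.permutation(n)
        lvl = toroidal_operators(
            gray, CoordinateGrids(u=u, v=v), FrequencyField(f, 0.5), R100
        )
        lvl_p = toroidal_operators(
            gray[:, perm],
            CoordinateGrids(u=u[:, perm], v=v[:, perm]),
            FrequencyField(f[:, perm], 0.5),
            R100,
        )
        np.testing.assert_array_equal(lvl.t_a_norm[:, perm], lvl_p.t_a_norm)
        np.testing.assert_array_equal(lvl.t_p_norm[:, perm], lvl_p.t_p_norm)

    def test_magnitude_bounds(self, rng):
        gray = rng.uniform(0, 255, (8, 8))
        g = make_grids(8, 8)
        f = (gray + 1) ** -0.2
        lvl = toroidal_operators(gray, g, FrequencyField(f, 0.2), R100)
        amax = (gray + 1).max()
        # reconstruct unnormalized magnitudes from the stored raw fields
        t_a = np.abs((gray + 1) * (lvl.tvd + lvl.thd))
        t_p = np.abs((gray + 1) ** 2 * (lvl.tvd * lvl.thd))
        assert t_a.max() <= amax * 2 * 101.0
        assert t_p.max() <= amax**2 * 101.0**2
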