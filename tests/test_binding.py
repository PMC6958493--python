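"""Exact depletion model, hyperbola approximation and Lindmo transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irfakit import (
    AntigenSeries,
    BindingParameters,
    CurvePoint,
    bound_fraction_exact,
    bound_fraction_hyperbola,
    generate_ideal_grid,
    lindmo_transform,
    DEFAULT_KD_AXIS,
)
from irfakit.binding import generate_depletion_curves

from conftest import fixed_point_bound_fraction


class TestExactModel:
    def test_zero_antigen_gives_zero(self, params):
        assert bound_fraction_exact(0.0, params) == 0.0

    def test_infinite_antigen_converges_to_r(self, params):
        assert bound_fraction_exact(1e9, params) == pytest.approx(0.7, abs=1e-6)

    def test_matches_fixed_point_oracle(self):
        p = BindingParameters(r=0.7, kd=1.0, T=0.1)
        oracle = fixed_point_bound_fraction(1.25, 0.7, 1.0, 0.1)
        assert oracle == pytest.approx(0.3835, abs=5e-5)  # frozen oracle value
        assert bound_fraction_exact(1.25, p) == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("ag0", [1.25, 5.0, 20.0, 80.0])
    @pytest.mark.parametrize("kd", [0.01, 1.0, 100.0])
    def test_satisfies_mass_balance(self, ag0, kd):
        p = BindingParameters(r=0.7, kd=kd, T=0.1)
        x = bound_fraction_exact(ag0, p)
        B = x * p.T
        lhs = x
        rhs = p.r * (ag0 - B) / ((ag0 - B) + kd)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    @pytest.mark.parametrize("ag0", [1.25, 80.0, 8000.0])
    def test_quadratic_root_residual(self, ag0):
        p = BindingParameters(r=0.7, kd=1.0, T=0.1)
        x = bound_fraction_exact(ag0, p)
        a = ag0 / p.T
        resid = x * x - (p.kd / p.T + a + p.r) * x + p.r * a
        assert abs(resid) < 1e-10 * max(1.0, a)

    def test_negative_antigen_rejected(self, params):
        with pytest.raises(ValueError):
            bound_fraction_exact(-1.0, params)

    @given(
        ag0=st.floats(0.01, 1e4),
        r=st.floats(0.05, 1.0),
        kd=st.floats(1e-3, 1e3),
        T=st.floats(1e-4, 100.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_depletion_bound_and_range(self, ag0, r, kd, T):
        """Exact value never exceeds the hyperbola, r, or available antigen."""
        p = BindingParameters(r=r, kd=kd, T=T)
        exact = bound_fraction_exact(ag0, p)
        hyp = bound_fraction_hyperbola(ag0, r, kd)
        assert 0.0 <= exact <= min(r, ag0 / T) + 1e-12
        assert exact <= hyp + 1e-12

    def test_depletion_vanishes_at_tiny_T(self):
        p = BindingParameters(r=0.7, kd=1.0, T=1e-9)
        for ag0 in (1.25, 10.0, 80.0):
            assert bound_fraction_exact(ag0, p) == pytest.approx(
                bound_fraction_hyperbola(ag0, 0.7, 1.0), abs=1e-8
            )

    def test_monotone_in_antigen_r_and_kd(self):
        ag = np.array([1.25, 2.5, 5, 10, 20, 40, 80.0])
        p = BindingParameters(r=0.7, kd=1.0, T=0.1)
        vals = bound_fraction_exact(ag, p)
        assert np.all(np.diff(vals) > 0)
        up_r = bound_fraction_exact(ag, BindingParameters(r=0.8, kd=1.0, T=0.1))
        assert np.all(up_r >= vals)
        up_kd = bound_fraction_exact(ag, BindingParameters(r=0.7, kd=3.16, T=0.1))
        assert np.all(up_kd <= vals)


class TestHyperbola:
    def test_half_saturation_at_kd(self):
        assert bound_fraction_hyperbola(2.0, 0.7, 2.0) == pytest.approx(0.35)

    def test_tenfold_kd_gives_91_percent_of_r(self):
        # single-point rule: ag0 = 10*KD yields ~91% of r
        v = bound_fraction_hyperbola(10.0, 0.7, 1.0)
        assert v == pytest.approx(0.7 * 10 / 11, rel=1e-12)
        assert v / 0.7 == pytest.approx(0.909, abs=1e-3)

    def test_zero_and_domain(self):
        assert bound_fraction_hyperbola(0.0, 0.7, 1.0) == 0.0
        with pytest.raises(ValueError):
            bound_fraction_hyperbola(1.0, 0.7, 0.0)


class TestLindmoTransform:
    def test_direct_reciprocals(self):
        pairs, dropped = lindmo_transform(
            [CurvePoint(1.0, 0.35), CurvePoint(2.0, 0.5)]
        )
        assert dropped == 0
        assert pairs[0] == (1.0, pytest.approx(1 / 0.35))
        assert pairs[1] == (0.5, pytest.approx(2.0))

    def test_exact_hyperbola_points_transform_to_exact_line(self):
        ag = np.array([1.25, 2.5, 5, 10, 20, 40, 80.0])
        pts = [CurvePoint(a, bound_fraction_hyperbola(a, 0.7, 1.0)) for a in ag]
        pairs, _ = lindmo_transform(pts)
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        slope, intercept = np.polyfit(x, y, 1)
        assert slope == pytest.approx(1.0 / 0.7, rel=1e-10)  # KD/r
        assert intercept == pytest.approx(1.0 / 0.7, rel=1e-10)  # 1/r
        assert np.max(np.abs(y - (slope * x + intercept))) < 1e-10

    def test_nonpositive_points_counted_not_silent(self):
        pts = [CurvePoint(1.0, -0.02), CurvePoint(2.0, 0.5), CurvePoint(4.0, 0.0)]
        pairs, dropped = lindmo_transform(pts)
        assert dropped == 2
        assert len(pairs) == 1


class TestGrid:
    def test_ideal_grid_matches_per_cell_oracle(self, ideal_grid):
        row = ideal_grid.row(1.0)
        for ag0, got in zip((1.25, 80.0), (row[0], row[-1])):
            oracle = fixed_point_bound_fraction(ag0, 0.7, 1.0, 0.1)
            assert got == pytest.approx(oracle, rel=1e-9)
        assert row[-1] == pytest.approx(0.69135, abs=1e-5)

    def test_grid_invariants(self, ideal_grid):
        v = ideal_grid.values
        assert np.all((v >= 0) & (v <= 1))
        assert np.all(v <= 0.7 + 1e-12)
        assert np.all(np.diff(v, axis=1) >= 0)  # non-decreasing in ag0

    def test_zero_r_gives_zero_grid(self, antigen):
        g = generate_ideal_grid([1.0], antigen, BindingParameters(r=0.0))
        assert np.all(g.values == 0)

    def test_tiny_T_grid_equals_hyperbola(self, antigen):
        g = generate_ideal_grid(DEFAULT_KD_AXIS, antigen, BindingParameters(T=1e-9))
        ag = antigen.as_array()
        for i, kd in enumerate(DEFAULT_KD_AXIS):
            assert g.values[i] == pytest.approx(
                bound_fraction_hyperbola(ag, 0.7, kd), abs=1e-6
            )

    def test_long_format_export(self, ideal_grid):
        df = ideal_grid.to_frame()
        assert list(df.columns) == ["kd_nM", "ag0_nM", "bound_fraction"]
        assert len(df) == 9 * 7


class TestDomainTypes:
    def test_antigen_series_must_increase_and_be_positive(self):
        with pytest.raises(ValueError):
            AntigenSeries((5.0, 2.5))
        with pytest.raises(ValueError):
            AntigenSeries((0.0, 1.0))
        s = AntigenSeries((1.0, 2.0, 2.0))  # duplicates permitted (saturation)
        assert len(s) == 3

    def test_binding_parameters_validation(self):
        with pytest.raises(ValueError):
            BindingParameters(r=1.5)
        with pytest.raises(ValueError):
            BindingParameters(kd=0.0)
        with pytest.raises(ValueError):
            BindingParameters(T=0.0)
        assert BindingParameters(kd=2.0, kon=0.1).koff == pytest.approx(0.2)


def test_depletion_curves_overestimate_marker():
    """Raising T above the smallest antigen level depresses bound fractions."""
    df = generate_depletion_curves([0.1, 13.3], (1.25, 2.5, 5, 10, 20, 40, 80))
    low = df[df.T_nM == 0.1].set_index("ag0_nM")["bound_fraction"]
    high = df[df.T_nM == 13.3].set_index("ag0_nM")["bound_fraction"]
    assert (high < low).all()
    assert high[1.25] < 0.1  # antigen nearly exhausted at the lowest level
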