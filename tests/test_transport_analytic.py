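import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lintflux import (
    DensityProfile,
    TransportSolution,
    accreted_count,
    accreted_mass,
    concentration,
    default_params,
    fiber_mass,
    fill_time,
    longtime_mass,
    order_of_magnitude,
    shorttime_mass,
)


class TestDensityProfile:
    def test_zero_extension_outside_domain(self, constant_n0, gaussian_n0, tabulated_n0):
        for profile in (constant_n0, gaussian_n0, tabulated_n0):
            assert profile(-0.01) == 0.0
            assert profile(0.11) == 0.0

    def test_constant_total(self, constant_n0):
        assert constant_n0.total_fibers() == pytest.approx(10.0)

    def test_gaussian_total_and_shape(self, gaussian_n0):
        assert gaussian_n0.total_fibers() == pytest.approx(10.0, rel=1e-6)
        assert gaussian_n0(0.05) > gaussian_n0(0.03) > gaussian_n0(0.01)

    def test_quadrature_matches_trapezoid_cross_check(self, tabulated_n0):
        quad = tabulated_n0.integrate(0.013, 0.087)
        trap = tabulated_n0.integrate_trapezoid(0.013, 0.087)
        assert quad == pytest.approx(trap, rel=1e-6)

    def test_csv_round_trip(self, tabulated_n0, tmp_path):
        path = tmp_path / "profile.csv"
        tabulated_n0.to_csv(path, n_points=401)
        loaded = DensityProfile.from_csv(path, L=0.1)
        x = np.linspace(0, 0.1, 57)
        np.testing.assert_allclose(loaded(x), tabulated_n0(x), atol=0.5)

    @pytest.mark.parametrize("bad", [
        dict(kind="constant", L=0.1, level=-1.0),
        dict(kind="gaussian", L=0.1, total=1.0, width=0.0),
        dict(kind="whatever", L=0.1),
    ])
    def test_invalid_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            DensityProfile(**bad)

    def test_tabulated_requires_increasing_x_in_domain(self):
        with pytest.raises(ValueError):
            DensityProfile.tabulated([0.0, 0.0, 0.1], [1, 1, 1], L=0.1)
        with pytest.raises(ValueError):
            DensityProfile.tabulated([0.0, 0.2], [1, 1], L=0.1)
        with pytest.raises(ValueError):
            DensityProfile.tabulated([0.0, 0.1], [1, -1], L=0.1)


class TestConcentration:
    def test_initial_condition(self, constant_n0, gaussian_n0, u_bar):
        for n0 in (constant_n0, gaussian_n0):
            x = np.linspace(0, 0.1, 11)
            np.testing.assert_allclose(concentration(x, 0.0, 1.0, u_bar, n0), n0(x))

    def test_pure_translation_of_constant_profile(self, constant_n0, u_bar):
        t = 1000.0
        front = u_bar * t
        assert concentration(front * 0.5, t, 0.0, u_bar, constant_n0) == 0.0
        assert concentration(front * 1.5, t, 0.0, u_bar, constant_n0) == pytest.approx(100.0)

    def test_navel_empties_after_fill_time(self, gaussian_n0, u_bar, t_fill):
        assert concentration(0.1, 1.2 * t_fill, 0.0, u_bar, gaussian_n0) == 0.0

    def test_outside_domain_rejected(self, constant_n0, u_bar):
        with pytest.raises(ValueError):
            concentration(0.2, 1.0, 1.0, u_bar, constant_n0)
        with pytest.raises(ValueError):
            concentration(0.05, -1.0, 1.0, u_bar, constant_n0)


class TestAccretedCount:
    def test_empty_navel_at_start(self, params):
        assert accreted_count(0.0, params) == 0.0

    def test_plateau_counts_all_initial_fibers(self, params, u_bar, t_fill):
        p0 = params.replace(A=0.0)
        assert accreted_count(t_fill, p0, u_bar) == pytest.approx(10.0)
        # and stays there: the n0 contribution is constant past the fill time
        assert accreted_count(3 * t_fill, p0, u_bar) == pytest.approx(10.0)

    def test_source_only_branch(self, params, u_bar):
        p0 = params.replace(n0_level=0.0)
        t = 500.0
        assert accreted_count(t, p0, u_bar) == pytest.approx(0.5 * 1.0 * u_bar * t * t)

    @given(t=st.floats(min_value=0.0, max_value=1.2e4),
           level=st.floats(min_value=0.0, max_value=500.0),
           a=st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_quadrature_matches_closed_form_for_constant_profile(self, t, level, a):
        """The integral branch and the two-branch closed form agree to
        machine precision for a constant initial level."""
        params = default_params().replace(n0_level=level, A=a)
        u = 2.7173913043478262e-05
        closed = accreted_count(t, params, u)
        tab = DensityProfile.tabulated([0.0, 0.1], [level, level], L=0.1)
        via_quadrature = accreted_count(t, params, u, n0=tab)
        assert via_quadrature == pytest.approx(closed, rel=1e-10, abs=1e-9)

    def test_continuous_at_fill_time(self, params, u_bar, t_fill):
        eps = 1e-9 * t_fill
        below = accreted_count(t_fill - eps, params, u_bar)
        above = accreted_count(t_fill + eps, params, u_bar)
        at = accreted_count(t_fill, params, u_bar)
        assert below == pytest.approx(at, rel=1e-6)
        assert above == pytest.approx(at, rel=1e-6)

    def test_initial_accretion_rate_is_flux_at_navel(self, params, u_bar, tabulated_n0):
        """dN_B/dt at t=0+ equals u_bar * n0(L), checked by finite
        difference on the translation term (A = 0 isolates it; with a
        source the rate gains the O(dt) term A*u_bar*dt/2)."""
        p0 = params.replace(A=0.0)
        for n0 in (tabulated_n0, None):
            dt = 1e-3
            rate = (accreted_count(dt, p0, u_bar, n0=n0)
                    - accreted_count(0.0, p0, u_bar, n0=n0)) / dt
            n_at_navel = n0(0.1) if n0 is not None else params.transport.n0_level
            assert rate == pytest.approx(u_bar * n_at_navel, rel=1e-3)

    def test_non_decreasing(self, params, u_bar, tabulated_n0):
        times = np.linspace(0, 8000, 50)
        counts = [accreted_count(t, params, u_bar, n0=tabulated_n0) for t in times]
        assert all(b >= a - 1e-9 for a, b in zip(counts, counts[1:]))

    def test_conservation_without_source(self, params, u_bar, gaussian_n0):
        """Absorbed + still-in-domain = initial total, at any time (A = 0)."""
        p0 = params.replace(A=0.0)
        for t in (0.0, 500.0, 2000.0, 5000.0):
            absorbed = accreted_count(t, p0, u_bar, n0=gaussian_n0)
            x = np.linspace(0, 0.1, 20001)
            in_domain = np.trapezoid(
                concentration(x, t, 0.0, u_bar, gaussian_n0), x)
            assert absorbed + in_domain == pytest.approx(10.0, abs=1e-3)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            accreted_count(-1.0, params)


class TestMassLaws:
    def test_mass_is_count_times_fiber_mass(self, params, u_bar):
        m_L = fiber_mass(params.geometry)
        for t in (100.0, 3680.0, 36000.0):
            assert accreted_mass(t, params, u_bar) == pytest.approx(
                m_L * accreted_count(t, params, u_bar), rel=1e-15)

    def test_ten_hour_mass_near_0p6_mg(self, params):
        assert longtime_mass(36000.0, params) * 1e6 == pytest.approx(0.622, rel=2e-3)

    def test_longtime_matches_source_only_exact_solution(self, params, u_bar):
        p0 = params.replace(n0_level=0.0)
        assert longtime_mass(36000.0, params, u_bar) == pytest.approx(
            accreted_mass(36000.0, p0, u_bar), rel=1e-12)

    def test_longtime_quadratic_in_time(self, params):
        assert longtime_mass(2000.0, params) == pytest.approx(
            4 * longtime_mass(1000.0, params), rel=1e-12)

    def test_asymptotic_dominance(self, params, u_bar):
        ratios = [accreted_mass(t, params, u_bar) / longtime_mass(t, params, u_bar)
                  for t in (1e5, 1e6, 1e7)]
        assert ratios[0] > ratios[1] > ratios[2] > 1.0
        assert ratios[2] == pytest.approx(1.0, rel=1e-2)

    def test_shorttime_linear_law_and_branch_identity(self, params, u_bar, t_fill):
        p0 = params.replace(A=0.0)
        for t in (10.0, 100.0, 0.5 * t_fill):
            assert shorttime_mass(t, params, u_bar) == pytest.approx(
                accreted_mass(t, p0, u_bar), rel=1e-12)

    def test_shorttime_limit_ratio(self, params, u_bar):
        """accreted/shorttime -> 1 as t -> 0; the deviation A*t/(2*n0)
        shrinks linearly with t."""
        ratios = [accreted_mass(t, params, u_bar) / shorttime_mass(t, params, u_bar)
                  for t in (10.0, 1.0, 0.1)]
        assert all(r > 1.0 for r in ratios)
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] == pytest.approx(1.0, abs=1e-3)

    def test_initial_population_mass_near_0p35_ug(self, params, u_bar, t_fill):
        assert shorttime_mass(t_fill, params, u_bar) * 1e9 == pytest.approx(0.353, rel=2e-3)


class TestFillTime:
    def test_nominal_fill_time_about_one_hour(self, params):
        t = fill_time(params)
        assert t == pytest.approx(3680.0, rel=1e-3)
        assert round(t / 3600.0) == 1

    def test_linear_in_length_inverse_in_pressure(self, params):
        assert fill_time(params.replace(L=0.05)) == pytest.approx(
            fill_time(params) / 2, rel=1e-12)
        assert fill_time(params.replace(p=200.0)) == pytest.approx(
            fill_time(params) / 2, rel=1e-12)

    def test_zero_drift_rejected(self, params):
        with pytest.raises(ValueError):
            fill_time(params, u_bar=0.0)


class TestOrderOfMagnitude:
    @pytest.mark.parametrize("value, convention, expected", [
        (0.62, "nearest", 1.0),
        (0.35, "floor", 0.1),
        (1.0, "nearest", 1.0),
        (1.0, "floor", 1.0),
        (2.717e-5, "floor", 1e-5),
        (1.67, "nearest", 1.0),
    ])
    def test_conventions(self, value, convention, expected):
        assert order_of_magnitude(value, convention) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            order_of_magnitude(0.0)
        with pytest.raises(ValueError):
            order_of_magnitude(1.0, "ceiling")


class TestTransportSolution:
    def test_series_columns_and_consistency(self, params):
        sol = TransportSolution.from_params(params)
        frame = sol.series([0.0, 1000.0, 3680.0])
        assert list(frame.columns) == ["t_s", "n_at_navel_per_m", "N_B_fibers", "m_B_kg"]
        m_L = fiber_mass(params.geometry)
        np.testing.assert_allclose(frame["m_B_kg"], m_L * frame["N_B_fibers"])
        assert frame["N_B_fibers"].is_monotonic_increasing
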