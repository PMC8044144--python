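"""Core model: domain types, forward maps, and their geometric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from coursemap.model import (
    CourseMap,
    IndividualEffects,
    LongitudinalDataset,
    build_mixing_matrix,
    exp_parallel,
    geodesic_eval,
    log_posterior,
    metric_weights,
    time_warp,
    trajectory_eval,
)


def toy_map(K=2, p0=(0.3, 0.5), v0=(0.1, 0.2), t0=76.0, n_sources=1):
    return CourseMap(
        t0=t0,
        p0=np.asarray(p0, dtype=float),
        v0=np.asarray(v0, dtype=float),
        sigma_noise=0.05,
        sigma_tau=4.0,
        sigma_xi=0.3,
        A=build_mixing_matrix(np.asarray(p0, float), np.asarray(v0, float), n_sources),
    )


def geodesic_ode_solution(p0, v0, t0, t_eval):
    """Independent oracle: integrate the geodesic ODE of g(p) = 1/(p(1-p))^2.

    In 1D the geodesic equation is p'' = Gamma(p) p'^2 with
    Gamma = -d/dp log sqrt(g) = (1 - 2p)/(p (1-p)).
    """

    def rhs(t, y):
        p, dp = y
        return [dp, (1.0 - 2.0 * p) / (p * (1.0 - p)) * dp**2]

    sol = solve_ivp(
        rhs,
        (t0, t_eval[-1]),
        [p0, v0],
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
        dense_output=False,
    )
    return sol.y[0]


class TestCourseMapInvariants:
    def test_valid_map_builds(self):
        m = toy_map()
        assert m.n_markers == 2 and m.n_sources == 1

    def test_p0_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            toy_map(p0=(0.0, 0.5))
        with pytest.raises(ValueError, match="p0"):
            toy_map(p0=(1.2, 0.5))

    def test_zero_velocity_rejected(self):
        with pytest.raises(ValueError, match="v0"):
            toy_map(v0=(0.0, 0.2))

    def test_nonpositive_scales_rejected(self):
        for field in ("sigma_noise", "sigma_tau", "sigma_xi"):
            kwargs = dict(
                t0=76.0, p0=np.array([0.3, 0.5]), v0=np.array([0.1, 0.2]),
                sigma_noise=0.05, sigma_tau=4.0, sigma_xi=0.3,
            )
            kwargs[field] = 0.0
            with pytest.raises(ValueError, match=field):
                CourseMap(**kwargs)

    def test_too_many_sources_rejected(self):
        A = np.zeros((2, 2))
        with pytest.raises(ValueError, match="K-1"):
            CourseMap(
                t0=76.0, p0=np.array([0.3, 0.5]), v0=np.array([0.1, 0.2]),
                sigma_noise=0.05, sigma_tau=4.0, sigma_xi=0.3, A=A,
            )

    def test_non_orthogonal_mixing_rejected(self):
        A = np.array([[1.0], [0.0]])
        with pytest.raises(ValueError, match="orthogonal"):
            toy_map().__class__(
                t0=76.0, p0=np.array([0.3, 0.5]), v0=np.array([0.1, 0.2]),
                sigma_noise=0.05, sigma_tau=4.0, sigma_xi=0.3, A=A,
            )


class TestMixingMatrix:
    def test_two_marker_direction_is_unique(self):
        # K=2: the single orthogonal direction is prop. to (g2 v2, -g1 v1)
        p0 = np.array([0.3, 0.5])
        v0 = np.array([0.1, 0.2])
        A = build_mixing_matrix(p0, v0, 1)
        g = metric_weights(p0)
        expected = np.array([g[1] * v0[1], -g[0] * v0[0]])
        expected /= np.linalg.norm(expected)
        assert np.allclose(np.abs(A[:, 0]), np.abs(expected), atol=1e-12)

    def test_full_rank_and_metric_orthogonality(self):
        p0 = np.array([0.2, 0.35, 0.45, 0.15])
        v0 = np.array([0.05, 0.08, 0.03, 0.06])
        A = build_mixing_matrix(p0, v0, 3)
        assert np.linalg.matrix_rank(A) == 3
        u = metric_weights(p0) * v0
        assert np.max(np.abs(A.T @ u)) / np.linalg.norm(u) < 1e-12

    def test_velocity_completes_the_basis(self):
        # appending the metric-weighted velocity raises the rank by one
        p0 = np.array([0.2, 0.35, 0.45, 0.15])
        v0 = np.array([0.05, 0.08, 0.03, 0.06])
        A = build_mixing_matrix(p0, v0, 2)
        u = (metric_weights(p0) * v0).reshape(-1, 1)
        assert np.linalg.matrix_rank(np.hstack([A, u])) == 3

    def test_bounds_enforced(self):
        p0 = np.array([0.3, 0.5])
        v0 = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            build_mixing_matrix(p0, v0, 2)
        with pytest.raises(ValueError):
            build_mixing_matrix(p0, v0, 0)

    def test_deterministic(self):
        p0 = np.array([0.2, 0.35, 0.45])
        v0 = np.array([0.05, 0.08, 0.03])
        assert np.array_equal(build_mixing_matrix(p0, v0, 2), build_mixing_matrix(p0, v0, 2))


class TestGeodesic:
    def test_initial_conditions(self):
        m = toy_map()
        assert np.allclose(geodesic_eval(m, m.t0), m.p0, atol=1e-14)
        h = 1e-6
        deriv = (geodesic_eval(m, m.t0 + h) - geodesic_eval(m, m.t0 - h)) / (2 * h)
        assert np.allclose(deriv, m.v0, rtol=1e-6)

    def test_logistic_limits(self):
        m = toy_map()
        assert np.all(geodesic_eval(m, m.t0 + 1e4) > 1 - 1e-9)
        assert np.all(geodesic_eval(m, m.t0 - 1e4) < 1e-9)

    def test_closed_form_value(self):
        # p0=0.5, v0=0.25, t-t0=1 -> logistic argument is exactly 1
        m = toy_map(p0=(0.5, 0.5), v0=(0.25, 0.25))
        val = geodesic_eval(m, m.t0 + 1.0)
        assert np.allclose(val, 1.0 / (1.0 + np.exp(-1.0)), atol=1e-12)

    def test_matches_geodesic_ode(self):
        # closed-form logistic vs numeric integration of the geodesic ODE
        m = toy_map(K=2, p0=(0.3, 0.5), v0=(0.1, 0.2))
        t_eval = np.linspace(m.t0, m.t0 + 15.0, 40)
        closed = geodesic_eval(m, t_eval)
        for k in range(2):
            numeric = geodesic_ode_solution(m.p0[k], m.v0[k], m.t0, t_eval)
            assert np.max(np.abs(closed[:, k] - numeric)) < 1e-6

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            geodesic_eval(toy_map(), np.inf)

    @given(st.floats(-30.0, 30.0), st.floats(-29.9, 30.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, dt1, dt2):
        m = toy_map()
        lo, hi = sorted((dt1, dt2))
        y_lo = geodesic_eval(m, m.t0 + lo)
        y_hi = geodesic_eval(m, m.t0 + hi)
        assert np.all((y_lo > 0) & (y_lo < 1))
        if hi - lo > 1e-9:
            assert np.all(y_hi > y_lo)  # v0 > 0 componentwise


class TestTimeWarp:
    def test_identity_warp(self):
        m = toy_map()
        z = IndividualEffects(tau=0.0, xi=0.0, sources=np.zeros(1))
        for t in (60.0, 76.0, 90.0):
            assert time_warp(m, z, t) == pytest.approx(t)

    def test_fixed_point(self):
        m = toy_map(t0=78.0)
        for alpha in (0.5, 1.0, 2.0):
            z = IndividualEffects(tau=-2.0, xi=np.log(alpha), sources=np.zeros(1))
            assert time_warp(m, z, 78.0 - 2.0) == pytest.approx(78.0)

    def test_printed_example(self):
        # t0=78, tau=-2, alpha=2, t=76 -> psi = 2*(76-78+2)+78 = 78
        m = toy_map(t0=78.0)
        z = IndividualEffects(tau=-2.0, xi=np.log(2.0), sources=np.zeros(1))
        assert time_warp(m, z, 76.0) == pytest.approx(78.0)


class TestExpParallel:
    def test_null_shift_is_identity(self):
        m = toy_map()
        t = np.linspace(m.t0 - 10, m.t0 + 10, 21)
        assert np.allclose(exp_parallel(m, np.zeros(2), t), geodesic_eval(m, t), atol=1e-14)

    def test_parallel_curves_opposite_shifts(self):
        # identical logistics: orthogonality forces w = (c, -c) and the two
        # markers are advanced/delayed symmetrically
        m = toy_map(p0=(0.4, 0.4), v0=(0.1, 0.1))
        w = m.A[:, 0]
        assert w[0] == pytest.approx(-w[1])
        c = 0.05
        shifted = exp_parallel(m, np.array([c, -c]), m.t0)
        delayed = geodesic_eval(m, m.t0 + c / 0.1)
        assert shifted[0] == pytest.approx(delayed[0])
        advanced = geodesic_eval(m, m.t0 - c / 0.1)
        assert shifted[1] == pytest.approx(advanced[1])

    def test_matches_transport_plus_exponential(self):
        # brute-force oracle: parallel-transport w along the geodesic, then
        # shoot the exponential map, per 1D component
        m = toy_map(p0=(0.3, 0.5), v0=(0.1, 0.2))
        w = m.A[:, 0] * 0.15  # metric-orthogonal by construction
        t_targets = [m.t0 - 6.0, m.t0 + 4.0, m.t0 + 11.0]

        def gamma_k(k, t):
            return geodesic_eval(m, t)[..., k]

        for t_star in t_targets:
            closed = exp_parallel(m, w, t_star)
            for k in range(2):
                # transport ODE along gamma_k: w' + Gamma(gamma) gamma' w = 0
                def transport_rhs(t, wv):
                    # dw/dt = -Gamma(gamma) gamma' w with Gamma = g'/(2g)
                    p = gamma_k(k, t)
                    dp = m.v0[k] * (p * (1 - p)) / (m.p0[k] * (1 - m.p0[k]))
                    gam = -(1.0 - 2.0 * p) / (p * (1.0 - p))
                    return [-gam * dp * wv[0]]

                sol = solve_ivp(
                    transport_rhs, (m.t0, t_star), [w[k]], rtol=1e-10, atol=1e-13
                )
                w_t = sol.y[0, -1]
                # exponential map: geodesic from gamma_k(t*) with velocity w_t
                p_star = gamma_k(k, t_star)

                def geo_rhs(s, y):
                    p, dp = y
                    return [dp, (1.0 - 2.0 * p) / (p * (1.0 - p)) * dp**2]

                sol2 = solve_ivp(
                    geo_rhs, (0.0, 1.0), [p_star, w_t], rtol=1e-10, atol=1e-13
                )
                assert abs(sol2.y[0, -1] - closed[k]) < 1e-6

    def test_zero_velocity_rejected(self):
        m = toy_map()
        m.v0 = np.array([0.1, 0.0])  # corrupt after construction
        with pytest.raises(ValueError):
            exp_parallel(m, np.zeros(2), m.t0)


class TestTrajectory:
    def test_zero_effects_follow_the_normative_curve(self):
        m = toy_map()
        z = IndividualEffects.null(1)
        t = np.linspace(66, 86, 11)
        assert np.allclose(trajectory_eval(m, z, t), geodesic_eval(m, t), atol=1e-14)

    def test_double_speed_halves_the_time(self):
        # alpha=2: f(theta, (0, ln 2, 0), t0 + d/2) = gamma0(t0 + d)
        m = toy_map()
        z = IndividualEffects(tau=0.0, xi=np.log(2.0), sources=np.zeros(1))
        for d in (1.0, 4.0, 10.0):
            assert np.allclose(
                trajectory_eval(m, z, m.t0 + d / 2), geodesic_eval(m, m.t0 + d), atol=1e-12
            )

    def test_composition_of_warp_and_shift(self):
        m = toy_map()
        z = IndividualEffects(tau=2.5, xi=-0.2, sources=np.array([0.7]))
        t = np.linspace(70, 85, 7)
        composed = exp_parallel(m, z.space_shift(m), time_warp(m, z, t))
        assert np.allclose(trajectory_eval(m, z, t), composed, atol=1e-14)

    @given(
        st.floats(-6.0, 6.0),
        st.floats(-0.6, 0.6),
        st.floats(-2.0, 2.0),
        st.floats(55.0, 95.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_values_strictly_inside_unit_interval(self, tau, xi, s, t):
        m = toy_map()
        z = IndividualEffects(tau=tau, xi=xi, sources=np.array([s]))
        y = trajectory_eval(m, z, t)
        assert np.all((y > 0.0) & (y < 1.0))
        w = z.space_shift(m)
        assert abs(metric_weights(m.p0) * m.v0 @ w) < 1e-10


class TestLogPosterior:
    def test_zero_residual_zero_prior_is_maximal(self):
        m = toy_map()
        z = IndividualEffects.null(1)
        t = np.array([74.0, 77.0])
        y = trajectory_eval(m, z, t)
        top = log_posterior(m, z, t, y)
        assert top == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(20):
            other = IndividualEffects(
                tau=rng.normal(0, 3), xi=rng.normal(0, 0.3), sources=rng.normal(0, 1, 1)
            )
            assert log_posterior(m, other, t, y) <= top + 1e-12

    def test_monotone_in_noise_scale(self):
        m = toy_map()
        z = IndividualEffects(tau=1.0, xi=0.1, sources=np.array([0.5]))
        t = np.array([74.0, 77.0])
        y = np.clip(trajectory_eval(m, z, t) + 0.1, 0.01, 0.95)
        lp1 = log_posterior(m, z, t, y)
        m2 = m.copy()
        m2.sigma_noise = 2 * m.sigma_noise
        lp2 = log_posterior(m2, z, t, y)
        assert lp2 > lp1

    def test_hand_expanded_sum(self):
        # K=2, 2 visits: 4 Gaussian terms + 3 prior terms, expanded by hand
        m = toy_map()
        z = IndividualEffects(tau=1.0, xi=-0.1, sources=np.array([0.4]))
        t = np.array([73.0, 78.0])
        y = np.array([[0.2, 0.4], [0.35, 0.7]])
        f = trajectory_eval(m, z, t)
        expected = (
            -((y[0, 0] - f[0, 0]) ** 2 + (y[0, 1] - f[0, 1]) ** 2
              + (y[1, 0] - f[1, 0]) ** 2 + (y[1, 1] - f[1, 1]) ** 2) / (2 * 0.05**2)
            - 1.0**2 / (2 * 4.0**2)
            - (-0.1) ** 2 / (2 * 0.3**2)
            - 0.4**2 / 2
        )
        assert log_posterior(m, z, t, y) == pytest.approx(expected, rel=1e-12)

    def test_missing_entries_contribute_nothing(self):
        m = toy_map()
        z = IndividualEffects(tau=1.0, xi=-0.1, sources=np.array([0.4]))
        t = np.array([73.0, 78.0])
        y = np.array([[0.2, np.nan], [0.35, 0.7]])
        y_full = np.array([[0.2, 0.99], [0.35, 0.7]])
        lp_missing = log_posterior(m, z, t, y)
        assert lp_missing > log_posterior(m, z, t, y_full)

    def test_all_missing_rejected(self):
        m = toy_map()
        z = IndividualEffects.null(1)
        with pytest.raises(ValueError):
            log_posterior(m, z, [75.0], [[np.nan, np.nan]])


class TestLongitudinalDataset:
    def test_strictly_increasing_times_required(self):
        with pytest.raises(ValueError, match="increasing"):
            LongitudinalDataset(
                ["a"], [np.array([75.0, 74.0])], [np.full((2, 2), 0.5)], ["m1", "m2"]
            )

    def test_calibration_requires_two_visits(self):
        ds = LongitudinalDataset(
            ["solo"], [np.array([75.0])], [np.full((1, 2), 0.5)], ["m1", "m2"]
        )
        with pytest.raises(ValueError, match="solo"):
            ds.require_calibratable()

    def test_padded_roundtrip_and_mask(self):
        vals0 = np.array([[0.1, np.nan], [0.2, 0.3]])
        vals1 = np.array([[0.5, 0.6]])
        ds = LongitudinalDataset(
            ["a", "b"], [np.array([70.0, 71.0]), np.array([75.0])],
            [vals0, vals1], ["m1", "m2"],
        )
        T, Y, M = ds.padded()
        assert T.shape == (2, 2) and M.sum() == 5
        assert not M[0, 0, 1] and not M[1, 1].any()
        df = ds.to_dataframe()
        back = LongitudinalDataset.from_dataframe(df)
        assert back.subject_ids == ["a", "b"]
        assert np.allclose(back.values[0], vals0, equal_nan=True)

    def test_duplicate_visits_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"ID": ["a", "a"], "TIME": [70.0, 70.0], "m1": [0.1, 0.2], "m2": [0.3, 0.4]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            LongitudinalDataset.from_dataframe(df)
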