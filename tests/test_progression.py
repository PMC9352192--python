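"""Time to progression: exact crossing, asymptotics, turning point, sweeps."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import spearmanr

from stemflux import (
    EigenStructure,
    RateConstants,
    StabilityLabel,
    TumorState,
    UndefinedApproximationError,
    ValidationError,
    build_system_matrix,
    eigenstructure,
    rates_at_dose,
    sweep_psr_esr,
    tmin_tp_parametric,
    ttp_approx,
    ttp_dose_curve,
    ttp_exact,
    ttp_exact_batch,
    turning_point,
)
from .conftest import random_rates, random_state

STABLE_RATES = RateConstants(
    b_S=0.1, d_S=0.3, k_SR=0.01, b_R=0.1, d_R=0.3, k_RS=0.01
)
GROWING_RATES = RateConstants(
    b_S=0.3, d_S=0.05, k_SR=0.01, b_R=0.2, d_R=0.05, k_RS=0.01
)


def dense_crossing_oracle(rates, x0, t_max, dt=1e-4):
    """Brute-force TTP: adaptive integration + sign-change scan at step dt."""
    A = build_system_matrix(rates).as_array()
    sol = solve_ivp(
        lambda _, x: A @ x, (0.0, t_max), x0.as_vector(),
        rtol=1e-11, atol=1e-11 * x0.N, dense_output=True,
    )
    # scan in chunks to bound memory
    lo = dt
    while lo < t_max:
        hi = min(lo + 50.0, t_max)
        t = np.arange(lo, hi, dt)
        N = sol.sol(t).sum(axis=0)
        above = N > x0.N
        if above.any():
            return t[np.argmax(above)]
        lo = hi
    return None


class TestTTPExact:
    def test_immediately_growing_population_has_zero_ttp(self, horizon):
        res = ttp_exact(GROWING_RATES, TumorState(x1=1e6, x2=1e4), horizon)
        assert res.t_P == 0.0
        assert not res.censored
        assert res.t_min == 0.0

    def test_extinction_is_censored(self, horizon):
        res = ttp_exact(STABLE_RATES, TumorState(x1=1e6, x2=1e4), horizon)
        assert res.censored
        assert res.t_P == horizon
        assert res.stability.label is StabilityLabel.STABLE_NODE

    @pytest.mark.parametrize("m", [30.0, 45.0, 85.0])
    def test_matches_dense_crossing_oracle(self, case_a, x0, horizon, m):
        rates = rates_at_dose(case_a.pharmacodynamics, m)
        res = ttp_exact(rates, x0, horizon)
        assert res.stability.label is StabilityLabel.SADDLE
        t_cross = dense_crossing_oracle(rates, x0, res.t_P * 1.5)
        assert t_cross is not None
        assert abs(res.t_P - t_cross) < 1e-3

    def test_crossing_value_and_strict_recovery(self, case_a, x0, horizon):
        rates = rates_at_dose(case_a.pharmacodynamics, 40.0)
        res = ttp_exact(rates, x0, horizon)
        eig = eigenstructure(build_system_matrix(rates), x0)

        def N(t):
            return eig.alpha1 * np.exp(eig.lambda1 * t) + eig.alpha2 * np.exp(
                eig.lambda2 * t
            )

        assert N(res.t_P) == pytest.approx(x0.N, rel=1e-6)
        assert N(res.t_P * 1.01) > x0.N
        assert 0 < res.t_min < res.t_P

    def test_unique_sign_change_in_saddle_regime(self, case_pds, x0, horizon):
        """N(t) - N(0) crosses zero exactly once on (0, horizon]."""
        for cid, pd_set in case_pds.items():
            for m in (25.0, 40.0, 60.0, 100.0):
                rates = rates_at_dose(pd_set, m)
                res = ttp_exact(rates, x0, horizon)
                if res.stability.label is not StabilityLabel.SADDLE:
                    continue
                eig = eigenstructure(build_system_matrix(rates), x0)
                t = np.arange(1e-3, horizon, 1e-2)
                N = eig.alpha1 * np.exp(eig.lambda1 * t) + eig.alpha2 * np.exp(
                    np.minimum(eig.lambda2 * t, 700.0)
                )
                signs = np.sign(N - x0.N)
                changes = np.count_nonzero(np.diff(signs[signs != 0]))
                if res.t_P > 0 and not res.censored:
                    assert changes == 1, f"case {cid}, m={m}"

    def test_horizon_validation(self, x0):
        with pytest.raises(ValidationError):
            ttp_exact(STABLE_RATES, x0, 0.0)


class TestTTPApprox:
    def _eig(self, c1, lam1=0.02):
        v1 = np.array([1.0, 0.0])
        v2 = np.array([0.0, 1.0])
        return EigenStructure(
            lambda1=lam1, lambda2=-0.1, v1=v1, v2=v2, c1=c1, c2=0.5
        )

    def test_aligned_initial_condition_gives_zero(self):
        N0 = 1e6
        assert ttp_approx(self._eig(c1=N0), N0) == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_scaled_by_e_gives_inverse_rate(self):
        N0 = 1e6
        eig = self._eig(c1=N0 / np.e, lam1=0.02)
        assert ttp_approx(eig, N0) == pytest.approx(1 / 0.02, rel=1e-12)

    def test_requires_growing_mode(self):
        eig = EigenStructure(
            lambda1=-0.01, lambda2=-0.1,
            v1=np.array([1.0, 0.0]), v2=np.array([0.0, 1.0]), c1=1.0, c2=0.0,
        )
        with pytest.raises(UndefinedApproximationError):
            ttp_approx(eig, 10.0)

    def test_requires_positive_amplitude(self):
        with pytest.raises(UndefinedApproximationError):
            ttp_approx(self._eig(c1=-1.0), 10.0)

    def test_accurate_when_decaying_mode_negligible(self, case_a, x0, horizon):
        """< 1 % relative error whenever |alpha2| e^{l2 tP} < 1e-3 N0."""
        checked = 0
        for m in np.linspace(25, 100, 16):
            rates = rates_at_dose(case_a.pharmacodynamics, float(m))
            res = ttp_exact(rates, x0, horizon)
            if res.t_P_star is None or res.t_P == 0:
                continue
            eig = eigenstructure(build_system_matrix(rates), x0)
            decaying = abs(eig.alpha2) * np.exp(eig.lambda2 * res.t_P)
            if decaying < 1e-3 * x0.N:
                checked += 1
                assert abs(res.t_P_star - res.t_P) / res.t_P < 0.01
        assert checked >= 5

    def test_error_invariant_under_population_scaling(self, case_a, horizon):
        """Linearity: scaling x0 with direction fixed rescales N(t) and the
        progression threshold N(0) together, so both the exact and the
        approximate TTP — hence their relative error — are unchanged."""
        rates = rates_at_dose(case_a.pharmacodynamics, 30.0)
        results = []
        for scale in (1.0, 10.0, 100.0):
            x0 = TumorState(x1=0.99e7 * scale, x2=0.01e7 * scale)
            res = ttp_exact(rates, x0, horizon)
            assert res.t_P_star is not None
            results.append(res)
        for res in results[1:]:
            assert res.t_P == pytest.approx(results[0].t_P, rel=1e-9)
            assert res.t_P_star == pytest.approx(results[0].t_P_star, rel=1e-9)


class TestTurningPoint:
    def test_growing_population(self, horizon):
        assert turning_point(GROWING_RATES, TumorState(x1=1e6, x2=1e4), horizon) == 0.0

    def test_decaying_population_boundary(self, horizon):
        assert (
            turning_point(STABLE_RATES, TumorState(x1=1e6, x2=1e4), horizon)
            == horizon
        )

    def test_interior_minimum_matches_dense_argmin(self, case_a, x0, horizon):
        rates = rates_at_dose(case_a.pharmacodynamics, 35.0)
        t_min = turning_point(rates, x0, horizon)
        assert 0 < t_min < horizon
        eig = eigenstructure(build_system_matrix(rates), x0)
        t = np.arange(0.0, 3 * t_min, 1e-4)
        N = eig.alpha1 * np.exp(eig.lambda1 * t) + eig.alpha2 * np.exp(eig.lambda2 * t)
        assert abs(t[np.argmin(N)] - t_min) < 1e-3
        # stationarity of N at the turning point
        dN = eig.alpha1 * eig.lambda1 * np.exp(eig.lambda1 * t_min) + (
            eig.alpha2 * eig.lambda2 * np.exp(eig.lambda2 * t_min)
        )
        assert abs(dN) < 1e-9 * x0.N


class TestDoseCurve:
    def test_case_b_monotone_non_decreasing(self, case_pds, x0, horizon):
        curve = ttp_dose_curve(case_pds["B"], x0, np.linspace(0, 100, 51), horizon)
        assert np.all(np.diff(curve.t_P) >= -1e-9)
        assert curve.argmax_dose == 100.0

    def test_case_a_interior_maximum(self, case_pds, x0, horizon):
        curve = ttp_dose_curve(case_pds["A"], x0, np.linspace(0, 100, 51), horizon)
        assert curve.argmax_dose < 100.0
        assert curve.max_t_P > curve.t_P[-1]

    def test_single_dose_grid_equals_direct_call(self, case_a, x0, horizon):
        curve = ttp_dose_curve(case_a.pharmacodynamics, x0, [42.0], horizon)
        direct = ttp_exact(rates_at_dose(case_a.pharmacodynamics, 42.0), x0, horizon)
        assert len(curve.doses) == 1
        assert curve.t_P[0] == direct.t_P
        assert curve.lambda1[0] == direct.stability.lambda1

    def test_lambda1_ttp_rank_inversion(self, case_a, x0, horizon):
        """Faster regrowth mode => earlier progression (negative rank corr)."""
        curve = ttp_dose_curve(case_a.pharmacodynamics, x0,
                               np.linspace(0, 100, 101), horizon)
        saddle = (np.array(curve.stability) == "SADDLE") & (curve.t_P > 0)
        rho = spearmanr(curve.lambda1[saddle], curve.t_P[saddle]).statistic
        assert rho < 0

    def test_columns_same_length(self, case_a, x0, horizon):
        curve = ttp_dose_curve(case_a.pharmacodynamics, x0, [0.0, 50.0], horizon)
        frame = curve.to_frame()
        assert len(frame) == 2
        assert set(frame.columns) == {
            "m", "t_P", "t_P_star", "lambda1", "lambda2", "stability", "censored"
        }


class TestBatchKernel:
    def test_matches_scalar_path_on_random_draws(self, horizon):
        rng = np.random.default_rng(37)
        n = 300
        rates = {k: np.empty(n) for k in ("b_S", "b_R", "d_S", "d_R", "k_SR", "k_RS")}
        x1 = np.empty(n)
        x2 = np.empty(n)
        scalars = []
        for i in range(n):
            rc = random_rates(rng)
            st = random_state(rng)
            for k in rates:
                rates[k][i] = getattr(rc, k)
            x1[i], x2[i] = st.x1, st.x2
            scalars.append(ttp_exact(rc, st, horizon))
        t_P, censored = ttp_exact_batch(rates, x1, x2, horizon)
        for i, res in enumerate(scalars):
            assert censored[i] == res.censored
            assert t_P[i] == pytest.approx(res.t_P, rel=1e-8, abs=1e-8)

    def test_broadcasting_over_doses(self, case_a, x0, horizon):
        m = np.linspace(0, 100, 21)
        pd_set = case_a.pharmacodynamics
        rates = {
            "b_S": pd_set.b_S, "b_R": pd_set.b_R, "k_RS": pd_set.k_RS,
            "d_S": pd_set.ds_curve(m), "d_R": pd_set.dr_curve(m),
            "k_SR": pd_set.ksr_curve(m),
        }
        t_P, _ = ttp_exact_batch(rates, x0.x1, x0.x2, horizon)
        curve = ttp_dose_curve(pd_set, x0, m, horizon)
        np.testing.assert_allclose(t_P, curve.t_P, rtol=1e-8, atol=1e-8)


@pytest.fixture(scope="module")
def surface(case_pds, x0, horizon):
    return sweep_psr_esr(
        case_pds["A"],
        P_SR_grid=[10.0, 30.0, 50.0, 70.0],
        E_SR_grid=[0.02, 0.1, 0.2],
        x0=x0,
        m_grid=np.linspace(0, 100, 41),
        horizon=horizon,
    )


class TestSweep:
    def test_maximum_dominates_mtd_value(self, surface):
        assert np.all(surface.max_t_P >= surface.t_P_at_MTD - 1e-9)

    def test_high_potency_column_peaks_at_mtd(self, surface):
        # low P_SR: induction saturates early, TTP is monotone in dose
        assert np.all(surface.argmax_dose[:, 0] == 100.0)

    def test_low_potency_column_interior_optimum(self, surface):
        assert np.all(surface.argmax_dose[:, 2] < 100.0)

    def test_mtd_ttp_decreases_with_induction_efficacy(self, surface):
        for j in range(surface.P_SR.size):
            col = surface.t_P_at_MTD[:, j]
            assert np.all(np.diff(col) <= 1e-9)

    def test_long_format_frame(self, surface):
        frame = surface.to_frame()
        assert len(frame) == 12
        assert set(frame.columns) == {
            "P_SR", "E_SR", "argmax_dose", "max_tP", "tP_at_MTD"
        }


class TestTminTpParametric:
    def test_progression_follows_turning_point(self, case_pds, x0, horizon):
        for cid, pd_set in case_pds.items():
            tab = tmin_tp_parametric(pd_set, x0, np.linspace(5, 100, 20), horizon)
            ok = ~tab["censored"] & (tab["t_P"] > 0)
            assert np.all(tab.loc[ok, "t_P"] > tab.loc[ok, "t_min"])

    def test_case_a_reference_doses_all_finite(self, case_a, x0, horizon):
        tab = tmin_tp_parametric(
            case_a.pharmacodynamics, x0, [23.0, 35.0, 45.0, 85.0], horizon
        )
        assert len(tab) == 4
        assert not tab["censored"].any()
        assert np.all(np.isfinite(tab["t_min"]))
        assert np.all(tab["t_P"] > tab["t_min"])
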