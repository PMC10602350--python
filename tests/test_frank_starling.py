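"""Two-compartment circulation model: map algebra, dynamics and stochastics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiovar import frank_starling as fs
from cardiovar.errors import NonPhysicalParametersError, UnstableMapError
from cardiovar.variability import poincare_indices


def random_valid_params(rng: np.random.Generator) -> fs.CompartmentParams:
    """Physiologically admissible draws.

    Requires R C_A >= 1 (per-cycle passive return cannot overshoot and empty
    the arterial compartment in a single relaxation step).
    """
    c_a = rng.uniform(0.5, 5.0)
    c_v = rng.uniform(10.0, 100.0)
    r = rng.uniform(1.2 / c_a, 10.0)
    beta = rng.uniform(0.05, 1.0) * c_v
    v_t = rng.uniform(100.0, 1000.0)
    return fs.CompartmentParams(c_a=c_a, c_v=c_v, r=r, beta=beta, v_t=v_t)


params_strategy = st.builds(
    lambda ca, cv, r, bf, vt: fs.CompartmentParams(
        c_a=ca, c_v=cv, r=r, beta=bf * cv, v_t=vt),
    ca=st.floats(0.5, 5.0), cv=st.floats(10.0, 100.0), r=st.floats(1.0, 10.0),
    bf=st.floats(0.01, 1.0), vt=st.floats(100.0, 1000.0),
)


class TestPressuresAndCoefficients:
    def test_pressure_is_volume_over_compliance(self):
        p = fs.CompartmentParams(c_a=2.0, c_v=50.0, r=3.0, beta=5.0, v_t=300.0)
        pa, pv = fs.pressures(fs.CompartmentState(v_v=100.0, v_a=200.0), p)
        assert pv == pytest.approx(2.0)
        assert pa == pytest.approx(100.0)

    def test_zero_venous_volume_gives_zero_pressure(self):
        p = fs.DEFAULT_PARAMS
        _, pv = fs.pressures(fs.CompartmentState(v_v=0.0, v_a=p.v_t), p)
        assert pv == 0.0

    def test_pressures_invariant_to_joint_volume_compliance_scaling(self):
        p1 = fs.CompartmentParams(c_a=2.0, c_v=50.0, r=3.0, beta=5.0, v_t=300.0)
        p2 = fs.CompartmentParams(c_a=4.0, c_v=100.0, r=3.0, beta=5.0, v_t=600.0)
        s1 = fs.CompartmentState(v_v=100.0, v_a=200.0)
        s2 = fs.CompartmentState(v_v=200.0, v_a=400.0)
        assert fs.pressures(s1, p1) == pytest.approx(fs.pressures(s2, p2))

    def test_vanishing_gain_limit_of_coefficients(self):
        # as beta -> 0 the map coefficients tend to A = bracket term, B = 0
        base = fs.DEFAULT_PARAMS
        c = fs.coefficients(base.replace(beta=1e-12))
        bracket = 1 - (1 / base.r) * (1 / base.c_a + 1 / base.c_v)
        assert c.a == pytest.approx(bracket, rel=1e-9)
        assert c.b == pytest.approx(0.0, abs=1e-9)

    def test_beta_equal_cv_collapses_memory(self):
        # beta = C_V empties the venous factor: A = 0 and the fixed point is B
        p = fs.DEFAULT_PARAMS.replace(beta=fs.DEFAULT_PARAMS.c_v)
        c = fs.coefficients(p)
        assert c.a == 0.0
        assert fs.fixed_point(p).sv == pytest.approx(c.b)

    def test_coefficients_match_regression_on_mechanistic_trajectory(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            c = fs.coefficients(p)
            if not c.stable:
                continue
            state = fs.CompartmentState(v_v=0.3 * p.v_t, v_a=0.7 * p.v_t)
            svs = []
            for _ in range(12):
                out = fs.step(state, p)
                state = out.state
                svs.append(out.sv)
            svs = np.array(svs)
            slope, intercept = np.polyfit(svs[:-1], svs[1:], 1)
            assert slope == pytest.approx(c.a, rel=1e-9, abs=1e-9)
            assert intercept == pytest.approx(c.b, rel=1e-9, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            fs.CompartmentParams(c_a=2.0, c_v=50.0, r=3.0, beta=60.0, v_t=300.0)
        with pytest.raises(ValueError):
            fs.CompartmentParams(c_a=-1.0, c_v=50.0, r=3.0, beta=5.0, v_t=300.0)


class TestStepDynamics:
    def test_single_step_obeys_affine_recursion_exactly(self, rng):
        for _ in range(200):
            p = random_valid_params(rng)
            c = fs.coefficients(p)
            state = fs.CompartmentState(
                v_v=rng.uniform(0.05, 0.95) * p.v_t, v_a=0.0)
            state = fs.CompartmentState(v_v=state.v_v, v_a=p.v_t - state.v_v)
            r1 = fs.step(state, p)
            r2 = fs.step(r1.state, p)
            assert r2.sv == pytest.approx(c.a * r1.sv + c.b, rel=1e-12, abs=1e-12)

    def test_state_at_fixed_point_is_stationary(self):
        p = fs.DEFAULT_PARAMS
        fp = fs.fixed_point(p)
        state = fs.CompartmentState(v_v=fp.v_v, v_a=p.v_t - fp.v_v)
        out = fs.step(state, p)
        assert out.sv == pytest.approx(fp.sv, rel=1e-12)
        assert out.state.v_v == pytest.approx(fp.v_v, rel=1e-12)

    def test_zero_gain_relaxes_toward_pressure_equilibrium(self):
        # beta ~ 0: no pumping; passive flow equalises pressures
        p = fs.DEFAULT_PARAMS.replace(beta=1e-12)
        state = fs.CompartmentState(v_v=0.9 * p.v_t, v_a=0.1 * p.v_t)
        for _ in range(2000):
            out = fs.step(state, p)
            assert out.sv == pytest.approx(0.0, abs=1e-9)
            state = out.state
        pa, pv = fs.pressures(state, p)
        assert pa == pytest.approx(pv, rel=1e-6)

    def test_negative_stroke_volume_is_clipped(self):
        p = fs.DEFAULT_PARAMS
        state = fs.CompartmentState(v_v=p.v_t / 2, v_a=p.v_t / 2)
        _, pv = fs.pressures(state, p)
        out = fs.step(state, p, preload_noise=-2 * pv)
        assert out.clipped and out.sv == 0.0

    def test_overdrawn_venous_volume_raises(self):
        p = fs.DEFAULT_PARAMS.replace(beta=fs.DEFAULT_PARAMS.c_v)
        state = fs.CompartmentState(v_v=10.0, v_a=p.v_t - 10.0)
        with pytest.raises(NonPhysicalParametersError):
            fs.step(state, p, preload_noise=100.0)

    @settings(derandomize=True, max_examples=100)
    @given(params_strategy, st.floats(0.05, 0.95), st.floats(-0.5, 0.5))
    def test_blood_volume_conserved_exactly(self, p, frac, noise):
        state = fs.CompartmentState(v_v=frac * p.v_t, v_a=(1 - frac) * p.v_t)
        try:
            out = fs.step(state, p, preload_noise=noise)
        except NonPhysicalParametersError:
            return
        assert out.state.v_v + out.state.v_a == pytest.approx(p.v_t, rel=1e-14)


class TestFixedPointAndConvergence:
    def test_iteration_lands_on_fixed_point(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            c = fs.coefficients(p)
            if not c.stable:
                continue
            fp = fs.fixed_point(p)
            state = fs.CompartmentState(v_v=p.v_t / 2, v_a=p.v_t / 2)
            sv = None
            for _ in range(500):
                out = fs.step(state, p)
                state, sv = out.state, out.sv
            assert sv == pytest.approx(fp.sv, abs=1e-9)

    def test_geometric_convergence_bound(self):
        p = fs.DEFAULT_PARAMS
        c = fs.coefficients(p)
        fp = fs.fixed_point(p)
        sim = fs.simulate(p, 200, noise=fs.NoiseSpec(sigma=0.0), initial_v_v=0.3 * p.v_t)
        err0 = abs(sim.sv[0] - fp.sv)
        for i, sv in enumerate(sim.sv):
            assert abs(sv - fp.sv) <= abs(c.a) ** i * err0 * (1 + 1e-12) + 1e-12

    def test_unstable_map_raises(self):
        p = fs.CompartmentParams(c_a=0.5, c_v=1.0, r=0.1, beta=0.1, v_t=100.0)
        assert not fs.coefficients(p).stable
        with pytest.raises(UnstableMapError):
            fs.fixed_point(p)
        with pytest.raises(UnstableMapError):
            fs.simulate(p, 100, noise=fs.NoiseSpec(sigma=0.1, seed=0))


class TestStochastics:
    def test_noiseless_simulation_converges_to_fixed_point(self):
        p = fs.DEFAULT_PARAMS
        sim = fs.simulate(p, 600, noise=fs.NoiseSpec(sigma=0.0))
        assert sim.sv[-1] == pytest.approx(fs.fixed_point(p).sv, abs=1e-9)

    @pytest.mark.parametrize("entry", ["recursion_additive", "preload"])
    def test_stationary_variance_matches_closed_form(self, entry):
        p = fs.params_for_a(0.5)
        noise = fs.NoiseSpec(entry=entry, sigma=0.3, seed=42)
        mom = fs.stationary_moments(p, noise)
        x = fs.simulate(p, 200_000, noise).stationary()
        # MC standard error of the variance of an AR(1) sample
        a = fs.coefficients(p).a
        se = mom.variance * np.sqrt(2 * (1 + a * a) / ((1 - a * a) * x.size))
        assert x.var() == pytest.approx(mom.variance, abs=3 * se)
        assert x.mean() == pytest.approx(mom.mean, rel=0.01)

    def test_poincare_indices_match_stationary_forms(self):
        p = fs.params_for_a(0.6)
        noise = fs.NoiseSpec(entry="preload", sigma=0.25, seed=9)
        mom = fs.stationary_moments(p, noise)
        idx = poincare_indices(fs.simulate(p, 200_000, noise).stationary())
        assert idx.sd1 == pytest.approx(mom.sd1, rel=0.02)
        assert idx.sd2 == pytest.approx(mom.sd2, rel=0.02)

    def test_white_noise_limit(self):
        p = fs.DEFAULT_PARAMS.replace(beta=fs.DEFAULT_PARAMS.c_v)  # A = 0
        noise = fs.NoiseSpec(entry="recursion_additive", sigma=0.7, seed=1)
        mom = fs.stationary_moments(p, noise)
        assert mom.variance == pytest.approx(0.49)
        assert mom.sd1 == mom.sd2 == pytest.approx(0.7)

    def test_variance_increases_with_memory(self):
        grid = [0.0, 0.2, 0.4, 0.6, 0.8, 0.9]
        base = fs.DEFAULT_PARAMS.replace(r=20.0)  # bracket close to 1: A up to 0.97 reachable
        noise = fs.NoiseSpec(entry="recursion_additive", sigma=0.5, seed=0)
        variances = [fs.stationary_moments(fs.params_for_a(a, base), noise).variance for a in grid]
        assert np.all(np.diff(variances) > 0)

    def test_parameter_recovery_by_regression(self):
        p = fs.params_for_a(0.5)
        c = fs.coefficients(p)
        noise = fs.NoiseSpec(entry="recursion_additive", sigma=0.5, seed=3)
        x = fs.simulate(p, 10_100, noise).sv[100:]
        X, y = x[:-1], x[1:]
        slope, intercept = np.polyfit(X, y, 1)
        resid = y - (slope * X + intercept)
        s2 = resid.var(ddof=2)
        sxx = ((X - X.mean()) ** 2).sum()
        se_slope = np.sqrt(s2 / sxx)
        se_int = np.sqrt(s2 * (1 / X.size + X.mean() ** 2 / sxx))
        assert abs(slope - c.a) < 3 * se_slope
        assert abs(intercept - c.b) < 3 * se_int

    def test_mechanistic_simulation_conserves_volume(self):
        p = fs.DEFAULT_PARAMS
        traj = fs.simulate_mechanistic(p, 5000, fs.NoiseSpec(entry="preload", sigma=0.3, seed=5))
        assert np.allclose(traj.v_v + traj.v_a, p.v_t, rtol=1e-13, atol=1e-9)


class TestBetaSweep:
    def test_gain_lowers_memory_and_raises_output(self):
        noise = fs.NoiseSpec(entry="preload", sigma=0.2, seed=0)
        sweep = fs.beta_sweep(fs.DEFAULT_PARAMS, np.linspace(0.5, 50.0, 25), noise)
        assert np.all(np.diff(sweep["A"]) < 0)          # A decreases with beta
        assert np.all(np.diff(sweep["SV_bar"]) > 0)     # output rises with beta
        # preload-noise variability vanishes with contractility
        assert sweep["sd"].iloc[0] < 0.25 * sweep["sd"].iloc[-1]

    def test_preload_sd_vanishes_as_beta_to_zero(self):
        noise = fs.NoiseSpec(entry="preload", sigma=0.2, seed=0)
        grid = np.array([1e-4, 1e-3, 1e-2, 0.1, 1.0])
        sweep = fs.beta_sweep(fs.DEFAULT_PARAMS, grid, noise)
        assert np.all(np.diff(sweep["sd"]) > 0)
        assert sweep["sd"].iloc[0] < 1e-4

    def test_unstable_rows_flagged_without_moments(self):
        p = fs.CompartmentParams(c_a=0.5, c_v=1.0, r=0.1, beta=0.5, v_t=100.0)
        sweep = fs.beta_sweep(p, [0.01, 1.0], fs.NoiseSpec(sigma=0.1))
        unstable = sweep[~sweep["stable"]]
        assert len(unstable) >= 1
        assert unstable[["SV_bar", "sd", "SD1", "SD2"]].isna().all().all()

    def test_empty_or_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            fs.beta_sweep(fs.DEFAULT_PARAMS, [], fs.NoiseSpec())
        with pytest.raises(ValueError):
            fs.beta_sweep(fs.DEFAULT_PARAMS, [100.0], fs.NoiseSpec())
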