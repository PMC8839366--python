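import numpy as np
import pytest
from scipy.integrate import solve_ivp

from delaykin import (
    ESKineticParams,
    GammaDelayKernel,
    InitialCondition,
    IntegratorSettings,
    MMRates,
    build_model,
    conservation_report,
    evaluate_rhs,
    integrate,
    oscillation_metrics,
    truncation_bound,
)
from delaykin.engine import DivergenceError
from delaykin.models import ModelError


def chain_trick_reference(kd, a, m, nS0, nE0, t_eval):
    """Independent oracle: integer-shape gamma delay as a cascade of m+1
    first-order stages driven by kd*nE*nS, solved as stiff-free ODEs."""
    m = int(m)

    def rhs(t, y):
        S, E = y[0], y[1]
        z = y[3:]
        u = E * S
        out = np.empty_like(y)
        out[0] = -kd * u
        out[1] = -kd * u + kd * z[-1]
        out[2] = kd * z[-1]
        out[3] = a * (u - z[0])
        for j in range(1, m + 1):
            out[3 + j] = a * (z[j - 1] - z[j])
        return out

    y0 = np.zeros(3 + m + 1)
    y0[0], y0[1] = nS0, nE0
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), y0, rtol=1e-10, atol=1e-12, dense_output=True
    )
    return sol.sol(t_eval)[:3]


class TestIntegrate:
    def test_zero_delay_reduces_to_exponential_decay(self):
        model = build_model("es_discrete", ESKineticParams(kd=1.0, delay=0.0))
        traj = integrate(
            model, InitialCondition.single(1.0, 1.0), 5.0, IntegratorSettings(dt=0.01)
        )
        np.testing.assert_allclose(traj["E"], 1.0, atol=1e-12)
        np.testing.assert_allclose(traj["S"], np.exp(-traj.times), atol=1e-4)
        assert traj["S"][-1] == pytest.approx(np.exp(-5.0), abs=1e-4)

    def test_zero_rates_keep_state_constant(self):
        model = build_model("mm", MMRates(0.0, 0.0, 0.0))
        traj = integrate(
            model, InitialCondition.single(0.7, 0.3), 10.0, IntegratorSettings(dt=0.1)
        )
        assert np.all(traj.values == traj.values[0])

    def test_chain_trick_oracle_agreement(self):
        kern = GammaDelayKernel(rate_a=1.0, shape_m=2.0, tau_min=0.0)
        model = build_model(
            "es_distributed",
            ESKineticParams(kd=0.05, delay=(kern, truncation_bound(kern, 0.9999))),
        )
        traj = integrate(
            model, InitialCondition.single(1.0, 1.0), 100.0, IntegratorSettings(dt=0.01)
        )
        ref = chain_trick_reference(0.05, 1.0, 2, 1.0, 1.0, traj.times)
        assert np.max(np.abs(traj.values.T - ref)) <= 1e-3

    def test_observed_order_at_least_two(self):
        model = build_model("es_discrete", ESKineticParams(kd=0.5, delay=1.0))
        init = InitialCondition.single(1.0, 0.8)
        sols = {}
        for dt in (0.1, 0.05, 0.025):
            traj = integrate(model, init, 20.0, IntegratorSettings(dt=dt))
            sols[dt] = traj.series("S", np.arange(0.0, 20.1, 0.5))
        e1 = np.max(np.abs(sols[0.1] - sols[0.025]))
        e2 = np.max(np.abs(sols[0.05] - sols[0.025]))
        order = np.log2(e1 / e2) if e2 > 0 else 2.0
        assert order >= 1.8

    def test_degenerate_kernel_approaches_discrete_delay(self):
        kd, nS0, nE0, t_end = 0.3, 1.0, 1.0, 15.0
        disc = build_model("es_discrete", ESKineticParams(kd, 1.0))
        st = IntegratorSettings(dt=0.005)
        ref = integrate(disc, InitialCondition.single(nS0, nE0), t_end, st)
        gaps = []
        for a in (400.0, 1600.0):  # variance 1/400, then /4
            kern = GammaDelayKernel(a, a - 1.0, 0.0)  # mean 1
            model = build_model(
                "es_distributed",
                ESKineticParams(kd, (kern, truncation_bound(kern, 0.95))),
            )
            traj = integrate(model, InitialCondition.single(nS0, nE0), t_end, st)
            gaps.append(np.max(np.abs(traj.values - ref.values)))
        dynamic_range = ref["S"].max() - ref["S"].min()
        assert gaps[0] < 0.01 * dynamic_range
        assert gaps[1] < gaps[0]

    def test_divergence_names_first_bad_step(self):
        model = build_model("es_discrete", ESKineticParams(kd=1e12, delay=0.0))
        with pytest.raises(DivergenceError, match="step"):
            integrate(model, InitialCondition.single(1.0, 1.0), 10.0,
                      IntegratorSettings(dt=0.5))

    def test_dt_snaps_down_to_divide_discrete_delay(self):
        model = build_model("es_discrete", ESKineticParams(kd=0.1, delay=1.0))
        with pytest.warns(UserWarning, match="adjusted"):
            traj = integrate(model, InitialCondition.single(1.0, 1.0), 5.0,
                             IntegratorSettings(dt=0.3))
        assert traj.dt <= 0.3
        assert (1.0 / traj.dt) == pytest.approx(round(1.0 / traj.dt))

    def test_compiled_loop_matches_reference_rhs(self):
        # one Heun step of the compiled loop against the pure-Python RHS
        kern = GammaDelayKernel(2.0, 1.0, 0.5)
        pair = (kern, truncation_bound(kern, 0.95))
        model = build_model("es_distributed", ESKineticParams(0.8, pair))
        init = InitialCondition.single(0.6, 0.4)
        dt = 0.05
        traj = integrate(model, init, dt, IntegratorSettings(dt=dt))
        quads = model.default_quadratures(dt)
        state0, hist = model.initial_state(init)

        def history(t):
            return hist if t < 0 else state0

        d1 = evaluate_rhs(model, 0.0, history, quads)
        pred = state0 + dt * d1

        def history2(t):
            if t < 0:
                return hist
            return state0 if t < dt else pred

        d2 = evaluate_rhs(model, dt, history2, quads)
        expected = state0 + 0.5 * dt * (d1 + d2)
        np.testing.assert_allclose(traj.values[1], expected, rtol=1e-12, atol=1e-15)

    def test_prehistory_follows_jump_convention(self):
        model = build_model("es_discrete", ESKineticParams(0.1, 3.0))
        traj = integrate(model, InitialCondition.single(0.5, 0.2), 5.0,
                         IntegratorSettings(dt=0.1))
        s_idx = model.index("S")
        e_idx = model.index("E")
        assert np.all(traj.hist_values[:, s_idx] == 0.0)
        assert np.all(traj.hist_values[:, e_idx] == 0.2)
        assert traj.values[0, s_idx] == 0.5

    def test_concentrations_stay_nonnegative(self):
        model = build_model("es_discrete", ESKineticParams(0.04, 10.0))
        traj = integrate(model, InitialCondition.single(0.5, 0.05), 500.0,
                         IntegratorSettings(dt=0.05))
        assert traj.values.min() >= -1e-9


class TestConservation:
    def test_zero_rate_run_has_exactly_zero_residuals(self):
        model = build_model("es_discrete", ESKineticParams(0.0, 5.0))
        traj = integrate(model, InitialCondition.single(1.0, 1.0), 10.0,
                         IntegratorSettings(dt=0.1))
        rep = conservation_report(traj, model)
        for r in rep.residuals.values():
            np.testing.assert_array_equal(r, 0.0)

    def test_discrete_model_bookkeeping(self):
        model = build_model("es_discrete", ESKineticParams(0.04, 10.0))
        traj = integrate(model, InitialCondition.single(0.05, 0.05), 500.0,
                         IntegratorSettings(dt=0.05))
        rep = conservation_report(traj, model)
        assert rep.max_residuals["enzyme"] < 1e-5
        assert rep.max_residuals["substrate"] < 1e-5

    def test_distributed_residual_bounded_by_truncation_deficit(self):
        kern = GammaDelayKernel(1.255818, 6.703709, 4.673685)
        rule = truncation_bound(kern, 0.95)
        model = build_model("es_distributed", ESKineticParams(0.04, (kern, rule)))
        traj = integrate(model, InitialCondition.single(0.05, 0.05), 500.0,
                         IntegratorSettings(dt=0.05))
        rep = conservation_report(traj, model)
        deficit = 1.0 - kern.cdf(rule.tau_M)
        consumed = 0.05 - traj["S"][-1]
        assert rep.max_residuals["enzyme"] <= deficit * consumed + 1e-5

    def test_mm_conserves_enzyme_and_substrate(self):
        model = build_model("mm", MMRates(2.0, 0.5, 1.0))
        traj = integrate(model, InitialCondition.single(1.0, 0.3), 20.0,
                         IntegratorSettings(dt=0.01))
        rep = conservation_report(traj, model)
        assert rep.max_residuals["enzyme"] < 1e-9
        assert rep.max_residuals["substrate"] < 1e-9

    def test_unregistered_family_raises(self):
        model = build_model("mm", MMRates(1.0, 0.5, 0.2))
        fake = type(model)(family="custom", species=model.species, terms=model.terms)
        traj = integrate(fake, InitialCondition.single(1.0, 0.3), 1.0,
                         IntegratorSettings(dt=0.1))
        with pytest.raises(ModelError, match="custom"):
            conservation_report(traj, fake)


class TestOscillationMetrics:
    def test_monotone_series_has_no_extrema(self):
        n, amp = oscillation_metrics(np.linspace(0, 1, 100), prominence=1e-9)
        assert n == 0 and amp == 0.0

    def test_damped_oscillation_counted(self):
        t = np.linspace(0, 20, 2000)
        x = np.exp(-0.2 * t) * np.cos(2 * np.pi * t / 4.0)
        n, amp = oscillation_metrics(x, prominence=1e-3)
        assert n >= 6
        assert 0.5 <= amp <= 2.0
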