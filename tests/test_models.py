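import numpy as np
import pytest

from delaykin import (
    Channel,
    ChannelRates,
    ESKineticParams,
    GammaDelayKernel,
    InitialCondition,
    IntegratorSettings,
    LatticeSpec,
    MMRates,
    build_model,
    evaluate_rhs,
    integrate,
    truncation_bound,
)
from delaykin.models import HistoryUnderflowError, ModelError


def es_distributed(kd=0.05, a=1.0, m=2.0, tau_min=0.0, c=0.99):
    kern = GammaDelayKernel(a, m, tau_min)
    return build_model("es_distributed", ESKineticParams(kd, (kern, truncation_bound(kern, c))))


def esi_channels(a01=0.02, a11=0.01, b10=0.015, b11=0.005, tau=5.0):
    return ChannelRates(
        substrate_channels=(Channel(0, 1, a01, tau), Channel(1, 1, a11, tau)),
        inhibitor_channels=(Channel(1, 0, b10, tau), Channel(1, 1, b11, tau)),
    )


class TestBuild:
    def test_mm_has_four_states(self):
        model = build_model("mm", MMRates(1.0, 0.5, 0.2))
        assert model.species == ("S", "E", "C", "P")

    def test_esi_has_five_states(self):
        model = build_model("esi_discrete", esi_channels())
        assert model.species == ("P01", "P11", "S1", "E", "I1")

    def test_lattice_full_one_one_has_eight_states(self):
        spec = LatticeSpec(
            N=1, M=1,
            alpha={(0, 1): 1.0, (1, 1): 0.5},
            alpha_rev={(0, 1): 0.1, (1, 1): 0.05},
            beta={(1, 0): 0.3, (1, 1): 0.2},
            beta_rev={(1, 0): 0.02, (1, 1): 0.01},
            gamma={(0, 1): 0.4, (1, 1): 0.2},
        )
        model = build_model("lattice_full", spec)
        assert len(model.species) == 8
        assert set(model.species) == {
            "S1", "I1", "R00", "R1_0", "R0_1", "R1_1", "P0_1", "P1_1"
        }

    def test_unknown_family(self):
        with pytest.raises(ModelError, match="unknown family"):
            build_model("qss", MMRates(1, 1, 1))

    def test_wrong_parameter_type(self):
        with pytest.raises(ModelError, match="expects"):
            build_model("mm", ESKineticParams(1.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError):
            MMRates(-1.0, 0.0, 0.0)
        with pytest.raises(ModelError):
            Channel(0, 1, -0.1)

    def test_duplicate_channel_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            ChannelRates(substrate_channels=(Channel(0, 1, 1.0), Channel(0, 1, 2.0)))

    def test_esi_rejects_out_of_lattice_channel(self):
        with pytest.raises(ModelError, match="esi"):
            build_model(
                "esi_discrete",
                ChannelRates(substrate_channels=(Channel(2, 1, 1.0, 1.0),)),
            )

    def test_lattice_full_rejects_out_of_range_rate(self):
        with pytest.raises(ModelError, match="outside"):
            LatticeSpec(N=1, M=1, alpha={(0, 2): 1.0})

    def test_no_product_from_inhibitor_only_complexes(self):
        with pytest.raises(ModelError, match="inhibitor-only"):
            build_model("lattice_full", LatticeSpec(N=1, M=1, gamma={(1, 0): 0.5}))

    def test_family_delay_kind_enforced(self):
        kern = GammaDelayKernel(1.0)
        pair = (kern, truncation_bound(kern, 0.9))
        with pytest.raises(ModelError, match="discrete"):
            build_model("es_discrete", ESKineticParams(1.0, pair))
        with pytest.raises(ModelError, match="kernel"):
            build_model("es_distributed", ESKineticParams(1.0, 2.0))

    def test_max_delay_horizon(self):
        model = build_model("es_discrete", ESKineticParams(1.0, 7.5))
        assert model.max_delay_horizon == 7.5
        dist = es_distributed(a=1.0, m=0.0, tau_min=0.0, c=0.75)
        assert dist.max_delay_horizon == pytest.approx(3.0)


class TestEvaluateRhs:
    def test_mm_direct_substitution(self):
        model = build_model("mm", MMRates(k1=1.0, k_minus1=0.0, k2=0.0))
        state = np.array([1.0, 1.0, 0.0, 0.0])
        d = evaluate_rhs(model, 0.0, lambda t: state)
        np.testing.assert_allclose(d, [-1.0, -1.0, 1.0, 0.0])

    def test_es_discrete_initial_jump_kills_return_terms(self):
        # substrate history is 0 before t=0, so the delayed return flux
        # vanishes at t=0 and only the consumption terms act
        kd, nE0, nS0, tau = 0.3, 0.7, 0.4, 2.0
        model = build_model("es_discrete", ESKineticParams(kd, tau))

        def history(t):
            if t < 0:
                return np.array([0.0, nE0, 0.0])
            return np.array([nS0, nE0, 0.0])

        d = evaluate_rhs(model, 0.0, history)
        np.testing.assert_allclose(
            d, [-kd * nE0 * nS0, -kd * nE0 * nS0, 0.0], atol=1e-15
        )

    def test_zero_rate_annihilates_everything(self):
        model = es_distributed(kd=0.0)
        quads = model.default_quadratures(0.1)
        d = evaluate_rhs(model, 0.0, lambda t: np.array([1.0, 1.0, 0.0]), quads)
        np.testing.assert_array_equal(d, 0.0)

    def test_history_underflow_raises(self):
        model = build_model("es_discrete", ESKineticParams(1.0, 5.0))
        history = lambda t: np.zeros(3)  # noqa: E731
        # lookups down to t - 5 = -2 are fine when the history starts at -2
        evaluate_rhs(model, 3.0, history, history_start=-2.0)
        with pytest.raises(HistoryUnderflowError):
            evaluate_rhs(model, 1.0, history, history_start=-2.0)

    def test_stoichiometric_balance_per_reaction(self):
        # every binding event consumes one S and one E and (later) returns
        # one E with one P: signed rates per factor pair must cancel
        model = es_distributed()
        by_pair = {}
        for term in model.terms:
            by_pair.setdefault(term.factors, []).append(term)
        for terms in by_pair.values():
            total = sum(t.sign * t.rate for t in terms)
            # S loss (-kd) + E net (0) + P gain (+kd) = 0
            assert total == pytest.approx(0.0, abs=1e-15)


class TestFamilyRelations:
    def test_esi_inhibitor_is_non_increasing(self):
        model = build_model("esi_discrete", esi_channels(tau=2.0))
        init = InitialCondition.single(nS0=0.5, nE0=0.3, nI0=0.4)
        traj = integrate(model, init, 100.0, IntegratorSettings(dt=0.05))
        assert np.all(np.diff(traj["I1"]) <= 1e-15)

    def test_esi_without_inhibitor_reduces_to_es(self):
        kern = GammaDelayKernel(1.5, 3.0, 1.0)
        pair = (kern, truncation_bound(kern, 0.99))
        kd = 0.04
        esi = build_model(
            "esi_distributed",
            ChannelRates(
                substrate_channels=(Channel(0, 1, kd / 2, pair), Channel(1, 1, kd / 2, pair)),
                inhibitor_channels=(Channel(1, 0, 0.0, pair), Channel(1, 1, 0.0, pair)),
            ),
        )
        es = build_model("es_distributed", ESKineticParams(kd, pair))
        st = IntegratorSettings(dt=0.02)
        traj_esi = integrate(
            esi, InitialCondition.single(0.5, 0.3, 0.2), 60.0, st
        )
        traj_es = integrate(es, InitialCondition.single(0.5, 0.3), 60.0, st)
        np.testing.assert_allclose(traj_esi["S1"], traj_es["S"], atol=1e-12)
        np.testing.assert_allclose(traj_esi["E"], traj_es["E"], atol=1e-12)
        np.testing.assert_allclose(
            traj_esi["P01"] + traj_esi["P11"], traj_es["P"], atol=1e-12
        )

    def test_lattice_full_conserves_total_enzyme(self):
        spec = LatticeSpec(
            N=1, M=1,
            alpha={(0, 1): 2.0, (1, 1): 1.0},
            alpha_rev={(0, 1): 0.2, (1, 1): 0.1},
            beta={(1, 0): 0.5, (1, 1): 0.4},
            beta_rev={(1, 0): 0.05, (1, 1): 0.04},
            gamma={(0, 1): 0.7, (1, 1): 0.3},
        )
        model = build_model("lattice_full", spec)
        init = InitialCondition.single(nS0=1.0, nE0=0.5, nI0=0.8)
        traj = integrate(model, init, 50.0, IntegratorSettings(dt=0.01))
        r_cols = [k for k, s in enumerate(model.species) if s.startswith("R")]
        total = traj.values[:, r_cols].sum(axis=1)
        np.testing.assert_allclose(total, 0.5, atol=1e-9)

    def test_lattice_delayed_general_channel_lists(self):
        # two substrates, one inhibitor, mixed channels
        kern = GammaDelayKernel(1.0, 1.0, 0.0)
        pair = (kern, truncation_bound(kern, 0.99))
        rates = ChannelRates(
            substrate_channels=(Channel(0, 1, 0.03, pair), Channel(0, 2, 0.02, pair),
                                Channel(1, 1, 0.01, pair)),
            inhibitor_channels=(Channel(1, 0, 0.02, pair),),
        )
        model = build_model("lattice_distributed", rates)
        assert model.species == ("P0_1", "P0_2", "P1_1", "S1", "S2", "E", "I1")
        init = InitialCondition(nS0=(0.4, 0.3), nE0=0.2, nI0=(0.1,))
        traj = integrate(model, init, 40.0, IntegratorSettings(dt=0.025))
        # inhibitor only decays; every species stays nonnegative
        assert np.all(np.diff(traj["I1"]) <= 1e-15)
        assert traj.values.min() >= -1e-9
        from delaykin import conservation_report

        rep = conservation_report(traj, model)
        deficit = 1.0 - kern.cdf(pair[1].tau_M)
        assert rep.max_residuals["enzyme"] <= deficit * 0.7 + 1e-5
        assert rep.max_residuals["substrate_S1"] <= deficit * 0.4 + 1e-5
        # the residual is dominated by discretization, not the truncation
        # deficit, and shrinks quadratically: halving dt quarters it
        traj2 = integrate(model, init, 40.0, IntegratorSettings(dt=0.0125))
        rep2 = conservation_report(traj2, model)
        assert rep2.max_residuals["enzyme"] < 0.4 * rep.max_residuals["enzyme"]

    def test_initial_condition_species_count_checked(self):
        model = build_model("mm", MMRates(1, 0, 0))
        with pytest.raises(ModelError, match="substrate"):
            model.initial_state(InitialCondition(nS0=(1.0, 2.0), nE0=1.0))

    def test_negative_initials_rejected(self):
        with pytest.raises(ModelError):
            InitialCondition.single(-1.0, 1.0)
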