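"""Unit tests for the kinetic-synapse primitives and assembled RHS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from thalcort.config import ModelConfig
from thalcort.core import (
    NetworkModel,
    NetworkState,
    PopulationSpec,
    ReceptorParams,
    SynapseSpec,
    channel_open_fraction_rhs,
    leak_current,
    membrane_rhs,
    network_rhs,
    synaptic_current,
    transmitter_concentration,
)
from thalcort.network import build_base_network


class TestTransmitterConcentration:
    def test_midpoint_is_half_max(self, exc_pop):
        assert transmitter_concentration(exc_pop.theta_u, exc_pop) == pytest.approx(
            0.5 * exc_pop.T_max
        )

    def test_saturation_limits(self, exc_pop):
        assert transmitter_concentration(-1e3, exc_pop) == pytest.approx(0.0, abs=1e-12)
        hi = transmitter_concentration(exc_pop.theta_u + 10 * exc_pop.sigma_u, exc_pop)
        assert hi == pytest.approx(exc_pop.T_max, abs=1e-4)

    @given(v=st.floats(-120, 20), dv=st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, v, dv):
        spec = PopulationSpec(
            name="TCR", kind="excitatory", V_rest=-65.0, theta_u=-56.0,
            sigma_u=4.0, g_lk=10.0, E_lk=-55.0,
        )
        a = transmitter_concentration(v, spec)
        b = transmitter_concentration(v + dv, spec)
        assert 0.0 < a < spec.T_max
        assert b > a

    def test_nonfinite_voltage_rejected(self, exc_pop):
        with pytest.raises(ValueError):
            transmitter_concentration(np.nan, exc_pop)


class TestChannelKinetics:
    def test_equilibrium_fraction(self, ampa):
        T = 0.3
        r_eq = ampa.alpha * T / (ampa.alpha * T + ampa.beta)
        assert channel_open_fraction_rhs(r_eq, T, ampa) == pytest.approx(0.0, abs=1e-12)

    def test_saturated_channels_decay_at_beta(self, ampa, gaba):
        for rec in (ampa, gaba):
            assert channel_open_fraction_rhs(1.0, 0.7, rec) == pytest.approx(-rec.beta)

    def test_direct_evaluation(self, ampa):
        # alpha*T*(1-r) - beta*r = 100*0.5*0.8 - 50*0.2 = 30
        assert channel_open_fraction_rhs(0.2, 0.5, ampa) == pytest.approx(30.0)

    def test_negative_concentration_rejected(self, ampa):
        with pytest.raises(ValueError):
            channel_open_fraction_rhs(0.5, -0.1, ampa)


class TestCurrents:
    def test_synaptic_current_zero_at_reversal(self, gaba):
        syn = SynapseSpec(pre="TRN", post="TCR", receptor=gaba, C=0.23, r=0.4)
        assert synaptic_current(syn, gaba.E_rev) == 0.0

    def test_lesioned_pathway_carries_no_current(self, ampa):
        syn = SynapseSpec(pre="TCR", post="Py4", receptor=ampa, C=0.0, r=0.9)
        assert synaptic_current(syn, -40.0) == 0.0

    def test_ampa_current_direct_value(self, ampa):
        # 0.062 * 100 * 0.5 * (-65 - 0) = -201.5
        syn = SynapseSpec(pre="Py6", post="TCR", receptor=ampa, C=0.062, r=0.5)
        assert synaptic_current(syn, -65.0) == pytest.approx(-201.5)

    def test_leak_current_values(self, exc_pop):
        assert leak_current(exc_pop.E_lk, exc_pop) == 0.0
        assert leak_current(-65.0, exc_pop) == pytest.approx(-100.0)
        assert leak_current(-45.0, exc_pop) == pytest.approx(100.0)

    def test_leak_on_exogenous_population_rejected(self):
        ret = PopulationSpec(name="Ret", kind="exogenous", V_rest=-65.0,
                             theta_u=-56.0, sigma_u=4.0)
        with pytest.raises(ValueError):
            leak_current(-65.0, ret)


def _toy_chain(C=0.071, g_max=300.0):
    """Minimal Ret -> TCR network (all other pathways absent), with a pinned
    release sigmoid so tests can hard-code the expected arithmetic."""
    cfg = ModelConfig(theta_u=-56.0, sigma_u=6.0, theta_overrides={},
                      sigma_overrides={})
    net = build_base_network(cfg)
    for s in net.synapses:
        s.C = 0.0
    net.synapse("Ret", "TCR").C = C
    return net


class TestMembraneRhs:
    def test_equilibrium_is_zero(self, base_net):
        net = base_net.copy()
        for s in net.synapses:
            s.C = 0.0
        state = net.initial_state()
        state.V = np.array([net.populations[n].E_lk for n in net.dynamic])
        for v in net.dynamic:
            assert membrane_rhs(v, state, net) == pytest.approx(0.0)

    def test_pure_leak_relaxation_rate(self, base_net):
        # with no synapses, dV/dt = -(g_lk/kappa) * (V - E_lk)
        net = base_net.copy()
        for s in net.synapses:
            s.C = 0.0
        state = net.initial_state()
        spec = net.populations["TCR"]
        i = net.dyn_index("TCR")
        expected = -(spec.g_lk / spec.kappa) * (state.V[i] - spec.E_lk)
        assert membrane_rhs("TCR", state, net) == pytest.approx(expected)

    def test_constant_drive_fixed_point_matches_root(self):
        # one AMPA afferent with constant presynaptic drive: the zero of
        # dV/dt found by an independent scalar root bracketing
        net = _toy_chain()
        syn = net.synapse("Ret", "TCR")
        spec = net.populations["TCR"]
        ret = net.populations["Ret"]
        T = transmitter_concentration(-65.0, ret)
        r_eq = syn.receptor.alpha * T / (syn.receptor.alpha * T + syn.receptor.beta)
        g_syn = syn.C * syn.receptor.g_max * r_eq

        def f(V):
            return -(g_syn * (V - syn.receptor.E_rev)
                     + spec.g_lk * (V - spec.E_lk))

        V_star = brentq(f, -100.0, 50.0, xtol=1e-12)
        state = net.initial_state()
        state.V[net.dyn_index("TCR")] = V_star
        state.r[[i for i, s in enumerate(net.synapses)
                 if (s.pre, s.post) == ("Ret", "TCR")][0]] = r_eq
        assert membrane_rhs("TCR", state, net) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_population_rejected(self, base_net):
        with pytest.raises(KeyError):
            membrane_rhs("L5", base_net.initial_state(), base_net)

    def test_direction_contract(self, base_net):
        """AMPA input depolarizes, GABA_A input hyperpolarizes."""
        net = base_net.copy()
        for s in net.synapses:
            s.C = 0.0
        state = net.initial_state()
        i = net.dyn_index("TCR")
        state.V[i] = net.populations["TCR"].E_lk  # leak-neutral

        ampa_idx = net._edges[("Ret", "TCR")]
        net.synapse("Ret", "TCR").C = 0.1
        state.r[ampa_idx] = 0.3
        assert membrane_rhs("TCR", state, net) > 0  # depolarizing
        net.synapse("Ret", "TCR").C = 0.0
        state.r[ampa_idx] = 0.0

        gaba_idx = net._edges[("TRN", "TCR")]
        net.synapse("TRN", "TCR").C = 0.1
        state.r[gaba_idx] = 0.3
        assert membrane_rhs("TCR", state, net) < 0  # hyperpolarizing


class TestNetworkRhs:
    DRIVE = {"Ret": -65.0, "Asy": -65.0, "Sy": -75.0}

    def test_zero_synapse_network_is_pure_leak(self, base_net):
        net = base_net.copy()
        for s in net.synapses:
            s.C = 0.0
        state = net.initial_state()
        dy = network_rhs(state, net, self.DRIVE)
        for k, name in enumerate(net.dynamic):
            spec = net.populations[name]
            expected = -(spec.g_lk / spec.kappa) * (state.V[k] - spec.E_lk)
            assert dy[k] == pytest.approx(expected)

    def test_initial_derivative_finite_and_r_nonnegative(self, base_net):
        state = base_net.initial_state()  # V = V_rest, r = 0
        dy = network_rhs(state, base_net, self.DRIVE)
        assert np.all(np.isfinite(dy))
        # r = 0 implies dr/dt = alpha*T >= 0
        assert np.all(dy[base_net.n_dynamic:] >= 0)

    def test_matches_independent_scalar_implementation(self, base_net):
        """Cross-check the assembled RHS of a Ret->TCR chain against a
        from-scratch scalar coding of the same equations."""
        net = _toy_chain()
        syn = net.synapse("Ret", "TCR")
        spec = net.populations["TCR"]
        i_tcr = net.dyn_index("TCR")
        i_syn = [i for i, s in enumerate(net.synapses)
                 if (s.pre, s.post) == ("Ret", "TCR")][0]
        rng = np.random.default_rng(42)
        for _ in range(10):
            state = net.initial_state()
            state.V = rng.uniform(-90, -30, size=state.V.shape)
            state.r = rng.uniform(0, 1, size=state.r.shape)
            V_ret = rng.uniform(-70, -60)
            drive = dict(self.DRIVE, Ret=V_ret)
            dy = network_rhs(state, net, drive)

            # independent scalar implementation
            V, r = state.V[i_tcr], state.r[i_syn]
            T = 1.0 / (1.0 + np.exp(-(V_ret + 56.0) / 6.0))
            dr = 100.0 * T * (1 - r) - 50.0 * r
            I_syn = 0.071 * 300.0 * r * (V - 0.0)
            I_lk = 10.0 * (V - (-55.0))
            dV = (-I_syn - I_lk) / spec.kappa

            assert dy[i_tcr] == pytest.approx(dV, rel=1e-12)
            assert dy[net.n_dynamic + i_syn] == pytest.approx(dr, rel=1e-12)

    def test_missing_drive_rejected(self, base_net):
        with pytest.raises(KeyError):
            network_rhs(base_net.initial_state(), base_net, {"Ret": -65.0})

    def test_dimension_mismatch_rejected(self, base_net):
        state = NetworkState(V=np.zeros(3), r=np.zeros(2))
        with pytest.raises(ValueError):
            network_rhs(state, base_net, self.DRIVE)


class TestSpecValidation:
    def test_exogenous_with_leak_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(name="Ret", kind="exogenous", V_rest=-65.0,
                           theta_u=-56.0, sigma_u=4.0, g_lk=10.0, E_lk=-55.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(name="TCR", kind="excitatory", V_rest=-65.0,
                           theta_u=-56.0, sigma_u=0.0, g_lk=10.0, E_lk=-55.0)

    def test_receptor_rates_positive(self):
        with pytest.raises(ValueError):
            ReceptorParams(psi="AMPA", alpha=0.0, beta=50.0, g_max=100.0,
                           E_rev=0.0)

    def test_negative_connectivity_rejected(self, ampa):
        with pytest.raises(ValueError):
            SynapseSpec(pre="a", post="b", receptor=ampa, C=-0.1)
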