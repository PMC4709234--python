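"""Compute-plane model anchors: closed forms, equilibria, and invariants."""

import math

import numpy as np
import pytest

from lpukit import default_registry, register_model
from lpukit.errors import DuplicateIdError
from lpukit.models import (
    ALPHA_DEFAULTS,
    AlphaState,
    CondState,
    HHState,
    LIF_DEFAULTS,
    LIFState,
    MLState,
    PRState,
    alpha_synapse_step,
    conductance_synapse_step,
    hh_rest_state,
    hodgkin_huxley_step,
    lif_isi_closed_form,
    lif_step,
    morris_lecar_equilibrium,
    morris_lecar_step,
    photoreceptor_step,
)


class TestLIF:
    def test_rest_is_a_fixed_point(self):
        state = LIFState(LIF_DEFAULTS["v_rest"])
        for _ in range(1000):
            state, spike = lif_step(state, 0.0, {}, 1e-4)
            assert spike == 0
        assert state.v == LIF_DEFAULTS["v_rest"]

    def test_interspike_interval_matches_closed_form(self):
        """Constant suprathreshold drive: ISI within 1% of
        tau*ln(RI/(RI - V_th + V_rest)) at dt = 1e-5 s."""
        current, dt = 20.0, 1e-5
        expected = lif_isi_closed_form(current)
        state, spikes = LIFState(LIF_DEFAULTS["v_rest"]), []
        for k in range(int(5 * expected / dt)):
            state, s = lif_step(state, current, {}, dt)
            if s:
                spikes.append(k)
        assert len(spikes) >= 3
        measured = (spikes[2] - spikes[1]) * dt
        assert measured == pytest.approx(expected, rel=0.01)

    def test_subthreshold_converges_monotonically_to_rest_plus_ri(self):
        current = 5.0  # RI = 5 mV < 10 mV threshold gap
        target = LIF_DEFAULTS["v_rest"] + LIF_DEFAULTS["r"] * current
        state, prev = LIFState(LIF_DEFAULTS["v_rest"]), LIF_DEFAULTS["v_rest"]
        for _ in range(200_000):
            state, spike = lif_step(state, current, {}, 1e-5)
            assert spike == 0
            assert state.v >= prev - 1e-12
            prev = state.v
        assert state.v == pytest.approx(target, abs=1e-6)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            lif_step(LIFState(-65.0), 0.0, {}, 0.0)

    def test_euler_error_halves_with_dt(self):
        """First-order convergence on the subthreshold trajectory against the
        exact exponential solution."""
        current, horizon = 5.0, 0.01
        p = LIF_DEFAULTS

        def exact(t):
            ri = p["r"] * current
            return p["v_rest"] + ri * (1.0 - math.exp(-t / p["tau"]))

        def final_error(dt):
            state = LIFState(p["v_rest"])
            for _ in range(int(horizon / dt)):
                state, _ = lif_step(state, current, {}, dt)
            return abs(state.v - exact(horizon))

        e1, e2 = final_error(2e-5), final_error(1e-5)
        assert e2 < e1
        assert e1 / e2 == pytest.approx(2.0, rel=0.2)


class TestMorrisLecar:
    def test_equilibrium_is_stationary(self):
        eq = morris_lecar_equilibrium()
        state = eq
        for _ in range(2000):
            state, _ = morris_lecar_step(state, 0.0, {}, 1e-5)
        assert state.v == pytest.approx(eq.v, abs=1e-6)
        assert state.n == pytest.approx(eq.n, abs=1e-9)

    def test_recovery_variable_stays_in_unit_interval(self):
        rng = np.random.default_rng(0)
        state = MLState(-60.0, 0.0)
        for _ in range(100_000):
            state, _ = morris_lecar_step(state, float(rng.normal(0, 50)), {}, 1e-5)
            assert 0.0 <= state.n <= 1.0
        assert math.isfinite(state.v)

    def test_nearby_initial_conditions_converge_to_same_rest(self):
        """Excitable regime: two perturbed starts relax to the rest state of
        a fine-step reference integration."""
        dt, duration = 1e-5, 0.4
        ref = MLState(-60.0, 0.1)
        for _ in range(int(duration / (dt / 10))):
            ref, _ = morris_lecar_step(ref, 0.0, {}, dt / 10)
        finals = []
        for v0 in (-55.0, -65.0):
            state = MLState(v0, 0.1)
            for _ in range(int(duration / dt)):
                state, _ = morris_lecar_step(state, 0.0, {}, dt)
            finals.append(state.v)
        assert finals[0] == pytest.approx(finals[1], abs=1e-3)
        assert finals[0] == pytest.approx(ref.v, abs=1e-2)

    def test_graded_output_is_membrane_potential(self):
        state, out = morris_lecar_step(MLState(-60.0, 0.0), 10.0, {}, 1e-5)
        assert out == state.v


class TestHodgkinHuxley:
    def test_rest_state_quiet_for_100ms(self):
        state = hh_rest_state()
        for _ in range(20_000):  # 100 ms at 5 us
            state, spike = hodgkin_huxley_step(state, 0.0, {}, 5e-6)
            assert spike == 0
        assert state.v == pytest.approx(-65.0, abs=1.0)

    def test_spike_count_matches_refined_reference(self):
        """Strong drive: 100 ms spike count within +-1 of a dt/100 run."""

        def count(dt):
            state, total = hh_rest_state(), 0
            for _ in range(int(0.1 / dt)):
                state, s = hodgkin_huxley_step(state, 15.0, {}, dt)
                total += s
            return total

        coarse = count(1e-5)
        fine = count(1e-7)
        assert coarse >= 3  # repetitive firing
        assert abs(coarse - fine) <= 1

    def test_gating_variables_bounded(self):
        rng = np.random.default_rng(1)
        state = hh_rest_state()
        for _ in range(20_000):
            state, _ = hodgkin_huxley_step(state, float(rng.normal(0, 20)), {}, 1e-5)
            assert 0.0 <= state.m <= 1.0
            assert 0.0 <= state.h <= 1.0
            assert 0.0 <= state.n <= 1.0

    def test_stability_bound_enforced_and_substeps_lift_it(self):
        with pytest.raises(ValueError, match="stability"):
            hodgkin_huxley_step(hh_rest_state(), 0.0, {}, 1e-3)
        state, _ = hodgkin_huxley_step(
            hh_rest_state(), 0.0, {"substeps": 100}, 1e-3
        )
        assert math.isfinite(state.v)


class TestSynapses:
    def test_alpha_kernel_peaks_at_tau(self):
        tau = ALPHA_DEFAULTS["tau"]
        dt = tau / 200
        state, _ = alpha_synapse_step(AlphaState(0.0, 0.0), 1.0, {}, dt)
        trace = []
        for _ in range(1000):
            state, current = alpha_synapse_step(state, 0.0, {}, dt)
            trace.append(current)
        t_peak = (trace.index(max(trace)) + 1) * dt
        assert abs(t_peak - tau) <= dt

    def test_alpha_silent_without_input(self):
        state = AlphaState(0.0, 0.0)
        for _ in range(100):
            state, current = alpha_synapse_step(state, 0.0, {}, 1e-4)
            assert current == 0.0

    def test_conductance_zero_driving_force(self):
        state = CondState(0.5)
        _, current = conductance_synapse_step(
            state, -40.0, {"e_rev": -80.0}, 1e-4, v_post=-80.0
        )
        assert current == 0.0

    def test_conductance_inhibitory_below_rest(self):
        state = CondState(0.0)
        for _ in range(200):
            state, current = conductance_synapse_step(
                state, -40.0, {}, 1e-4, v_post=-60.0
            )
        assert state.g > 0.0
        assert current < 0.0  # e_rev=-80 below the postsynaptic potential


class TestPhotoreceptor:
    def test_dark_rest(self):
        state = PRState(-65.0)
        for _ in range(1000):
            state, v = photoreceptor_step(state, 0.0, {}, 1e-4)
        assert v == pytest.approx(-65.0)

    def test_light_depolarizes_logarithmically(self):
        def steady(intensity):
            state = PRState(-65.0)
            for _ in range(5000):
                state, v = photoreceptor_step(state, intensity, {}, 1e-4)
            return v

        v1, v10 = steady(math.e - 1.0), steady(math.e**2 - 1.0)
        assert v1 == pytest.approx(-55.0, abs=0.01)  # rest + gain*1
        assert v10 == pytest.approx(-45.0, abs=0.01)  # rest + gain*2

    def test_shot_noise_is_seeded_and_optional(self):
        params = {"noise_rate": 100.0}
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            state = PRState(-65.0)
            vals = []
            for _ in range(100):
                state, v = photoreceptor_step(state, 5.0, params, 1e-3, rng)
                vals.append(v)
            runs.append(vals)
        assert runs[0] == runs[1]


class TestRegistry:
    def test_builtin_contains_named_models_plus_surrogate(self):
        reg = default_registry()
        assert set(reg.names) == {
            "LeakyIAF", "MorrisLecar", "HodgkinHuxley",
            "AlphaSynapse", "ConductanceSynapse", "PhotoreceptorSurrogate",
        }

    def test_duplicate_name_rejected(self):
        reg = default_registry()
        with pytest.raises(DuplicateIdError):
            register_model(
                reg, "LeakyIAF", lambda p, rng: None,
                lambda s, d, p, dt, rng, vp: (s, {}),
            )

    def test_custom_model_runs_from_declarative_spec(self):
        import networkx as nx

        from lpukit import LPUSpec, PortDecl, PortIdentifier, attach_mappers

        reg = default_registry()

        def echo_step(state, drive, params, dt, rng, v_post):
            return state, {"gpot": drive * params["gain"], "spike": 0, "current": 0.0}

        register_model(
            reg, "EchoGain", lambda p, rng: None, echo_step,
            defaults={"gain": 2.0}, kind="neuron",
        )
        g = nx.DiGraph()
        g.add_node("e", model="EchoGain", gain=3.0)
        in_id, out_id = PortIdentifier(("x", "in", 0)), PortIdentifier(("x", "out", 0))
        spec = LPUSpec(
            id="x",
            interface=(PortDecl(in_id, "in", "gpot"), PortDecl(out_id, "out", "gpot")),
            components=g,
            port_bindings={in_id: "e", out_id: "e"},
        )
        rt = attach_mappers(spec, registry=reg)
        rt.pm["gpot"]["/x/in[0]"] = 0.5
        rt.step(0, 1e-3)
        assert rt.pm["gpot"]["/x/out[0]"][0] == pytest.approx(1.5)

    def test_defaults_must_satisfy_schema(self):
        reg = default_registry()
        with pytest.raises(ValueError, match="schema"):
            register_model(
                reg, "Bad", lambda p, rng: None,
                lambda s, d, p, dt, rng, vp: (s, {}),
                schema={"a": "number"}, defaults={"b": 1.0},
            )


def test_model_steps_are_pure():
    """Same (state, input, params, dt) twice gives bitwise-equal results."""
    cases = [
        (lif_step, (LIFState(-60.0), 5.0, {}, 1e-4)),
        (morris_lecar_step, (MLState(-60.0, 0.1), 10.0, {}, 1e-5)),
        (hodgkin_huxley_step, (hh_rest_state(), 8.0, {}, 1e-5)),
        (alpha_synapse_step, (AlphaState(0.5, 0.2), 1.0, {}, 1e-4)),
    ]
    for fn, args in cases:
        assert fn(*args) == fn(*args)
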