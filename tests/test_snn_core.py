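"""Unit and property tests for the LIF/STDP simulation engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flydec.snn_core import (
    LIFConfig,
    Network,
    NeuronPopulation,
    STDPConfig,
    SimulationError,
    SynapseGroup,
    lif_step,
    stdp_delta,
)

LIF = LIFConfig()  # v_th=0.1, v_r=0, tau_m=20, R=1


class TestLIFStep:
    @pytest.mark.parametrize(
        "v0, current, expect_v, expect_spike",
        [
            (0.0, 0.0, 0.0, False),        # rest state stays at rest
            (0.0, 2.0, 0.0, True),         # 0 + (1/20)*2 = 0.1 = v_th
            (0.05, 0.0, 0.0475, False),    # pure leak: 0.05 - 0.05/20
        ],
    )
    def test_single_step(self, v0, current, expect_v, expect_spike):
        v, spiked = lif_step(np.array([v0]), LIF, np.array([current]), dt=1.0)
        assert spiked[0] == expect_spike
        assert v[0] == pytest.approx(expect_v)

    def test_non_finite_current_raises(self):
        with pytest.raises(SimulationError):
            lif_step(np.array([0.0]), LIF, np.array([np.inf]), dt=1.0)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            lif_step(np.array([0.0]), LIF, np.array([0.0]), dt=0.0)

    def test_euler_consistency_with_closed_form(self):
        """Halving dt moves the first-spike time under constant current by
        less than dt, and both bracket the closed-form crossing of
        v(t) = RI(1 - exp(-t/tau))."""
        current = 0.15
        t_exact = -LIF.tau_m * np.log(1.0 - LIF.v_th / (LIF.R * current))

        def first_spike(dt):
            v = np.array([0.0])
            t = 0.0
            for _ in range(int(200 / dt)):
                t += dt
                v, spiked = lif_step(v, LIF, np.array([current]), dt)
                if spiked[0]:
                    return t
            raise AssertionError("no spike")

        for dt in (1.0, 0.5, 0.25, 0.125):
            assert abs(first_spike(dt) - first_spike(dt / 2)) < dt
        assert abs(first_spike(0.01) - t_exact) < 0.1


class TestSTDPDelta:
    CFG = STDPConfig()  # A+=0.925, A-=0.9, tau=20

    def test_potentiation_one_tau(self):
        assert stdp_delta(20.0, self.CFG) == pytest.approx(
            0.925 * np.exp(-1.0), abs=1e-4
        )

    def test_depression_one_tau(self):
        assert stdp_delta(-20.0, self.CFG) == pytest.approx(
            -0.9 * np.exp(-1.0), abs=1e-4
        )

    def test_long_delays_vanish(self):
        assert stdp_delta(1e6, self.CFG) == pytest.approx(0.0, abs=1e-12)
        assert stdp_delta(-1e6, self.CFG) == pytest.approx(0.0, abs=1e-12)

    def test_simultaneous_spikes_no_change(self):
        assert stdp_delta(0.0, self.CFG) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_sign_antisymmetry(self, x):
        assert stdp_delta(x, self.CFG) > 0
        assert stdp_delta(-x, self.CFG) < 0


def _single_neuron_net(i_ext: float) -> Network:
    net = Network()
    pop = net.add_population(NeuronPopulation("n", 1))
    pop.i_ext[:] = i_ext
    return net


class TestNetworkRun:
    def test_empty_network(self):
        rec = Network().run(100.0, dt=1.0, rng=0)
        assert rec.n_spikes() == 0

    def test_constant_current_spikes_every_ms(self):
        rec = _single_neuron_net(2.0).run(100.0, dt=1.0, rng=0)
        times = rec.spikes("n", 0)
        assert times == pytest.approx(list(np.arange(1.0, 101.0)))

    def test_determinism(self):
        def make():
            net = Network()
            a = net.add_population(NeuronPopulation("a", 3))
            b = net.add_population(NeuronPopulation("b", 2, tie_break=True))
            a.i_ext[:] = [1.0, 2.0, 0.4]
            net.connect(SynapseGroup(a, b, 0.8, plastic=True))
            return net

        rec1 = make().run(200.0, dt=1.0, rng=42)
        rec2 = make().run(200.0, dt=1.0, rng=42)
        assert rec1 == rec2
        assert rec1.n_spikes() > 0

    def test_duration_not_multiple_of_dt(self):
        with pytest.raises(ValueError):
            _single_neuron_net(0.0).run(100.5, dt=1.0, rng=0)

    def test_unwired_population_rejected(self):
        net = Network()
        a = net.add_population(NeuronPopulation("a", 1))
        stray = NeuronPopulation("stray", 1)
        with pytest.raises(ValueError):
            net.connect(SynapseGroup(a, stray, 1.0))

    def test_weights_stay_bounded_after_plastic_run(self):
        net = Network()
        a = net.add_population(NeuronPopulation("a", 2))
        b = net.add_population(NeuronPopulation("b", 2))
        a.i_ext[:] = 1.0  # pre fires every ~3 ms, so pairings have dt > 0
        g = net.connect(SynapseGroup(a, b, 1.0, plastic=True,
                                     w_min=0.0, w_max=3.0))
        net.run(500.0, dt=1.0, rng=1)
        assert np.all(g.W >= 0.0) and np.all(g.W <= 3.0)
        assert np.any(g.W > 1.0)  # potentiation actually happened

    def test_inhibition_suppresses_firing(self):
        """An inhibited neuron spikes less than an uninhibited twin."""
        net = Network()
        drv = net.add_population(NeuronPopulation("drv", 1))
        tgt = net.add_population(NeuronPopulation("tgt", 2))
        drv.i_ext[:] = 2.0
        tgt.i_ext[:] = 0.15
        mask = np.array([[1.0, 0.0]])
        net.connect(SynapseGroup(drv, tgt, 1.0, sign=-1, mask=mask))
        rec = net.run(500.0, dt=1.0, rng=0)
        assert len(rec.spikes("tgt", 0)) < len(rec.spikes("tgt", 1))

    def test_tie_break_selects_single_winner(self, rng):
        net = Network()
        out = net.add_population(NeuronPopulation("out", 2, tie_break=True))
        out.i_ext[:] = 2.0  # both cross threshold on the same step
        spikes = net.step(1.0, 1.0, rng)
        assert spikes["out"].sum() == 1

    def test_spike_record_csv_round_trip(self, tmp_path):
        rec = _single_neuron_net(2.0).run(3.0, dt=1.0, rng=0)
        path = tmp_path / "spikes.csv"
        rec.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time_ms,population,neuron_id"
        assert lines[1].startswith("1.0,n,0")
        assert len(lines) == 4
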