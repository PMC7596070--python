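"""Tests for the conditioning phase: dopamine trace, punishment rule and
one-shot learning."""

import numpy as np
import pytest

from flydec import (
    DATrace,
    build_model,
    da_level,
    encode,
    punish_update,
    train_pattern,
    train_task,
)
from flydec.snn_core import NeuronPopulation, SynapseGroup


class TestDATrace:
    TRACE = DATrace(t_pun=100.0, peak=10.0, tau_t=2.0)

    def test_peak_at_punishment(self):
        assert da_level(self.TRACE, 100.0) == pytest.approx(10.0)

    def test_one_decay_constant(self):
        assert da_level(self.TRACE, 102.0) == pytest.approx(
            10.0 * np.exp(-1.0), abs=1e-4
        )

    def test_long_time_vanishes(self):
        assert da_level(self.TRACE, 1e5) == pytest.approx(0.0, abs=1e-12)

    def test_query_before_punishment_rejected(self):
        with pytest.raises(ValueError):
            da_level(self.TRACE, 99.9)

    def test_strictly_decreasing(self):
        ts = np.linspace(100.0, 120.0, 50)
        levels = [da_level(self.TRACE, t) for t in ts]
        assert np.all(np.diff(levels) < 0)


def _ff_group(weight: float) -> SynapseGroup:
    pre = NeuronPopulation("pre", 5)
    post = NeuronPopulation("post", 2)
    return SynapseGroup(pre, post, weight, plastic=True, w_min=0.0, w_max=10.0)


class TestPunishUpdate:
    def test_no_trace_leaves_weights_unchanged(self):
        g = _ff_group(5.0)
        before = g.W.copy()
        punish_update(g, None, np.ones(5, bool), 1, t=10.0, dt=1.0, cutoff=0.1)
        np.testing.assert_array_equal(g.W, before)

    def test_cumulative_decrement_is_da_peak(self):
        """Integrating DA(t) * dt / tau_t over the trace removes about
        DA_peak = 10 in total, so a weight of 5 is clipped at zero and
        a weight of 12 ends near 2 (dt-invariant)."""
        for dt in (1.0, 0.1):
            g = _ff_group(5.0)
            g.w_max = 12.0
            g.W[0, 0] = 12.0
            trace = DATrace(t_pun=0.0)
            active = np.array([True, True, False, False, False])
            t = 0.0
            while t < 30.0:
                t += dt
                punish_update(g, trace, active, 1, t, dt, cutoff=0.1)
            assert g.W[1, 0] == 0.0                      # 5 - 10 clipped
            assert g.W[0, 0] == pytest.approx(2.0, abs=0.3)
            assert g.W[2, 0] == 5.0                      # inactive untouched
            np.testing.assert_array_equal(g.W[:, 1], 5.0)  # other column

    def test_only_chosen_column_touched(self):
        g = _ff_group(5.0)
        punish_update(g, DATrace(t_pun=0.0), np.ones(5, bool), 2,
                      t=0.5, dt=0.5, cutoff=0.1)
        assert np.all(g.W[:, 0] == 5.0)
        assert np.all(g.W[:, 1] < 5.0)


class TestTrainPattern:
    def test_punished_first_choice_depresses_weights(self):
        model = build_model(seed=3)
        green = encode("green", "upright")
        blue = encode("blue", "upright")
        ep = train_pattern(model, blue, green, punished=True)
        if ep.chosen_behavior == 1:
            assert ep.punishment_applied
        # blue channel is index 2; after the episode the punished column is
        # fully depressed and the safe column saturated
        col = model.W_cc[2]
        assert col.max() >= 9.0 and col.min() <= 0.5

    def test_cc_and_mb_matrices_agree(self, trained_model_factory):
        model = trained_model_factory(seed=0)
        np.testing.assert_array_equal(model.W_cc, model.W_mb)

    def test_epochs_zero_leaves_model_unchanged(self):
        model = build_model(seed=0)
        before = model.W_cc.copy()
        out = train_task(model, encode("green", "upright"),
                         encode("blue", "inverted"), epochs=0)
        assert out == []
        np.testing.assert_array_equal(model.W_cc, before)

    def test_training_log_csv(self, tmp_path):
        model = build_model(seed=1)
        path = tmp_path / "log.csv"
        train_task(model, encode("green", "upright"),
                   encode("blue", "inverted"), epochs=1, log_path=path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("episode,pattern,chosen_behavior")
        assert len(lines) == 3

    def test_at_most_one_punished_episode_per_pattern(self):
        """Reinforcement-learning bound: after at most one incorrect
        (punished) episode the correct behaviour is chosen thereafter."""
        for seed in range(8):
            model = build_model(seed=seed)
            safe, pun = encode("green", "upright"), encode("blue", "inverted")
            episodes = train_task(model, safe, pun, epochs=2)
            for name in (safe.name, pun.name):
                flags = [ep.punishment_applied for ep in episodes
                         if ep.pattern == name]
                assert sum(flags) <= 1
                # once correct, stays correct: no punishment after the first
                # clean episode
                if False in flags:
                    assert not any(flags[flags.index(False):])

    def test_learning_fixed_point(self, trained_model_factory):
        model = trained_model_factory(seed=1)
        episodes = train_task(model, encode("green", "upright"),
                              encode("blue", "inverted"), epochs=1)
        assert not any(ep.punishment_applied for ep in episodes)

    def test_swapped_roles_mirror_weights(self):
        a = build_model(seed=5)
        train_task(a, encode("green", "upright"), encode("blue", "inverted"),
                   epochs=1)
        b = build_model(seed=5)
        train_task(b, encode("blue", "inverted"), encode("green", "upright"),
                   epochs=1)
        # behaviour-1 and behaviour-2 columns exchange roles
        np.testing.assert_allclose(a.W_cc[:, 0], b.W_cc[:, 1], atol=1.0)
        np.testing.assert_allclose(a.W_cc[:, 1], b.W_cc[:, 0], atol=1.0)
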