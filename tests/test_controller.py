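"""Sliding windows, controller network contracts, clamps, and torque law."""

import numpy as np
import pytest

from gaitforge.controller import (
    ClampRanges,
    ControllerCorpus,
    ImpedanceCommand,
    JointState,
    WindowConfig,
    build_eq_net,
    build_kb_net,
    clamp_equilibrium,
    eq_unit_to_degrees,
    impedance_torque,
    load_controllers,
    make_windows,
    predict_command,
    save_controllers,
    train_controllers,
)
from gaitforge.core import ANGLE_GAIN, DataError, TimeSeriesGait, \
    denormalize_value
from gaitforge.timeseries import ImpedanceRanges


def _series(n, rng=None):
    gait = (np.sin(np.arange(n)[:, None] * 0.07 + np.arange(4)[None, :])
            * 0.1 + 0.5)
    imp = np.clip(gait[:, [1, 2, 3, 0]] + 0.05, 0, 1)
    return TimeSeriesGait(gait, impedance=imp)


class TestMakeWindows:
    def test_window_count_formula(self):
        corpus = make_windows(_series(100), WindowConfig())
        assert len(corpus) == 100 - 50 - 20 + 1 == 31
        assert corpus.eq_x.shape == (31, 50, 2)
        assert corpus.kb_x.shape == (31, 50, 4)

    def test_first_eq_target_index(self):
        s = _series(100)
        corpus = make_windows(s, WindowConfig())
        # first window history [0, 50); target 20 samples past its end
        expected = denormalize_value(s.gait[69, [2, 3]], ANGLE_GAIN)
        assert np.allclose(corpus.eq_y[0], expected)

    def test_kb_target_at_window_end(self):
        s = _series(100)
        corpus = make_windows(s, WindowConfig())
        assert np.allclose(corpus.kb_y[0], s.impedance[49])

    def test_constant_series_identical_windows(self):
        gait = np.full((120, 4), 0.5)
        imp = np.full((120, 4), 0.3)
        corpus = make_windows(TimeSeriesGait(gait, impedance=imp))
        assert np.allclose(corpus.eq_x, corpus.eq_x[0])
        assert np.allclose(corpus.kb_y, 0.3)

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            make_windows(_series(60), WindowConfig())

    def test_missing_impedance_rejected(self):
        with pytest.raises(DataError):
            make_windows(TimeSeriesGait(np.full((200, 4), 0.5)))


class TestNetworkContracts:
    def test_output_widths(self, rng):
        eq = build_eq_net(seed=0)
        kb = build_kb_net(seed=0)
        x2 = rng.uniform(size=(7, 50, 2))
        x4 = rng.uniform(size=(7, 50, 4))
        assert eq.forward(x2).shape == (7, 2)
        assert kb.forward(x4).shape == (7, 4)

    def test_inference_deterministic_noise_only_in_training(self, rng):
        eq = build_eq_net(seed=0)
        x = rng.uniform(size=(3, 50, 2))
        assert np.array_equal(eq.forward(x), eq.forward(x))
        assert not np.array_equal(eq.forward(x, train=True),
                                  eq.forward(x, train=True))

    def test_kb_outputs_in_unit_interval(self, rng):
        kb = build_kb_net(seed=1)
        out = kb.forward(rng.uniform(size=(10, 50, 4)))
        assert np.all(out > 0) and np.all(out < 1)


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self):
        corpus = make_windows(_series(400))
        from gaitforge.controller import EQ_NET_SPEC, KB_NET_SPEC
        import dataclasses

        eq_spec = dataclasses.replace(EQ_NET_SPEC, batch_size=64)
        kb_spec = dataclasses.replace(KB_NET_SPEC, batch_size=64)
        _, _, hist_a = train_controllers(corpus, eq_spec, kb_spec, seed=3)
        _, _, hist_b = train_controllers(corpus, eq_spec, kb_spec, seed=3)
        assert len(hist_a["eq"]) == len(hist_a["kb"]) == 15
        assert hist_a["eq"][-1] < hist_a["eq"][0]
        assert hist_a["kb"][-1] < hist_a["kb"][0]
        assert hist_a == hist_b

    def test_empty_corpus_rejected(self):
        empty = ControllerCorpus(*(np.zeros((0, 50, 2)), np.zeros((0, 2)),
                                   np.zeros((0, 50, 4)), np.zeros((0, 4))))
        with pytest.raises(DataError):
            train_controllers(empty)


class TestClampsAndCommands:
    def test_clamp_worked_examples(self):
        knee, ankle = clamp_equilibrium(150.0, -12.0)
        assert knee == 120.0
        assert ankle == -8.0

    @pytest.mark.parametrize("knee_raw,ankle_raw", [
        (1e6, 1e6), (-1e6, -1e6), (60.0, 0.0),
    ])
    def test_clamps_hold_for_any_raw_output(self, knee_raw, ankle_raw):
        knee, ankle = clamp_equilibrium(knee_raw, ankle_raw)
        assert 0.0 <= knee <= 120.0
        assert -8.0 <= ankle <= 8.0

    def test_kb_zero_maps_to_table_lower_bounds(self, rng):
        from gaitforge.timeseries import scale_to_physical

        vals = [scale_to_physical(0.0, j, k)
                for j in ("knee", "ankle") for k in ("stiffness", "damping")]
        assert vals == [1.5, 0.05, 3.0, 0.05]

    def test_predict_command_within_bounds(self, rng):
        eq = build_eq_net(seed=0)
        kb = build_kb_net(seed=0)
        cmd = predict_command(rng.uniform(size=(50, 2)),
                              rng.uniform(size=(50, 4)), eq, kb)
        assert 0.0 <= cmd.theta_eq_knee <= 120.0
        assert -8.0 <= cmd.theta_eq_ankle <= 8.0
        assert 1.5 <= cmd.k_knee <= 5.0
        assert 0.05 <= cmd.b_knee <= 0.5
        assert 3.0 <= cmd.k_ankle <= 8.0
        assert 0.05 <= cmd.b_ankle <= 0.15

    def test_malformed_history_rejected(self, rng):
        eq = build_eq_net(seed=0)
        kb = build_kb_net(seed=0)
        with pytest.raises(DataError):
            predict_command(rng.uniform(size=(50, 3)),
                            rng.uniform(size=(50, 4)), eq, kb)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        eq = build_eq_net(seed=7)
        kb = build_kb_net(seed=8)
        path = tmp_path / "ctrl.npz"
        save_controllers(path, eq, kb)
        eq2, kb2 = load_controllers(path)
        x = rng.uniform(size=(2, 50, 2))
        assert np.array_equal(eq.forward(x), eq2.forward(x))


class TestImpedanceTorque:
    def _cmd(self, **kw):
        base = dict(theta_eq_knee=10.0, theta_eq_ankle=0.0, k_knee=3.0,
                    b_knee=0.1, k_ankle=4.0, b_ankle=0.1)
        base.update(kw)
        return ImpedanceCommand(**base)

    def test_zero_at_equilibrium(self):
        cmd = self._cmd()
        tau = impedance_torque(JointState("knee", 10.0, 0.0), cmd)
        assert tau == 0.0

    def test_hand_value(self):
        cmd = self._cmd(theta_eq_knee=0.0, k_knee=3.0, b_knee=0.1)
        tau = impedance_torque(JointState("knee", 5.0, 10.0), cmd)
        assert tau == pytest.approx(-16.0)

    def test_no_damping_ignores_velocity(self):
        cmd = self._cmd(b_ankle=0.0)
        t1 = impedance_torque(JointState("ankle", 3.0, 100.0), cmd)
        t2 = impedance_torque(JointState("ankle", 3.0, -100.0), cmd)
        assert t1 == t2

    def test_restoring_sign(self, rng):
        cmd = self._cmd()
        for angle in rng.uniform(-50, 80, size=20):
            tau = impedance_torque(JointState("knee", float(angle), 0.0), cmd)
            if angle != cmd.theta_eq_knee:
                assert np.sign(tau) == -np.sign(angle - cmd.theta_eq_knee)


def test_eq_unit_to_degrees_endpoints():
    out = eq_unit_to_degrees(np.array([[0.0, 0.0], [1.0, 1.0]]))
    assert np.allclose(out, [[0.0, -8.0], [120.0, 8.0]])
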