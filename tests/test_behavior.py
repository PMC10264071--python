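"""Behavioral metric extraction: envelope, speed, normalization contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorstates.behavior import (BehaviorSession, compute_epoch_metrics,
                                  effective_motor_control, epoch_grid,
                                  minmax_normalize, movement_speed, slowness,
                                  tremor_amplitude)

FS = 100.0


def _interior(values):
    """Epoch means away from trial-edge filter transients."""
    return np.asarray(values)[1:-1]


class TestTremorAmplitude:
    def test_envelope_of_pure_sinusoid_equals_amplitude(self, make_session):
        t = np.arange(0, 35, 1 / FS)
        xy = np.column_stack([0.8 * np.sin(2 * np.pi * 5 * t),
                              np.zeros_like(t)])
        res = tremor_amplitude(make_session(xy))
        vals = _interior(res.epochs["tremor"].dropna())
        assert np.all(np.abs(vals - 0.8) < 0.008)

    def test_constant_cursor_has_zero_tremor(self, make_session):
        xy = np.full((3000, 2), 3.7)
        res = tremor_amplitude(make_session(xy))
        assert np.nanmax(res.epochs["tremor"]) < 1e-9

    def test_low_frequency_drift_rejected(self, make_session):
        # 5 Hz tremor (amp 0.5) superimposed on large 1 Hz drift (amp 5):
        # the bandpass isolates the 5 Hz component
        t = np.arange(0, 35, 1 / FS)
        x = 0.5 * np.sin(2 * np.pi * 5 * t) + 5.0 * np.sin(2 * np.pi * 1 * t)
        res = tremor_amplitude(make_session(np.column_stack([x, 0 * t])))
        vals = _interior(res.epochs["tremor"].dropna())
        assert np.all(np.abs(vals - 0.5) < 0.01)

    def test_rotation_invariance(self, make_session, rng):
        t = np.arange(0, 28, 1 / FS)
        xy = np.column_stack([0.6 * np.sin(2 * np.pi * 6 * t),
                              0.05 * rng.standard_normal(len(t))])
        theta = 0.9
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = tremor_amplitude(make_session(xy)).epochs["tremor"].dropna()
        b = tremor_amplitude(make_session(xy @ R.T)).epochs["tremor"].dropna()
        assert np.all(np.abs(a.to_numpy() - b.to_numpy())
                      / a.to_numpy() < 0.01)

    def test_short_trial_skipped_with_warning(self, make_session):
        xy = np.random.default_rng(1).standard_normal((80, 2))
        sess = make_session(xy, trial_spans=[(0.0, 0.8)])
        with pytest.warns(UserWarning, match="skipped"):
            res = tremor_amplitude(sess)
        assert np.all(np.isnan(res.values))


class TestMovementSpeed:
    def test_straight_line_speed(self, make_session):
        t = np.arange(0, 35, 1 / FS)
        xy = np.column_stack([4.0 * t, np.zeros_like(t)])
        res = movement_speed(make_session(xy))
        vals = _interior(res.epochs["speed"].dropna())
        assert np.all(np.abs(vals - 4.0) < 0.08)

    def test_stationary_cursor_zero_speed(self, make_session):
        xy = np.full((3000, 2), 1.0)
        res = movement_speed(make_session(xy))
        assert np.nanmax(res.epochs["speed"]) < 1e-9

    def test_tremor_removed_by_lowpass(self, make_session):
        # 4 deg/s drift plus 1 deg 5 Hz tremor; lowpass rejects the tremor
        t = np.arange(0, 35, 1 / FS)
        x = 4.0 * t + 1.0 * np.sin(2 * np.pi * 5 * t)
        res = movement_speed(make_session(np.column_stack([x, 0 * t])))
        vals = _interior(res.epochs["speed"].dropna())
        assert np.all(np.abs(vals - 4.0) < 0.2)


class TestSlowness:
    def test_endpoints_forced_by_definition(self):
        np.testing.assert_allclose(slowness([2.0, 4.0, 6.0]), [1.0, 0.5, 0.0])

    def test_fastest_epoch_is_zero(self, rng):
        v = rng.uniform(1, 5, size=30)
        s = slowness(v)
        assert s[np.argmax(v)] == 0.0
        assert s[np.argmin(v)] == 1.0

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        v = np.array([1.0, 2.5, 3.0, 7.0, 4.2])
        np.testing.assert_allclose(slowness(a * v + b), slowness(v),
                                   atol=1e-9)

    def test_degenerate_speeds_raise(self):
        with pytest.raises(ValueError):
            slowness([3.0, 3.0, 3.0])


class TestEffectiveMotorControl:
    @pytest.mark.parametrize("tn,sl,expected", [
        (0.0, 0.0, 1.0),
        (1.0, 1.0, 0.0),
        (1.0, 0.0, 0.5),
    ])
    def test_formula(self, tn, sl, expected):
        assert effective_motor_control(np.array([tn]),
                                       np.array([sl]))[0] == expected

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ValueError):
            effective_motor_control(np.array([1.5]), np.array([0.0]))

    def test_order_relations(self, rng):
        speeds = rng.uniform(1, 5, 40)
        sl = slowness(speeds)
        emc = effective_motor_control(np.zeros(40), sl)
        # slowness order-reverses speed; emc order-preserves it
        assert np.all(np.argsort(sl) == np.argsort(-speeds))
        assert np.all(np.argsort(emc) == np.argsort(speeds))


class TestEpoching:
    def test_partial_final_window_dropped(self, make_session):
        sess = make_session(np.zeros((2000, 2)), trial_spans=[(0.0, 20.0)])
        grid = epoch_grid(sess, 7.0)
        assert grid == [(0.0, 7.0), (7.0, 14.0)]

    def test_epochs_tile_within_trials(self, make_session):
        sess = make_session(np.zeros((3000, 2)),
                            trial_spans=[(0.0, 15.0), (15.0, 30.0)])
        grid = epoch_grid(sess, 7.0)
        assert len(grid) == 4
        assert grid[2][0] == 15.0

    def test_metrics_table_schema(self, make_session, rng):
        t = np.arange(0, 60, 1 / FS)
        xy = np.column_stack([np.sin(2 * np.pi * 5 * t) + 2 * t,
                              rng.standard_normal(len(t)) * 0.01])
        df = compute_epoch_metrics(make_session(xy))
        assert set(df.columns) >= {"epoch_index", "t_start", "tremor",
                                   "speed", "slowness", "emc", "epoch_len"}
        assert df["slowness"].between(0, 1).all()
        assert df["emc"].between(0, 1).all()
        assert (df["tremor"] >= 0).all()


class TestSessionIO:
    def test_csv_roundtrip(self, tmp_path, make_session, rng):
        xy = rng.standard_normal((500, 2))
        sess = make_session(xy, trial_spans=[(0.0, 2.0), (2.5, 5.0)])
        path = tmp_path / "session.csv"
        sess.to_csv(path)
        back = BehaviorSession.from_csv(path)
        np.testing.assert_allclose(back.cursor_xy, sess.cursor_xy)
        assert back.fs == pytest.approx(sess.fs)

    def test_invariant_violations_raise(self):
        with pytest.raises(ValueError):
            BehaviorSession(time=np.array([0.0, 0.0, 1.0]),
                            cursor_xy=np.zeros((3, 2)),
                            target_xy=np.zeros((3, 2)),
                            trial_spans=[(0.0, 1.0)], fs=100.0)
        with pytest.raises(ValueError):
            BehaviorSession(time=np.arange(3) / 10.0,
                            cursor_xy=np.zeros((3, 2)),
                            target_xy=np.zeros((3, 2)),
                            trial_spans=[(0.0, 1.0)], fs=10.0)
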