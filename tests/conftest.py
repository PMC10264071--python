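import numpy as np
import pytest

from motorstates.behavior import BehaviorSession


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def make_session():
    """Factory for single-trial sessions from explicit cursor traces."""

    def _make(cursor_xy, fs=100.0, target_xy=None, trial_spans=None):
        cursor_xy = np.asarray(cursor_xy, dtype=float)
        n = len(cursor_xy)
        t = np.arange(n) / fs
        if target_xy is None:
            target_xy = np.zeros_like(cursor_xy)
        if trial_spans is None:
            trial_spans = [(0.0, n / fs)]
        return BehaviorSession(time=t, cursor_xy=cursor_xy,
                               target_xy=target_xy, trial_spans=trial_spans,
                               fs=fs)

    return _make
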