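"""Ground-truth generator: determinism, state statistics, injected couplings."""

import numpy as np
import pytest

from motorstates.behavior import compute_epoch_metrics, epoch_grid
from motorstates.spectral import coherence_features, power_features
from motorstates.synthetic import (CoherenceCoupling, Coupling, SimConfig,
                                   simulate_behavior, simulate_neural,
                                   simulate_site_map, stationary_distribution)


def _epoch_latent(truth, epochs, which="tremor"):
    series = (truth.latent_tremor if which == "tremor"
              else truth.latent_slowness)
    bins = np.arange(len(series)) * truth.bin_s
    return np.array([series[(bins >= a) & (bins < b)].mean()
                     for a, b in epochs])


class TestSimulateBehavior:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(duration_s=60.0, seed=11)
        s1, t1 = simulate_behavior(cfg)
        s2, t2 = simulate_behavior(cfg)
        np.testing.assert_array_equal(s1.cursor_xy, s2.cursor_xy)
        np.testing.assert_array_equal(t1.latent_state, t2.latent_state)

    def test_zero_gain_suppresses_tremor_metric(self):
        base = dict(duration_s=120.0, seed=4)
        on, _ = simulate_behavior(SimConfig(tremor_gain=1.0, **base))
        off, _ = simulate_behavior(SimConfig(tremor_gain=0.0, **base))
        m_on = compute_epoch_metrics(on)["tremor"].mean()
        m_off = compute_epoch_metrics(off)["tremor"].mean()
        assert m_off < 0.05 * m_on

    def test_two_state_occupancy_matches_stationary_distribution(self):
        # two-state chain (slow state unreachable): stationary tremor 0.3
        P = np.array([[0.950, 0.0, 0.050],
                      [0.0, 1.0, 0.0],
                      [0.0214285714, 0.0, 0.9785714286]])
        pi = stationary_distribution(P)
        assert pi[0] == pytest.approx(0.3, abs=1e-3)   # oracle
        cfg = SimConfig(duration_s=700.0, state_transition_probs=P, seed=2)
        _, truth = simulate_behavior(cfg)
        occ = np.mean(truth.latent_state == 0)
        assert abs(occ - pi[0]) < 0.05

    def test_tremor_band_energy_scales_with_gain_squared(self):
        base = dict(duration_s=300.0, seed=9)
        c0, _ = simulate_behavior(SimConfig(tremor_gain=0.0, **base))
        c1, _ = simulate_behavior(SimConfig(tremor_gain=1.0, **base))
        c2, _ = simulate_behavior(SimConfig(tremor_gain=0.5, **base))
        # identical seed: the injected oscillation is the only difference
        p1 = np.var(c1.cursor_xy - c0.cursor_xy)
        p2 = np.var(c2.cursor_xy - c0.cursor_xy)
        assert p1 / p2 == pytest.approx(4.0, rel=0.10)

    def test_trial_spans_cover_session(self):
        sess, _ = simulate_behavior(SimConfig(duration_s=120.0, seed=0))
        spans = sess.trial_spans
        assert spans[0][0] == 0.0
        assert spans[-1][1] == pytest.approx(120.0)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 == pytest.approx(a1)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": -5.0},
        {"fs_behavior": 0.0},
        {"tremor_freq": 12.0},
        {"fs_neural": 500.0},
    ])
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_nonstochastic_rows_raise(self):
        P = np.eye(3) * 0.5
        with pytest.raises(ValueError):
            SimConfig(state_transition_probs=P)


class TestSimulateNeural:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(duration_s=30.0, seed=5,
                        coupling_map=[Coupling(0, "beta", "slowness", 1.0)])
        sess, truth = simulate_behavior(cfg)
        r1 = simulate_neural(sess, truth, cfg)[0]
        r2 = simulate_neural(sess, truth, cfg)[0]
        np.testing.assert_array_equal(r1.signal, r2.signal)

    def test_theta_alpha_power_tracks_latent_tremor(self):
        cfg = SimConfig(duration_s=300.0, seed=7,
                        coupling_map=[Coupling(0, "theta_alpha", "tremor",
                                               2.0)])
        sess, truth = simulate_behavior(cfg)
        rec = simulate_neural(sess, truth, cfg)[0]
        epochs = epoch_grid(sess, 7.0)
        feats = power_features(rec, epochs, log=False)
        theta = feats.values[:, :7].mean(axis=1)
        latent = _epoch_latent(truth, feats.epoch_spans, "tremor")
        r = np.corrcoef(theta, latent)[0, 1]
        assert r >= 0.7

    def test_shared_component_creates_metric_gated_coherence(self):
        cfg = SimConfig(
            duration_s=280.0, seed=3, n_channels=2,
            coherence_couplings=[CoherenceCoupling((0, 1), (18.0, 22.0),
                                                   "slowness", 4.0)])
        sess, truth = simulate_behavior(cfg)
        recs = simulate_neural(sess, truth, cfg)
        epochs = epoch_grid(sess, 7.0)
        coh = coherence_features(recs[0].signal, recs[1].signal, cfg.fs_neural,
                                 epochs)
        latent = _epoch_latent(truth, coh.epoch_spans, "slowness")
        beta = coh.values[:, 7:14].mean(axis=1)
        hi, lo = latent > np.median(latent), latent <= np.median(latent)
        assert beta[hi].mean() > beta[lo].mean()

    def test_band_outside_range_raises(self):
        cfg = SimConfig(duration_s=30.0, seed=0,
                        coupling_map=[Coupling(0, (1.0, 5.0), "tremor", 1.0)])
        sess, truth = simulate_behavior(cfg)
        with pytest.raises(ValueError, match="3-400"):
            simulate_neural(sess, truth, cfg)


class TestSimulateSiteMap:
    def test_zero_gradient_gives_identical_coupling(self):
        cfg = SimConfig(duration_s=30.0,
                        coupling_map=[Coupling(0, "beta", "slowness", 1.5)])
        sites = simulate_site_map(4, 0.0, cfg)
        slopes = [c.coupling_map[0].slope for _, c in sites]
        assert slopes == [1.5] * 4

    def test_single_site_map_is_valid(self):
        cfg = SimConfig(duration_s=30.0)
        sites = simulate_site_map(1, 0.5, cfg)
        assert len(sites) == 1

    def test_slopes_vary_monotonically_along_axis(self):
        cfg = SimConfig(duration_s=30.0,
                        coupling_map=[Coupling(0, "theta_alpha", "tremor",
                                               2.0)])
        sites = simulate_site_map(5, {"tremor": 0.4}, cfg,
                                  axis=(0.0, 0.0, 1.0))
        slopes = [c.coupling_map[0].slope for _, c in sites]
        assert np.all(np.diff(slopes) > 0)
        zs = [xyz[2] for xyz, _ in sites]
        assert np.all(np.diff(zs) == pytest.approx(1.0))   # 1 mm grid

    def test_degenerate_axis_raises(self):
        with pytest.raises(ValueError, match="axis"):
            simulate_site_map(3, 0.1, SimConfig(duration_s=30.0),
                              axis=(0.0, 0.0, 0.0))
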