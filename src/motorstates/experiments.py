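"""Canned validation experiments on synthetic ground truth.

Each function sets up a known study condition with the synthetic generator
(or a closed-form construction), runs the relevant pipeline stage, and
returns the measured quantities. They are the package's self-validation
battery: envelope and speed oracles, coherence identities, decoder and
spatial recovery rates, permutation-test calibration, timescale recovery and
mixed-model calibration. All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .behavior import (BehaviorSession, compute_epoch_metrics, epoch_grid,
                       movement_speed, tremor_amplitude)
from .decoding import cross_metric_apply, shuffled_null, train_decoder
from .dynamics import fit_episode_gamma, fwhm, metric_autocorrelogram
from .lmm import fit_random_intercepts
from .spatial import SiteResult, bin_sites, voxelwise_paired_test
from .spectral import coherence_features, feature_labels, power_features
from .synthetic import (Coupling, SimConfig, simulate_behavior,
                        simulate_neural, simulate_site_map)


def feature_count(seed: int = 0) -> dict:
    """Number of spectral feature columns produced per 7 s epoch."""
    rng = np.random.default_rng(seed)
    from .spectral import NeuralRecording
    rec = NeuralRecording(signal=rng.standard_normal(21000), fs=1000.0)
    power = power_features(rec, [(0.0, 7.0), (7.0, 14.0)])
    coh = coherence_features(rec.signal, rng.standard_normal(21000), 1000.0,
                             [(0.0, 7.0)])
    return {"n_power_features": power.values.shape[1],
            "n_coherence_features": coh.values.shape[1],
            "n_labels": len(feature_labels())}


def _single_trial_session(xy: np.ndarray, fs: float = 100.0
                          ) -> BehaviorSession:
    t = np.arange(len(xy)) / fs
    return BehaviorSession(time=t, cursor_xy=xy,
                           target_xy=np.zeros_like(xy),
                           trial_spans=[(0.0, len(xy) / fs)], fs=fs)


def envelope_oracle() -> dict:
    """Tremor envelope of a 5 Hz, 0.8 deg oscillation and speed of a
    4 deg/s drift with 1 deg tremor superimposed (interior epochs)."""
    fs = 100.0
    t = np.arange(0, 35, 1 / fs)
    sess = _single_trial_session(np.column_stack(
        [0.8 * np.sin(2 * np.pi * 5 * t), np.zeros_like(t)]))
    trem = tremor_amplitude(sess).epochs["tremor"].dropna().to_numpy()[1:-1]
    sess2 = _single_trial_session(np.column_stack(
        [4.0 * t + 1.0 * np.sin(2 * np.pi * 5 * t), np.zeros_like(t)]))
    spd = movement_speed(sess2).epochs["speed"].dropna().to_numpy()[1:-1]
    return {"tremor_deg": float(trem.mean()), "speed_deg_s": float(spd.mean())}


def coherence_identity(seed: int = 0) -> dict:
    """Self-coherence and the bias floor of independent-noise coherence."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(14000)
    y = rng.standard_normal(14000)
    self_c = coherence_features(x, x, 1000.0, [(0.0, 7.0)]).values
    indep = coherence_features(x, y, 1000.0,
                               [(0.0, 7.0), (7.0, 14.0)]).values
    return {"self_coherence": float(self_c.mean()),
            "self_coherence_max_dev": float(np.abs(self_c - 1.0).max()),
            "independent_coherence": float(indep.mean())}


def _coupled_session(seed: int, slopes: dict[str, float],
                     n_epochs: int = 100):
    """One session + recording with the given band couplings, sized so the
    epoch grid yields about ``n_epochs`` 7 s epochs."""
    duration = n_epochs * 7.0 + 12.0
    coupling = []
    if "tremor" in slopes:
        coupling.append(Coupling(0, "theta_alpha", "tremor",
                                 slopes["tremor"]))
    if "slowness" in slopes:
        coupling.append(Coupling(0, "beta", "slowness", slopes["slowness"]))
    cfg = SimConfig(duration_s=duration, n_trials=int(duration / 25),
                    slow_gain=0.9, coupling_map=coupling, seed=seed)
    sess, truth = simulate_behavior(cfg)
    rec = simulate_neural(sess, truth, cfg)[0]
    em = compute_epoch_metrics(sess)
    spans = [(r, r + 7.0) for r in em["t_start"]]
    feats = power_features(rec, spans)
    return em, feats


def decoder_recovery(n_repeats: int = 20, seed: int = 0,
                     n_folds: int = 25, n_null: int = 50) -> dict:
    """Recovery of a theta/alpha-to-tremor coupling (envelope SNR 2).

    Per repeat: 100-epoch session, tremor decoder vs its shuffled null;
    success requires the empirical r2 to exceed the null 95th percentile
    AND the mean theta/alpha weight to be positive.
    """
    wins, r2s, null95s = 0, [], []
    for rep in range(n_repeats):
        s = seed * 1000 + rep
        em, feats = _coupled_session(s, {"tremor": 2.0})
        y = em["tremor"].to_numpy()
        model, res = train_decoder(feats, y, n_folds=n_folds, seed=s)
        null = shuffled_null(feats, y, n_models=n_null, n_folds=n_folds,
                             seed=s)
        p95 = float(np.percentile(null.r2, 95))
        theta_w = float(model.weights[:7].mean())
        wins += (res.r2 > p95) and (theta_w > 0)
        r2s.append(res.r2)
        null95s.append(p95)
    return {"success_rate": wins / n_repeats,
            "mean_r2": float(np.mean(r2s)),
            "mean_null95": float(np.mean(null95s)),
            "n_repeats": n_repeats}


def weight_test_calibration(n_repeats: int = 100, n_iter: int = 1000,
                            n_recordings: int = 20, seed: int = 0) -> dict:
    """Type-I rate under the exchangeable null and power for an injected
    7-feature offset of twice the between-recording difference sd."""
    from .weights import contiguity_permutation_test

    rates, detected = [], 0
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed * 10000 + rep)
        W_a = rng.standard_normal((n_recordings, 42))
        W_b = rng.standard_normal((n_recordings, 42))
        res = contiguity_permutation_test(W_a, W_b, n_iter=n_iter,
                                          seed=seed * 10000 + rep)
        rates.append(float((res.p < 0.05).mean()))
        W_a[:, 5:12] += 2.0 * np.sqrt(2.0)
        res = contiguity_permutation_test(W_a, W_b, n_iter=n_iter,
                                          seed=seed * 10000 + rep)
        detected += any(c.sign > 0
                        and len(set(range(c.start, c.end + 1))
                                & set(range(5, 12))) >= 5
                        for c in res.clusters)
    return {"type1_rate": float(np.mean(rates)),
            "cluster_power": detected / n_repeats,
            "n_repeats": n_repeats}


def cross_metric_contract(seed: int = 0, n_folds: int = 25) -> dict:
    """Sign identity of negated transfer plus weak disjoint-band transfer."""
    em, feats = _coupled_session(seed, {"tremor": 3.0, "slowness": 3.0})
    y_t = em["tremor"].to_numpy()
    y_s = em["slowness"].to_numpy()
    model_t, res_t = train_decoder(feats, y_t, n_folds=n_folds, seed=seed)
    model_s, res_s = train_decoder(feats, y_s, n_folds=n_folds, seed=seed)
    fwd = cross_metric_apply(model_t, feats, y_t)
    neg = cross_metric_apply(model_t, feats, -y_t)
    cross_ts = cross_metric_apply(model_t, feats, y_s)
    cross_st = cross_metric_apply(model_s, feats, y_t)
    return {"sign_identity_error": abs(neg + fwd),
            "within_r2_tremor": res_t.r2,
            "within_r2_slowness": res_s.r2,
            "cross_tremor_to_slowness": cross_ts,
            "cross_slowness_to_tremor": cross_st,
            "max_cross_to_within_ratio": max(
                abs(cross_ts), abs(cross_st)) / min(res_t.r2, res_s.r2)}


def spatial_recovery(n_repeats: int = 20, seed: int = 0, n_sites: int = 6,
                     n_epochs: int = 36, n_folds: int = 25) -> dict:
    """Opposed dorsoventral coupling gradients: does the tremor-vs-slowness
    Z map separate its signed peaks along the configured axis?

    The gradients span each coupling's full range (zero at the far end), and
    the slowness base slope is larger so the two metrics reach comparable
    peak decodability — slowness is intrinsically harder to decode because
    its sub-second episodes average away within 7 s epochs.
    """
    hits = 0
    for rep in range(n_repeats):
        s = seed * 1000 + rep
        duration = n_epochs * 7.0 + 12.0
        cfg = SimConfig(duration_s=duration, n_trials=int(duration / 25),
                        slow_gain=0.9, seed=s,
                        coupling_map=[Coupling(0, "theta_alpha", "tremor",
                                               2.0),
                                      Coupling(0, "beta", "slowness", 3.0)])
        sess, truth = simulate_behavior(cfg)
        em = compute_epoch_metrics(sess)
        spans = [(r, r + 7.0) for r in em["t_start"]]
        sites = simulate_site_map(
            n_sites, {"tremor": 0.8, "slowness": -1.2}, cfg,
            axis=(0.0, 0.0, 1.0))
        results = []
        for k, (xyz, site_cfg) in enumerate(sites):
            rec = simulate_neural(sess, truth, site_cfg)[0]
            feats = power_features(rec, spans)
            r2s = {}
            for metric in ("tremor", "slowness"):
                _, res = train_decoder(feats, em[metric].to_numpy(),
                                       n_folds=n_folds, seed=s + k)
                r2s[metric] = res.r2
            results.append(SiteResult(mni_xyz=xyz, r2_by_metric=r2s,
                                      recording_id=f"site{k}"))
        maps = bin_sites(results)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            sp = voxelwise_paired_test(maps["tremor"], maps["slowness"],
                                       n_perm=1000, seed=s)
        hits += sp.peak_a[0][2] > sp.peak_b[0][2]
    return {"separation_rate": hits / n_repeats, "n_repeats": n_repeats}


def timescale_oracle(seed: int = 0) -> dict:
    """FWHM of an AR(1) latent (phi=0.5 per 100 ms) and gamma-shape MLE
    recovery at n=2000."""
    rng = np.random.default_rng(seed)
    n = 100000
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = 0.5 * x[i - 1] + eps[i]
    _, acf = metric_autocorrelogram(x, 2.0)
    width = fwhm(acf, 0.1)
    d = stats.gamma.rvs(2.0, scale=1.0, size=2000, random_state=rng)
    shape, scale, _ = fit_episode_gamma(d)
    return {"ar1_fwhm_s": float(width), "gamma_shape": float(shape),
            "gamma_scale": float(scale)}


def lmm_calibration(seed: int = 0, n_recovery: int = 20,
                    n_type1: int = 200) -> dict:
    """Slope recovery and type-I rate of the random-intercepts model."""
    hits = 0
    for rep in range(n_recovery):
        rng = np.random.default_rng(seed * 100 + rep)
        subj = np.repeat(np.arange(20), 50)
        x = rng.standard_normal(1000)
        y = (2.0 + 0.5 * x + np.repeat(rng.standard_normal(20), 50)
             + rng.standard_normal(1000))
        res = fit_random_intercepts(y, x, subj)
        hits += 0.4 <= res.beta.iloc[1] <= 0.6
    false_pos = 0
    for rep in range(n_type1):
        rng = np.random.default_rng(seed * 100 + 5000 + rep)
        subj = np.repeat(np.arange(20), 10)
        x = rng.standard_normal(200)
        y = (np.repeat(rng.standard_normal(20), 10)
             + rng.standard_normal(200))
        res = fit_random_intercepts(y, x, subj)
        false_pos += res.p.iloc[1] < 0.05
    return {"slope_recovery_rate": hits / n_recovery,
            "type1_rate": false_pos / n_type1,
            "n_recovery": n_recovery, "n_type1": n_type1}
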