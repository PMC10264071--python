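"""Synthetic behavior and neural data with known ground-truth coupling.

The generator emulates the statistical structure of intraoperative
target-tracking sessions in Parkinson's disease:

* a three-state Markov chain over {tremor, slow, effective} at 100 ms
  resolution sets the latent symptomatic state, with default dwell times of
  roughly 2 s (tremor), 0.5 s (slow) and 8 s (effective) — the distinct
  episode timescales of the two cardinal motor signs;
* the cursor tracks a smoothly moving target; the slow state scales the
  tracking rate down (lower cursor speed), and the tremor state adds a
  3–10 Hz oscillation of amplitude ``tremor_gain`` along a fixed random axis,
  with state edges smoothed by a 200 ms raised-cosine ramp;
* each neural channel is 1/f-shaped background noise plus band-limited
  Gaussian components whose instantaneous envelope is an affine function
  (1 + slope * metric) of the coupled latent metric; an optional shared
  band-limited component injected into two channels creates metric-gated
  cross-channel coherence;
* ``simulate_site_map`` lays recording sites on a 1 mm grid along a spatial
  axis in MNI millimetres with coupling slopes varying linearly along it,
  emulating a dorsolateral-tremor / ventromedial-slowness gradient.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import BehaviorSession
from .spectral import BANDS, NeuralRecording

STATES = ("tremor", "slow", "effective")

#: per-100 ms transition matrix; mean dwell ~2 s (tremor), ~0.67 s (slow),
#: ~3 s (effective); stationary occupancy roughly 0.25 / 0.12 / 0.63
DEFAULT_TRANSITIONS = np.array([
    [0.950, 0.005, 0.045],
    [0.010, 0.850, 0.140],
    [0.012, 0.022, 0.966],
])


@dataclass
class Coupling:
    """Band-limited neural component tied to a latent behavioral metric."""

    channel: int
    band: str | tuple[float, float]      # canonical band name or (lo, hi) Hz
    metric: str                          # tremor | slowness
    slope: float                         # envelope = 1 + slope * metric

    def band_edges(self) -> tuple[float, float]:
        lo, hi = BANDS[self.band] if isinstance(self.band, str) else self.band
        if lo < 3.0 or hi > 400.0 or lo >= hi:
            raise ValueError(f"coupling band {lo}-{hi} Hz outside 3-400 Hz")
        return float(lo), float(hi)


@dataclass
class CoherenceCoupling:
    """Shared band-limited component in two channels, gated by a metric."""

    channels: tuple[int, int]
    band: str | tuple[float, float]
    metric: str
    slope: float

    def band_edges(self) -> tuple[float, float]:
        lo, hi = BANDS[self.band] if isinstance(self.band, str) else self.band
        if lo < 3.0 or hi > 400.0 or lo >= hi:
            raise ValueError(f"coupling band {lo}-{hi} Hz outside 3-400 Hz")
        return float(lo), float(hi)


@dataclass
class SimConfig:
    duration_s: float = 280.0
    fs_behavior: float = 100.0
    fs_neural: float = 1000.0
    n_trials: int = 14
    tremor_gain: float = 1.0            # deg, oscillation amplitude in tremor state
    tremor_freq: float = 5.0            # Hz, within 3-10
    state_transition_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    speed_profile: float = 4.0          # deg/s baseline target speed
    coupling_map: list[Coupling] = field(default_factory=list)
    coherence_couplings: list[CoherenceCoupling] = field(default_factory=list)
    n_channels: int = 1
    noise_exponent: float = 1.0         # 1/f^a background slope
    component_amplitude: float = 1.0    # baseline std of each coupled component
    slow_gain: float = 0.7              # fractional tracking-rate reduction
    tracking_rate: float = 4.0          # 1/s first-order tracking gain
    measurement_noise_deg: float = 0.01
    bin_s: float = 0.1                  # latent-state resolution
    ramp_s: float = 0.2                 # raised-cosine state-edge smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_behavior <= 0 or self.fs_neural <= 0:
            raise ValueError("sampling rates must be positive")
        if self.fs_neural < 1000:
            raise ValueError("fs_neural must be >= 1000 Hz")
        if not (3.0 <= self.tremor_freq <= 10.0):
            raise ValueError("tremor_freq must lie within [3, 10] Hz")
        P = np.asarray(self.state_transition_probs, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0) or \
                not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be >= 0 and sum to 1")
        self.state_transition_probs = P


@dataclass
class GroundTruth:
    """Latent state sequence and smoothed metric latents at 100 ms bins."""

    latent_state: np.ndarray        # int codes into STATES, per bin
    latent_tremor: np.ndarray       # deg, per bin (ramp-smoothed)
    latent_slowness: np.ndarray     # [0, 1], per bin (ramp-smoothed)
    coupling_map: list[Coupling]
    bin_s: float = 0.1

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "t": np.arange(len(self.latent_state)) * self.bin_s,
            "state": [STATES[s] for s in self.latent_state],
            "latent_tremor": self.latent_tremor,
            "latent_slowness": self.latent_slowness,
        }).to_csv(path, index=False)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Closed-form stationary distribution of a row-stochastic matrix."""
    vals, vecs = np.linalg.eig(np.asarray(P, dtype=float).T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


def _markov_states(P: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    states = np.empty(n, dtype=np.int64)
    cum = np.cumsum(P, axis=1)
    states[0] = rng.choice(3, p=stationary_distribution(P))
    u = rng.random(n)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return states


def _raised_cosine(width_samples: int) -> np.ndarray:
    # Hann window normalized to unit sum; width = ramp duration
    if width_samples < 2:
        return np.ones(1)
    win = np.hanning(width_samples + 2)[1:-1]
    return win / win.sum()


def _smooth_indicator(ind: np.ndarray, fs: float, ramp_s: float) -> np.ndarray:
    kern = _raised_cosine(int(round(ramp_s * fs)))
    return np.convolve(ind, kern, mode="same")


def _upsample_bins(x: np.ndarray, bin_s: float, fs: float, n_out: int) -> np.ndarray:
    reps = int(round(bin_s * fs))
    out = np.repeat(x, reps)
    if len(out) < n_out:
        out = np.concatenate([out, np.full(n_out - len(out), out[-1])])
    return out[:n_out]


def _trial_spans(duration: float, n_trials: int,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    """Contiguous trials of 10-30 s tiling the session."""
    n_trials = max(1, min(n_trials, int(duration // 10) or 1))
    lengths = rng.uniform(10.0, 30.0, size=n_trials)
    lengths *= duration / lengths.sum()
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    edges[-1] = duration
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_trials)]


def simulate_behavior(cfg: SimConfig) -> tuple[BehaviorSession, GroundTruth]:
    """Cursor/target traces driven by the latent symptomatic state chain."""
    rng = np.random.default_rng(cfg.seed)
    fs, dur = cfg.fs_behavior, cfg.duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    n_bins = int(np.ceil(dur / cfg.bin_s))

    states = _markov_states(cfg.state_transition_probs, n_bins, rng)
    trem_ind = (states == 0).astype(float)
    slow_ind = (states == 1).astype(float)

    trem_fs = _smooth_indicator(_upsample_bins(trem_ind, cfg.bin_s, fs, n),
                                fs, cfg.ramp_s) * cfg.tremor_gain
    slow_fs = _smooth_indicator(_upsample_bins(slow_ind, cfg.bin_s, fs, n),
                                fs, cfg.ramp_s)

    # smoothed bin-level latents for ground truth
    trem_bins = trem_fs[::int(round(cfg.bin_s * fs))][:n_bins]
    slow_bins = slow_fs[::int(round(cfg.bin_s * fs))][:n_bins]

    # target: random smooth path at constant baseline speed — heading is an
    # integrated Ornstein-Uhlenbeck process with a soft restoring pull toward
    # the workspace centre, giving a curvy trajectory within ~+/-10 deg
    dt = 1.0 / fs
    heading = rng.uniform(0, 2 * np.pi)
    turn_noise = rng.standard_normal(n)
    target = np.empty((n, 2))
    target[0] = (0.0, 0.0)
    for i in range(1, n):
        pos = target[i - 1]
        # steer back toward centre when drifting out
        r = np.hypot(pos[0], pos[1])
        if r > 6.0:
            to_center = np.arctan2(-pos[1], -pos[0])
            dh = np.angle(np.exp(1j * (to_center - heading)))
            heading += 0.8 * dh * dt * (r - 6.0)
        heading += 1.5 * turn_noise[i] * np.sqrt(dt)
        target[i, 0] = pos[0] + cfg.speed_profile * np.cos(heading) * dt
        target[i, 1] = pos[1] + cfg.speed_profile * np.sin(heading) * dt

    # first-order tracking; the slow state scales the tracking velocity
    # down, and catch-up speed is capped, so the cursor trails the curvy
    # target and cuts corners (persistently lower cursor speed)
    rate = cfg.tracking_rate * (1.0 - cfg.slow_gain * slow_fs)
    cap = 1.3 * cfg.speed_profile
    cursor = np.empty_like(target)
    cursor[0] = target[0]
    for i in range(1, n):
        v = rate[i - 1] * (target[i - 1] - cursor[i - 1])
        speed = np.hypot(v[0], v[1])
        if speed > cap:
            v *= cap / speed
        cursor[i] = cursor[i - 1] + dt * v

    # additive tremor oscillation along a fixed random axis
    angle = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(angle), np.sin(angle)])
    osc = trem_fs * np.sin(2 * np.pi * cfg.tremor_freq * t + rng.uniform(0, 2 * np.pi))
    cursor = cursor + osc[:, None] * axis[None, :]
    cursor = cursor + rng.normal(0.0, cfg.measurement_noise_deg, size=cursor.shape)

    session = BehaviorSession(
        time=t, cursor_xy=cursor, target_xy=target,
        trial_spans=_trial_spans(dur, cfg.n_trials, rng),
        fs=fs, subject_id=f"sim{cfg.seed}", group="PD")
    truth = GroundTruth(latent_state=states, latent_tremor=trem_bins,
                        latent_slowness=slow_bins,
                        coupling_map=list(cfg.coupling_map), bin_s=cfg.bin_s)
    return session, truth


def _oneoverf_noise(n: int, fs: float, exponent: float,
                    rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(X * shape, n)
    return x / x.std()


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _metric_series(truth: GroundTruth, cfg: SimConfig, metric: str,
                   n: int) -> np.ndarray:
    """Latent metric on the neural clock, normalized to [0, 1]."""
    if metric == "tremor":
        bins = truth.latent_tremor / max(cfg.tremor_gain, 1e-12)
    elif metric == "slowness":
        bins = truth.latent_slowness
    else:
        raise ValueError(f"unknown metric '{metric}'")
    return np.clip(_upsample_bins(bins, truth.bin_s, cfg.fs_neural, n), 0.0, None)


def simulate_neural(session: BehaviorSession, truth: GroundTruth,
                    cfg: SimConfig) -> list[NeuralRecording]:
    """Channels of 1/f background plus metric-coupled band-limited power."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    fs = cfg.fs_neural
    n = int(round(cfg.duration_s * fs))
    chans = [
        _oneoverf_noise(n, fs, cfg.noise_exponent, rng)
        for _ in range(cfg.n_channels)
    ]
    for cpl in cfg.coupling_map:
        lo, hi = cpl.band_edges()
        if not (0 <= cpl.channel < cfg.n_channels):
            raise ValueError(f"coupling channel {cpl.channel} out of range")
        env = 1.0 + cpl.slope * _metric_series(truth, cfg, cpl.metric, n)
        comp = _band_noise(n, fs, (lo, hi), rng)
        chans[cpl.channel] = chans[cpl.channel] + \
            cfg.component_amplitude * np.clip(env, 0.0, None) * comp
    for cc in cfg.coherence_couplings:
        lo, hi = cc.band_edges()
        env = 1.0 + cc.slope * _metric_series(truth, cfg, cc.metric, n)
        shared = cfg.component_amplitude * np.clip(env, 0.0, None) * \
            _band_noise(n, fs, (lo, hi), rng)
        for ch in cc.channels:
            chans[ch] = chans[ch] + shared
    return [
        NeuralRecording(signal=x, fs=fs, channel_type="micro",
                        subject_id=session.subject_id,
                        session_id=f"{session.subject_id}_sess0")
        for x in chans
    ]


def simulate_site_map(n_sites: int,
                      axis_gradient: float | dict[str, float],
                      cfg: SimConfig,
                      axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
                      origin: tuple[float, float, float] = (-12.0, -10.0, -6.0),
                      ) -> list[tuple[tuple[float, float, float], SimConfig]]:
    """Recording sites on a 1 mm grid with coupling slopes varying linearly
    along ``axis``.

    ``axis_gradient`` is the slope change per millimetre of projection onto
    the axis; a mapping metric -> gradient applies distinct (e.g. opposite)
    gradients to couplings of different metrics, emulating spatially
    segregated symptom representations. Slopes are clipped at zero.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    ax = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(ax)
    if norm == 0:
        raise ValueError("degenerate (zero-length) spatial axis")
    ax = ax / norm
    if not isinstance(axis_gradient, dict):
        axis_gradient = {"tremor": float(axis_gradient),
                         "slowness": float(axis_gradient)}
    out = []
    center = (n_sites - 1) / 2.0
    for k in range(n_sites):
        proj_mm = k - center
        xyz = tuple(np.asarray(origin, dtype=float) + ax * k)
        couplings = []
        for cpl in cfg.coupling_map:
            g = axis_gradient.get(cpl.metric, 0.0)
            couplings.append(replace(
                cpl, slope=max(0.0, cpl.slope + g * proj_mm)))
        out.append((xyz, replace(cfg, coupling_map=couplings,
                                 seed=cfg.seed + k)))
    return out
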