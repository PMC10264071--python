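"""Behavioral metrics from cursor-tracking sessions.

Motor (dys-)function is quantified from 2-D cursor traces recorded while a
subject tracks a moving target:

* **tremor** — amplitude (degrees of visual angle) of 3–10 Hz cursor
  oscillation, measured as the Hilbert envelope of the one-dimensional
  principal-axis projection of the bandpass-filtered trace;
* **speed** — Euclidean cursor speed (deg/s) after lowpass filtering at 3 Hz
  to remove the tremor contribution;
* **slowness** — within-session min–max normalized inverse of speed
  (0 = fastest epoch, 1 = slowest epoch), a bradykinesia surrogate;
* **effective motor control (emc)** — ((1 − tremor_norm) + (1 − slowness))/2,
  where tremor_norm is the per-session min–max normalized epoch tremor;
  1 indicates optimal, symptom-free performance.

Per-sample metrics are averaged into non-overlapping epochs (7 s by default
for decoding; 100 ms for timescale analysis) tiled within each trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class BehaviorSession:
    """Synchronized cursor/target traces with trial structure.

    Attributes
    ----------
    time : (n,) array, seconds, monotone increasing.
    cursor_xy, target_xy : (n, 2) arrays in degrees of visual angle.
    trial_spans : list of (start_s, end_s), non-overlapping.
    fs : sampling rate in Hz (> 20 Hz so the 3–10 Hz tremor band is resolvable).
    """

    time: np.ndarray
    cursor_xy: np.ndarray
    target_xy: np.ndarray
    trial_spans: list[tuple[float, float]]
    fs: float
    subject_id: str = "s0"
    group: str = "PD"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cursor_xy = np.asarray(self.cursor_xy, dtype=float)
        self.target_xy = np.asarray(self.target_xy, dtype=float)
        if self.cursor_xy.ndim != 2 or self.cursor_xy.shape[1] != 2:
            raise ValueError("cursor_xy must be (n, 2)")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.fs <= 20:
            raise ValueError("fs must exceed 20 Hz to resolve the tremor band")
        spans = sorted(self.trial_spans)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("trial spans must be non-overlapping")

    def trial_slices(self) -> list[slice]:
        out = []
        for t0, t1 in self.trial_spans:
            i0 = int(np.searchsorted(self.time, t0, side="left"))
            i1 = int(np.searchsorted(self.time, t1, side="right"))
            out.append(slice(i0, i1))
        return out

    def to_csv(self, path) -> None:
        trial_id = np.full(len(self.time), -1)
        for k, sl in enumerate(self.trial_slices()):
            trial_id[sl] = k
        pd.DataFrame(
            {
                "t": self.time,
                "cursor_x": self.cursor_xy[:, 0],
                "cursor_y": self.cursor_xy[:, 1],
                "target_x": self.target_xy[:, 0],
                "target_y": self.target_xy[:, 1],
                "trial_id": trial_id,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float | None = None, subject_id: str = "s0",
                 group: str = "PD") -> "BehaviorSession":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
        spans = []
        for k, sub in df[df["trial_id"] >= 0].groupby("trial_id"):
            spans.append((float(sub["t"].iloc[0]),
                          float(sub["t"].iloc[-1]) + 1.0 / fs))
        return cls(
            time=t,
            cursor_xy=df[["cursor_x", "cursor_y"]].to_numpy(),
            target_xy=df[["target_x", "target_y"]].to_numpy(),
            trial_spans=spans,
            fs=fs,
            subject_id=subject_id,
            group=group,
        )


def epoch_grid(session: BehaviorSession, epoch_len: float = 7.0
               ) -> list[tuple[float, float]]:
    """Non-overlapping ``epoch_len`` windows tiled within each trial.

    The final partial window of each trial is dropped.
    """
    epochs = []
    for t0, t1 in session.trial_spans:
        n = int(np.floor((t1 - t0) / epoch_len + 1e-9))
        for k in range(n):
            epochs.append((t0 + k * epoch_len, t0 + (k + 1) * epoch_len))
    return epochs


def _butter_sos(kind: str, cut, fs: float, order: int = 4):
    return signal.butter(order, cut, btype=kind, fs=fs, output="sos")


def _epoch_means(time: np.ndarray, values: np.ndarray,
                 epochs: list[tuple[float, float]]) -> np.ndarray:
    out = np.full(len(epochs), np.nan)
    for k, (t0, t1) in enumerate(epochs):
        i0 = int(np.searchsorted(time, t0, side="left"))
        i1 = int(np.searchsorted(time, t1, side="left"))
        seg = values[i0:i1]
        good = np.isfinite(seg)
        if good.any():
            out[k] = float(np.mean(seg[good]))
    return out


def _principal_axis_projection(xy: np.ndarray) -> np.ndarray:
    """Project a (centered) 2-D trace onto its first principal axis."""
    c = xy - xy.mean(axis=0)
    # SVD of n x 2 matrix; first right-singular vector = dominant axis
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return c @ vt[0]


@dataclass
class MetricTrace:
    """Per-sample metric values plus their epoch means."""

    values: np.ndarray                    # per-sample, NaN outside usable trials
    epochs: pd.DataFrame                  # epoch_index, t_start, value columns
    epoch_spans: list[tuple[float, float]] = field(default_factory=list)


def tremor_amplitude(session: BehaviorSession,
                     band: tuple[float, float] = (3.0, 10.0),
                     epoch_len: float = 7.0,
                     epochs: list[tuple[float, float]] | None = None
                     ) -> MetricTrace:
    """Tremor amplitude: envelope of the bandpassed, 1-D-projected cursor.

    Per trial the 2-D cursor trace is bandpass filtered (zero-phase 4th-order
    Butterworth, default 3–10 Hz), projected onto its first principal axis,
    and the amplitude of the analytic signal is taken as the instantaneous
    tremor amplitude in degrees. Trials shorter than three filter time
    constants (3/f_low seconds) are skipped with a warning.
    """
    if epochs is None:
        epochs = epoch_grid(session, epoch_len)
    sos = _butter_sos("bandpass", list(band), session.fs)
    env = np.full(len(session.time), np.nan)
    min_len = 3.0 / band[0]
    for sl, (t0, t1) in zip(session.trial_slices(), session.trial_spans):
        if (t1 - t0) < min_len:
            warnings.warn(
                f"trial [{t0:.2f}, {t1:.2f}] s shorter than 3 filter "
                f"time constants ({min_len:.2f} s); skipped")
            continue
        filt = signal.sosfiltfilt(sos, session.cursor_xy[sl], axis=0)
        proj = _principal_axis_projection(filt)
        env[sl] = np.abs(signal.hilbert(proj))
    means = _epoch_means(session.time, env, epochs)
    df = pd.DataFrame({
        "epoch_index": np.arange(len(epochs)),
        "t_start": [e[0] for e in epochs],
        "tremor": means,
    })
    return MetricTrace(values=env, epochs=df, epoch_spans=epochs)


def movement_speed(session: BehaviorSession,
                   lowpass: float = 3.0,
                   epoch_len: float = 7.0,
                   epochs: list[tuple[float, float]] | None = None
                   ) -> MetricTrace:
    """Cursor speed after 3 Hz lowpass filtering (removes tremor).

    Speed is the Euclidean norm of the time derivative (central differences)
    of the lowpass-filtered 2-D cursor trace, in deg/s; epoch values are the
    arithmetic mean of the per-sample speed.
    """
    if epochs is None:
        epochs = epoch_grid(session, epoch_len)
    sos = _butter_sos("lowpass", lowpass, session.fs)
    speed = np.full(len(session.time), np.nan)
    min_len = 3.0 / lowpass
    for sl, (t0, t1) in zip(session.trial_slices(), session.trial_spans):
        if (t1 - t0) < min_len:
            warnings.warn(
                f"trial [{t0:.2f}, {t1:.2f}] s shorter than 3 filter "
                f"time constants ({min_len:.2f} s); skipped")
            continue
        filt = signal.sosfiltfilt(sos, session.cursor_xy[sl], axis=0)
        vel = np.gradient(filt, 1.0 / session.fs, axis=0)
        speed[sl] = np.hypot(vel[:, 0], vel[:, 1])
    means = _epoch_means(session.time, speed, epochs)
    df = pd.DataFrame({
        "epoch_index": np.arange(len(epochs)),
        "t_start": [e[0] for e in epochs],
        "speed": means,
    })
    return MetricTrace(values=speed, epochs=df, epoch_spans=epochs)


def slowness(epoch_speeds: np.ndarray) -> np.ndarray:
    """Within-session min–max normalized inverse speed.

    slowness_i = (max − v_i) / (max − min); 0 marks the fastest epoch of the
    session and 1 the slowest. Raises on a degenerate (constant) speed vector.
    """
    v = np.asarray(epoch_speeds, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise ValueError("need at least two finite epoch speeds")
    vmax, vmin = finite.max(), finite.min()
    if vmax == vmin:
        raise ValueError("all epoch speeds are equal; slowness is undefined")
    return (vmax - v) / (vmax - vmin)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a vector onto [0, 1] by its within-session min and max."""
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or finite.max() == finite.min():
        raise ValueError("degenerate vector; min–max normalization undefined")
    return (x - finite.min()) / (finite.max() - finite.min())


def effective_motor_control(tremor_norm: np.ndarray,
                            slowness_vals: np.ndarray) -> np.ndarray:
    """emc = ((1 − tremor_norm) + (1 − slowness)) / 2, on [0, 1].

    0 indicates a fully symptomatic epoch (maximal tremor and slowness),
    1 optimal motor performance.
    """
    tn = np.asarray(tremor_norm, dtype=float)
    sl = np.asarray(slowness_vals, dtype=float)
    for name, v in (("tremor_norm", tn), ("slowness", sl)):
        vv = v[np.isfinite(v)]
        if vv.size and (vv.min() < -1e-12 or vv.max() > 1 + 1e-12):
            raise ValueError(f"{name} must lie in [0, 1]")
    return ((1.0 - tn) + (1.0 - sl)) / 2.0


def compute_epoch_metrics(session: BehaviorSession,
                          epoch_len: float = 7.0,
                          band: tuple[float, float] = (3.0, 10.0),
                          lowpass: float = 3.0) -> pd.DataFrame:
    """All four epoch metrics on a shared epoch grid.

    Returns a DataFrame with columns epoch_index, t_start, tremor (deg),
    speed (deg/s), slowness, emc, epoch_len; epochs from skipped trials are
    dropped.
    """
    epochs = epoch_grid(session, epoch_len)
    trem = tremor_amplitude(session, band=band, epochs=epochs)
    spd = movement_speed(session, lowpass=lowpass, epochs=epochs)
    df = trem.epochs.merge(spd.epochs, on=["epoch_index", "t_start"])
    df = df.dropna(subset=["tremor", "speed"]).reset_index(drop=True)
    df["slowness"] = slowness(df["speed"].to_numpy())
    df["emc"] = effective_motor_control(
        minmax_normalize(df["tremor"].to_numpy()), df["slowness"].to_numpy())
    df["epoch_len"] = epoch_len
    return df
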