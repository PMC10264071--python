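"""Neural preprocessing and 42-dimensional spectral feature construction.

Raw intracranial voltage traces (microelectrode, macroelectrode, or ECoG) are
bandpass filtered 2–600 Hz, notch filtered at 60 Hz and harmonics, and
downsampled to 1 kHz. Instantaneous power is obtained from a complex Morlet
wavelet convolution (wave number 7) at 1 Hz intervals covering 3–400 Hz and
grouped into six canonical bands — θ/α (3–12 Hz), β (12–30), γ_low (30–60),
γ_mid (60–100), γ_high (100–200), hfo (200–400) — each partitioned into 7
log-spaced sub-bands, yielding 42 features per epoch. Cross-channel coupling
uses Welch magnitude-squared coherence (Hann windows, 1024-sample segments,
512-sample hop) averaged into the same 42 bins.

The Morlet convolution is evaluated in the frequency domain: the transfer
function of a Morlet wavelet with centre frequency f and wave number w is a
Gaussian in frequency with standard deviation f/w, so each frequency row is a
single spectral multiply plus inverse FFT. The bank is normalized so that a
pure sinusoid of amplitude A yields an instantaneous amplitude envelope A
(power A**2) at its own frequency row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

#: canonical band name -> (f_low, f_high) in Hz
BANDS: dict[str, tuple[float, float]] = {
    "theta_alpha": (3.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma_low": (30.0, 60.0),
    "gamma_mid": (60.0, 100.0),
    "gamma_high": (100.0, 200.0),
    "hfo": (200.0, 400.0),
}

N_SUB_BANDS = 7
DEFAULT_FREQS = np.arange(3, 401, dtype=float)   # 1 Hz steps, 398 rows


@dataclass
class NeuralRecording:
    """One channel of neural data with its anatomical annotation."""

    signal: np.ndarray          # µV
    fs: float                   # Hz
    channel_type: str = "micro"     # micro | macro | ecog
    mni_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0)
    depth_mm: float = 0.0
    subject_id: str = "s0"
    session_id: str = "sess0"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    def to_npz(self, path) -> None:
        np.savez(path, signal=self.signal, fs=self.fs,
                 channel_type=self.channel_type, mni_xyz=np.asarray(self.mni_xyz),
                 depth_mm=self.depth_mm, subject_id=self.subject_id,
                 session_id=self.session_id)

    @classmethod
    def from_npz(cls, path) -> "NeuralRecording":
        d = np.load(path, allow_pickle=False)
        return cls(signal=d["signal"], fs=float(d["fs"]),
                   channel_type=str(d["channel_type"]),
                   mni_xyz=tuple(d["mni_xyz"]), depth_mm=float(d["depth_mm"]),
                   subject_id=str(d["subject_id"]), session_id=str(d["session_id"]))


@dataclass
class FeatureLabel:
    band: str
    sub_index: int
    f_low: float
    f_high: float


@dataclass
class FeatureMatrix:
    """Epochs x 42 spectral features with frequency labels."""

    values: np.ndarray
    labels: list[FeatureLabel]
    kind: str = "power"            # power | coherence
    epoch_spans: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("values must be epochs x n_labels")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.attrs["kind"] = self.kind
            lab = np.array([(l.band, l.sub_index, l.f_low, l.f_high)
                            for l in self.labels],
                           dtype=[("band", "S16"), ("sub_index", "i4"),
                                  ("f_low", "f8"), ("f_high", "f8")])
            f.create_dataset("labels", data=lab)
            if self.epoch_spans:
                f.create_dataset("epoch_spans", data=np.asarray(self.epoch_spans))

    @classmethod
    def from_hdf5(cls, path) -> "FeatureMatrix":
        with h5py.File(path, "r") as f:
            values = f["values"][...]
            labels = [FeatureLabel(r["band"].decode(), int(r["sub_index"]),
                                   float(r["f_low"]), float(r["f_high"]))
                      for r in f["labels"][...]]
            spans = ([tuple(s) for s in f["epoch_spans"][...]]
                     if "epoch_spans" in f else [])
            return cls(values=values, labels=labels, kind=str(f.attrs["kind"]),
                       epoch_spans=spans)

    def to_csv(self, path) -> None:
        cols = [f"{l.band}_{l.sub_index}" for l in self.labels]
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)


def feature_labels(n_sub: int = N_SUB_BANDS) -> list[FeatureLabel]:
    """The canonical 42-feature layout: 7 log-spaced sub-bands per band."""
    out = []
    for band, (lo, hi) in BANDS.items():
        edges = np.geomspace(lo, hi, n_sub + 1)
        for k in range(n_sub):
            out.append(FeatureLabel(band, k, float(edges[k]), float(edges[k + 1])))
    return out


def _sub_band_assignment(freqs: np.ndarray,
                         labels: list[FeatureLabel]) -> list[np.ndarray]:
    """Indices of the 1 Hz frequency rows belonging to each feature column."""
    groups = []
    top = max(l.f_high for l in labels)
    for lab in labels:
        hi_closed = lab.f_high >= top        # include the global upper edge
        sel = (freqs >= lab.f_low) & (
            (freqs <= lab.f_high) if hi_closed else (freqs < lab.f_high))
        groups.append(np.nonzero(sel)[0])
    return groups


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw: NeuralRecording,
               strip_channels: list[NeuralRecording] | None = None,
               target_fs: float = 1000.0) -> NeuralRecording:
    """Standard conditioning chain down to 1 kHz.

    ECoG channels may pass the other channels of their subdural strip in
    ``strip_channels`` (including or excluding ``raw`` itself; ``raw`` is
    always part of the reference set), in which case the per-sample median
    across the strip is subtracted before filtering. All signals are then
    bandpass filtered 2–600 Hz (zero-phase Butterworth), notch filtered at
    60 Hz and harmonics up to 540 Hz, and resampled to ``target_fs`` with a
    polyphase anti-aliasing filter.
    """
    fs = raw.fs
    if fs < 1200:
        raise ValueError("raw sampling rate must be >= 1200 Hz to honor the "
                         "600 Hz band edge")
    x = raw.signal.astype(float)
    if strip_channels:
        stack = [x] + [c.signal for c in strip_channels
                       if c.signal is not raw.signal]
        x = x - np.median(np.vstack(stack), axis=0)
    sos = signal.butter(4, [2.0, 600.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    for f0 in np.arange(60.0, 541.0, 60.0):
        if f0 >= fs / 2:
            break
        b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
        x = signal.filtfilt(b, a, x)
    up, down = (np.array([target_fs, fs]) /
                math.gcd(int(round(target_fs)), int(round(fs)))).astype(int)
    x = signal.resample_poly(x, up, down)
    return NeuralRecording(signal=x, fs=target_fs,
                           channel_type=raw.channel_type, mni_xyz=raw.mni_xyz,
                           depth_mm=raw.depth_mm, subject_id=raw.subject_id,
                           session_id=raw.session_id)


# ---------------------------------------------------------------------------
# Morlet wavelet power
# ---------------------------------------------------------------------------

def _check_wavelet_args(n: int, fs: float, freqs: np.ndarray, w: float) -> None:
    if w < 5:
        warnings.warn("wave number < 5 gives a poor time-frequency tradeoff")
    # support of the slowest wavelet: +/- 4.5 temporal s.d., sigma_t = w/(2 pi f)
    support = int(np.ceil(9.0 * w * fs / (2 * np.pi * freqs.min())))
    if n < support:
        raise ValueError(
            f"series of {n} samples shorter than the {freqs.min():.0f} Hz "
            f"wavelet support ({support} samples)")


def _wavelet_transfer(freq_axis: np.ndarray, f0: float, w: float) -> np.ndarray:
    """One-sided Gaussian transfer function of a Morlet wavelet.

    Peak fixed at 2 so that a real sinusoid of amplitude A (whose one-sided
    spectral line has height A/2) maps to an analytic envelope of amplitude A.
    """
    sigma_f = f0 / w
    return 2.0 * np.exp(-0.5 * ((freq_axis - f0) / sigma_f) ** 2)


def _wavelet_rows(x: np.ndarray, fs: float, freqs: np.ndarray, w: float,
                  chunk: int = 32):
    """Yield (row_indices, power rows) chunks of the time-frequency plane."""
    n = len(x)
    support = int(np.ceil(9.0 * w * fs / (2 * np.pi * freqs.min())))
    nfft = sp_fft.next_fast_len(n + support)
    X = sp_fft.fft(x.astype(np.complex64), nfft)
    freq_axis = (sp_fft.fftfreq(nfft, d=1.0 / fs)).astype(np.float32)
    for start in range(0, len(freqs), chunk):
        sel = np.arange(start, min(start + chunk, len(freqs)))
        G = np.empty((len(sel), nfft), dtype=np.float32)
        for j, fi in enumerate(freqs[sel]):
            g = _wavelet_transfer(freq_axis, float(fi), w)
            g[freq_axis < 0] = 0.0           # analytic: positive freqs only
            G[j] = g
        Y = sp_fft.ifft(X[None, :] * G, axis=1)[:, :n]
        yield sel, (Y.real ** 2 + Y.imag ** 2).astype(np.float64)


def wavelet_power(x: np.ndarray, fs: float = 1000.0,
                  freqs: np.ndarray | None = None,
                  w: float = 7.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous power on a (frequency x time) grid.

    Returns ``(freqs, power)`` where ``power[i, t]`` is the squared analytic
    amplitude of the signal filtered by a Morlet wavelet of centre frequency
    ``freqs[i]`` and wave number ``w``.
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    _check_wavelet_args(len(x), fs, freqs, w)
    power = np.empty((len(freqs), len(x)))
    for sel, rows in _wavelet_rows(x, fs, freqs, w):
        power[sel] = rows
    return freqs, power


def _epoch_sample_ranges(n: int, fs: float, epochs, t0: float = 0.0):
    """(i0, i1) sample ranges per epoch; epochs past the data are flagged."""
    ranges, kept = [], []
    for k, (e0, e1) in enumerate(epochs):
        i0 = int(round((e0 - t0) * fs))
        i1 = int(round((e1 - t0) * fs))
        if i0 < 0 or i1 > n:
            warnings.warn(f"epoch {k} extends past the data; dropped")
            continue
        ranges.append((i0, i1))
        kept.append(k)
    return ranges, kept


def wavelet_epoch_power(x: np.ndarray, fs: float,
                        epochs: list[tuple[float, float]],
                        freqs: np.ndarray | None = None,
                        w: float = 7.0, t0: float = 0.0
                        ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-epoch mean wavelet power, without storing the full plane.

    Fast path: each Morlet row is band-limited to the Gaussian window around
    its centre frequency, so the analytic signal is recovered exactly on a
    decimated time grid by inverse-transforming only that spectral window at
    a power-of-two length P (time-domain subsampling with stride nfft/P).
    Epoch means are taken over the decimated grid, which satisfies Nyquist
    for every row's envelope. Returns (freqs, power[n_freq, n_epochs], kept).
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    _check_wavelet_args(len(x), fs, freqs, w)
    n = len(x)
    ranges, kept = _epoch_sample_ranges(n, fs, epochs, t0)
    support = int(np.ceil(9.0 * w * fs / (2 * np.pi * freqs.min())))
    nfft = 1 << int(np.ceil(np.log2(n + support)))
    X = sp_fft.fft(x.astype(np.complex64), nfft)
    df = fs / nfft
    out = np.empty((len(freqs), len(ranges)))
    half = nfft // 2
    for i, f0 in enumerate(freqs):
        sigma_f = f0 / w
        k0 = max(0, int(np.floor((f0 - 4.0 * sigma_f) / df)))
        k1 = min(half, int(np.ceil((f0 + 4.0 * sigma_f) / df)) + 1)
        m = k1 - k0
        P = 1 << int(np.ceil(np.log2(max(m, 16384))))
        D = nfft // P
        g = _wavelet_transfer((k0 + np.arange(m)) * df, float(f0), w
                              ).astype(np.float32)
        Yw = X[k0:k1] * g
        z = np.zeros(P, dtype=np.complex64)
        pos = k0 % P
        head = min(m, P - pos)
        z[pos:pos + head] += Yw[:head]
        if head < m:
            z[:m - head] += Yw[head:]
        env = sp_fft.ifft(z)
        power = (env.real ** 2 + env.imag ** 2) / (D * D)
        for e, (i0, i1) in enumerate(ranges):
            j0 = -(-i0 // D)           # ceil division
            j1 = max(j0 + 1, -(-i1 // D))
            out[i, e] = power[j0:j1].mean()
    return freqs, out, kept


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def band_features(power: np.ndarray, fs: float,
                  epochs: list[tuple[float, float]],
                  freqs: np.ndarray | None = None,
                  log: bool = True, t0: float = 0.0) -> FeatureMatrix:
    """Group a (frequency x time) power plane into the 42-feature matrix.

    Each feature is the mean power over the sub-band's 1 Hz rows and the
    epoch's samples, log10-transformed by default.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    ranges, kept = _epoch_sample_ranges(power.shape[1], fs, epochs, t0)
    labels = feature_labels()
    groups = _sub_band_assignment(freqs, labels)
    vals = np.empty((len(ranges), len(labels)))
    for e, (i0, i1) in enumerate(ranges):
        row_means = power[:, i0:i1].mean(axis=1)
        for c, idx in enumerate(groups):
            vals[e, c] = row_means[idx].mean()
    if log:
        vals = np.log10(np.maximum(vals, 1e-300))
    return FeatureMatrix(values=vals, labels=labels,
                         kind="power", epoch_spans=[epochs[k] for k in kept])


def power_features(rec: NeuralRecording,
                   epochs: list[tuple[float, float]],
                   w: float = 7.0, log: bool = True,
                   t0: float = 0.0) -> FeatureMatrix:
    """42-dimensional power features straight from a 1 kHz recording.

    Memory-light path: the Morlet plane is averaged into epochs on the fly.
    """
    freqs, ep_power, kept = wavelet_epoch_power(
        rec.signal, rec.fs, epochs, w=w, t0=t0)
    labels = feature_labels()
    groups = _sub_band_assignment(freqs, labels)
    vals = np.empty((ep_power.shape[1], len(labels)))
    for c, idx in enumerate(groups):
        vals[:, c] = ep_power[idx].mean(axis=0)
    if log:
        vals = np.log10(np.maximum(vals, 1e-300))
    return FeatureMatrix(values=vals, labels=labels, kind="power",
                         epoch_spans=[epochs[k] for k in kept])


def coherence_features(x: np.ndarray, y: np.ndarray, fs: float,
                       epochs: list[tuple[float, float]],
                       nperseg: int = 1024, noverlap: int = 512,
                       t0: float = 0.0) -> FeatureMatrix:
    """Per-epoch Welch magnitude-squared coherence in the 42 feature bins.

    Hann windows, 1024-sample segments with a 512-sample hop; epochs shorter
    than two segments are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    labels = feature_labels()
    hop = nperseg - noverlap
    vals, spans = [], []
    for k, (e0, e1) in enumerate(epochs):
        i0 = int(round((e0 - t0) * fs))
        i1 = int(round((e1 - t0) * fs))
        if i0 < 0 or i1 > len(x) or (i1 - i0) < nperseg + hop:
            warnings.warn(f"epoch {k} too short for two segments; dropped")
            continue
        f, cxy = signal.coherence(x[i0:i1], y[i0:i1], fs=fs, window="hann",
                                  nperseg=nperseg, noverlap=noverlap)
        groups = _sub_band_assignment(f, labels)
        row = []
        for lab, idx in zip(labels, groups):
            if idx.size == 0:
                # sub-band narrower than the Welch grid: use the nearest bin
                idx = np.array([np.argmin(np.abs(
                    f - 0.5 * (lab.f_low + lab.f_high)))])
            row.append(cxy[idx].mean())
        vals.append(row)
        spans.append((e0, e1))
    return FeatureMatrix(values=np.asarray(vals, dtype=float), labels=labels,
                         kind="coherence", epoch_spans=spans)
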