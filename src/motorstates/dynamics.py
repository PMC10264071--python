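"""Timescales of motor-metric fluctuation and sustained symptomatic episodes.

Metrics binned at 100 ms are characterized by their autocorrelogram and its
full-width half-maximum (FWHM); the FWHM sets the minimum duration for a
supra-threshold run of bins to count as a sustained symptomatic episode.
Episode-duration distributions are summarized by a location-fixed gamma
maximum-likelihood fit and their empirical median.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def metric_autocorrelogram(series: np.ndarray, max_lag: float,
                           bin_s: float = 0.1
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Biased autocorrelation of a binned metric, normalized to 1 at lag 0.

    Returns ``(lags_s, acf)`` for lags 0..max_lag. The series must be at
    least 10x max_lag long; a constant series has no autocorrelation.
    """
    x = np.asarray(series, dtype=float)
    max_lag_bins = int(round(max_lag / bin_s))
    if len(x) < 10 * max_lag_bins:
        raise ValueError("series must be >= 10 x max_lag bins long")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("constant series has zero variance")
    full = np.correlate(x, x, mode="full")[len(x) - 1:]
    acf = full[:max_lag_bins + 1] / denom
    lags = np.arange(max_lag_bins + 1) * bin_s
    return lags, acf


def fwhm(acf: np.ndarray, bin_s: float = 0.1) -> float:
    """Full width at half maximum of a normalized autocorrelogram, seconds.

    The half-width is the positive lag where the acf crosses 0.5 (linear
    interpolation between bins); the full width is twice that, by symmetry
    of the autocorrelation.
    """
    acf = np.asarray(acf, dtype=float)
    if not np.isclose(acf[0], 1.0, atol=1e-6):
        raise ValueError("acf must be normalized to 1 at lag 0")
    below = np.nonzero(acf < 0.5)[0]
    if below.size == 0:
        raise ValueError("acf never falls below 0.5 within the window; "
                         "increase max_lag")
    k = int(below[0])
    # crossing between bins k-1 and k
    frac = (acf[k - 1] - 0.5) / (acf[k - 1] - acf[k])
    return 2.0 * (k - 1 + frac) * bin_s


def symptomatic_episodes(series: np.ndarray, threshold: float,
                         min_dur: float, bin_s: float = 0.1,
                         metric: str = "metric"
                         ) -> tuple[pd.DataFrame, float]:
    """Maximal runs of strictly supra-threshold bins lasting >= min_dur.

    The threshold is supplied by the caller (for tremor/slowness the 95th
    percentile of pooled control data; for effective motor control the
    session median). Ties at the threshold count as sub-threshold. Returns
    the episode table and the median episode duration (NaN if none).
    """
    if min_dur < bin_s:
        raise ValueError("min_dur must be at least one bin")
    x = np.asarray(series, dtype=float)
    above = x > threshold
    # run-length encode
    padded = np.concatenate([[False], above, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    rows = []
    for s, e in zip(starts, ends):
        dur = (e - s) * bin_s
        if dur >= min_dur - 1e-12:
            rows.append({"metric": metric, "start_s": s * bin_s,
                         "end_s": e * bin_s, "duration_s": dur})
    table = pd.DataFrame(rows, columns=["metric", "start_s", "end_s",
                                        "duration_s"])
    med = float(table["duration_s"].median()) if len(table) else float("nan")
    return table, med


def fit_episode_gamma(durations: np.ndarray, loc: float = 0.0
                      ) -> tuple[float, float, float]:
    """Location-fixed gamma MLE of episode durations.

    Returns (shape, scale, empirical median). With fewer than 10 durations
    only the empirical median is reliable (shape/scale are NaN, with a
    warning); an all-equal sample is a degenerate fit (NaN, warning).
    """
    d = np.asarray(durations, dtype=float)
    med = float(np.median(d)) if d.size else float("nan")
    if d.size < 10:
        warnings.warn("fewer than 10 durations; returning empirical median only")
        return float("nan"), float("nan"), med
    if np.allclose(d, d[0]):
        warnings.warn("all durations equal; gamma fit is degenerate")
        return float("nan"), float("nan"), med
    shape, _, scale = stats.gamma.fit(d, floc=loc)
    return float(shape), float(scale), med
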