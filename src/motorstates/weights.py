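"""Contiguity-sensitive permutation tests on decoder weight spectra.

To ask which spectral features a decoder uses consistently across recordings,
each recording's 42-feature weight vector is smoothed with a 3-feature moving
average and compared, feature by feature, between two conditions — empirical
vs. metric-shuffled models, or two metrics' models — with a paired t-test
across recordings. The null distribution of the per-feature T statistic is
built by randomly swapping each recording's condition pair (equivalently,
sign-flipping its paired difference) over many iterations; empirical
two-sided p-values are Benjamini-Hochberg corrected and runs of at least
three contiguous surviving features are reported as signed clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests


@dataclass
class Cluster:
    start: int          # inclusive feature index
    end: int            # inclusive
    sign: int           # +1 if condition A > condition B over the run

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class WeightTestResult:
    mean_diff: np.ndarray       # per-feature mean smoothed difference (A - B)
    t: np.ndarray               # per-feature empirical paired T
    p: np.ndarray               # per-feature empirical two-sided p, in (0, 1]
    p_adj: np.ndarray           # BH-adjusted p
    significant: np.ndarray     # BH rejection mask
    clusters: list[Cluster]
    n_iterations: int


def smooth_weights(w: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average along the ordered feature axis.

    Window must be odd; at the edges the window truncates to the available
    neighbors. Works on vectors or (recordings x features) matrices.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[-1]
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError("window exceeds the feature count")
    kernel = np.ones(window)
    num = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), -1, w)
    den = np.convolve(np.ones(n), kernel, mode="same")
    return num / den


def _paired_t(D: np.ndarray) -> np.ndarray:
    """One-sample t of paired differences, per feature (columns)."""
    n = D.shape[0]
    m = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _find_clusters(mask: np.ndarray, mean_diff: np.ndarray,
                   min_contig: int) -> list[Cluster]:
    clusters = []
    padded = np.concatenate([[False], mask, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    for s, e in zip(starts, ends):
        if e - s >= min_contig:
            sign = 1 if mean_diff[s:e].mean() > 0 else -1
            clusters.append(Cluster(start=int(s), end=int(e - 1), sign=sign))
    return clusters


def contiguity_permutation_test(W_a: np.ndarray, W_b: np.ndarray,
                                n_iter: int = 10000, q: float = 0.05,
                                min_contig: int = 3, window: int = 3,
                                seed: int = 0) -> WeightTestResult:
    """Paired, sign-flip permutation test over the ordered feature axis.

    ``W_a`` and ``W_b`` are matched (recordings x features) weight matrices
    (e.g. empirical vs. metric-shuffled models). Both are smoothed, the
    per-feature paired T is computed, and its null is built by flipping each
    recording's (a, b) assignment with probability 1/2 per iteration.
    Empirical two-sided p-values use the add-one rule, BH correction is
    applied at level ``q``, and runs of >= ``min_contig`` surviving features
    are reported with the sign of the mean difference.
    """
    W_a = np.asarray(W_a, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    if W_a.shape != W_b.shape:
        raise ValueError("weight matrices must have matching shapes")
    n_rec = W_a.shape[0]
    if n_rec < 5:
        raise ValueError("need at least 5 recordings for a paired test")
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    D = smooth_weights(W_a, window) - smooth_weights(W_b, window)
    t_emp = _paired_t(D)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, n_rec))
    # sign-flipped paired t, vectorized: per-feature sum of squares is
    # invariant under sign flips, only the mean moves
    M = signs @ D / n_rec                        # (n_iter, n_features)
    ss = (D ** 2).sum(axis=0)                    # (n_features,)
    var = (ss - n_rec * M ** 2) / (n_rec - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = M / np.sqrt(var / n_rec)
    t_null = np.nan_to_num(t_null)
    p = ((np.abs(t_null) >= np.abs(t_emp)).sum(axis=0) + 1.0) / (n_iter + 1.0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    clusters = _find_clusters(reject, D.mean(axis=0), min_contig)
    return WeightTestResult(mean_diff=D.mean(axis=0), t=t_emp, p=p,
                            p_adj=p_adj, significant=reject,
                            clusters=clusters, n_iterations=n_iter)


def compare_metric_models(W_metric_a: np.ndarray, W_metric_b: np.ndarray,
                          n_iter: int = 10000, q: float = 0.05,
                          min_contig: int = 3, window: int = 3,
                          seed: int = 0) -> WeightTestResult:
    """Feature-wise contrast of two metrics' decoder weights.

    Identical machinery to :func:`contiguity_permutation_test`, with the two
    metrics' weight matrices in place of empirical vs. shuffled.
    """
    return contiguity_permutation_test(W_metric_a, W_metric_b, n_iter=n_iter,
                                       q=q, min_contig=min_contig,
                                       window=window, seed=seed)
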