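"""Linear support-vector regression decoding of behavioral metrics.

A linear ε-insensitive SVR maps the 42 spectral features of each 7 s epoch
to the co-occurring behavioral metric: y = W·x + intercept. Models are fit
with Monte-Carlo cross-validation (default 100 random 2:1 train/test splits
of epochs); features and the target are z-scored on each training set,
out-of-fold predictions are pooled per epoch by averaging across folds, and
performance is the squared Pearson correlation (r²) between pooled
predictions and the observed metric. Chance level is estimated by refitting
with the train-set metric/feature correspondence shuffled. A frozen model
applied to a different metric reports a signed r² (sign of r times r²) so
that anti-correlated transfer is negative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVR

from .spectral import FeatureMatrix


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


@dataclass
class DecodeModel:
    """Mean standardized-scale SVR weights plus the standardization state."""

    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    y_mean: float
    y_sd: float
    trained_metric: str = ""
    svr_C: float = 1.0
    svr_epsilon: float = 0.1

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError("feature layout mismatch")
        Z = (X - self.feature_means) / self.feature_sds
        return (Z @ self.weights + self.intercept) * self.y_sd + self.y_mean

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_means": self.feature_means.tolist(),
                "feature_sds": self.feature_sds.tolist(),
                "y_mean": self.y_mean, "y_sd": self.y_sd,
                "trained_metric": self.trained_metric,
                "svr_C": self.svr_C, "svr_epsilon": self.svr_epsilon,
            }, f)


@dataclass
class DecodeResult:
    r2: float
    signed_r2: float
    predictions: np.ndarray        # pooled out-of-fold predictions per epoch
    n_folds: int
    seed: int
    per_depth_r2: list[tuple[float, float]] = field(default_factory=list)


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    good = np.isfinite(a) & np.isfinite(b)
    if good.sum() < 3 or np.std(a[good]) == 0 or np.std(b[good]) == 0:
        return 0.0
    return float(stats.pearsonr(a[good], b[good])[0])


def _standardize(train: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    bad = sd <= 0
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} zero-variance feature column(s); "
                      "sd floored at machine epsilon")
        sd = np.where(bad, np.finfo(float).eps, sd)
    return mu, sd


def _fit_svr(Z: np.ndarray, yz: np.ndarray, C: float, epsilon: float):
    svr = LinearSVR(C=C, epsilon=epsilon, loss="epsilon_insensitive",
                    max_iter=10000, tol=1e-5, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svr.fit(Z, yz)
    return svr


def train_decoder(X, y: np.ndarray, n_folds: int = 100,
                  test_frac: float = 1.0 / 3.0, seed: int = 0,
                  C: float = 1.0, epsilon: float = 0.1,
                  metric: str = "", shuffle_train_y: bool = False,
                  blocked: bool = False
                  ) -> tuple[DecodeModel, DecodeResult]:
    """Monte-Carlo cross-validated linear SVR decoder.

    Each fold draws a random 2:1 train/test split of epochs (``blocked=True``
    instead holds out a contiguous block, for leakage-sensitivity checks),
    z-scores features and target on the training set, fits the SVR and
    predicts the held-out epochs. Pooled per-epoch out-of-fold predictions
    give one r²; the returned weights are the per-fold mean on the
    standardized scale. ``shuffle_train_y`` permutes the training-set metric
    within each fold (the chance model).
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Xm.shape[0] != n:
        raise ValueError("X and y must have matching epoch counts")
    if n < 15:
        raise ValueError("need at least 15 epochs")
    if not np.all(np.isfinite(y)) or np.std(y) == 0:
        raise ValueError("y must be finite with nonzero variance")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(n * test_frac)))
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    w_sum = np.zeros(Xm.shape[1])
    b_sum = 0.0
    mu_all, sd_all = _standardize(Xm)
    y_mu_all, y_sd_all = float(y.mean()), float(y.std())
    for _ in range(n_folds):
        if blocked:
            start = rng.integers(0, n - n_test + 1)
            test_idx = np.arange(start, start + n_test)
            train_idx = np.setdiff1d(np.arange(n), test_idx)
        else:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
        mu, sd = _standardize(Xm[train_idx])
        y_tr = y[train_idx]
        if shuffle_train_y:
            y_tr = rng.permutation(y_tr)
        y_mu, y_sd = float(y_tr.mean()), float(y_tr.std())
        if y_sd == 0:
            continue
        svr = _fit_svr((Xm[train_idx] - mu) / sd, (y_tr - y_mu) / y_sd,
                       C, epsilon)
        z_test = (Xm[test_idx] - mu) / sd
        pred = svr.predict(z_test) * y_sd + y_mu
        pred_sum[test_idx] += pred
        pred_cnt[test_idx] += 1
        w_sum += svr.coef_
        b_sum += float(np.ravel(svr.intercept_)[0])
    pooled = np.full(n, np.nan)
    seen = pred_cnt > 0
    pooled[seen] = pred_sum[seen] / pred_cnt[seen]
    r = _pearson_r(pooled, y)
    model = DecodeModel(
        weights=w_sum / n_folds, intercept=b_sum / n_folds,
        feature_means=mu_all, feature_sds=sd_all,
        y_mean=y_mu_all, y_sd=y_sd_all, trained_metric=metric,
        svr_C=C, svr_epsilon=epsilon)
    result = DecodeResult(r2=r * r, signed_r2=np.sign(r) * r * r,
                          predictions=pooled, n_folds=n_folds, seed=seed)
    return model, result


@dataclass
class NullDistribution:
    r2: np.ndarray            # (n_models,)
    weights: np.ndarray       # (n_models, n_features) standardized-scale


def shuffled_null(X, y: np.ndarray, n_models: int = 100,
                  n_folds: int = 100, seed: int = 0, C: float = 1.0,
                  epsilon: float = 0.1) -> NullDistribution:
    """Chance-level r² distribution from train-set metric shuffling."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    r2s, ws = [], []
    for m in range(n_models):
        mdl, res = train_decoder(X, y, n_folds=n_folds, seed=seed * 100003 + m,
                                 C=C, epsilon=epsilon, shuffle_train_y=True)
        r2s.append(res.r2)
        ws.append(mdl.weights)
    return NullDistribution(r2=np.asarray(r2s), weights=np.asarray(ws))


def cross_metric_apply(model: DecodeModel, X, other_y: np.ndarray) -> float:
    """Signed r² of a frozen model's predictions against a different metric.

    sign(r)·r², so that transfer onto an anti-correlated metric comes out
    negative rather than spuriously positive.
    """
    pred = model.predict(X)
    r = _pearson_r(pred, np.asarray(other_y, dtype=float))
    return float(np.sign(r) * r * r)


def whole_trajectory_model(depth_recordings: list[tuple[float, object, np.ndarray]],
                           seed: int = 0, C: float = 1.0,
                           epsilon: float = 0.1, metric: str = ""
                           ) -> tuple[DecodeModel, DecodeResult]:
    """One SVR over pooled multi-depth recordings, with per-depth r².

    Each depth's epochs are split 2:1 (train:test); a single model is fit on
    the union of the training portions, the overall r² is evaluated on the
    union of the test portions, and a per-depth r² is the squared Pearson
    correlation of the whole-trajectory model's predictions against the
    observed metric within that depth's epochs. Depths with fewer than three
    epochs are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    usable = []
    for depth, X, y in depth_recordings:
        y = np.asarray(y, dtype=float)
        if len(y) < 3:
            warnings.warn(f"depth {depth} has fewer than 3 epochs; excluded")
            continue
        usable.append((depth, _as_matrix(X), y))
    if len(usable) < 2:
        raise ValueError("need at least two usable depths")
    Xtr, ytr, Xte, yte = [], [], [], []
    for depth, X, y in usable:
        perm = rng.permutation(len(y))
        n_test = max(1, len(y) // 3)
        Xte.append(X[perm[:n_test]])
        yte.append(y[perm[:n_test]])
        Xtr.append(X[perm[n_test:]])
        ytr.append(y[perm[n_test:]])
    Xtr, ytr = np.vstack(Xtr), np.concatenate(ytr)
    Xte, yte = np.vstack(Xte), np.concatenate(yte)
    mu, sd = _standardize(Xtr)
    y_mu, y_sd = float(ytr.mean()), float(ytr.std())
    if y_sd == 0:
        raise ValueError("pooled training metric has zero variance")
    svr = _fit_svr((Xtr - mu) / sd, (ytr - y_mu) / y_sd, C, epsilon)
    model = DecodeModel(weights=svr.coef_, intercept=float(np.ravel(svr.intercept_)[0]),
                        feature_means=mu, feature_sds=sd,
                        y_mean=y_mu, y_sd=y_sd, trained_metric=metric,
                        svr_C=C, svr_epsilon=epsilon)
    r = _pearson_r(model.predict(Xte), yte)
    per_depth = []
    for depth, X, y in usable:
        rd = _pearson_r(model.predict(X), y)
        per_depth.append((float(depth), rd * rd))
    result = DecodeResult(r2=r * r, signed_r2=np.sign(r) * r * r,
                          predictions=model.predict(Xte), n_folds=1,
                          seed=seed, per_depth_r2=per_depth)
    return model, result
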