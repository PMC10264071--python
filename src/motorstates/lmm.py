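"""Random-intercepts mixed models and multiple-testing correction.

Population contrasts and decoding-performance comparisons are repeated
measurements within subjects, so fixed effects are estimated with a
random-intercepts linear mixed model, y = Xβ + Zu + ε, one random intercept
per subject (REML by default). Inference is Wald: Z = β/se against the
normal distribution. Families of p-values are corrected with the
Benjamini-Hochberg step-up procedure (q = 0.05 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class LMMResult:
    beta: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series                 # two-sided normal p
    random_intercept_var: float
    residual_var: float
    converged: bool

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({
                "beta": self.beta.to_dict(), "se": self.se.to_dict(),
                "z": self.z.to_dict(), "p": self.p.to_dict(),
                "random_intercept_var": self.random_intercept_var,
                "residual_var": self.residual_var,
                "converged": self.converged,
            }, f)


def _design_matrix(X) -> pd.DataFrame:
    """Numeric design with intercept; categorical labels are dummy-coded."""
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[:, None]
        if X.dtype.kind in "OUS":        # categorical labels
            df = pd.get_dummies(pd.DataFrame(X, columns=[f"x{i}" for i in
                                                         range(X.shape[1])]),
                                drop_first=True, dtype=float)
        else:
            df = pd.DataFrame(np.asarray(X, dtype=float),
                              columns=[f"x{i}" for i in range(X.shape[1])])
    df.insert(0, "const", 1.0)
    return df


def _check_rank(exog: pd.DataFrame) -> None:
    mat = exog.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the columns whose removal restores full column rank
        bad = []
        for j, col in enumerate(exog.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(str(col))
        raise ValueError(f"singular design matrix; collinear columns: {bad}")


def fit_random_intercepts(y: np.ndarray, X, groups: np.ndarray,
                          reml: bool = True) -> LMMResult:
    """REML (or ML) fit of y = Xβ + Zu + ε with per-group random intercepts.

    ``X`` may be a numeric vector/matrix, a DataFrame, or an array of
    categorical labels (dummy-coded against the first level). Fixed-effect
    p-values come from the normal approximation to β/se.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    exog = _design_matrix(X)
    _check_rank(exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        fit = None
        for method in (None, "lbfgs", "powell"):
            try:
                fit = model.fit(reml=reml) if method is None else \
                    model.fit(reml=reml, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:
            raise np.linalg.LinAlgError(
                "mixed-model optimization failed for all optimizers")
    k = exog.shape[1]
    beta = fit.fe_params[:k]
    se = fit.bse[:k]
    z = beta / se
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=z.index)
    return LMMResult(beta=beta, se=se, z=z, p=p,
                     random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
                     residual_var=float(fit.scale),
                     converged=bool(fit.converged))


def bh_correct(p: np.ndarray, q: float = 0.05
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q: (adjusted p, rejection mask)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
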