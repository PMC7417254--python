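"""Model-selection arithmetic and group comparisons.

The core of the package's inferential machinery: Akaike information
criterion (AIC), its small-sample correction (AICc), AIC differences
(:math:`\\Delta_i`) and Akaike weights (:math:`w_i`), plus the group
comparisons used around them (one-way ANOVA, Kruskal-Wallis, binomial
GLMs for binary birth/conception outcomes).

Given candidate models with maximized log-likelihood :math:`\\hat\\ell`
and :math:`k` estimated parameters fitted to :math:`n` observations,

.. math::

    \\mathrm{AIC} = 2k - 2\\hat\\ell, \\qquad
    \\mathrm{AICc} = \\mathrm{AIC} + \\frac{2k(k+1)}{n-k-1},

    \\Delta_i = \\mathrm{AICc}_i - \\min_j \\mathrm{AICc}_j, \\qquad
    w_i = \\frac{e^{-\\Delta_i/2}}{\\sum_j e^{-\\Delta_j/2}}.

Weights are computed with log-sum-exp stabilisation so that very poor
models (large :math:`\\Delta_i`) cannot underflow the normalising sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "ModelFit",
    "ModelSelectionTable",
    "aic",
    "aicc",
    "akaike_table",
    "one_way_anova",
    "kruskal_wallis",
    "fit_binary_glm",
]


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, ``2k - 2*loglik``."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    if k < 1:
        raise ValueError("parameter count k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def aicc(aic_value: float, k: int, n: int) -> float:
    """Small-sample corrected AIC.

    Parameters
    ----------
    aic_value : plain AIC of the model.
    k : number of estimated parameters.
    n : effective sample size; must exceed ``k + 1`` for the correction
        denominator to be positive.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return aic_value + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelFit:
    """A fitted candidate model, the unit of model selection.

    Either ``loglik`` or a precomputed ``aic`` may be supplied; ``n`` is
    the effective sample size used for the AICc correction.
    """

    name: str
    k: int
    n: int
    loglik: float | None = None
    aic: float | None = None
    separated: bool = False

    def __post_init__(self) -> None:
        if (self.loglik is None) == (self.aic is None):
            raise ValueError("supply exactly one of loglik or aic")
        if self.n <= self.k + 1:
            raise ValueError("n must exceed k+1 for AICc")

    @property
    def aic_(self) -> float:
        return self.aic if self.aic is not None else aic(self.loglik, self.k)

    @property
    def aicc_(self) -> float:
        return aicc(self.aic_, self.k, self.n)


@dataclass
class ModelSelectionTable:
    """Rows of {name, k, AIC, AICc, delta, weight}, in input order."""

    table: pd.DataFrame = field(repr=False)

    @property
    def best(self) -> str:
        return str(self.table.loc[self.table["delta"].idxmin(), "model"])

    def weight(self, name: str) -> float:
        row = self.table[self.table["model"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["weight"].iloc[0])

    def to_csv(self, path, decimals: int | None = None) -> None:
        out = self.table
        if decimals is not None:
            out = out.copy()
            for col in ("AIC", "AICc", "delta", "weight"):
                out[col] = out[col].round(decimals)
        out.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


def akaike_table(
    fits: Sequence[ModelFit] | None = None,
    *,
    aicc_values: Sequence[float] | None = None,
    names: Sequence[str] | None = None,
) -> ModelSelectionTable:
    """Build the AICc / delta / Akaike-weight comparison table.

    Accepts either fitted models or a bare sequence of AICc values (as
    when re-deriving weights from a published table). All supplied rows
    form one candidate set: weights are normalised across every row.
    """
    if (fits is None) == (aicc_values is None):
        raise ValueError("supply exactly one of fits or aicc_values")
    if fits is not None:
        if len(fits) == 0:
            raise ValueError("need at least one candidate model")
        names = [f.name for f in fits]
        ks = [f.k for f in fits]
        aics = np.array([f.aic_ for f in fits], dtype=float)
        aiccs = np.array([f.aicc_ for f in fits], dtype=float)
    else:
        aiccs = np.asarray(aicc_values, dtype=float)
        if aiccs.size == 0:
            raise ValueError("need at least one candidate model")
        if names is None:
            names = [f"model_{i}" for i in range(aiccs.size)]
        ks = [np.nan] * aiccs.size
        aics = np.full(aiccs.size, np.nan)
    if not np.all(np.isfinite(aiccs)):
        raise ValueError("non-finite AICc among candidates")

    delta = aiccs - aiccs.min()
    # weights via log-sum-exp: w_i = exp(-d_i/2 - logsumexp(-d/2))
    logw = -delta / 2.0 - logsumexp(-delta / 2.0)
    weight = np.exp(logw)
    df = pd.DataFrame(
        {
            "model": list(names),
            "k": ks,
            "AIC": aics,
            "AICc": aiccs,
            "delta": delta,
            "weight": weight,
        }
    )
    return ModelSelectionTable(df)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA.

    Returns ``(F, df_between, df_within, p)``. With zero within-group
    variance and equal means the F ratio is 0/0; that case is flagged by
    returning ``F = nan, p = nan``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(a.size for a in arrays)
    df1 = len(arrays) - 1
    df2 = n_total - len(arrays)
    if df2 < 1:
        raise ValueError("need at least one within-group degree of freedom")
    grand = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            warnings.warn("zero variance everywhere: F undefined", RuntimeWarning)
            return float("nan"), df1, df2, float("nan")
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction.

    Returns ``(H, df, p)`` with ``df = n_groups - 1``; p from the
    chi-square approximation. All-identical data give ``H = 0, p = 1``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), df, float(p)


# ---------------------------------------------------------------------------
# binomial GLM (logit link) for 0/1 birth / conception outcomes
# ---------------------------------------------------------------------------

_SEPARATION_COEF = 15.0  # |beta| beyond this on a 0/1 design implies separation


def fit_binary_glm(
    y: Sequence[int],
    X: np.ndarray,
    name: str = "glm",
    *,
    ridge_alpha: float = 1e-3,
) -> ModelFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``X`` is the full design matrix (include the intercept column
    yourself); ``k`` is its column count. Complete or quasi-complete
    separation is detected from runaway coefficients and handled by an
    L2-penalised refit, flagged on the returned :class:`ModelFit`.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X row counts differ")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n, k = X.shape
    if n <= k:
        raise ValueError("need n > k observations")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
            params = res.params
        except Exception:  # non-convergence on separated data
            params = None
    if params is None or not np.all(np.isfinite(params)) or np.any(
        np.abs(params) > _SEPARATION_COEF
    ):
        separated = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(alpha=ridge_alpha, L1_wt=0.0)
            params = res.params
    loglik = float(model.loglike(np.asarray(params)))
    return ModelFit(name=name, k=k, n=n, loglik=loglik, separated=separated)
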