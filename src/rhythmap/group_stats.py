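"""Group-level behavioral models: OLS with hierarchical effect sizes,
Pearson correlations with Fisher-z confidence intervals, and Fisher's exact
test on 2x2 counts.

Hierarchical effect size for a predictor block is Cohen's
f2 = (R2_full - R2_reduced) / (1 - R2_full), computed from nested OLS fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelFit",
    "EffectSize",
    "ols_fit",
    "effect_sizes",
    "cohens_f2",
    "pearson",
    "fisher_exact",
]


@dataclass
class ModelFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (95%)
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    exog_names: tuple

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "SE": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": self.conf_int.iloc[:, 0],
                "ci_high": self.conf_int.iloc[:, 1],
            }
        )


@dataclass
class EffectSize:
    delta_r2: float
    cohens_f2: float


def ols_fit(X, y, names: list[str] | None = None, add_intercept: bool = True) -> ModelFit:
    """Ordinary least squares with classical (homoskedastic) inference.

    Raises on rank deficiency, naming the offending columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("names length != number of predictors")
    exog = pd.DataFrame(X, columns=list(names))
    if add_intercept:
        exog = sm.add_constant(exog)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        # locate collinear columns from the QR diagonal
        _, Rq = np.linalg.qr(exog.to_numpy())
        bad = [exog.columns[i] for i in np.where(np.abs(np.diag(Rq)) < 1e-10)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if exog.shape[0] <= exog.shape[1]:
        raise ValueError("need more observations than predictors")
    res = sm.OLS(y, exog).fit()
    return ModelFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=res.conf_int(alpha=0.05),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        exog_names=tuple(exog.columns),
    )


def effect_sizes(fit_full: ModelFit, fit_reduced: ModelFit) -> EffectSize:
    """Hierarchical delta-R2 and Cohen's f2 for the block dropped from full.

    f2 = delta_R2 / (1 - R2_full). The reduced model's predictors must be a
    subset of the full model's.
    """
    if not set(fit_reduced.exog_names) <= set(fit_full.exog_names):
        raise ValueError("reduced model is not nested in the full model")
    delta = fit_full.r_squared - fit_reduced.r_squared
    denom = 1.0 - fit_full.r_squared
    if denom <= 0:
        raise ValueError("full model R2 is 1; f2 undefined")
    return EffectSize(delta_r2=float(delta), cohens_f2=float(max(delta, 0.0) / denom))


def cohens_f2(delta_r2: float, r2_full: float) -> float:
    """Cohen's f2 directly from a delta-R2 and the full-model R2."""
    if not 0 <= r2_full < 1:
        raise ValueError("R2_full must be in [0, 1)")
    return float(delta_r2 / (1.0 - r2_full))


def pearson(x, y) -> tuple[float, float, tuple[float, float]]:
    """Pearson r with two-sided p and 95% CI via the Fisher z transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def fisher_exact(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns (odds ratio ad/bc, two-sided p by the sum-of-smaller-probability
    rule). The odds ratio is inf when bc = 0 with ad > 0.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if table.shape != (2, 2) or (table < 0).any() or not np.allclose(table, table.round()):
            raise ValueError("table must be 2x2 nonnegative integers")
        table = table.astype(int)
    res = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return float(odds), float(res.pvalue)
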