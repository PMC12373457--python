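"""Single-case inference against a small normative sample (Crawford-Howell t).

The Crawford-Howell test treats a single case's score x* as a draw from the
normative population and tests its atypicality with

    t = (x* - mean) / (sd * sqrt((n + 1) / n)),   df = n - 1,

which keeps the type-I error calibrated even for normative samples of a few
dozen controls, unlike the naive z-score. Impairment is a one-tailed call on
the lower tail (deficit direction: below the normative mean) at a
conservative alpha of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "NormativeSample",
    "CaseResult",
    "normative_stats",
    "ch_test",
    "classify_cohort",
    "CrawfordHowellClassifier",
]

DEFAULT_ALPHA = 0.02


@dataclass
class NormativeSample:
    mean: float
    sd: float
    n: int
    excluded_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("normative sample needs n >= 2")
        if not self.sd > 0:
            raise ValueError("normative sd must be positive")


@dataclass
class CaseResult:
    case_score: float
    t_statistic: float
    df: int
    p_one_tailed: float
    impaired: bool
    alpha: float


def normative_stats(
    scores: Sequence[float],
    exclude_ids: Sequence = (),
    ids: Sequence | None = None,
) -> NormativeSample:
    """Normative mean/sd/n after dropping explicitly listed control ids.

    Exclusion is by id only (e.g. the one control flagged on inspection);
    no automatic outlier removal is performed.
    """
    scores = np.asarray(scores, dtype=float)
    exclude = set(exclude_ids)
    if exclude:
        if ids is None:
            raise ValueError("exclude_ids given but no ids supplied")
        if len(ids) != scores.size:
            raise ValueError("ids and scores lengths differ")
        keep = np.array([i not in exclude for i in ids])
        scores = scores[keep]
    if scores.size < 2:
        raise ValueError("fewer than 2 normative scores after exclusion")
    sd = float(np.std(scores, ddof=1))
    if sd == 0.0:
        raise ValueError("normative scores are constant (sd = 0)")
    return NormativeSample(
        mean=float(np.mean(scores)), sd=sd, n=int(scores.size),
        excluded_ids=tuple(exclude_ids),
    )


def ch_test(
    case_score: float, norm: NormativeSample, alpha: float = DEFAULT_ALPHA
) -> CaseResult:
    """Crawford-Howell t test of one case against the normative sample.

    One-tailed p from the lower tail of t with df = n - 1; the case is flagged
    impaired when p < alpha and the score lies below the normative mean.
    """
    t = (case_score - norm.mean) / (norm.sd * np.sqrt((norm.n + 1) / norm.n))
    df = norm.n - 1
    p = float(stats.t.cdf(t, df))
    return CaseResult(
        case_score=float(case_score),
        t_statistic=float(t),
        df=df,
        p_one_tailed=p,
        impaired=bool(p < alpha and case_score < norm.mean),
        alpha=alpha,
    )


def classify_cohort(
    case_scores: Sequence[float],
    norm: NormativeSample,
    alpha: float = DEFAULT_ALPHA,
    ids: Sequence | None = None,
) -> pd.DataFrame:
    """Crawford-Howell classification of every case; returns a tidy table."""
    case_scores = np.asarray(case_scores, dtype=float)
    if ids is None:
        ids = list(range(len(case_scores)))
    rows = []
    for cid, score in zip(ids, case_scores):
        r = ch_test(score, norm, alpha=alpha)
        rows.append(
            dict(
                case=cid, score=r.case_score, t=r.t_statistic, df=r.df,
                p_one_tailed=r.p_one_tailed, impaired=r.impaired, alpha=alpha,
            )
        )
    return pd.DataFrame(
        rows, columns=["case", "score", "t", "df", "p_one_tailed", "impaired", "alpha"]
    )


class CrawfordHowellClassifier(BaseEstimator):
    """Impairment classifier built on the Crawford-Howell single-case t test.

    fit(X) ingests the normative (control) scores; predict(X) flags each case
    as impaired (True) when its one-tailed p falls below ``alpha`` and the
    score is below the normative mean.

    Parameters
    ----------
    alpha : float
        One-tailed significance cutoff (default 0.02, the conservative value
        recommended for small normative samples).
    exclude_ids : sequence
        Normative ids dropped before computing mean/sd; requires ``ids=`` in fit.

    Attributes
    ----------
    norm_ : NormativeSample
    mean_, sd_, n_ : float, float, int
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, exclude_ids: tuple = ()):
        self.alpha = alpha
        self.exclude_ids = exclude_ids

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("scores must be a 1-d array or a single-column matrix")
        return X

    def fit(self, X, y=None, ids: Sequence | None = None) -> "CrawfordHowellClassifier":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        scores = self._as_1d(X)
        self.norm_ = normative_stats(scores, exclude_ids=self.exclude_ids, ids=ids)
        self.mean_, self.sd_, self.n_ = self.norm_.mean, self.norm_.sd, self.norm_.n
        return self

    def decision_function(self, X) -> np.ndarray:
        """Crawford-Howell t statistic per case (negative = below the norm)."""
        self._check_fitted()
        cases = self._as_1d(X)
        return (cases - self.mean_) / (self.sd_ * np.sqrt((self.n_ + 1) / self.n_))

    def predict_p(self, X) -> np.ndarray:
        """One-tailed (lower) p value per case."""
        return stats.t.cdf(self.decision_function(X), self.n_ - 1)

    def predict(self, X) -> np.ndarray:
        cases = self._as_1d(X)
        p = self.predict_p(cases)
        return (p < self.alpha) & (cases < self.mean_)

    def classification_table(self, X, ids: Sequence | None = None) -> pd.DataFrame:
        self._check_fitted()
        return classify_cohort(self._as_1d(X), self.norm_, alpha=self.alpha, ids=ids)

    def _check_fitted(self) -> None:
        if not hasattr(self, "norm_"):
            raise ValueError("classifier is not fitted; call fit(normative_scores) first")
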