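"""Bayesian correlation screening and supine-vs-standing paired tests.

The screening statistic regresses X on Y,

    X = alpha + beta * Y + eps,

and reports cor(X, Y) = beta_hat * sd(Y) / sd(X).  Under a flat prior the
posterior of beta is a Student-t centered at the least-squares slope with
the usual standard error and n - 2 degrees of freedom, so the point
estimate of cor equals Pearson's r and everything is available in closed
form — no sampler, deterministic results.  Significance is gated on the
maximum probability of effect (MPE), the larger of P(beta > 0 | data) and
P(beta < 0 | data); a pair is reported when MPE > 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cardioresp.types import ParameterTable

__all__ = [
    "BayesCorrResult",
    "BayesianCorrelation",
    "bayes_correlation",
    "CorrelationMatrixResult",
    "correlation_matrix",
    "PositionTestResult",
    "position_tests",
]

MPE_THRESHOLD = 0.9


@dataclass
class BayesCorrResult:
    """Posterior summary of one screened pair."""

    x_name: str
    y_name: str
    beta_hat: float
    cor: float
    mpe: float
    n: int
    significant: bool

    def summary(self) -> str:
        flag = "*" if self.significant else " "
        return (
            f"cor({self.x_name}, {self.y_name}) = {self.cor:+.3f}  "
            f"beta = {self.beta_hat:+.4g}  MPE = {self.mpe:.3f} {flag} (n={self.n})"
        )


class BayesianCorrelation:
    """Model object for the screening regression of one pair.

    Parameters
    ----------
    x, y : array-like
        Equal-length numeric vectors (n >= 10) with positive variance.
    names : (str, str)
        Labels used in the result and summary.
    """

    def __init__(self, x, y, names=("x", "y"), mpe_threshold: float = MPE_THRESHOLD):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D vectors")
        if len(x) < 10:
            raise ValueError("at least 10 paired observations required")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in input")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero variance in input vector")
        self.x, self.y = x, y
        self.names = tuple(names)
        self.mpe_threshold = mpe_threshold

    def fit(self) -> BayesCorrResult:
        x, y = self.x, self.y
        n = len(x)
        yc = y - y.mean()
        xc = x - x.mean()
        syy = float(yc @ yc)
        beta = float(yc @ xc) / syy
        resid = xc - beta * yc
        df = n - 2
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 / syy)
        # flat prior: beta | data ~ t_df(beta_hat, se); MPE is the mass on
        # the dominant sign
        if se == 0:
            mpe = 1.0
        else:
            mpe = float(stats.t.cdf(abs(beta) / se, df))
        sd_ratio = float(np.std(y, ddof=1) / np.std(x, ddof=1))
        cor = beta * sd_ratio
        return BayesCorrResult(
            x_name=self.names[0],
            y_name=self.names[1],
            beta_hat=beta,
            cor=cor,
            mpe=mpe,
            n=n,
            significant=mpe > self.mpe_threshold,
        )


def bayes_correlation(x, y, names=("x", "y"), mpe_threshold: float = MPE_THRESHOLD) -> BayesCorrResult:
    """Convenience wrapper: fit :class:`BayesianCorrelation` in one call."""
    return BayesianCorrelation(x, y, names=names, mpe_threshold=mpe_threshold).fit()


@dataclass
class CorrelationMatrixResult:
    """All-pairs screening over one parameter table."""

    columns: list
    results: dict          # frozenset({a, b}) -> BayesCorrResult
    masked_reasons: dict   # frozenset({a, b}) -> str (degenerate cells)
    mpe_threshold: float

    def to_frame(self, masked: bool = True) -> pd.DataFrame:
        """Symmetric correlation frame; non-significant cells NaN when masked."""
        k = len(self.columns)
        mat = np.full((k, k), np.nan)
        for i, a in enumerate(self.columns):
            for j, b in enumerate(self.columns):
                if i == j:
                    continue
                res = self.results.get(frozenset((a, b)))
                if res is None:
                    continue
                if masked and not res.significant:
                    continue
                # cor is symmetric in the pair (reduces to Pearson's r)
                mat[i, j] = res.cor
        return pd.DataFrame(mat, index=self.columns, columns=self.columns)

    def significant_pairs(self) -> list:
        return [r for r in self.results.values() if r.significant]


def correlation_matrix(
    table: ParameterTable, mpe_threshold: float = MPE_THRESHOLD
) -> CorrelationMatrixResult:
    """Screen every unordered column pair of a parameter table.

    Cells whose inputs are degenerate (zero variance) are masked with a
    reason instead of failing the whole matrix.
    """
    if table.n_subjects < 10:
        raise ValueError("at least 10 subjects required for screening")
    cols = table.columns
    results, masked = {}, {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            key = frozenset((a, b))
            try:
                results[key] = bayes_correlation(
                    table[a], table[b], names=(a, b), mpe_threshold=mpe_threshold
                )
            except ValueError as err:
                masked[key] = str(err)
    return CorrelationMatrixResult(
        columns=cols, results=results, masked_reasons=masked,
        mpe_threshold=mpe_threshold,
    )


@dataclass
class PositionTestResult:
    parameter: str
    test_used: str       # "paired-t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    normality_p: float
    n: int

    def summary(self) -> str:
        return (
            f"{self.parameter:>8s}: {self.test_used:<9s} stat={self.statistic:+.3f} "
            f"p={self.p_value:.4g} (Shapiro p={self.normality_p:.3g}, n={self.n})"
        )


def position_tests(
    supine: ParameterTable, standing: ParameterTable, alpha: float = 0.05
) -> list[PositionTestResult]:
    """Paired supine-vs-standing comparison per parameter.

    Subjects are inner-joined on id.  The paired differences are checked
    for normality with Shapiro-Wilk; a paired t-test is used when the
    differences look normal (p > alpha), a Wilcoxon signed-rank test
    otherwise.  All-zero differences are degenerate and reported with p = 1.
    """
    common = [s for s in supine.subject_ids if s in set(standing.subject_ids)]
    if len(common) < 3:
        raise ValueError("fewer than 3 paired subjects")
    shared = [c for c in supine.columns if c in standing.columns]
    out = []
    for param in shared:
        a = supine.data.loc[common, param].to_numpy()
        b = standing.data.loc[common, param].to_numpy()
        d = b - a
        if np.allclose(d, 0):
            out.append(PositionTestResult(param, "degenerate", 0.0, 1.0, 1.0, len(d)))
            continue
        sw_p = float(stats.shapiro(d).pvalue)
        if sw_p > alpha:
            res = stats.ttest_rel(b, a)
            out.append(PositionTestResult(
                param, "paired-t", float(res.statistic), float(res.pvalue), sw_p, len(d)
            ))
        else:
            res = stats.wilcoxon(b, a)
            out.append(PositionTestResult(
                param, "wilcoxon", float(res.statistic), float(res.pvalue), sw_p, len(d)
            ))
    return out
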