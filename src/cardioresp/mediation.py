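"""Exploratory mediation analysis with Sobel tests.

For a candidate path X -> M -> Y two ordinary least-squares fits

    M = i1 + a * X
    Y = i2 + c' * X + b * M

give the indirect effect a*b, whose first-order (delta-method) standard
error yields the Sobel statistic

    z = a*b / sqrt(b^2 * se_a^2 + a^2 * se_b^2),
    p = 2 * (1 - Phi(|z|)).

A configuration flag adds the second-order se_a^2 * se_b^2 term to the
variance.  Two-sided p-values are reported throughout; the test is known
to be conservative for small indirect effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from cardioresp.types import ParameterTable

__all__ = [
    "MediationResult",
    "Mediation",
    "mediate",
    "sobel_test",
    "mediate_standard_paths",
    "STANDARD_PATHS",
]

#: The five exploratory paths evaluated in the batch report:
#: (X, M, Y, position).
STANDARD_PATHS = (
    ("RMSSD", "HR", "cInsT", "supine"),
    ("HR", "cInsT", "cExpT", "supine"),
    ("HR", "cInsT", "cInsV", "supine"),
    ("cInsT", "ciRR", "HR", "standing"),
    ("cInsV", "ciRR", "HR", "standing"),
)


def sobel_test(
    a: float, se_a: float, b: float, se_b: float, second_order: bool = False
) -> tuple[float, float]:
    """(z, two-sided p) for the indirect effect a*b.

    A zero indirect effect gives z = 0 and p = 1 exactly, also when the
    delta-method variance degenerates to zero.
    """
    indirect = a * b
    var = b * b * se_a * se_a + a * a * se_b * se_b
    if second_order:
        var += se_a * se_a * se_b * se_b
    if indirect == 0:
        return 0.0, 1.0
    if var <= 0:
        return float(np.sign(indirect) * np.inf), 0.0
    z = indirect / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class MediationResult:
    x_name: str
    m_name: str
    y_name: str
    position: str | None
    a: float
    se_a: float
    b: float
    se_b: float
    c_prime: float
    indirect: float
    sobel_z: float
    sobel_p: float
    n: int

    def summary(self) -> str:
        pos = f" [{self.position}]" if self.position else ""
        return (
            f"{self.x_name} -> {self.m_name} -> {self.y_name}{pos}: "
            f"a={self.a:+.4g} (se {self.se_a:.3g}), b={self.b:+.4g} "
            f"(se {self.se_b:.3g}), c'={self.c_prime:+.4g}, "
            f"indirect={self.indirect:+.4g}, Sobel z={self.sobel_z:+.3f}, "
            f"p={self.sobel_p:.4g} (n={self.n})"
        )


def _ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and standard errors of an OLS fit (design incl. intercept)."""
    import statsmodels.api as sm

    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design in mediation regression")
    fit = sm.OLS(y, design).fit()
    return np.asarray(fit.params), np.asarray(fit.bse)


class Mediation:
    """Model object for one X -> M -> Y path on a parameter table."""

    def __init__(
        self,
        table: ParameterTable,
        x: str,
        m: str,
        y: str,
        second_order: bool = False,
    ):
        for col in (x, m, y):
            if col not in table.columns:
                raise ValueError(f"missing column {col!r}")
        if len({x, m, y}) != 3:
            raise ValueError("x, m, y must be three distinct columns")
        if table.n_subjects < 10:
            raise ValueError("at least 10 subjects required")
        xv, mv = table[x], table[m]
        r_xm = float(np.corrcoef(xv, mv)[0, 1])
        if abs(r_xm) > 0.999:
            raise ValueError("X and M are collinear (|r| > 0.999)")
        self.table = table
        self.names = (x, m, y)
        self.second_order = second_order

    def fit(self) -> MediationResult:
        x, m, y = self.names
        xv, mv, yv = self.table[x], self.table[m], self.table[y]
        n = len(xv)
        one = np.ones(n)
        coef_m, se_m = _ols(mv, np.column_stack([one, xv]))
        coef_y, se_y = _ols(yv, np.column_stack([one, xv, mv]))
        a, se_a = float(coef_m[1]), float(se_m[1])
        c_prime = float(coef_y[1])
        b, se_b = float(coef_y[2]), float(se_y[2])
        z, p = sobel_test(a, se_a, b, se_b, self.second_order)
        return MediationResult(
            x_name=x, m_name=m, y_name=y, position=self.table.position,
            a=a, se_a=se_a, b=b, se_b=se_b, c_prime=c_prime,
            indirect=a * b, sobel_z=z, sobel_p=p, n=n,
        )


def mediate(
    table: ParameterTable, x: str, m: str, y: str, second_order: bool = False
) -> MediationResult:
    """Convenience wrapper: fit :class:`Mediation` in one call."""
    return Mediation(table, x, m, y, second_order=second_order).fit()


def mediate_standard_paths(
    supine: ParameterTable,
    standing: ParameterTable,
    paths=STANDARD_PATHS,
    second_order: bool = False,
) -> list[MediationResult]:
    """Evaluate the batch of exploratory paths on the two position tables."""
    tables = {"supine": supine, "standing": standing}
    out = []
    for x, m, y, position in paths:
        table = tables[position]
        if table.position is None:
            table = ParameterTable(table.data, position=position)
        out.append(mediate(table, x, m, y, second_order=second_order))
    return out
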