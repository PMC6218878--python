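"""Generalized correlations and the pairwise direction rule.

The generalized measure of correlation (GMC) of Y given X is the fraction
of var(Y) explained by the nonparametric regression E(Y | X):

    GMC(Y | X) = 1 - E[(Y - E(Y|X))^2] / var(Y),

estimated with Nadaraya-Watson kernel regression (Gaussian kernel,
Silverman's rule-of-thumb bandwidth).  The signed square root

    r*_{y|x} = sign(r_xy) * sqrt(GMC(Y | X))

is asymmetric: when X drives Y through a nonlinear mechanism with additive
noise, X typically explains Y better than the reverse, so
|r*_{y|x}| > |r*_{x|y}| points to X as the likelier cause.  The asymmetry
is accepted only when a paired bootstrap of the |r*| difference is
significant; otherwise the pair is left undecided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardioresp.association import bayes_correlation
from cardioresp.types import CausalGraph, ParameterTable

__all__ = ["GeneralizedCorrPair", "generalized_correlation", "gc_graph"]


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = 0.9 * spread * n ** (-0.2)
    if not np.isfinite(bw) or bw <= 0:
        raise ValueError("degenerate bandwidth (constant predictor)")
    return bw


def _nw_conditional_mean(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray) -> np.ndarray:
    bw = _silverman_bandwidth(x)
    # single precision for the n x n kernel matrix: the GMC is a ratio of
    # second moments, far above float32 resolution
    xs = (x / bw).astype(np.float32)
    es = (x_eval / bw).astype(np.float32)
    z = es[:, None] - xs[None, :]
    w = np.exp(-0.5 * z * z)
    denom = w.sum(axis=1)
    denom[denom == 0] = 1.0
    return (w @ y.astype(np.float32)).astype(float) / denom.astype(float)


def _gmc(x: np.ndarray, y: np.ndarray) -> float:
    yhat = _nw_conditional_mean(x, y, x)
    var = float(np.var(y))
    if var == 0:
        raise ValueError("zero variance in response")
    gmc = 1.0 - float(np.mean((y - yhat) ** 2)) / var
    return float(np.clip(gmc, 0.0, 1.0))


@dataclass
class GeneralizedCorrPair:
    x_name: str
    y_name: str
    r_xy: float
    gmc_y_given_x: float
    gmc_x_given_y: float
    rstar_y_given_x: float
    rstar_x_given_y: float
    direction: str      # "x_causes_y" | "y_causes_x" | "undecided"
    p_value: float

    def summary(self) -> str:
        return (
            f"{self.x_name} vs {self.y_name}: r={self.r_xy:+.3f} "
            f"|r*_y|x|={abs(self.rstar_y_given_x):.3f} "
            f"|r*_x|y|={abs(self.rstar_x_given_y):.3f} "
            f"-> {self.direction} (p={self.p_value:.3g})"
        )


def generalized_correlation(
    x,
    y,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
    names: tuple = ("x", "y"),
) -> GeneralizedCorrPair:
    """Both-direction generalized correlations with a bootstrap asymmetry test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 30:
        raise ValueError("at least 30 observations required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")

    r_xy = float(np.corrcoef(x, y)[0, 1])
    sgn = np.sign(r_xy) if r_xy != 0 else 1.0
    gmc_yx = _gmc(x, y)
    gmc_xy = _gmc(y, x)
    rstar_yx = sgn * np.sqrt(gmc_yx)
    rstar_xy = sgn * np.sqrt(gmc_xy)

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            deltas[b] = 0.0
            continue
        deltas[b] = np.sqrt(_gmc(xb, yb)) - np.sqrt(_gmc(yb, xb))
    p_hi = float(np.mean(deltas <= 0))
    p_lo = float(np.mean(deltas >= 0))
    p_value = min(2.0 * min(p_hi, p_lo), 1.0)

    if p_value < alpha and abs(rstar_yx) > abs(rstar_xy):
        direction = "x_causes_y"
    elif p_value < alpha and abs(rstar_xy) > abs(rstar_yx):
        direction = "y_causes_x"
    else:
        direction = "undecided"

    return GeneralizedCorrPair(
        x_name=names[0], y_name=names[1], r_xy=r_xy,
        gmc_y_given_x=gmc_yx, gmc_x_given_y=gmc_xy,
        rstar_y_given_x=float(rstar_yx), rstar_x_given_y=float(rstar_xy),
        direction=direction, p_value=p_value,
    )


def gc_graph(
    table: ParameterTable,
    mask=None,
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
    screen_mpe: bool = True,
    mpe_threshold: float = 0.9,
) -> CausalGraph:
    """Pairwise generalized-correlation graph over a parameter table.

    Each unmasked pair that passes the Bayesian-correlation MPE screen
    (optional but on by default, mirroring the analysis flow that only
    treats meaningfully correlated pairs as causal candidates) contributes
    one directed edge when its direction is decided.  Being purely
    pairwise, the result may contain cycles.
    """
    mask = {frozenset(p) for p in (mask or ())}
    cols = table.columns
    edges = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if frozenset((a, b)) in mask:
                continue
            try:
                if screen_mpe:
                    screen = bayes_correlation(table[a], table[b], names=(a, b))
                    if screen.mpe <= mpe_threshold:
                        continue
                pair = generalized_correlation(
                    table[a], table[b], alpha=alpha, n_boot=n_boot,
                    seed=seed, names=(a, b),
                )
            except ValueError:
                continue
            if pair.direction == "x_causes_y":
                edges.append((a, b, "directed"))
            elif pair.direction == "y_causes_x":
                edges.append((b, a, "directed"))
    return CausalGraph(nodes=tuple(cols), edges=tuple(edges), method="GC")
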