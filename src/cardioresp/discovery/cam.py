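"""Causal additive modeling (CAM-lite).

Two stages, following the causal-additive-model recipe for additive-noise
identifiability:

1. *Order/edge search* — starting from the empty graph, greedily add the
   directed edge with the largest gain in additive-model log-likelihood,
   where each node's conditional is a sum of univariate cubic-spline
   functions of its current parents, while the gain exceeds the BIC penalty
   for the added spline block and acyclicity is preserved.
2. *Pruning* — in the implied topological order, each node is refit on all
   its predecessors and only predecessors whose spline block is significant
   (F-test at ``prune_alpha``, default 0.001) are kept as parents.

Nonlinear mechanisms (e.g. sin, cubic) give the additive fit a directional
advantage; for linear-Gaussian data the direction is not identifiable and
only the skeleton is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from cardioresp.discovery.score import _as_frame
from cardioresp.types import CausalGraph

__all__ = ["cam_learn"]

_EPS = 1e-9
_VAR_FLOOR = 1e-12


def _spline_basis(x: np.ndarray, df: int = 5, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` columns, knots at quantiles."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise ValueError("constant column: spline basis undefined")
    n_interior = df - degree - 1 + 1  # df columns after dropping one for identifiability
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior > 0 else np.array([])
    pad = 1e-9 * (hi - lo)
    t = np.concatenate([
        np.repeat(lo - pad, degree + 1), interior, np.repeat(hi + pad, degree + 1)
    ])
    design = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    # drop the first column: with an explicit intercept the basis sums to 1
    return design[:, 1:]


class _AdditiveFitter:
    """Cached additive-spline regressions over a fixed data frame."""

    def __init__(self, table, df: int = 5):
        frame = _as_frame(table)
        self.columns = list(frame.columns)
        self.n = len(frame)
        self.df = df
        self._x = {c: frame[c].to_numpy(dtype=float) for c in self.columns}
        self._basis = {c: _spline_basis(self._x[c], df) for c in self.columns}
        self._cache: dict = {}

    @property
    def block_size(self) -> int:
        return self._basis[self.columns[0]].shape[1]

    def rss(self, child: str, parents) -> float:
        key = (child, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        y = self._x[child]
        ps = sorted(key[1])
        blocks = [np.ones((self.n, 1))] + [self._basis[p] for p in ps]
        design = np.hstack(blocks)
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        out = max(float(resid @ resid), _VAR_FLOOR)
        self._cache[key] = out
        return out

    def loglik(self, child: str, parents) -> float:
        sigma2 = self.rss(child, parents) / self.n
        return -0.5 * self.n * (math.log(2 * math.pi * sigma2) + 1.0)


def cam_learn(table, prune_alpha: float = 0.001, df: int = 5, mask=None) -> CausalGraph:
    """CAM-lite structure learning; returns a directed acyclic graph."""
    fitter = _AdditiveFitter(table, df=df)
    n, cols = fitter.n, fitter.columns
    if n < 50:
        raise ValueError("at least 50 rows required for additive-model search")
    block = fitter.block_size
    if n <= block + 2:
        raise ValueError("fewer rows than spline degrees of freedom")
    mask = {frozenset(p) for p in (mask or ())}
    penalty = 0.5 * block * math.log(n)

    import networkx as nx

    dag = nx.DiGraph()
    dag.add_nodes_from(cols)
    parents: dict = {c: set() for c in cols}

    while True:
        best, best_gain = None, penalty + _EPS
        for p in cols:
            for c in cols:
                if p == c or p in parents[c] or frozenset((p, c)) in mask:
                    continue
                if nx.has_path(dag, c, p):
                    continue
                if (len(parents[c]) + 1) * block + 1 >= n:
                    continue
                gain = fitter.loglik(c, parents[c] | {p}) - fitter.loglik(c, parents[c])
                if gain > best_gain + _EPS:
                    best, best_gain = (p, c), gain
        if best is None:
            break
        p, c = best
        parents[c].add(p)
        dag.add_edge(p, c)

    # implied order: topological, canonical column order breaking ties
    rank = {c: i for i, c in enumerate(cols)}
    order = list(nx.lexicographical_topological_sort(dag, key=lambda v: rank[v]))

    # pruning: refit each node on all predecessors, keep significant blocks
    kept_edges = []
    for i, node in enumerate(order):
        preds = order[:i]
        if not preds:
            continue
        max_preds = max((n - 2) // block - 1, 1)
        if len(preds) > max_preds:
            # too few rows for all predecessors: restrict to searched parents
            preds = [p for p in preds if p in parents[node]][:max_preds]
        if not preds:
            continue
        rss_full = fitter.rss(node, preds)
        df_resid = n - (1 + block * len(preds))
        if df_resid <= 0:
            preds = sorted(parents[node])
            rss_full = fitter.rss(node, preds)
            df_resid = n - (1 + block * len(preds))
        for p in preds:
            reduced = [q for q in preds if q != p]
            rss_red = fitter.rss(node, reduced)
            f_stat = ((rss_red - rss_full) / block) / (rss_full / df_resid)
            p_val = float(stats.f.sf(max(f_stat, 0.0), block, df_resid))
            if p_val < prune_alpha:
                kept_edges.append((p, node, "directed"))

    return CausalGraph(nodes=tuple(cols), edges=tuple(kept_edges), method="CAM")
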