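"""Gaussian BIC scoring for continuous Bayesian networks.

The score is decomposable: each node contributes the maximized Gaussian
log-likelihood of its linear regression on its parents minus a (k/2) ln n
penalty, with k counting the regression coefficients, the intercept and the
residual variance.  The per-node maximum-likelihood variance makes the
total score constant across Markov-equivalent DAGs, which is what lets
greedy search operate on equivalence classes.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from cardioresp.types import CausalGraph, ParameterTable

__all__ = ["BICScorer", "bic_score"]

_VAR_FLOOR = 1e-12


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, ParameterTable):
        return table.data
    return pd.DataFrame(table)


class BICScorer:
    """Cached per-node Gaussian BIC over a fixed data frame."""

    def __init__(self, table, ridge: float = 1e-8):
        df = _as_frame(table)
        self.columns = list(df.columns)
        self.n = len(df)
        self._x = {c: df[c].to_numpy(dtype=float) for c in self.columns}
        self._cache: dict = {}
        self.ridge = ridge

    def local(self, child: str, parents) -> float:
        """BIC contribution of ``child`` given ``parents`` (iterable of names)."""
        key = (child, frozenset(parents))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        y = self._x[child]
        n = self.n
        ps = sorted(key[1])
        if ps:
            design = np.column_stack([np.ones(n)] + [self._x[p] for p in ps])
            coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            if rank < design.shape[1]:
                # collinear parents: ridge fallback keeps the score finite
                warnings.warn(
                    f"collinear parents for {child}; ridge fallback", stacklevel=2
                )
                gram = design.T @ design + self.ridge * np.eye(design.shape[1])
                coef = np.linalg.solve(gram, design.T @ y)
            resid = y - design @ coef
        else:
            resid = y - y.mean()
        sigma2 = max(float(resid @ resid) / n, _VAR_FLOOR)
        ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        k = len(ps) + 2  # slopes + intercept + variance
        score = ll - 0.5 * k * math.log(n)
        self._cache[key] = score
        return score

    def total(self, parent_map: dict) -> float:
        return sum(self.local(c, parent_map.get(c, ())) for c in self.columns)


def bic_score(table, dag) -> float:
    """Total Gaussian BIC of a DAG over the table's columns (higher is better).

    ``dag`` may be a :class:`~cardioresp.types.CausalGraph` (directed edges
    only) or an iterable of ``(parent, child)`` pairs.
    """
    scorer = BICScorer(table)
    if isinstance(dag, CausalGraph):
        edges = dag.directed_edges
    else:
        edges = [(a, b) for a, b, *_ in (tuple(e) for e in dag)]
    parent_map: dict = {c: set() for c in scorer.columns}
    for p, c in edges:
        parent_map[c].add(p)
    # acyclicity check
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(scorer.columns)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("graph passed to bic_score contains a directed cycle")
    return scorer.total(parent_map)
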