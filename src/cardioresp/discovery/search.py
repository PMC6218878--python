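"""Greedy score-based DAG search: hill-climbing and tabu.

Both searches move through DAG space with single-edge add / delete /
reverse operations scored by the decomposable Gaussian BIC.  Tie-breaking
is lexicographic on (operation, node pair) in the table's canonical column
order, so results are deterministic for a fixed seed.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from cardioresp.discovery.score import BICScorer
from cardioresp.types import CausalGraph

__all__ = ["hc_learn", "tabu_learn"]

_EPS = 1e-9
_OP_ORDER = {"add": 0, "del": 1, "rev": 2}


class _DagState:
    def __init__(self, columns, mask=None):
        self.columns = list(columns)
        self.parents = {c: set() for c in self.columns}
        self.mask = {frozenset(p) for p in (mask or ())}

    def copy(self):
        new = _DagState(self.columns)
        new.parents = {c: set(p) for c, p in self.parents.items()}
        new.mask = set(self.mask)
        return new

    def has_edge(self, a, b):
        return a in self.parents[b]

    def edges(self):
        return sorted((p, c) for c, ps in self.parents.items() for p in ps)

    def _reachable(self, src, dst):
        # is there a directed path src ~> dst?
        stack, seen = [src], {src}
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            for child, ps in self.parents.items():
                if node in ps and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False

    def legal_moves(self):
        """All admissible moves in deterministic order."""
        moves = []
        for a in self.columns:
            for b in self.columns:
                if a == b or frozenset((a, b)) in self.mask:
                    continue
                if self.has_edge(a, b):
                    moves.append(("del", a, b))
                    # reverse a->b into b->a: b must not reach a otherwise
                    self.parents[b].discard(a)
                    if not self._reachable(a, b):
                        moves.append(("rev", a, b))
                    self.parents[b].add(a)
                elif not self.has_edge(b, a):
                    if not self._reachable(b, a):
                        moves.append(("add", a, b))
        moves.sort(key=lambda m: (_OP_ORDER[m[0]], m[1], m[2]))
        return moves

    def delta(self, move, scorer: BICScorer):
        op, a, b = move
        pb = frozenset(self.parents[b])
        if op == "add":
            return scorer.local(b, pb | {a}) - scorer.local(b, pb)
        if op == "del":
            return scorer.local(b, pb - {a}) - scorer.local(b, pb)
        pa = frozenset(self.parents[a])
        return (
            scorer.local(b, pb - {a}) - scorer.local(b, pb)
            + scorer.local(a, pa | {b}) - scorer.local(a, pa)
        )

    def apply(self, move):
        op, a, b = move
        if op == "add":
            self.parents[b].add(a)
        elif op == "del":
            self.parents[b].discard(a)
        else:
            self.parents[b].discard(a)
            self.parents[a].add(b)

    def score(self, scorer):
        return scorer.total({c: frozenset(p) for c, p in self.parents.items()})


def _greedy_ascent(state: _DagState, scorer: BICScorer):
    while True:
        best_move, best_delta = None, _EPS
        for move in state.legal_moves():
            d = state.delta(move, scorer)
            if d > best_delta:
                best_move, best_delta = move, d
        if best_move is None:
            return
        state.apply(best_move)


def _to_graph(state: _DagState, scorer: BICScorer, method: str) -> CausalGraph:
    edges = tuple((a, b, "directed") for a, b in state.edges())
    return CausalGraph(
        nodes=tuple(state.columns), edges=edges, method=method,
        score=state.score(scorer),
    )


def hc_learn(table, mask=None, restarts: int = 0, seed: int = 0) -> CausalGraph:
    """Hill-climbing DAG search from the empty graph.

    Greedy single-edge add/delete/reverse moves are applied while any move
    improves the Gaussian BIC.  Optional random restarts perturb the local
    optimum with random edge flips and re-ascend, keeping the best-scoring
    graph found.
    """
    scorer = BICScorer(table)
    state = _DagState(scorer.columns, mask)
    _greedy_ascent(state, scorer)
    best, best_score = state, state.score(scorer)
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        cand = best.copy()
        for _ in range(3):  # perturb with random edge flips, then re-ascend
            moves = cand.legal_moves()
            if not moves:
                break
            cand.apply(moves[int(rng.integers(0, len(moves)))])
        _greedy_ascent(cand, scorer)
        s = cand.score(scorer)
        if s > best_score + _EPS:
            best, best_score = cand, s
    return _to_graph(best, scorer, "HC")


def _inverse(move):
    op, a, b = move
    if op == "add":
        return ("del", a, b)
    if op == "del":
        return ("add", a, b)
    return ("rev", b, a)


def tabu_learn(
    table, mask=None, tabu_len: int = 10, max_iter: int = 100, seed: int = 0
) -> CausalGraph:
    """Tabu search: hill-climbing that escapes local optima.

    After the greedy ascent, up to ``max_iter`` further moves are taken:
    each iteration applies the best admissible move even when it lowers the
    score, while forbidding the inverses of the last ``tabu_len`` moves.
    The best graph seen anywhere along the trajectory is returned, so the
    result never scores below plain hill-climbing with the same tie-breaks.
    """
    scorer = BICScorer(table)
    state = _DagState(scorer.columns, mask)
    _greedy_ascent(state, scorer)
    best = state.copy()
    best_score = state.score(scorer)

    tabu: deque = deque(maxlen=max(tabu_len, 1))
    current_score = best_score
    if tabu_len > 0:
        for _ in range(max_iter):
            best_move, best_delta = None, -np.inf
            for move in state.legal_moves():
                if move in tabu:
                    continue
                d = state.delta(move, scorer)
                if d > best_delta + _EPS:
                    best_move, best_delta = move, d
            if best_move is None:
                break
            state.apply(best_move)
            tabu.append(_inverse(best_move))
            current_score += best_delta
            if current_score > best_score + _EPS:
                best, best_score = state.copy(), current_score
    return _to_graph(best, scorer, "TABU")
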