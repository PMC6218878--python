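"""Greedy equivalence search (GES) over CPDAGs with the Gaussian BIC.

The search operates directly on equivalence classes: the forward phase
repeatedly applies the best-scoring valid Insert(X, Y, T) operator until no
insertion improves the score, then the backward phase applies the best
valid Delete(X, Y, H) likewise.  After each operator the partially directed
graph is completed to a CPDAG by finding a consistent DAG extension and
re-closing it (v-structures + Meek rules), so the state is always a valid
equivalence-class representative.  Because the Gaussian BIC is score
equivalent, the result is a CPDAG whose undirected edges are exactly those
the class leaves unoriented.
"""

from __future__ import annotations

from itertools import chain, combinations

from cardioresp.discovery.score import BICScorer
from cardioresp.types import CausalGraph

__all__ = ["ges_learn", "dag_to_cpdag", "pdag_to_dag"]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# PDAG utilities (directed edge set D, undirected edge set U of frozensets)
# ---------------------------------------------------------------------------

def _adjacent(node, directed, undirected):
    out = set()
    for a, b in directed:
        if a == node:
            out.add(b)
        elif b == node:
            out.add(a)
    for e in undirected:
        if node in e:
            out |= set(e) - {node}
    return out


def _neighbors(node, undirected):
    out = set()
    for e in undirected:
        if node in e:
            out |= set(e) - {node}
    return out


def _parents(node, directed):
    return {a for a, b in directed if b == node}


def _is_clique(nodes, directed, undirected):
    nodes = list(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if b not in _adjacent(a, directed, undirected):
                return False
    return True


def _semi_directed_path_exists(src, dst, directed, undirected, blocked):
    """Path src ~> dst along undirected or src-to-dst directed edges,
    avoiding ``blocked`` nodes."""
    if src in blocked:
        return False
    stack, seen = [src], {src}
    succ = {}
    for a, b in directed:
        succ.setdefault(a, set()).add(b)
    for e in undirected:
        a, b = tuple(e)
        succ.setdefault(a, set()).add(b)
        succ.setdefault(b, set()).add(a)
    while stack:
        node = stack.pop()
        for nxt in succ.get(node, ()):
            if nxt in blocked or nxt in seen:
                continue
            if nxt == dst:
                return True
            seen.add(nxt)
            stack.append(nxt)
    return False


def pdag_to_dag(nodes, directed, undirected):
    """Consistent DAG extension of a PDAG (Dor-Tarsi); raises if none exists."""
    cur_dir = set(directed)
    cur_und = set(undirected)
    remaining = set(nodes)
    out = set(directed)
    while remaining:
        found = None
        for x in sorted(remaining):
            # x must have no outgoing directed edges in the current subgraph
            if any(a == x for a, _ in cur_dir):
                continue
            nbrs = _neighbors(x, cur_und)
            adj_x = _adjacent(x, cur_dir, cur_und)
            if all(adj_x - {y} <= _adjacent(y, cur_dir, cur_und) for y in nbrs):
                found = x
                break
        if found is None:
            raise ValueError("PDAG admits no consistent extension")
        for y in _neighbors(found, cur_und):
            out.add((y, found))
        cur_dir = {(a, b) for a, b in cur_dir if found not in (a, b)}
        cur_und = {e for e in cur_und if found not in e}
        remaining.discard(found)
    return out


def dag_to_cpdag(nodes, dag_edges):
    """CPDAG of a DAG: skeleton + v-structures, closed under Meek rules."""
    dag_edges = set(dag_edges)
    skeleton = {frozenset(e) for e in dag_edges}
    adj = {n: set() for n in nodes}
    for a, b in dag_edges:
        adj[a].add(b)
        adj[b].add(a)
    parents = {n: {a for a, b in dag_edges if b == n} for n in nodes}

    directed = set()
    for c in nodes:
        ps = sorted(parents[c])
        for i, a in enumerate(ps):
            for b in ps[i + 1:]:
                if b not in adj[a]:  # v-structure a -> c <- b
                    directed.add((a, c))
                    directed.add((b, c))
    undirected = set(skeleton)
    for a, b in directed:
        undirected.discard(frozenset((a, b)))
    _meek_closure(nodes, directed, undirected)
    return directed, undirected


def _meek_closure(nodes, directed, undirected):
    """Apply Meek rules R1-R3 until fixpoint (in place)."""
    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=lambda s: tuple(sorted(s))):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                if _meek_orient(x, y, directed, undirected):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
            if changed:
                break


def _meek_orient(x, y, directed, undirected):
    adj_y = _adjacent(y, directed, undirected)
    adj_x = _adjacent(x, directed, undirected)
    # R1: w -> x, x - y, w not adjacent y  =>  x -> y
    for w, v in directed:
        if v == x and w not in adj_y and w != y:
            return True
    # R2: x -> w -> y with x - y  =>  x -> y
    for w, v in directed:
        if w == x and (v, y) in directed:
            return True
    # R3: x - w1 -> y, x - w2 -> y, w1/w2 non-adjacent, x - y  =>  x -> y
    inc = [w for w, v in directed if v == y and frozenset((x, w)) in undirected]
    for i, w1 in enumerate(inc):
        for w2 in inc[i + 1:]:
            if w2 not in _adjacent(w1, directed, undirected):
                return True
    return False


def _subsets(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


# ---------------------------------------------------------------------------
# GES proper
# ---------------------------------------------------------------------------

class _GESState:
    def __init__(self, columns, scorer, mask=None):
        self.columns = list(columns)
        self.scorer = scorer
        self.directed: set = set()
        self.undirected: set = set()
        self.mask = {frozenset(p) for p in (mask or ())}

    def _recompute_cpdag(self):
        dag = pdag_to_dag(self.columns, self.directed, self.undirected)
        self.directed, self.undirected = dag_to_cpdag(self.columns, dag)

    # ---- forward phase -------------------------------------------------
    def best_insert(self):
        best = None  # (gain, x, y, T)
        for y in self.columns:
            adj_y = _adjacent(y, self.directed, self.undirected)
            pa_y = _parents(y, self.directed)
            nbr_y = _neighbors(y, self.undirected)
            for x in self.columns:
                if x == y or x in adj_y or frozenset((x, y)) in self.mask:
                    continue
                na = {n for n in nbr_y
                      if n in _adjacent(x, self.directed, self.undirected)}
                t0 = {n for n in nbr_y
                      if n not in _adjacent(x, self.directed, self.undirected)}
                for T in _subsets(t0):
                    cond = na | set(T)
                    if not _is_clique(cond, self.directed, self.undirected):
                        continue
                    if _semi_directed_path_exists(
                        y, x, self.directed, self.undirected, cond
                    ):
                        continue
                    base = pa_y | cond
                    gain = (
                        self.scorer.local(y, base | {x})
                        - self.scorer.local(y, base)
                    )
                    key = (gain, x, y, tuple(sorted(T)))
                    if best is None or gain > best[0] + _EPS:
                        best = key
        return best

    def apply_insert(self, x, y, T):
        self.directed.add((x, y))
        for t in T:
            self.undirected.discard(frozenset((t, y)))
            self.directed.add((t, y))
        self._recompute_cpdag()

    # ---- backward phase ------------------------------------------------
    def best_delete(self):
        best = None  # (gain, x, y, H)
        pairs = []
        for x, y in sorted(self.directed):
            pairs.append((x, y))
        for e in sorted(self.undirected, key=lambda s: tuple(sorted(s))):
            a, b = sorted(e)
            pairs.append((a, b))
            pairs.append((b, a))
        for x, y in pairs:
            pa_y = _parents(y, self.directed)
            nbr_y = _neighbors(y, self.undirected)
            na = {n for n in nbr_y
                  if n in _adjacent(x, self.directed, self.undirected)}
            for H in _subsets(na):
                keep = na - set(H)
                if not _is_clique(keep, self.directed, self.undirected):
                    continue
                base = (pa_y | keep) - {x}
                gain = (
                    self.scorer.local(y, base)
                    - self.scorer.local(y, base | {x})
                )
                if best is None or gain > best[0] + _EPS:
                    best = (gain, x, y, tuple(sorted(H)))
        return best

    def apply_delete(self, x, y, H):
        self.directed.discard((x, y))
        self.undirected.discard(frozenset((x, y)))
        for h in H:
            if frozenset((y, h)) in self.undirected:
                self.undirected.discard(frozenset((y, h)))
                self.directed.add((y, h))
            if frozenset((x, h)) in self.undirected:
                self.undirected.discard(frozenset((x, h)))
                self.directed.add((x, h))
        self._recompute_cpdag()


def ges_learn(table, mask=None) -> CausalGraph:
    """Two-phase greedy equivalence search; returns a CPDAG.

    Undirected edges in the result are those the learned Markov equivalence
    class does not orient (e.g. a pure chain stays fully undirected while a
    collider is oriented).
    """
    scorer = BICScorer(table)
    state = _GESState(scorer.columns, scorer, mask)

    while True:
        best = state.best_insert()
        if best is None or best[0] <= _EPS:
            break
        state.apply_insert(best[1], best[2], best[3])
    while True:
        best = state.best_delete()
        if best is None or best[0] <= _EPS:
            break
        state.apply_delete(best[1], best[2], best[3])

    edges = tuple(
        [(a, b, "directed") for a, b in sorted(state.directed)]
        + [tuple(sorted(e)) + ("undirected",) for e in state.undirected]
    )
    dag = pdag_to_dag(state.columns, state.directed, state.undirected)
    parent_map: dict = {c: set() for c in state.columns}
    for a, b in dag:
        parent_map[b].add(a)
    score = scorer.total(parent_map)
    return CausalGraph(nodes=tuple(state.columns), edges=edges, method="GES", score=score)
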