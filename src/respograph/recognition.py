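"""Recognition: from an unlabeled digraph back to a game.

A digraph is the response graph of some two-player game iff

1. its underlying undirected graph is the comparability graph of an
   ``n x m`` grid — the rook's graph, the Cartesian product of two complete
   graphs — under some labeling of nodes by profiles, and
2. within every row and every column, the arc pattern is realizable by real
   payoffs, i.e. forms a total preorder (no strict arc inside a strongly
   connected component of the clique).

The labeling is recovered by clique-factorizing a vertex neighborhood: in a
rook's graph the neighbors of any vertex split into its row-mates and its
column-mates, two cliques with no cross edges.  Cross profiles are then
located as unique common neighbors, and the candidate labeling is validated
against the full edge set — which rejects impostors such as strongly regular
lookalikes of rook's graphs.  Uniqueness holds up to renaming strategies and
(for square grids) swapping the players.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .games_core import Game, Profile
from .response_graph import ResponseGraph, comparable_pairs


@dataclass
class RecognitionResult:
    success: bool
    n_rows: Optional[int] = None
    n_cols: Optional[int] = None
    labeling: Optional[dict] = None          # node -> Profile
    graph: Optional[ResponseGraph] = None    # relabeled input, on success
    reason: Optional[str] = None

    def __bool__(self):
        return self.success


def _fail(reason: str) -> RecognitionResult:
    return RecognitionResult(success=False, reason=reason)


def _as_digraph(g) -> nx.DiGraph:
    """Normalize the input: accept a (Multi)DiGraph, Graph or edge iterable."""
    if isinstance(g, nx.Graph) and not g.is_directed():
        return nx.DiGraph(g)  # undirected edges become arcs both ways
    if isinstance(g, nx.DiGraph):
        return nx.DiGraph(g)  # collapses parallel arcs of a MultiDiGraph
    d = nx.DiGraph()
    d.add_edges_from(g)
    return d


def _is_clique(u: nx.Graph, nodes) -> bool:
    nodes = list(nodes)
    return all(u.has_edge(a, b) for a, b in itertools.combinations(nodes, 2))


def _label_grid(u: nx.Graph) -> "tuple[dict, int, int] | str":
    """Find a profile labeling making ``u`` an n x m rook's graph.

    Returns (labeling, n, m) or a failure reason string.
    """
    nv = u.number_of_nodes()
    if nv == 0:
        return "empty graph"
    if not nx.is_connected(u):
        return "underlying graph is not connected; not a comparability grid"
    v0 = min(u.nodes, key=lambda v: (u.degree(v), str(v)))
    nbrs = list(u.neighbors(v0))
    comps = [list(c) for c in nx.connected_components(u.subgraph(nbrs))] \
        if nbrs else []
    if len(comps) > 2:
        return ("neighborhood of a vertex splits into more than two cliques; "
                "not a comparability grid")
    for comp in comps:
        if not _is_clique(u, comp):
            return ("neighborhood component is not a clique; "
                    "not a comparability grid")
    if len(comps) <= 1:
        # One player has a single strategy: the grid is 1 x k and the
        # comparability graph is complete.
        if u.number_of_edges() != nv * (nv - 1) // 2:
            return ("single-clique neighborhood but graph is not complete; "
                    "not a comparability grid")
        order = sorted(u.nodes, key=str)
        return {v: Profile(0, j) for j, v in enumerate(order)}, 1, nv
    a, b = sorted(comps, key=len)       # rows of v0's column, cols of its row
    n, m = len(a) + 1, len(b) + 1
    if n * m != nv:
        return (f"vertex degrees suggest a {n}x{m} grid but the graph has "
                f"{nv} nodes")
    label = {v0: Profile(0, 0)}
    a = sorted(a, key=str)
    b = sorted(b, key=str)
    for i, v in enumerate(a, start=1):
        label[v] = Profile(i, 0)
    for j, v in enumerate(b, start=1):
        label[v] = Profile(0, j)
    nbr_sets = {v: set(u.neighbors(v)) for v in u.nodes}
    for i, av in enumerate(a, start=1):
        for j, bv in enumerate(b, start=1):
            common = (nbr_sets[av] & nbr_sets[bv]) - {v0}
            if len(common) != 1:
                return ("cross profile is not a unique common neighbor; "
                        "not a comparability grid")
            w = common.pop()
            if w in label:
                return ("cross profile clashes with an already-labeled node; "
                        "not a comparability grid")
            label[w] = Profile(i, j)
    if len(label) != nv:
        return "labeling does not cover every node; not a comparability grid"
    # Global validation: the edge set must be exactly the rook's-graph edges.
    inv = {p: v for v, p in label.items()}
    expected = {frozenset((inv[p], inv[q])) for p, q in comparable_pairs(n, m)}
    actual = {frozenset((x, y)) for x, y in u.edges}
    if expected != actual:
        return ("edge set differs from the grid comparability graph "
                "(rook's-graph impostor)")
    return label, n, m


def _realizable_preorders(rg: ResponseGraph) -> Optional[str]:
    """Check each row/column clique's arcs form a total preorder.

    Payoff values induce, within each clique, a relation whose strict part is
    acyclic; a strict arc inside a strongly connected component (formed via
    ties) cannot come from real payoffs.
    """
    lines = [[Profile(r, c) for r in range(rg.n_rows)]
             for c in range(rg.n_cols)]
    lines += [[Profile(r, c) for c in range(rg.n_cols)]
              for r in range(rg.n_rows)]
    for line in lines:
        g = nx.DiGraph()
        g.add_nodes_from(line)
        strict = []
        for p, q in itertools.combinations(line, 2):
            s = rg.sign(p, q)
            if s >= 0:
                g.add_edge(p, q)
            if s <= 0:
                g.add_edge(q, p)
            if s != 0:
                strict.append((p, q) if s > 0 else (q, p))
        comp_of = {}
        for i, comp in enumerate(nx.strongly_connected_components(g)):
            for v in comp:
                comp_of[v] = i
        for src, dst in strict:
            if comp_of[src] == comp_of[dst]:
                return ("preferences within a row or column are cyclic; "
                        "no payoff assignment exists")
    return None


def recognize(g) -> RecognitionResult:
    """Decide whether ``g`` is the response graph of some two-player game.

    Accepts a networkx (di)graph or an iterable of (src, dst) edges; pairs of
    opposite arcs are read as undirected edges.  On success the result
    carries the grid dimensions, the node labeling and the relabeled
    :class:`ResponseGraph`; failure is a result with a reason, never an
    exception.  Near-linear in the number of arcs for valid inputs.
    """
    d = _as_digraph(g)
    if any(d.has_edge(v, v) for v in d.nodes):
        return _fail("self-loops cannot occur in a response graph")
    res = _label_grid(d.to_undirected())
    if isinstance(res, str):
        return _fail(res)
    label, n, m = res
    inv = {p: v for v, p in label.items()}
    signs = {}
    for p, q in comparable_pairs(n, m):
        fwd = d.has_edge(inv[p], inv[q])
        bwd = d.has_edge(inv[q], inv[p])
        signs[(p, q)] = 0 if (fwd and bwd) else (1 if fwd else -1)
    rg = ResponseGraph(n, m, signs)
    reason = _realizable_preorders(rg)
    if reason is not None:
        return _fail(reason)
    return RecognitionResult(success=True, n_rows=n, n_cols=m,
                             labeling=label, graph=rg)


def game_from_graph(g) -> Game:
    """Construct a game whose response graph is (isomorphic to) ``g``.

    Payoffs are integer layer indices: within each column, player 1's values
    follow the topological order of the tie-condensed strict preferences, and
    symmetrically per row for player 2.  Raises ``ValueError`` when
    recognition fails.
    """
    res = g if isinstance(g, RecognitionResult) else recognize(g)
    if not res.success:
        raise ValueError(f"not a response graph: {res.reason}")
    rg = res.graph
    n, m = rg.shape

    def layers(line):
        dg = nx.DiGraph()
        dg.add_nodes_from(line)
        for p, q in itertools.combinations(line, 2):
            s = rg.sign(p, q)
            if s >= 0:
                dg.add_edge(p, q)
            if s <= 0:
                dg.add_edge(q, p)
        cond = nx.condensation(dg)
        vals = {}
        for rank, node in enumerate(nx.topological_sort(cond)):
            for p in cond.nodes[node]["members"]:
                vals[p] = rank
        return vals

    u1 = np.zeros((n, m))
    u2 = np.zeros((n, m))
    for c in range(m):
        for p, v in layers([Profile(r, c) for r in range(n)]).items():
            u1[p.row, p.col] = v
    for r in range(n):
        for p, v in layers([Profile(r, c) for c in range(m)]).items():
            u2[p.row, p.col] = v
    game = Game(u1, u2)
    from .response_graph import build_response_graph

    assert build_response_graph(game) == rg
    return game


def read_edge_list(text: str) -> nx.DiGraph:
    """Parse plain ``a -> b`` lines (node names are arbitrary strings)."""
    d = nx.DiGraph()
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.startswith("dims"):
            continue
        src, _, dst = ln.partition("->")
        if not _:
            raise ValueError(f"cannot parse edge line: {ln!r}")
        dst = dst.split()[0]
        d.add_edge(src.strip(), dst.strip())
    return d
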