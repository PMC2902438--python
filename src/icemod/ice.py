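"""Iterative Clique Enumeration (ICE): relatively independent maximal cliques
as co-expression modules.

Co-expression networks contain astronomically many maximal cliques, nearly
all of them heavily overlapping.  ICE sidesteps full enumeration: it finds
the maximum clique of a *residual* graph (the input graph with all earlier
modules' nodes removed), expands that disjoint "core" to the largest maximal
clique of the original graph containing it, emits the pair as a module,
removes the expanded clique's nodes from the residual, and repeats until the
residual maximum clique drops below ``c_min``.  Cores are pairwise disjoint,
so every module contributes at least ``c_min`` genes seen in no earlier
module, while expansion still allows controlled overlap between modules.

The maximum-clique search is an exact branch-and-bound with greedy-coloring
upper bounds; ties between maximum cliques are broken toward the
lexicographically smallest sorted node-label sequence, so results are fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx

__all__ = [
    "CliqueModule",
    "ICEResult",
    "maximum_clique",
    "expand_to_largest_maximal",
    "ice_enumerate",
    "write_modules_tsv",
    "read_modules_tsv",
]


def _adjacency(g: nx.Graph) -> tuple[list, list[set[int]]]:
    """Integer-relabelled adjacency with node order sorted by label."""
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in nodes]
    for u, v in g.edges():
        if u == v:
            continue
        iu, iv = index[u], index[v]
        adj[iu].add(iv)
        adj[iv].add(iu)
    return nodes, adj


def _color_sort(vertices: Sequence[int], adj: list[set[int]]) -> tuple[list[int], list[int]]:
    """Greedy coloring in ascending vertex order.

    Returns vertices flattened by color class together with each vertex's
    color number (1-based); a vertex's color bounds the size of any clique
    inside the prefix ending at it.
    """
    classes: list[set[int]] = []
    for v in vertices:
        for cls in classes:
            if not (adj[v] & cls):
                cls.add(v)
                break
        else:
            classes.append({v})
    order: list[int] = []
    bounds: list[int] = []
    for color, cls in enumerate(classes, start=1):
        for v in sorted(cls):
            order.append(v)
            bounds.append(color)
    return order, bounds


def _clique_number(
    adj: list[set[int]], vertices: Iterable[int], stop_at: int | None = None
) -> int:
    """Exact maximum-clique size among ``vertices`` (branch and bound).

    When ``stop_at`` is given the search returns as soon as a clique of that
    size is found, which turns the function into a cheap existence test.
    """
    best = 0

    def expand(size: int, candidates: Sequence[int]) -> None:
        nonlocal best
        order, bounds = _color_sort(candidates, adj)
        for i in range(len(order) - 1, -1, -1):
            if size + bounds[i] <= best:
                return
            v = order[i]
            nxt = [u for u in order[:i] if u in adj[v]]
            if not nxt:
                if size + 1 > best:
                    best = size + 1
            else:
                expand(size + 1, nxt)
            if stop_at is not None and best >= stop_at:
                return

    verts = sorted(vertices)
    if verts:
        expand(0, verts)
    return best


def maximum_clique(g: nx.Graph) -> set:
    """An exact maximum clique of ``g`` with a deterministic tie-break.

    Among all maximum cliques, the one whose sorted node-label sequence is
    lexicographically smallest is returned.  The empty graph yields the
    empty set.
    """
    nodes, adj = _adjacency(g)
    if not nodes:
        return set()
    k = _clique_number(adj, range(len(nodes)))
    chosen: list[int] = []
    candidates = list(range(len(nodes)))
    while len(chosen) < k:
        need = k - len(chosen) - 1
        for v in candidates:
            nbrs = [u for u in candidates if u != v and u in adj[v]]
            if len(nbrs) < need:
                continue
            if need == 0 or _clique_number(adj, nbrs, stop_at=need) >= need:
                chosen.append(v)
                candidates = nbrs
                break
        else:  # pragma: no cover - k came from the same search space
            raise RuntimeError("internal error: clique reconstruction failed")
    return {nodes[i] for i in chosen}


def expand_to_largest_maximal(g: nx.Graph, core: Iterable[Hashable]) -> set:
    """Largest maximal clique of ``g`` containing the clique ``core``.

    The extension is exactly a maximum clique of the subgraph induced on the
    common neighbors of all core nodes; the same lexicographic tie-break as
    :func:`maximum_clique` applies to that extension.
    """
    core = set(core)
    if not core:
        raise ValueError("core must be nonempty")
    for v in core:
        if v not in g:
            raise ValueError(f"core node {v!r} not in graph")
        missing = core - {v} - set(g[v])
        if missing:
            raise ValueError(f"core is not a clique: {v!r} not adjacent to {missing!r}")
    common: set | None = None
    for v in core:
        nbrs = set(g[v]) - core
        common = nbrs if common is None else (common & nbrs)
    if not common:
        return core
    extension = maximum_clique(g.subgraph(common))
    return core | extension


@dataclass(frozen=True)
class CliqueModule:
    """One ICE module: disjoint residual-graph core and its expansion in the input graph."""

    index: int
    core: frozenset
    expanded: frozenset

    def __post_init__(self) -> None:
        if not self.core <= self.expanded:
            raise ValueError("core must be a subset of the expanded clique")


@dataclass
class ICEResult:
    modules: list[CliqueModule]
    c_min: int
    residual_sizes: list[int]  # residual node count at the start of each iteration

    def module_gene_sets(self) -> dict[int, frozenset]:
        return {m.index: m.expanded for m in self.modules}


def ice_enumerate(g: nx.Graph, c_min: int = 10) -> ICEResult:
    """Run ICE on ``g``: emit modules while the residual maximum clique has >= c_min nodes.

    Each iteration removes at least ``c_min`` nodes from the residual graph,
    so the loop terminates after at most |V|/c_min modules.  Output order and
    content are deterministic for a fixed input.
    """
    if c_min < 1:
        raise ValueError("c_min must be at least 1")
    residual = g.copy()
    modules: list[CliqueModule] = []
    residual_sizes: list[int] = []
    index = 0
    while residual.number_of_nodes() > 0:
        residual_sizes.append(residual.number_of_nodes())
        core = maximum_clique(residual)
        if len(core) < c_min:
            break
        expanded = expand_to_largest_maximal(g, core)
        modules.append(CliqueModule(index, frozenset(core), frozenset(expanded)))
        residual.remove_nodes_from(expanded)
        index += 1
    return ICEResult(modules=modules, c_min=c_min, residual_sizes=residual_sizes)


def write_modules_tsv(result: ICEResult, path) -> None:
    """module_id<TAB>gene<TAB>in_core rows, genes sorted within a module."""
    with open(path, "w") as fh:
        fh.write("module_id\tgene\tin_core\n")
        for mod in result.modules:
            for gene in sorted(mod.expanded):
                fh.write(f"{mod.index}\t{gene}\t{'yes' if gene in mod.core else 'no'}\n")


def read_modules_tsv(path) -> dict[str, frozenset]:
    """Read a modules TSV back as module_id -> expanded gene set."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("module_id"):
            raise ValueError("expected a module_id\tgene\tin_core header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            module_id, gene = line.split("\t")[:2]
            sets.setdefault(module_id, set()).add(gene)
    return {m: frozenset(s) for m, s in sets.items()}
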