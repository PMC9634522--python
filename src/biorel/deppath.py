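"""Shortest dependency paths between candidate entities.

The directed dependency parse of a sentence is converted to an
undirected graph (each dependency contributes one edge carrying its
type), and the minimum-hop path between the two entity head tokens is
found with Dijkstra's algorithm under unit edge weights.  Among
equal-length paths the lexicographically smallest token-index sequence
is returned, so the output is deterministic for any parse graph.

For the Bacteria-Biotope task the path is always oriented from the
microorganism entity to the location/phenotype entity, regardless of
sentence order; tasks without an orientation priority keep sentence
order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from .parses import SentenceGraph
from .standoff import Entity
from .task import ConstraintRule


class DegeneratePathError(ValueError):
    """Both path endpoints are the same token."""


@dataclass(frozen=True)
class ShortestPath:
    """An oriented shortest dependency path.

    ``token_seq`` holds the surface words from the first entity head to
    the second (length m); ``deptype_seq`` the m-1 dependency types of
    the edges along it; ``token_indices`` the sentence-local indices.
    """

    token_indices: tuple[int, ...]
    token_seq: tuple[str, ...]
    deptype_seq: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.token_seq)

    def reverse(self) -> "ShortestPath":
        return ShortestPath(
            token_indices=self.token_indices[::-1],
            token_seq=self.token_seq[::-1],
            deptype_seq=self.deptype_seq[::-1],
        )


def build_undirected_graph(sent: SentenceGraph) -> dict[int, list[tuple[int, str]]]:
    """Adjacency map: token index -> sorted list of (neighbour, edge label)."""
    adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(len(sent.tokens))}
    for h, d, lab in sent.edges:
        adj[h].append((d, lab))
        adj[d].append((h, lab))
    for i in adj:
        adj[i].sort()
    return adj


def _edge_label(adj: dict, u: int, v: int) -> str:
    # parallel edges: the sorted adjacency makes min-label deterministic
    labels = [lab for nbr, lab in adj[u] if nbr == v]
    return min(labels)


def shortest_dependency_path(
    graph: dict[int, list[tuple[int, str]]],
    e1_token: int,
    e2_token: int,
    sent: SentenceGraph,
):
    """Minimum-hop path between two tokens, or ``None`` when disconnected.

    Dijkstra with unit weights over a heap keyed by (distance, path):
    popping the target the first time yields the shortest path whose
    token-index sequence is lexicographically smallest.
    """
    if e1_token == e2_token:
        raise DegeneratePathError(f"both endpoints are token {e1_token}")
    for t in (e1_token, e2_token):
        if t not in graph:
            raise ValueError(f"token index {t} not in graph")
    heap: list[tuple[int, tuple[int, ...]]] = [(0, (e1_token,))]
    done: set[int] = set()
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == e2_token:
            words = tuple(sent.tokens[i].word for i in path)
            deps = tuple(
                _edge_label(graph, u, v) for u, v in zip(path, path[1:])
            )
            return ShortestPath(token_indices=path, token_seq=words, deptype_seq=deps)
        for nbr, _lab in graph[node]:
            if nbr not in done:
                heapq.heappush(heap, (dist + 1, path + (nbr,)))
    return None


def entity_head_token(entity: Entity) -> int:
    """Path endpoint for an entity: its last token (head-final heuristic)."""
    if entity.token_span is None:
        raise ValueError(f"entity {entity.id} has no token span")
    return entity.token_span[2]


def orient_path(
    path: ShortestPath, e1: Entity, e2: Entity, rules: ConstraintRule
) -> ShortestPath:
    """Reverse the path if the orientation-priority type sits at its end.

    ``e1``/``e2`` are in sentence order with ``path`` running e1 -> e2.
    When neither (or both) endpoint types carry priority the sentence
    order is kept.
    """
    prio = {t: i for i, t in enumerate(rules.orientation_priority)}
    r1 = prio.get(e1.etype, len(prio))
    r2 = prio.get(e2.etype, len(prio))
    if r2 < r1:
        return path.reverse()
    return path


def connected(graph: dict[int, list[tuple[int, str]]], a: int, b: int) -> bool:
    """Whether two tokens share a component (BFS; used by path filtering)."""
    if a == b:
        return True
    seen = {a}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for v, _lab in graph[u]:
                if v == b:
                    return True
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return False
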