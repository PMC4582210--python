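"""Budgeted enumeration of elementary cycles in the de Bruijn graph.

Every elementary cycle is a potential exact tandem repeat, so the search is
exhaustive in spirit but budgeted in practice: from each start vertex a
depth-first search first looks for cycles of up to ``lambda_max_long``
vertices; once ``eta`` arcs have been traversed from that start and arcs
remain unexplored, the search restarts from the same vertex with the
tighter limit ``lambda_max_short``.  Start vertices are processed in
descending short-read occurrence order and removed from the graph for
subsequent starts (Johnson-style), so each cycle is reported from its
highest-occurrence eligible vertex.

Outgoing arcs are explored in descending frequency order: arcs belonging to
a genuine tandem repeat are traversed once per copy and therefore tend to
carry the highest counts, so they are reached within the arc budget first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

from .debruijn import DeBruijnGraph

logger = logging.getLogger(__name__)

DEFAULT_MAX_CYCLES = 100_000


@dataclass(frozen=True)
class SearchBudget:
    """Exploration limits for the cycle search.

    eta
        Arc-traversal budget per start vertex at the long length limit.
    lambda_max_long
        Maximum cycle length (vertex count) in the first phase.
    lambda_max_short
        Maximum cycle length after the budget is exhausted; must not
        exceed ``lambda_max_long``.
    """

    eta: int
    lambda_max_long: int
    lambda_max_short: int

    def __post_init__(self) -> None:
        if self.lambda_max_short > self.lambda_max_long:
            raise ValueError("lambda_max_short must be <= lambda_max_long")
        if self.eta < 0 or self.lambda_max_short < 1:
            raise ValueError("budgets must be non-negative / positive")


@dataclass(frozen=True)
class CycleRecord:
    """An elementary cycle, stored starting at its search-start vertex."""

    vertices: tuple[str, ...]
    arcs: tuple[tuple[tuple[str, str], int], ...]  # ((vi, vj), raw count)
    start_vertex: str

    def __len__(self) -> int:
        return len(self.vertices)


def canonical_cycle_key(c: "CycleRecord | Iterable[str]") -> tuple[str, ...]:
    """Rotation-invariant identity of a cycle: its minimal rotation."""
    verts = tuple(c.vertices) if isinstance(c, CycleRecord) else tuple(c)
    return min(verts[i:] + verts[:i] for i in range(len(verts)))


def _make_record(g: DeBruijnGraph, path: tuple[str, ...]) -> CycleRecord:
    arcs = []
    for i, v in enumerate(path):
        w = path[(i + 1) % len(path)]
        arcs.append(((v, w), g.arcs[(v, w)]))
    return CycleRecord(vertices=path, arcs=tuple(arcs), start_vertex=path[0])


def _dfs(
    g: DeBruijnGraph,
    start: str,
    limit: int,
    eta: int | None,
    sigma: int,
    removed: set[str],
    emit: Callable[[tuple[str, ...]], None],
    succ_order: dict[str, list[str]],
) -> bool:
    """Depth-limited elementary-path DFS from ``start``.

    Emits every elementary cycle through ``start`` of at most ``limit``
    vertices whose members all have occ >= sigma.  Returns True when the
    arc budget ran out with arcs still unexplored.
    """
    arc_counter = 0
    path = [start]
    on_path = {start}
    stack = [iter(succ_order[start])] if start in succ_order else [iter(())]
    while stack:
        descended = False
        for w in stack[-1]:
            arc_counter += 1
            if eta is not None and arc_counter > eta:
                return True
            if w == start:
                emit(tuple(path))
                continue
            if w in on_path or w in removed:
                continue
            if g.vertices.get(w, 0) < sigma:
                continue
            if len(path) >= limit:
                continue
            path.append(w)
            on_path.add(w)
            stack.append(iter(succ_order.get(w, ())))
            descended = True
            break
        if not descended:
            stack.pop()
            on_path.discard(path.pop())
    return False


def find_elementary_cycles(
    g: DeBruijnGraph,
    starts: list[str],
    budget: SearchBudget,
    sigma: int,
    *,
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> list[CycleRecord]:
    """Enumerate elementary cycles reachable from the given start vertices.

    ``starts`` should already be filtered and ordered (descending occ);
    each start is removed from the graph once processed, and cycles are
    additionally deduplicated by their canonical rotation key.
    """
    # Arc order: descending frequency, ties broken by target k-mer.
    succ_order = {
        v: sorted(ws, key=lambda w: (-g.arcs[(v, w)], w))
        for v, ws in g.out_arcs.items()
    }
    removed: set[str] = set()
    found: dict[tuple[str, ...], CycleRecord] = {}
    capped = False
    switches = 0

    def emit(path: tuple[str, ...]) -> None:
        nonlocal capped
        if len(found) >= max_cycles:
            capped = True
            return
        key = canonical_cycle_key(path)
        if key not in found:
            found[key] = _make_record(g, path)

    for s in starts:
        if s in removed:
            continue
        overflow = True
        if budget.eta > 0:
            overflow = _dfs(
                g, s, budget.lambda_max_long, budget.eta, sigma, removed,
                emit, succ_order,
            )
        if overflow:
            switches += 1
            _dfs(
                g, s, budget.lambda_max_short, None, sigma, removed,
                emit, succ_order,
            )
        removed.add(s)
        if capped:
            logger.warning("cycle cap of %d reached; search truncated", max_cycles)
            break

    logger.info(
        "cycle search: %d starts, %d cycles, %d budget switches",
        len(starts), len(found), switches,
    )
    return list(found.values())
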