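"""De Bruijn graph over k-mers of the short-read set.

Vertices are k-mers with their occurrence counts in SR; arcs are backed by
observed (k+1)-mers and carry the (k+1)-mer occurrence count.  The arc
frequency ``count / delta`` estimates how many times the arc must be
traversed to assemble the underlying genome, which is what the cycle
frequency analysis consumes.

Strands are NOT canonicalised: a k-mer and its reverse complement are
distinct vertices.  The read set is expected to have been reverse-complement
augmented upstream, which makes the graph strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .io import ReadSet


@dataclass
class DeBruijnGraph:
    k: int
    delta: float
    vertices: dict[str, int] = field(default_factory=dict)
    arcs: dict[tuple[str, str], int] = field(default_factory=dict)
    out_arcs: dict[str, list[str]] = field(default_factory=dict)
    in_arcs: dict[str, list[str]] = field(default_factory=dict)

    def occ(self, v: str) -> int:
        return self.vertices.get(v, 0)

    def successors(self, v: str) -> list[str]:
        return self.out_arcs.get(v, [])

    def predecessors(self, v: str) -> list[str]:
        return self.in_arcs.get(v, [])

    def has_arc(self, vi: str, vj: str) -> bool:
        return (vi, vj) in self.arcs

    def arc_count(self, vi: str, vj: str) -> int:
        return self.arcs[(vi, vj)]


def build_graph(
    sr: ReadSet,
    k: int,
    *,
    require_augmented: bool = True,
) -> DeBruijnGraph:
    """Build G^k from a read set by counting k-mers and (k+1)-mers.

    Every read corresponds to an oriented path in the resulting graph.
    Reads shorter than k contribute nothing.  ``require_augmented`` may be
    switched off for controlled single-strand fixtures.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if require_augmented and not sr.rc_augmented:
        raise ValueError(
            "short reads must be reverse-complement augmented before graph "
            "construction (or pass require_augmented=False)"
        )
    vertices: dict[str, int] = {}
    arcs: dict[tuple[str, str], int] = {}
    for seq in sr.sequences():
        n = len(seq)
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            vertices[kmer] = vertices.get(kmer, 0) + 1
        for i in range(n - k):
            key = (seq[i : i + k], seq[i + 1 : i + k + 1])
            arcs[key] = arcs.get(key, 0) + 1

    out_arcs: dict[str, list[str]] = {}
    in_arcs: dict[str, list[str]] = {}
    for vi, vj in arcs:
        out_arcs.setdefault(vi, []).append(vj)
        in_arcs.setdefault(vj, []).append(vi)
    # Deterministic adjacency independent of read order.
    for lst in out_arcs.values():
        lst.sort()
    for lst in in_arcs.values():
        lst.sort()
    return DeBruijnGraph(
        k=k,
        delta=sr.coverage_depth,
        vertices=vertices,
        arcs=arcs,
        out_arcs=out_arcs,
        in_arcs=in_arcs,
    )


def arc_frequency(g: DeBruijnGraph, arc: tuple[str, str]) -> float:
    """f(alpha, SR) = (k+1)-mer occurrence count / coverage depth."""
    if arc not in g.arcs:
        raise KeyError(f"arc {arc} not in graph")
    return g.arcs[arc] / g.delta


def long_read_kmer_index(lr: Union[ReadSet, Iterable[str]], k: int) -> set[str]:
    """Set of all exact k-mers present in the long reads.

    Built once and reused; erroneous long reads still contain many exact
    k-mers, which is what the anchor condition occ(v, LR) > 0 relies on.
    """
    seqs = lr.sequences() if isinstance(lr, ReadSet) else lr
    index: set[str] = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            index.add(seq[i : i + k])
    return index


def eligible_start_vertices(
    g: DeBruijnGraph,
    sigma: int,
    lr: Union[ReadSet, set[str]],
) -> list[str]:
    """Vertices usable as cycle-search starts.

    A start must be well covered in the short reads (occ >= sigma, which
    screens out vertices created by sequencing errors) and must occur
    exactly in at least one long read, so that the pattern it anchors can
    later be located for validation.  Sorted by descending occurrence,
    ties broken lexicographically for determinism.
    """
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    index = lr if isinstance(lr, set) else long_read_kmer_index(lr, g.k)
    chosen = [
        v for v, occ in g.vertices.items() if occ >= sigma and v in index
    ]
    chosen.sort(key=lambda v: (-g.vertices[v], v))
    return chosen
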