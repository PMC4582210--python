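
import networkx as nx

from mixtar.cycles import SearchBudget, canonical_cycle_key, find_elementary_cycles
from mixtar.debruijn import DeBruijnGraph

from .conftest import tiling_graph


def _toy_graph(arcs, occ=None):
    """Graph from explicit arcs; vertex labels stand in for k-mers."""
    vertices = {}
    for a, b in arcs:
        vertices.setdefault(a, 1)
        vertices.setdefault(b, 1)
    if occ:
        vertices.update(occ)
    arc_counts = {(a, b): 1 for a, b in arcs}
    out_arcs, in_arcs = {}, {}
    for a, b in arcs:
        out_arcs.setdefault(a, []).append(b)
        in_arcs.setdefault(b, []).append(a)
    for lst in out_arcs.values():
        lst.sort()
    for lst in in_arcs.values():
        lst.sort()
    return DeBruijnGraph(
        k=2, delta=1.0, vertices=vertices, arcs=arc_counts,
        out_arcs=out_arcs, in_arcs=in_arcs,
    )


UNBOUNDED = SearchBudget(eta=10**9, lambda_max_long=50, lambda_max_short=50)


def _keys(cycles):
    return {canonical_cycle_key(c) for c in cycles}


def test_repeat_graph_yields_single_cycle(attgcg_repeat):
    g = tiling_graph([attgcg_repeat], k=4)
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    cycles = find_elementary_cycles(g, starts, UNBOUNDED, sigma=1)
    assert len(cycles) == 1 and len(cycles[0]) == 6
    # start vertex is the highest-occurrence member (ties lexicographic)
    assert cycles[0].start_vertex == "ATTG"


def test_two_disjoint_planted_cycles_both_found():
    g = tiling_graph(["ATTGCG" * 3, "CCGTA" * 4], k=4)
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    cycles = find_elementary_cycles(g, starts, UNBOUNDED, sigma=1)
    assert sorted(len(c) for c in cycles) == [5, 6]


def test_matches_reference_enumerator_on_random_graphs(rng):
    for trial in range(30):
        n = rng.randint(4, 12)
        arcs = set()
        for _ in range(rng.randint(n, 3 * n)):
            a, b = rng.sample(range(n), 2)
            arcs.add((f"v{a}", f"v{b}"))
        g = _toy_graph(sorted(arcs))
        starts = sorted(g.vertices)
        got = _keys(
            find_elementary_cycles(
                g, starts,
                SearchBudget(10**9, len(g.vertices), len(g.vertices)),
                sigma=1,
            )
        )
        ref = nx.DiGraph(sorted(arcs))
        want = {
            canonical_cycle_key(tuple(c)) for c in nx.simple_cycles(ref)
            if len(c) >= 2  # no self-loops in a de Bruijn cycle search
        }
        assert got == want


def test_budget_only_removes_cycles(rng):
    arcs = set()
    for _ in range(30):
        a, b = rng.sample(range(10), 2)
        arcs.add((f"v{a}", f"v{b}"))
    g = _toy_graph(sorted(arcs))
    starts = sorted(g.vertices)
    loose = _keys(find_elementary_cycles(g, starts, SearchBudget(10**9, 10, 10), 1))
    for eta, lam in [(5, 10), (50, 4), (0, 3)]:
        tight = _keys(
            find_elementary_cycles(g, starts, SearchBudget(eta, 10, lam), 1)
        )
        assert tight <= loose


def test_eta_zero_skips_long_phase():
    # A 6-cycle and a 3-cycle sharing no vertices; lambda_max_short=4 can
    # only see the short one when eta = 0.
    g = tiling_graph(["ATTGCG" * 3, "CGA" * 4], k=3)
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    budget = SearchBudget(eta=0, lambda_max_long=10, lambda_max_short=4)
    cycles = find_elementary_cycles(g, starts, budget, sigma=1)
    assert all(len(c) <= 4 for c in cycles)
    assert any(len(c) == 3 for c in cycles)


def test_sigma_excludes_low_occurrence_members():
    g = tiling_graph(["ATTGCG" * 3], k=4)
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    # Cycle members with occ=2 are unusable at sigma=3: no cycle survives.
    assert find_elementary_cycles(g, starts, UNBOUNDED, sigma=3) == []


def test_cycle_records_are_structurally_valid(rng):
    g = tiling_graph(["ATTGCG" * 3, "CCGTA" * 4], k=4)
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    for c in find_elementary_cycles(g, starts, UNBOUNDED, sigma=1):
        assert len(set(c.vertices)) == len(c.vertices)
        for (vi, vj), count in c.arcs:
            assert g.has_arc(vi, vj) and count == g.arc_count(vi, vj)


def test_canonical_key_rotation_invariant(rng):
    for _ in range(50):
        n = rng.randint(2, 8)
        verts = tuple(f"v{i}_{rng.randint(0, 9)}" for i in range(n))
        r = rng.randrange(n)
        rotated = verts[r:] + verts[:r]
        assert canonical_cycle_key(verts) == canonical_cycle_key(rotated)
    assert canonical_cycle_key(("A", "B", "C")) == canonical_cycle_key(("B", "C", "A"))
    assert canonical_cycle_key(("A", "B", "C")) != canonical_cycle_key(("A", "C", "B"))
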