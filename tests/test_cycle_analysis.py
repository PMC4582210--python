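
import pytest

from mixtar.cycle_analysis import (
    CleanedCycle,
    check_arc_frequency_property,
    clean_cycle_frequencies,
    flanking_arcs,
    make_candidate,
    spell_pattern,
)
from mixtar.cycles import SearchBudget, find_elementary_cycles
from mixtar.trfind import canonical_rotation, is_primitive

from .conftest import random_dna, tiling_graph

UNBOUNDED = SearchBudget(eta=10**9, lambda_max_long=40, lambda_max_short=40)


def _only_cycle(g):
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    cycles = find_elementary_cycles(g, starts, UNBOUNDED, sigma=1)
    assert len(cycles) == 1
    return cycles[0]


def test_flanking_arcs_of_flanked_repeat(attgcg_repeat):
    g = tiling_graph(["C" + attgcg_repeat + "T"], k=4)
    c = _only_cycle(g)
    fl = flanking_arcs(g, c)
    assert fl.a_in == (("CATT", "ATTG"),)
    assert fl.a_out == (("TGCG", "GCGT"),)


def test_isolated_cycle_has_no_flanks(attgcg_repeat):
    g = tiling_graph([attgcg_repeat], k=4)
    fl = flanking_arcs(g, _only_cycle(g))
    assert fl.a_in == () and fl.a_out == ()


def test_cleaning_without_air_leaves_frequencies_unchanged(attgcg_repeat):
    g = tiling_graph(["C" + attgcg_repeat + "T"], k=4)
    c = _only_cycle(g)
    fl = flanking_arcs(g, c)
    cc = clean_cycle_frequencies(g, c, fl, (fl.a_in[0], fl.a_out[0]))
    assert cc.freqs == [3.0, 3.0, 2.0, 2.0, 2.0, 2.0]
    assert cc.v1 == "ATTG" and cc.ve == "TGCG"


@pytest.mark.parametrize("strict", [True, False])
def test_cleaning_removes_interspersed_repeat_contribution(attgcg_repeat, strict):
    """An extra non-tandem copy inflates the shared cycle arcs; cleaning
    with the repeat's own flank couple must recover the repeat-only
    frequencies (oracle: the graph built from the flanked repeat alone)."""
    flanked = "C" + attgcg_repeat + "T"
    air = "T" + "ATTGCGA" + "C"  # forward-path AIR, distinct flanks
    g = tiling_graph([flanked, air], k=4)
    c = _only_cycle(g)
    fl = flanking_arcs(g, c)
    assert len(fl.a_in) == 2 and len(fl.a_out) == 2
    cc = clean_cycle_frequencies(
        g, c, fl, (("CATT", "ATTG"), ("TGCG", "GCGT")), strict=strict
    )
    oracle = tiling_graph([flanked], k=4)
    want = [
        oracle.arcs[(cc.vertices[i], cc.vertices[(i + 1) % 6])] for i in range(6)
    ]
    assert cc.freqs == [float(w) for w in want]
    assert check_arc_frequency_property(cc, 0.0).passes


@pytest.mark.parametrize("strict", [True, False])
def test_cleaning_handles_return_path_air(attgcg_repeat, strict):
    # AIR touching only the return path: GCGATT occurs once more elsewhere.
    flanked = "C" + attgcg_repeat + "T"
    air = "A" + "GCGATT" + "C"
    g = tiling_graph([flanked, air], k=4)
    c = _only_cycle(g)
    fl = flanking_arcs(g, c)
    cc = clean_cycle_frequencies(
        g, c, fl, (("CATT", "ATTG"), ("TGCG", "GCGT")), strict=strict
    )
    oracle = tiling_graph([flanked], k=4)
    want = [
        float(oracle.arcs[(cc.vertices[i], cc.vertices[(i + 1) % 6])])
        for i in range(6)
    ]
    assert cc.freqs == want


def test_property_fixture_passes_with_pinned_split(attgcg_repeat):
    g = tiling_graph(["C" + attgcg_repeat + "T"], k=4)
    c = _only_cycle(g)
    fl = flanking_arcs(g, c)
    cc = clean_cycle_frequencies(g, c, fl, (fl.a_in[0], fl.a_out[0]))
    v = check_arc_frequency_property(cc, 0.0)
    assert v.passes and v.x == 3.0


def test_uniform_frequencies_fail_every_split():
    cc = CleanedCycle(
        vertices=tuple("ABCDEF"),
        freqs=[2.0] * 6,
        couple=(None, None),
        v1=None,
        ve=None,
    )
    assert not check_arc_frequency_property(cc, 0.25).passes


def test_tolerance_band_admits_noisy_levels():
    cc = CleanedCycle(
        vertices=tuple("ABCDEF"),
        freqs=[3.1, 2.9, 2.05, 1.95, 2.0, 2.1],
        couple=(("X", "A"), ("C", "Y")),
        v1="A",
        ve="C",
    )
    v = check_arc_frequency_property(cc, 0.15)
    assert v.passes and v.x == pytest.approx(3.0)
    assert not check_arc_frequency_property(cc, 0.0).passes


def test_negative_cleaned_frequency_fails():
    cc = CleanedCycle(
        vertices=tuple("ABCD"),
        freqs=[2.0, 2.0, -0.5, 1.0],
        couple=(("X", "A"), ("C", "Y")),
        v1="A",
        ve="C",
    )
    assert not check_arc_frequency_property(cc, 0.25).passes


def test_property_holds_for_random_planted_repeats(rng):
    """Isolated repeat graphs always contain a |p|-vertex cycle whose raw
    frequencies satisfy the x / x-1 signature exactly (rho = 0)."""
    done = 0
    while done < 100:
        plen = rng.randint(2, 30)
        cn = rng.randint(2, 6)
        k = rng.randint(2, 12)
        p = random_dna(rng, plen)
        if not is_primitive(p):
            continue
        eps = p * cn
        if len(eps) < plen + k:
            continue
        # The |p|-vertex cycle exists when the |p| leading k-mers are
        # pairwise distinct (guaranteed for k >= |p|; occasional k-mer
        # collisions at k < |p| collapse vertices and change the shape).
        if len({eps[i : i + k] for i in range(plen)}) != plen:
            continue
        g = tiling_graph([eps], k=k)
        starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
        budget = SearchBudget(10**9, plen, plen)
        cycles = [
            c for c in find_elementary_cycles(g, starts, budget, 1)
            if len(c) == plen
        ]
        assert cycles, (p, cn, k)
        c = cycles[0]
        cc = clean_cycle_frequencies(g, c, flanking_arcs(g, c), (None, None))
        # Pin the split at the repeat's true first and last k-mers.
        v1, ve = eps[:k], eps[-k:]
        i = cc.vertices.index(v1)
        pinned = CleanedCycle(
            vertices=cc.vertices[i:] + cc.vertices[:i],
            freqs=cc.freqs[i:] + cc.freqs[:i],
            couple=cc.couple,
            v1=v1,
            ve=ve,
        )
        verdict = check_arc_frequency_property(pinned, 0.0)
        assert verdict.passes, (p, cn, k, pinned.freqs)
        assert verdict.x is not None and verdict.x >= 1.0
        done += 1


def test_spelled_pattern_is_rotation_of_planted(rng):
    done = 0
    while done < 40:
        plen = rng.randint(3, 15)
        k = rng.randint(2, 8)
        p = random_dna(rng, plen)
        if not is_primitive(p):
            continue
        eps = p * 4
        if len(eps) < plen + k:
            continue
        if len({eps[i : i + k] for i in range(plen)}) != plen:
            continue
        g = tiling_graph([eps], k=k)
        starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
        cycles = [
            c
            for c in find_elementary_cycles(
                g, starts, SearchBudget(10**9, plen, plen), 1
            )
            if len(c) == plen
        ]
        for v1 in cycles[0].vertices:
            _, spelled = spell_pattern(cycles[0], v1)
            assert canonical_rotation(spelled) == canonical_rotation(p)
        done += 1


def test_spell_pattern_worked_example(attgcg_repeat):
    g = tiling_graph([attgcg_repeat], k=4)
    c = _only_cycle(g)
    eps, p = spell_pattern(c, "ATTG")
    assert eps == "ATTGCGATT" and p == "ATTGCG"


def test_candidate_reduces_to_primitive_root():
    g = tiling_graph(["ATATATATAT"], k=3)
    starts = sorted(g.vertices, key=lambda v: (-g.vertices[v], v))
    cycles = find_elementary_cycles(g, starts, SearchBudget(10**9, 4, 4), 1)
    c = next(c for c in cycles if len(c) == 2)
    cand = make_candidate(c, c.vertices[0])
    assert cand is not None and cand.pattern in ("AT", "TA")
    assert is_primitive(cand.pattern)
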