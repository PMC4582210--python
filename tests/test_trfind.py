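import random

import pytest

from mixtar.io import reverse_complement
from mixtar.trfind import (
    canonical_pattern,
    canonical_rotation,
    copy_number,
    find_approx_tr,
    find_exact_tr,
    is_primitive,
    smallest_period,
)

from .conftest import random_dna


def test_smallest_period_examples():
    assert smallest_period("ATATAT") == 2
    assert smallest_period("ATTGCG") == 6
    assert smallest_period("AAAA") == 1
    assert smallest_period("ABCAB") == 3  # period need not divide length


def test_smallest_period_matches_brute_force(rng):
    for _ in range(300):
        s = random_dna(rng, rng.randint(1, 30))
        brute = next(
            q
            for q in range(1, len(s) + 1)
            if all(s[i] == s[i + q] for i in range(len(s) - q))
        )
        assert smallest_period(s) == brute


def test_copy_number_examples():
    assert copy_number("ATTGCGATTGCGATTGCG", "ATTGCG") == 3
    assert copy_number("ATATATA", "AT") == 3.5
    assert copy_number("ACGT", "ACGT") == 1
    with pytest.raises(ValueError):
        copy_number("ACG", "ACGT")


def test_find_exact_examples():
    (tr,) = [t for t in find_exact_tr("GGATATATAGG") if t.pattern in ("AT", "TA")]
    assert (tr.pattern, tr.copy_number, tr.start, tr.end) == ("AT", 3.5, 3, 9)

    (tr,) = find_exact_tr("ATTGCGATTGCGATTGCG")
    assert tr.pattern == "ATTGCG" and tr.copy_number == 3

    (tr,) = find_exact_tr("ACGTACGTACG")
    assert tr.pattern == "ACGT" and tr.copy_number == 2.75


def test_exact_recovery_of_planted_repeats(rng):
    """Planted (p, cn) runs in random flanks are recovered with the exact
    pattern, copy number and position."""
    done = 0
    while done < 200:
        plen = rng.randint(2, 15)
        cn = rng.randint(2, 6)
        p = random_dna(rng, plen)
        if not is_primitive(p):
            continue
        left = random_dna(rng, rng.randint(20, 60))
        right = random_dna(rng, rng.randint(20, 60))
        seq = left + p * cn + right
        s0 = len(left)
        # enforce maximality at the junctions
        if s0 and seq[s0 - 1] == seq[s0 + plen - 1]:
            continue
        e0 = s0 + plen * cn
        if e0 < len(seq) and seq[e0] == seq[e0 - plen]:
            continue
        hits = [
            t
            for t in find_exact_tr(seq, 2, 20)
            if canonical_rotation(t.pattern) == canonical_rotation(p)
            and t.copy_number >= cn
        ]
        assert hits, (p, cn)
        best = max(hits, key=lambda t: t.copy_number)
        assert best.start == s0 + 1 and best.end == e0
        assert best.copy_number == cn
        done += 1


def test_all_reported_patterns_are_primitive(rng):
    for _ in range(30):
        seq = random_dna(rng, 300)
        for t in find_exact_tr(seq, 2, 30):
            assert is_primitive(t.pattern)
            assert len(t.pattern) >= 2  # homopolymers never reported


def test_approx_joins_mutated_copy():
    seq = "ATTGCG" + "ATTGCG" + "ATTACG"
    (tr,) = [t for t in find_approx_tr(seq, 2, 10, 0.6) if len(t.pattern) == 6]
    assert tr.kind == "ATR" and tr.copy_number == 3
    assert tr.pattern == "ATTGCG" and tr.sequence == seq


def test_approx_stops_below_threshold():
    seq = "ATTGCG" + "ATTGCG" + "CCCCCC"
    (tr,) = [t for t in find_approx_tr(seq, 2, 10, 0.6) if len(t.pattern) == 6]
    assert tr.kind == "ETR" and tr.copy_number == 2


def test_pure_exact_input_reported_as_etr():
    seq = "GG" + "ACGTT" * 4 + "AA"
    exact = find_exact_tr(seq, 2, 10)
    approx = find_approx_tr(seq, 2, 10, 0.8)
    assert [(t.pattern, t.copy_number, t.kind) for t in exact] == [
        (t.pattern, t.copy_number, t.kind) for t in approx
    ]


def test_exact_is_subset_of_approx_at_full_threshold(rng):
    for _ in range(20):
        seq = random_dna(rng, 200)
        exact = {
            (t.pattern, t.copy_number, t.start) for t in find_exact_tr(seq, 2, 20)
        }
        approx = {
            (t.pattern, t.copy_number, t.start)
            for t in find_approx_tr(seq, 2, 20, 1.0)
        }
        assert exact <= approx


def test_canonical_pattern_identifies_strands_and_rotations():
    assert canonical_pattern("ATTGCG") == canonical_pattern("CGCAAT")
    assert canonical_pattern("ATTGCG") == canonical_pattern("TTGCGA")
    assert canonical_pattern("ATTGCG") == canonical_pattern(
        reverse_complement("GATTGC")
    )


def test_distinct_primitive_patterns_have_distinct_canonical_forms(rng):
    seen = {}
    for _ in range(200):
        p = random_dna(rng, rng.randint(3, 10))
        if not is_primitive(p):
            continue
        c = canonical_pattern(p)
        if c in seen:
            q = seen[c]
            rots = {q[i:] + q[:i] for i in range(len(q))}
            rc = reverse_complement(q)
            rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
            assert p in rots
        seen[c] = p
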