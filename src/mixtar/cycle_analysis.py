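"""Turning elementary cycles into tandem-repeat pattern candidates.

A cycle formed by an exact tandem repeat has a characteristic frequency
signature: arcs on the path from the repeat's first k-mer ``v1`` to its
last k-mer ``ve`` are traversed once per copy (frequency x), while arcs on
the return path are traversed once less (x - 1).  Other repeats that share
k-mers with the cycle (additional interspersed repeats, AIR) inflate the
arc frequencies; the cleaning pass subtracts their contribution using the
cycle's flanking arcs as markers, after which the x / x - 1 signature is
tested within a relative tolerance band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cycles import CycleRecord, canonical_cycle_key
from .debruijn import DeBruijnGraph
from .trfind import smallest_period

Arc = tuple[str, str]


@dataclass(frozen=True)
class FlankingArcs:
    """Non-cycle arcs incident to a cycle, split by direction."""

    a_in: tuple[Arc, ...]   # (x, v): x outside the cycle, v on it
    a_out: tuple[Arc, ...]  # (v, y): v on the cycle, y outside


@dataclass
class CleanedCycle:
    """Per-arc frequencies of a cycle after AIR removal for one couple.

    ``vertices`` start at v1 (the head of the chosen input arc) and follow
    the cycle orientation; ``freqs[i]`` is the cleaned frequency of the arc
    leaving ``vertices[i]``.
    """

    vertices: tuple[str, ...]
    freqs: list[float]
    couple: tuple[Optional[Arc], Optional[Arc]]
    v1: Optional[str]
    ve: Optional[str]


@dataclass(frozen=True)
class Property1Verdict:
    passes: bool
    x: Optional[float]
    rho: float
    v1: Optional[str] = None
    ve: Optional[str] = None


@dataclass(frozen=True)
class PatternCandidate:
    """A spelled cycle pattern awaiting long-read validation."""

    pattern: str
    anchor: str          # cycle vertex with max occ in SR, present in LR
    cycle_key: tuple[str, ...]
    x: Optional[float] = None


def flanking_arcs(g: DeBruijnGraph, c: CycleRecord) -> FlankingArcs:
    """Input and output arcs connecting the cycle to the rest of the graph."""
    members = set(c.vertices)
    a_in: list[Arc] = []
    a_out: list[Arc] = []
    for v in c.vertices:
        for x in g.predecessors(v):
            if x not in members:
                a_in.append((x, v))
        for y in g.successors(v):
            if y not in members:
                a_out.append((v, y))
    return FlankingArcs(a_in=tuple(sorted(a_in)), a_out=tuple(sorted(a_out)))


def _rotate_to(vertices: tuple[str, ...], v: str) -> tuple[str, ...]:
    i = vertices.index(v)
    return vertices[i:] + vertices[:i]


def clean_cycle_frequencies(
    g: DeBruijnGraph,
    c: CycleRecord,
    fl: FlankingArcs,
    couple: tuple[Optional[Arc], Optional[Arc]],
    *,
    strict: bool = True,
) -> CleanedCycle:
    """Subtract the frequency contribution of AIR from a cycle's arcs.

    The couple (alpha_in, alpha_out) marks the candidate repeat's own entry
    and exit; every other flanking arc is attributed to AIR.  Walking the
    cycle from v1, a running balance of AIR entries minus exits is carried
    in ``f_acc`` and subtracted from each cycle arc.  A residual balance at
    the end of the walk is attributed on a second pass.

    With ``strict`` the second pass uses the literally specified outgoing
    values (which are always zero, so the residual is subtracted from every
    arc unchanged); with ``strict=False`` the pre-clamp deficit at each
    vertex is stored instead, so the residual shrinks as it is attributed
    to the arcs that incurred it.
    """
    alpha_in, alpha_out = couple
    if alpha_in is not None and alpha_in not in fl.a_in:
        raise ValueError(f"{alpha_in} is not an input arc of the cycle")
    if alpha_out is not None and alpha_out not in fl.a_out:
        raise ValueError(f"{alpha_out} is not an output arc of the cycle")

    vertices = (
        _rotate_to(c.vertices, alpha_in[1]) if alpha_in is not None else c.vertices
    )
    l = len(vertices)
    delta = g.delta

    f_input = {v: 0.0 for v in vertices}
    f_output = {v: 0.0 for v in vertices}
    for arc in fl.a_in:
        if arc != alpha_in:
            f_input[arc[1]] += g.arcs[arc] / delta
    for arc in fl.a_out:
        if arc != alpha_out:
            f_output[arc[0]] += g.arcs[arc] / delta

    freqs = [
        g.arcs[(vertices[i], vertices[(i + 1) % l])] / delta for i in range(l)
    ]

    f_acc = 0.0
    saved_output = [0.0] * l
    for i, v in enumerate(vertices):
        pre = f_acc + f_input[v] - f_output[v]
        f_acc = max(pre, 0.0)
        freqs[i] -= f_acc
        saved_output[i] = max(-f_acc, 0.0) if strict else max(-pre, 0.0)

    if f_acc > 0:
        for i in range(l):
            f_acc = max(f_acc - saved_output[i], 0.0)
            freqs[i] -= f_acc

    return CleanedCycle(
        vertices=vertices,
        freqs=freqs,
        couple=couple,
        v1=vertices[0] if alpha_in is not None else None,
        ve=alpha_out[0] if alpha_out is not None else None,
    )


def _band_ok(values: list[float], level: float, rho: float) -> bool:
    lo, hi = level * (1 - rho), level * (1 + rho)
    if lo > hi:  # level < 0 flips the band; treat as failure
        return False
    return all(lo - 1e-9 <= f <= hi + 1e-9 for f in values)


def _check_split(
    freqs: list[float], d: int, rho: float, coverage_tol: float
) -> Optional[float]:
    """Verdict for a split with ``d`` forward arcs; returns x or None.

    The forward path must be uniform within ``rho`` of its mean x_f, the
    return path uniform within ``rho`` of its mean x_r, and the separation
    x_f - x_r must equal the one-traversal difference of Property 1 up to
    ``coverage_tol`` (the separation scales with the *local* coverage of
    the repeat locus, which fluctuates around the global depth delta).
    With rho = 0 and exact coverage this reduces to forward = x,
    return = x - 1 exactly.
    """
    forward, ret = freqs[:d], freqs[d:]
    if d == 0:
        # v1 == ve: the forward path is empty and the whole cycle is the
        # return path at level x - 1; no separation is measurable.
        x_r = sum(ret) / len(ret)
        if x_r < -1e-9 or not _band_ok(ret, x_r, rho):
            return None
        return x_r + 1.0
    x_f = sum(forward) / len(forward)
    if x_f < 1.0 - 1e-9:
        return None
    if not _band_ok(forward, x_f, rho):
        return None
    if ret:
        x_r = sum(ret) / len(ret)
        if x_r < -1e-9 or not _band_ok(ret, x_r, rho):
            return None
        if abs((x_f - x_r) - 1.0) > coverage_tol + 1e-9:
            return None
    return x_f


def check_arc_frequency_property(
    cc: CleanedCycle,
    rho: float,
    coverage_tol: float = 0.5,
) -> Property1Verdict:
    """Test the x / x - 1 arc-frequency signature of an exact tandem repeat.

    With a known couple, the split between forward and return path is
    pinned by v1 and ve.  Without one (an isolated cycle), every split with
    non-empty forward and return paths is tried and the first passing one
    wins.

    Non-homogeneous coverage means the check uses intervals rather than
    exact values, derived from the coverage depth and the cycle's own mean
    arc frequencies: each path must be uniform within a relative band of
    half-width ``rho`` around its mean, and the forward/return separation
    must match the one-extra-traversal difference within ``coverage_tol``
    (absolute, in frequency units — the separation is proportional to the
    repeat locus's local coverage over delta).
    """
    freqs = cc.freqs
    l = len(freqs)
    if any(f < -1e-9 for f in freqs):
        return Property1Verdict(False, None, rho, cc.v1, cc.ve)

    if cc.v1 is not None and cc.ve is not None:
        d = cc.vertices.index(cc.ve)  # arcs 0..d-1 lie on the v1->ve path
        x = _check_split(freqs, d, rho, coverage_tol)
        return Property1Verdict(x is not None, x, rho, cc.v1, cc.ve)

    for start in range(l):
        rotated = freqs[start:] + freqs[:start]
        for d in range(1, l):
            x = _check_split(rotated, d, rho, coverage_tol)
            if x is not None:
                return Property1Verdict(
                    True, x, rho,
                    cc.vertices[start],
                    cc.vertices[(start + d) % l],
                )
    return Property1Verdict(False, None, rho, None, None)


def spell_pattern(c: CycleRecord, v1: str) -> tuple[str, str]:
    """Spell the repeat string and pattern from a cycle starting at v1.

    Returns (epsilon, p) where epsilon = v1 + v2[k] + ... + vl[k] (length
    k - 1 + l) and p = epsilon[:l].
    """
    vertices = _rotate_to(c.vertices, v1)
    epsilon = vertices[0] + "".join(v[-1] for v in vertices[1:])
    return epsilon, epsilon[: len(vertices)]


def make_candidate(
    c: CycleRecord,
    v1: str,
    *,
    x: Optional[float] = None,
) -> Optional[PatternCandidate]:
    """Build a pattern candidate from a verified cycle.

    The pattern is reduced to its primitive root (copies must be
    primitive); a root shorter than 2 bp cannot be a pattern and the
    candidate is discarded.
    """
    _, p = spell_pattern(c, v1)
    period = smallest_period(p)
    if period < len(p):
        if period < 2:
            return None
        p = p[:period]
    return PatternCandidate(
        pattern=p,
        anchor=c.start_vertex,
        cycle_key=canonical_cycle_key(c),
        x=x,
    )
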