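"""Maximal tandem repeat search in plain DNA sequences.

Used on assembled contigs and on reference/truth sequences.  Reports
maximal runs of two or more copies of a primitive pattern (|p| >= 2), with
a fractional credit for a partial last copy.  Exact runs are found by
scanning, for each period q, the positions where ``s[i] == s[i+q]``;
approximate repeats extend an exact core copy-by-copy while each flanking
window still aligns to the pattern above a score threshold.

This is a deliberately small tool: no resolution parameter and a fixed
pattern (rather than a rolling consensus) as the reference for approximate
copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .align import global_score
from .io import reverse_complement


@dataclass(frozen=True)
class TandemRepeat:
    """A maximal tandem repeat occurrence.

    Coordinates are 1-based inclusive within ``source``.  ``copy_number``
    is decimal: complete copies plus partial-last-copy length over |p|.
    """

    pattern: str
    copy_number: float
    sequence: str
    source: str
    start: int
    end: int
    kind: str  # "ETR" | "ATR"

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("pattern must have length >= 2")
        if self.copy_number < 2:
            raise ValueError("a tandem repeat needs at least two complete copies")


def smallest_period(s: str) -> int:
    """Smallest q >= 1 with s[i] == s[i+q] for all valid i (KMP border)."""
    n = len(s)
    if n == 0:
        raise ValueError("empty string has no period")
    border = [0] * (n + 1)
    j = 0
    for i in range(1, n):
        while j and s[i] != s[j]:
            j = border[j]
        if s[i] == s[j]:
            j += 1
        border[i + 1] = j
    return n - border[n]


def is_primitive(s: str) -> bool:
    return smallest_period(s) == len(s)


def canonical_rotation(s: str) -> str:
    """Lexicographically minimal rotation of s."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def canonical_pattern(p: str) -> str:
    """Strand- and rotation-invariant identity of a repeat pattern."""
    return min(canonical_rotation(p), canonical_rotation(reverse_complement(p)))


def copy_number(epsilon: str, p: str) -> float:
    """Decimal copy count of p at the start of epsilon (exact copies).

    Counts complete leading copies of p, then credits the longest exact
    prefix of p matching the remainder as a fraction.
    """
    if len(epsilon) < len(p):
        raise ValueError("sequence shorter than pattern")
    q = len(p)
    full = 0
    i = 0
    while epsilon[i : i + q] == p:
        full += 1
        i += q
    partial = 0
    while i + partial < len(epsilon) and partial < q and epsilon[i + partial] == p[partial]:
        partial += 1
    return full + partial / q


def find_exact_tr(
    seq: str,
    pmin: int = 2,
    pmax: Optional[int] = None,
    *,
    source: str = "",
) -> list[TandemRepeat]:
    """All maximal exact tandem repeats with primitive pattern length in
    [pmin, pmax] and at least two complete copies.

    Runs at different pattern lengths over the same locus are all
    reported; non-primitive patterns are skipped (their runs reappear at
    the primitive period).
    """
    n = len(seq)
    pmax = min(pmax if pmax is not None else n // 2, n // 2)
    out: list[TandemRepeat] = []
    if n < 2 * max(pmin, 2):
        return out
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for q in range(max(pmin, 2), pmax + 1):
        eq = arr[: n - q] == arr[q:]
        if not eq.any():
            continue
        # Maximal runs of consecutive True in eq.
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive
        for s0, e0 in zip(starts, ends):
            run_len = int(e0 - s0) + q  # bp spanned by the repeat
            if run_len < 2 * q:
                continue
            p = seq[s0 : s0 + q]
            if smallest_period(p) != q:
                continue
            out.append(
                TandemRepeat(
                    pattern=p,
                    copy_number=run_len / q,
                    sequence=seq[s0 : s0 + run_len],
                    source=source,
                    start=int(s0) + 1,
                    end=int(s0) + run_len,
                    kind="ETR",
                )
            )
    out.sort(key=lambda t: (t.start, t.end, t.pattern))
    return out


def _copy_matches(window: str, p: str, frac: float) -> bool:
    return global_score(window, p) / len(p) >= frac - 1e-9


def find_approx_tr(
    seq: str,
    pmin: int = 2,
    pmax: Optional[int] = None,
    copy_score_frac: float = 0.8,
    *,
    source: str = "",
) -> list[TandemRepeat]:
    """Maximal approximate tandem repeats grown from exact cores.

    Each exact run is extended copy-by-copy: a flanking window of |p| bases
    joins as a copy while its global alignment score against p stays at or
    above ``copy_score_frac * |p|``.  A repeat whose copies are all exact
    is reported as ETR, otherwise as ATR.  The partial last copy is
    credited by exact prefix match only.
    """
    if not 0 < copy_score_frac <= 1:
        raise ValueError("copy_score_frac must be in (0, 1]")
    n = len(seq)
    cores = find_exact_tr(seq, pmin, pmax, source=source)
    out: list[TandemRepeat] = []
    seen: set[tuple[int, int, str]] = set()
    for core in cores:
        q = len(core.pattern)
        p = core.pattern
        # Trim the core to whole copies; re-grow the partial afterwards.
        s0 = core.start - 1
        full_copies = int(core.copy_number)
        e0 = s0 + full_copies * q  # exclusive end of complete copies
        approx = False
        while s0 - q >= 0 and _copy_matches(seq[s0 - q : s0], p, copy_score_frac):
            s0 -= q
            if seq[s0 : s0 + q] != p:
                approx = True
        while e0 + q <= n and _copy_matches(seq[e0 : e0 + q], p, copy_score_frac):
            if seq[e0 : e0 + q] != p:
                approx = True
            e0 += q
        copies = (e0 - s0) // q
        partial = 0
        while (
            e0 + partial < n and partial < q and seq[e0 + partial] == p[partial]
        ):
            partial += 1
        if not approx:
            # Pure exact repeat: defer to the exact record (which already
            # carries the maximal fractional extension).
            key = (core.start, core.end, p)
            if key not in seen:
                seen.add(key)
                out.append(core)
            continue
        cn = copies + partial / q
        key = (s0 + 1, s0 + copies * q + partial, p)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            TandemRepeat(
                pattern=p,
                copy_number=cn,
                sequence=seq[s0 : s0 + copies * q + partial],
                source=source,
                start=s0 + 1,
                end=s0 + copies * q + partial,
                kind="ATR",
            )
        )
    out.sort(key=lambda t: (t.start, t.end, t.pattern))
    return out
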