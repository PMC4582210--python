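"""Alignment scores used throughout the pipeline.

All three scores use the same fixed scheme: +1 per match, -1 per mismatch,
insertion or deletion.  Only scores are computed, never tracebacks — every
downstream decision (pattern validation, read selection, greedy merging)
thresholds a score.

The dynamic programs are vectorised row-by-row with numpy; the horizontal
gap recurrence is closed with a prefix-max scan (``D[i][j] =
max_{j'<=j} cand[j'] - (j - j')`` becomes an accumulate over
``cand + arange``), which keeps the inner loop out of Python.
"""

from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -1
INDEL = -1

_NEG = -(10**9)  # -inf sentinel that survives integer arithmetic
_M32 = np.int32(1)
_X32 = np.int32(-1)


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _close_row(row: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # Horizontal-gap closure: row[j] = max(row[j], row[j'] - (j - j')) for j' < j.
    return np.maximum(row, np.maximum.accumulate(row + idx) - idx)


def global_score(s1: str, s2: str) -> int:
    """Needleman-Wunsch score of the best global alignment of s1 and s2."""
    if not s1 or not s2:
        raise ValueError("global_score requires non-empty strings")
    a, b = _encode(s1), _encode(s2)
    n = a.size
    idx = np.arange(n + 1, dtype=np.int64)
    prev = -idx.copy()
    for i in range(1, b.size + 1):
        sub = np.where(a == b[i - 1], MATCH, MISMATCH)
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = -i
        cur[1:] = np.maximum(prev[:-1] + sub, prev[1:] + INDEL)
        prev = _close_row(cur, idx)
    return int(prev[n])


def semiglobal_max(s1: str, s2: str) -> int:
    """Best score of s1 globally aligned against any substring of s2.

    Equivalent to free end-gaps on the s2 side only: the substring's start
    and end are not penalised, but s1 must be consumed in full.
    """
    if not s1 or not s2:
        raise ValueError("semiglobal_max requires non-empty strings")
    a, b = _encode(s1), _encode(s2)
    n = a.size
    idx = np.arange(n + 1, dtype=np.int64)
    prev = -idx.copy()
    best = int(prev[n])  # empty substring of s2
    for i in range(1, b.size + 1):
        sub = np.where(a == b[i - 1], MATCH, MISMATCH)
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = 0  # substring may start at position i
        cur[1:] = np.maximum(prev[:-1] + sub, prev[1:] + INDEL)
        prev = _close_row(cur, idx)
        best = max(best, int(prev[n]))  # substring may end at position i
    return best


def overlap_max(s1: str, s2: str, lmin: int) -> int:
    """Best score aligning a prefix of s1 against a suffix of s2.

    Both the prefix and the suffix must consume at least ``lmin``
    characters of their string; within the chosen pieces the alignment is
    global, so the result may be negative.
    """
    if not s1 or not s2:
        raise ValueError("overlap_max requires non-empty strings")
    if lmin < 1 or lmin > min(len(s1), len(s2)):
        raise ValueError(
            f"lmin={lmin} must be in [1, min(|s1|, |s2|)={min(len(s1), len(s2))}]"
        )
    a, b = _encode(s1), _encode(s2)
    n, m = a.size, b.size
    idx = np.arange(n + 1, dtype=np.int64)
    # Row i aligns against b[i:] candidates; the suffix of s2 may start at
    # any row i with m - i >= lmin.  Row 0 consumes all of s2.
    prev = -idx.copy()
    for i in range(1, m + 1):
        sub = np.where(a == b[i - 1], MATCH, MISMATCH)
        cur = np.empty(n + 1, dtype=np.int64)
        # the suffix may start here, or have started earlier with the
        # preceding s2 characters consumed by leading gaps
        cur[0] = max(0 if m - i >= lmin else _NEG, prev[0] + INDEL)
        cur[1:] = np.maximum(prev[:-1] + sub, prev[1:] + INDEL)
        prev = _close_row(cur, idx)
    return int(prev[lmin:].max())


def overlap_max_arg(s1: str, s2: str, lmin: int) -> tuple[int, int]:
    """Like :func:`overlap_max` but also return the prefix length of s1.

    The returned prefix length is the number of s1 characters consumed by
    the best overlap, which is what a merge of the two strings needs:
    ``merged = s2 + s1[prefix_len:]``.  Ties prefer the longer prefix.
    """
    if not s1 or not s2:
        raise ValueError("overlap_max_arg requires non-empty strings")
    if lmin < 1 or lmin > min(len(s1), len(s2)):
        raise ValueError("lmin out of range")
    a, b = _encode(s1), _encode(s2)
    n, m = a.size, b.size
    idx = np.arange(n + 1, dtype=np.int64)
    prev = -idx.copy()
    for i in range(1, m + 1):
        sub = np.where(a == b[i - 1], MATCH, MISMATCH)
        cur = np.empty(n + 1, dtype=np.int64)
        # the suffix may start here, or have started earlier with the
        # preceding s2 characters consumed by leading gaps
        cur[0] = max(0 if m - i >= lmin else _NEG, prev[0] + INDEL)
        cur[1:] = np.maximum(prev[:-1] + sub, prev[1:] + INDEL)
        prev = _close_row(cur, idx)
    tail = prev[lmin:]
    j = int(tail.size - 1 - tail[::-1].argmax())  # rightmost argmax
    return int(tail[j]), lmin + j


def _close_rows(rows: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.maximum(rows, np.maximum.accumulate(rows + idx, axis=1) - idx)


def _batch_prefix_of_query(s1: str, block: np.ndarray, lmin: int) -> np.ndarray:
    """overlap_max(s1, row, lmin) for every row of an equal-length block."""
    a = _encode(s1)
    n = a.size
    nrows, m = block.shape
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.tile(-idx, (nrows, 1))
    cur = np.empty_like(prev)
    for i in range(1, m + 1):
        sub = np.where(block[:, i - 1 : i] == a[None, :], _M32, _X32)
        np.maximum(prev[:, 0] + INDEL, 0 if m - i >= lmin else _NEG, out=cur[:, 0])
        np.maximum(prev[:, :-1] + sub, prev[:, 1:] + INDEL, out=cur[:, 1:])
        prev, cur = _close_rows(cur, idx), prev
    return prev[:, lmin:].max(axis=1).astype(np.int64)


def _batch_suffix_of_query(block: np.ndarray, s2: str, lmin: int) -> np.ndarray:
    """overlap_max(row, s2, lmin) for every row of an equal-length block."""
    b = _encode(s2)
    m = b.size
    nrows, n = block.shape
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.tile(-idx, (nrows, 1))
    cur = np.empty_like(prev)
    for i in range(1, m + 1):
        sub = np.where(block == b[i - 1], _M32, _X32)
        np.maximum(prev[:, 0] + INDEL, 0 if m - i >= lmin else _NEG, out=cur[:, 0])
        np.maximum(prev[:, :-1] + sub, prev[:, 1:] + INDEL, out=cur[:, 1:])
        prev, cur = _close_rows(cur, idx), prev
    return prev[:, lmin:].max(axis=1).astype(np.int64)


def mutual_overlap_scores(s: str, seqs: list[str], lmin: int) -> np.ndarray:
    """max(overlap_max(s, r, lmin), overlap_max(r, s, lmin)) for each r.

    Sequences shorter than lmin score the -inf sentinel.  Sequences are
    grouped by length internally so the dynamic programs run batched.
    """
    out = np.full(len(seqs), _NEG, dtype=np.int64)
    if not seqs or lmin > len(s):
        return out
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(seqs):
        if len(r) >= lmin:
            groups.setdefault(len(r), []).append(i)
    for length, members in groups.items():
        block = np.frombuffer(
            "".join(seqs[i] for i in members).encode("ascii"), dtype=np.uint8
        ).reshape(len(members), length)
        fwd = _batch_prefix_of_query(s, block, lmin)
        rev = _batch_suffix_of_query(block, s, lmin)
        out[members] = np.maximum(fwd, rev)
    return out


def directional_overlap_scores(
    s: str, seqs: list[str], lmin: int
) -> tuple[np.ndarray, np.ndarray]:
    """(overlap_max(s, r, lmin), overlap_max(r, s, lmin)) arrays per r.

    The first array scores a prefix of ``s`` against a suffix of each r
    (merge r + s-tail); the second scores a prefix of each r against a
    suffix of ``s`` (merge s + r-tail).
    """
    fwd = np.full(len(seqs), _NEG, dtype=np.int64)
    rev = np.full(len(seqs), _NEG, dtype=np.int64)
    if not seqs or lmin > len(s):
        return fwd, rev
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(seqs):
        if len(r) >= lmin:
            groups.setdefault(len(r), []).append(i)
    for length, members in groups.items():
        block = np.frombuffer(
            "".join(seqs[i] for i in members).encode("ascii"), dtype=np.uint8
        ).reshape(len(members), length)
        fwd[members] = _batch_prefix_of_query(s, block, lmin)
        rev[members] = _batch_suffix_of_query(block, s, lmin)
    return fwd, rev


def _grouped(seqs: list[str], lmin: int):
    groups: dict[int, list[int]] = {}
    for i, r in enumerate(seqs):
        if len(r) >= lmin:
            groups.setdefault(len(r), []).append(i)
    for length, members in groups.items():
        block = np.frombuffer(
            "".join(seqs[i] for i in members).encode("ascii"), dtype=np.uint8
        ).reshape(len(members), length)
        yield members, block


def overlap_scores_prefix(s: str, seqs: list[str], lmin: int) -> np.ndarray:
    """overlap_max(s, r, lmin) for each r: prefix of s vs suffix of r."""
    out = np.full(len(seqs), _NEG, dtype=np.int64)
    if not seqs or lmin > len(s):
        return out
    for members, block in _grouped(seqs, lmin):
        out[members] = _batch_prefix_of_query(s, block, lmin)
    return out


def overlap_scores_suffix(s: str, seqs: list[str], lmin: int) -> np.ndarray:
    """overlap_max(r, s, lmin) for each r: prefix of r vs suffix of s."""
    out = np.full(len(seqs), _NEG, dtype=np.int64)
    if not seqs or lmin > len(s):
        return out
    for members, block in _grouped(seqs, lmin):
        out[members] = _batch_suffix_of_query(block, s, lmin)
    return out
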