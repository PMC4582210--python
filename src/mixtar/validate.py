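"""Long-read validation of candidate tandem-repeat patterns.

A candidate pattern p is accepted only if at least two adjacent copies of
it can be located in at least one long read.  Long reads are too erroneous
for exact matching, so the test is score-based: a search string s (a run of
concatenated copies of p, long enough to contain the anchor k-mer) is
aligned semi-globally against a window of the read around each exact
occurrence of the anchor, and the per-base score ratio t/|s| must stay at
or above tau percent.  While the ratio holds but s does not yet contain
two full copies (occ(p+p, s) = 0), s grows by one more copy of p and the
test repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .align import semiglobal_max
from .cycle_analysis import PatternCandidate
from .io import ReadSet, count_occurrences

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationParams:
    """tau is a percentage: the attempt fails when t/|s| < tau/100.

    The window factor is fixed at 2: insertions dominate long-read errors,
    so a window of length 2|s| around the anchor leaves room for the true
    copy region even when it is stretched by insertions.
    """

    tau: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 100:
            raise ValueError("tau must be in (0, 100]")


@dataclass(frozen=True)
class ValidationEvidence:
    read_id: str
    pos: int            # 0-based anchor position in the read
    score: int
    s_length: int


@dataclass(frozen=True)
class ValidatedPattern:
    pattern: str
    status: str  # "validated" | "rejected"
    evidence: Optional[ValidationEvidence] = None
    reason: Optional[str] = None

    @property
    def is_validated(self) -> bool:
        return self.status == "validated"


def anchored_search_string(p: str, v: str) -> str:
    """Shortest concatenation of copies of p containing the anchor v.

    v is a k-mer of the repeat spelled by p's source cycle, so it occurs in
    p itself, spans a copy boundary, or (when |p| < k) spans several
    copies; a bounded number of concatenations always suffices.
    """
    max_m = -(-(len(v) + len(p)) // len(p)) + 1  # ceil + 1
    s = p
    m = 1
    while count_occurrences(v, s) == 0:
        m += 1
        if m > max_m:
            raise RuntimeError(
                f"anchor {v!r} not found in {max_m} concatenations of {p!r}; "
                "candidate and anchor are inconsistent"
            )
        s += p
    return s


def _attempt(
    s0: str, p: str, r: str, pos: int, tau: float
) -> Optional[tuple[int, int]]:
    """Grow-and-score loop at one anchor position.

    Returns (score, |s|) when the pattern is validated here, else None.
    """
    s = s0
    while len(s) <= 2 * len(r):
        start = max(0, pos - len(s))
        window = r[start : start + 2 * len(s)]
        if len(window) < len(s):
            return None
        t = semiglobal_max(s, window)
        if t / len(s) < tau / 100.0:
            return None
        if count_occurrences(p + p, s) > 0:
            return (t, len(s))
        s += p
    logger.debug("search string outgrew read (|r|=%d); attempt abandoned", len(r))
    return None


def validate_pattern(
    cand: PatternCandidate,
    lr: ReadSet,
    params: ValidationParams,
) -> ValidatedPattern:
    """Search the long reads for two adjacent approximate copies of a pattern.

    Only reads containing an exact occurrence of the candidate's anchor
    k-mer are examined; anchor positions are tried left to right and the
    first success wins.
    """
    p, v = cand.pattern, cand.anchor
    s0 = anchored_search_string(p, v)
    anchored_any = False
    for read in lr:
        r = read.sequence
        pos = r.find(v)
        while pos != -1:
            anchored_any = True
            hit = _attempt(s0, p, r, pos, params.tau)
            if hit is not None:
                score, s_len = hit
                return ValidatedPattern(
                    pattern=p,
                    status="validated",
                    evidence=ValidationEvidence(read.identifier, pos, score, s_len),
                )
            pos = r.find(v, pos + 1)
    reason = "score below threshold" if anchored_any else "no anchor occurrence"
    return ValidatedPattern(pattern=p, status="rejected", reason=reason)
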