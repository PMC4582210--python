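"""Comparison of detected tandem repeats against a truth set.

The DNA strand of assembled contigs is unknown, so a repeat and its
reverse complement count as the same repeat: identities are canonical
forms, minimal over all rotations of the pattern and of its reverse
complement.  A truth repeat is fully detected (TP) when some detected
repeat's sequence contains it in either orientation; partially detected
(TPi) when a detected repeat with the same canonical pattern covers only
part of it; missed (FN) otherwise.  A detected repeat whose sequence does
not occur anywhere in the target sequence D, in either orientation, is a
false positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import reverse_complement
from .trfind import TandemRepeat, canonical_pattern

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    tpi: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tpi, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float:
        denom = self.tp + self.tpi + self.fp
        if denom == 0:
            logger.info("precision denominator 0; reporting 1 (vacuous)")
            return 1.0
        return (self.tp + self.tpi) / denom

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.tpi + self.fn
        if denom == 0:
            logger.info("sensitivity denominator 0; reporting 1 (vacuous)")
            return 1.0
        return (self.tp + self.tpi) / denom


def canonical_tr(t: TandemRepeat) -> tuple[str, str]:
    """Strand/rotation-invariant identity: (canonical pattern, canonical
    orientation of the repeat sequence)."""
    return (
        canonical_pattern(t.pattern),
        min(t.sequence, reverse_complement(t.sequence)),
    )


def _occurs_either_strand(needle: str, haystack: str) -> bool:
    return needle in haystack or reverse_complement(needle) in haystack


def classify_detections(
    detected: list[TandemRepeat],
    truth: list[TandemRepeat],
    target: str,
) -> EvaluationReport:
    """Count TP / TPi / FN / FP for a detected set against a truth set.

    ``target`` is the DNA sequence D the truth repeats live on; false
    positives are detections whose repeat sequence does not occur in D in
    either orientation.  A detected repeat credits at most one truth
    repeat (longest truth first), and a truth repeat is credited by at
    most one detection.
    """
    tp = tpi = fn = 0
    detected = sorted(
        detected, key=lambda d: (-len(d.sequence), d.sequence)
    )
    credited: set[int] = set()
    for t in sorted(truth, key=lambda t: (-len(t.sequence), t.sequence)):
        t_canon_pat = canonical_pattern(t.pattern)
        full_hit = None
        partial_hit = None
        for i, d in enumerate(detected):
            if i in credited:
                continue
            if _occurs_either_strand(t.sequence, d.sequence):
                full_hit = i
                break
            if (
                partial_hit is None
                and canonical_pattern(d.pattern) == t_canon_pat
                and d.copy_number < t.copy_number
                and _occurs_either_strand(d.sequence, t.sequence)
            ):
                partial_hit = i
        if full_hit is not None:
            tp += 1
            credited.add(full_hit)
        elif partial_hit is not None:
            tpi += 1
            credited.add(partial_hit)
        else:
            fn += 1

    fp = sum(
        1 for d in detected if not _occurs_either_strand(d.sequence, target)
    )
    return EvaluationReport(tp=tp, tpi=tpi, fn=fn, fp=fp)


def precision_sensitivity(r: EvaluationReport) -> tuple[float, float]:
    return r.precision, r.sensitivity


def dedupe_canonical(detected: list[TandemRepeat]) -> list[TandemRepeat]:
    """Collapse detections equal under the canonical form, keeping the
    first (detections sorted by descending length beforehand keep the most
    complete representative)."""
    seen: set[tuple[str, str]] = set()
    out: list[TandemRepeat] = []
    for d in sorted(detected, key=lambda d: (-len(d.sequence), d.sequence)):
        key = canonical_tr(d)
        if key not in seen:
            seen.add(key)
            out.append(d)
    return out
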