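"""Synthetic genomes and read sets with planted tandem repeats.

All test inputs are generated here: a random background sequence with
primitive tandem-repeat patterns planted at non-overlapping, recorded loci,
then short reads (substitution errors, the Illumina regime) and long reads
(insertion-dominated errors, the PacBio regime) sampled from it.  Every
generator is deterministic under its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .io import Read, ReadSet
from .trfind import TandemRepeat, is_primitive

BASES = "ACGT"


@dataclass(frozen=True)
class TRSpec:
    """What to plant: pattern lengths, copy numbers, mutation level."""

    n_tr: int = 10
    pattern_len_range: tuple[int, int] = (5, 20)
    copy_number_range: tuple[int, int] = (3, 6)
    atr_mutation_rate: float = 0.0  # per-copy substitution probability
    min_gap: int = 300              # minimum spacing between planted loci

    def __post_init__(self) -> None:
        if self.pattern_len_range[0] < 2:
            raise ValueError("patterns must have length >= 2")
        if self.copy_number_range[0] < 2:
            raise ValueError("need at least two copies")


@dataclass(frozen=True)
class ErrorModel:
    """Error structure of the two read types.

    Short reads carry substitutions only.  Long-read errors are dominated
    by insertions (70% of errors); the remainder splits 2:1 between
    deletions and substitutions.
    """

    short_sub_rate: float = 0.01
    long_error_rate: float = 0.16
    long_insertion_frac: float = 0.70

    def __post_init__(self) -> None:
        for v in (self.short_sub_rate, self.long_error_rate, self.long_insertion_frac):
            if not 0 <= v <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _random_primitive_pattern(rng: random.Random, length: int) -> str:
    while True:
        p = "".join(rng.choice(BASES) for _ in range(length))
        if is_primitive(p):
            return p


def _mutate_copy(rng: random.Random, copy: str, rate: float) -> str:
    if rate <= 0:
        return copy
    out = []
    for c in copy:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


def generate_genome(
    length: int, spec: TRSpec, seed: int
) -> tuple[str, list[TandemRepeat]]:
    """Random genome with planted tandem repeats and their truth records.

    Loci are spaced by at least ``min_gap`` background bases; the bases
    directly flanking each repeat are resampled so the planted run is
    maximal at its period (the recorded copy number is exact), and flank
    windows accidentally periodic at the planted period are rejected.
    """
    rng = random.Random(seed)
    spans: list[tuple[str, str, float]] = []  # (repeat sequence, pattern, cn)
    total_tr = 0
    for _ in range(spec.n_tr):
        plen = rng.randint(*spec.pattern_len_range)
        cn = rng.randint(*spec.copy_number_range)
        p = _random_primitive_pattern(rng, plen)
        copies = [
            _mutate_copy(rng, p, spec.atr_mutation_rate) if i > 0 else p
            for i in range(cn)
        ]
        seq = "".join(copies)
        spans.append((seq, p, float(cn)))
        total_tr += len(seq)
    if total_tr + (spec.n_tr + 1) * spec.min_gap > length:
        raise ValueError("genome too short for the requested repeats")

    # Place repeats at evenly jittered, non-overlapping offsets.
    free = length - total_tr
    gaps = _random_partition(rng, free, spec.n_tr + 1, spec.min_gap)
    pieces: list[str] = []
    truth: list[TandemRepeat] = []
    pos = 0
    for i, (seq, p, cn) in enumerate(spans):
        flank = _background(rng, gaps[i])
        pieces.append(flank)
        pos += len(flank)
        pieces.append(seq)
        truth.append(
            TandemRepeat(
                pattern=p,
                copy_number=cn,
                sequence=seq,
                source="genome",
                start=pos + 1,
                end=pos + len(seq),
                kind="ETR" if spec.atr_mutation_rate == 0 else "ATR",
            )
        )
        pos += len(seq)
    pieces.append(_background(rng, gaps[-1]))
    genome = list("".join(pieces))

    # Enforce maximality: the base before each locus must break the period
    # leftwards, the base after must break it rightwards.
    for t in truth:
        q = len(t.pattern)
        s0, e0 = t.start - 1, t.end  # 0-based [s0, e0)
        if s0 - 1 >= 0:
            while genome[s0 - 1] == genome[s0 + q - 1]:
                genome[s0 - 1] = rng.choice(BASES)
        if e0 < len(genome):
            while genome[e0] == genome[e0 - q]:
                genome[e0] = rng.choice(BASES)
    return "".join(genome), truth


def _random_partition(
    rng: random.Random, total: int, parts: int, minimum: int
) -> list[int]:
    """Split ``total`` into ``parts`` integers each >= minimum."""
    spare = total - parts * minimum
    cuts = sorted(rng.randint(0, spare) for _ in range(parts - 1))
    sizes = []
    prev = 0
    for c in cuts + [spare]:
        sizes.append(minimum + c - prev)
        prev = c
    return sizes


def _background(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def simulate_short_reads(
    genome: str,
    coverage: float,
    model: ErrorModel,
    seed: int,
    read_len: int = 100,
) -> ReadSet:
    """Uniformly placed single-end short reads with substitution errors.

    The read count is round(coverage * |genome| / read_len); the returned
    set records ``coverage`` as its depth.
    """
    if read_len > len(genome):
        raise ValueError("read length exceeds genome length")
    rng = random.Random(seed)
    n_reads = round(coverage * len(genome) / read_len)
    # placements drawn before errors: the same seed yields the same read
    # positions regardless of the error model
    starts = [rng.randint(0, len(genome) - read_len) for _ in range(n_reads)]
    reads: list[Read] = []
    for i, start in enumerate(starts):
        seq = genome[start : start + read_len]
        if model.short_sub_rate > 0:
            seq = _mutate_copy(rng, seq, model.short_sub_rate)
        reads.append(Read(f"sr{i}", seq))
    return ReadSet(reads, coverage_depth=coverage, rc_augmented=False)


def _corrupt_long(rng: random.Random, seq: str, model: ErrorModel) -> str:
    e = model.long_error_rate
    if e <= 0:
        return seq
    p_ins = model.long_insertion_frac
    p_del = (1 - p_ins) * 2 / 3
    out: list[str] = []
    for c in seq:
        if rng.random() < e:
            u = rng.random()
            if u < p_ins:
                out.append(rng.choice(BASES))  # insertion before the base
                out.append(c)
            elif u < p_ins + p_del:
                pass  # deletion
            else:
                out.append(rng.choice([b for b in BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


def simulate_long_reads(
    genome: str,
    coverage: float,
    model: ErrorModel,
    seed: int,
    len_range: tuple[int, int] = (1000, 20000),
) -> ReadSet:
    """Long reads with insertion-dominated errors.

    Lengths are uniform in ``len_range`` clipped to the genome length;
    reads are drawn until the total sampled bases reach
    coverage * |genome|.
    """
    rng = random.Random(seed)
    lo = min(len_range[0], len(genome))
    hi = min(len_range[1], len(genome))
    target = coverage * len(genome)
    # placements drawn before errors, as for the short reads
    placements: list[tuple[int, int]] = []
    total = 0
    while total < target:
        ln = rng.randint(lo, hi)
        placements.append((rng.randint(0, len(genome) - ln), ln))
        total += ln
    reads: list[Read] = []
    for i, (start, ln) in enumerate(placements):
        seq = _corrupt_long(rng, genome[start : start + ln], model)
        if seq:
            reads.append(Read(f"lr{i}", seq))
    return ReadSet(reads, coverage_depth=coverage, rc_augmented=False)
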