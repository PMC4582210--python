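"""Read sets, the DNA alphabet contract, and occurrence counting.

Short reads (SR) and long reads (LR) are both held as :class:`ReadSet`
objects carrying the sequencing coverage depth ``delta`` used downstream to
convert k-mer counts into arc frequencies.  The detection pipeline works on
a read set *together with its reverse complements*, so augmentation is an
explicit, one-shot operation tracked by the ``rc_augmented`` flag.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AmbiguousBaseError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class ParseError(ValueError):
    """A sequence file is malformed."""


@dataclass(frozen=True)
class Read:
    """A named DNA string over the alphabet {A, C, G, T}."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.identifier!r}: empty sequence")
        if not DNA_ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise AmbiguousBaseError(
                f"read {self.identifier!r}: non-ACGT characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """A collection of reads plus the coverage depth they were sequenced at.

    Parameters
    ----------
    reads
        Member reads, order preserved from the source file.
    coverage_depth
        Average number of reads covering a genome position (delta).  Not
        estimated from the data; supplied by the caller or configuration.
    rc_augmented
        True once each read's reverse complement has been appended.
    """

    reads: list[Read] = field(default_factory=list)
    coverage_depth: float = 1.0
    rc_augmented: bool = False

    def __post_init__(self) -> None:
        if self.coverage_depth <= 0:
            raise ValueError("coverage depth must be positive")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def sequences(self) -> Iterator[str]:
        for r in self.reads:
            yield r.sequence


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string; an involution on ACGT strings."""
    if not DNA_ALPHABET.issuperset(s):
        bad = sorted(set(s) - DNA_ALPHABET)
        raise AmbiguousBaseError(f"non-ACGT characters {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Union[str, Path]) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def parse_reads(
    path: Union[str, Path],
    fmt: str | None = None,
    *,
    coverage_depth: float = 1.0,
    ambiguous: str = "reject",
    seed: int = 0,
) -> ReadSet:
    """Parse a FASTA or FASTQ file (optionally gzipped) into a ReadSet.

    FASTQ base qualities are discarded: nothing downstream consumes them.

    Parameters
    ----------
    fmt
        "fasta" or "fastq"; inferred from the file name when omitted.
    ambiguous
        Policy for non-ACGT characters: "reject" raises, "mask" replaces
        each offending character with a base drawn from a seeded RNG.
    """
    if ambiguous not in {"reject", "mask"}:
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    fmt = fmt or _sniff_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {fmt!r}")
    rng = random.Random(seed)
    reads: list[Read] = []
    with _open_text(path) as handle:
        try:
            for idx, record in enumerate(SeqIO.parse(handle, fmt)):
                seq = str(record.seq).upper()
                if not DNA_ALPHABET.issuperset(seq):
                    if ambiguous == "reject":
                        raise AmbiguousBaseError(
                            f"record {idx} ({record.id!r}): non-ACGT characters"
                        )
                    seq = "".join(
                        c if c in DNA_ALPHABET else rng.choice("ACGT")
                        for c in seq
                    )
                reads.append(Read(record.id, seq))
        except ValueError as exc:
            if isinstance(exc, AmbiguousBaseError):
                raise
            raise ParseError(
                f"malformed {fmt} record at index {len(reads)}: {exc}"
            ) from exc
    return ReadSet(reads, coverage_depth=coverage_depth, rc_augmented=False)


def augment_with_reverse_complements(rs: ReadSet) -> ReadSet:
    """Append the reverse complement of every read.

    The result has exactly twice as many records; self-reverse-complementary
    reads are deliberately kept twice so that occurrence counting over the
    augmented set is uniform.  Raises if ``rs`` is already augmented, which
    would silently double every count.
    """
    if rs.rc_augmented:
        raise ValueError("read set is already reverse-complement augmented")
    rc_reads = [Read(r.identifier + "_rc", reverse_complement(r.sequence)) for r in rs]
    return ReadSet(
        list(rs.reads) + rc_reads,
        coverage_depth=rs.coverage_depth,
        rc_augmented=True,
    )


def count_occurrences(s: str, source: Union[str, ReadSet, Iterable[str]]) -> int:
    """Number of (possibly overlapping) occurrences of ``s``.

    For a ReadSet or iterable of strings, sums the per-string counts.
    """
    if not s:
        raise ValueError("query string must be non-empty")
    if isinstance(source, str):
        return _count_in_string(s, source)
    if isinstance(source, ReadSet):
        return sum(_count_in_string(s, t) for t in source.sequences())
    return sum(_count_in_string(s, t) for t in source)


def _count_in_string(s: str, t: str) -> int:
    # str.count skips overlaps; scan with str.find instead.
    n = 0
    i = t.find(s)
    while i != -1:
        n += 1
        i = t.find(s, i + 1)
    return n


def write_fasta(path: Union[str, Path], records: Iterable[tuple[str, str]]) -> None:
    """Write (identifier, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
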