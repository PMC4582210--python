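"""Local greedy assembly of the short reads around validated patterns.

For each validated pattern p, the short reads overlapping a small run of
copies of p (the set SR_p) are assembled into contigs by repeatedly merging
the pair with the highest overlap alignment score.  Contigs without any
tandem repeat are dropped; a contig whose repeat touches a contig end is a
*seed*, presumed incomplete, and is extended with reads not claimed by any
pattern before the repeat search is re-run on it.

The assembler is intentionally simple: content-based tie-breaking makes the
output invariant to read order, and approximate overlaps are admitted only
through the +-1 alignment scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence


from .align import (
    directional_overlap_scores,
    mutual_overlap_scores,
    overlap_max_arg,
    overlap_scores_prefix,
    overlap_scores_suffix,
)
from .io import Read, ReadSet
from .trfind import TandemRepeat

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblyParams:
    """Knobs of the read-selection and greedy-merging stages.

    gamma
        Minimum length of the pattern concatenation used to fish reads
        out of SR (and the minimum overlap for that fishing score).
    theta
        Minimum overlap alignment score for a read to join SR_p and for a
        merge to be accepted.
    min_merge_overlap
        Minimum overlap length for contig merging; at least k is
        recommended so that merges are no looser than graph arcs.
    edge_margin
        A repeat within this many bases of a contig end marks the contig
        as a seed.
    max_extension
        Cap on the bases a seed may grow per side during extension; a
        missing part of a repeat is short, so unbounded chromosome-walking
        is pointless.
    """

    gamma: int = 10
    theta: int = 10
    min_merge_overlap: int = 17
    edge_margin: int = 17
    max_extension: int = 300
    merge_score: int | None = None

    def __post_init__(self) -> None:
        if self.gamma < 2 or self.theta < 1 or self.min_merge_overlap < 2:
            raise ValueError("invalid assembly parameters")

    @property
    def merge_score_min(self) -> int:
        """Acceptance score for a merge.

        theta alone (tuned for fishing reads out of SR) would accept
        20-bp overlaps at 25% mismatch, and loci with similar patterns
        provide pattern-length stretches of cross-locus similarity; both
        chimerise contigs.  True merge overlaps at reasonable coverage
        run close to the read length, so the default floor of twice the
        minimum overlap length separates them sharply.  Truncation this
        causes at cluster boundaries is repaired by seed extension."""
        if self.merge_score is not None:
            return self.merge_score
        return max(self.theta, 2 * self.min_merge_overlap)


@dataclass(frozen=True)
class Contig:
    sequence: str
    read_ids: tuple[str, ...]
    origin_pattern: str = ""
    is_seed: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def pattern_probe(p: str, gamma: int) -> str:
    """Shortest concatenation of copies of p of length >= gamma."""
    s = p
    while len(s) < gamma:
        s += p
    return s


def select_overlapping_reads(
    p: str, sr: ReadSet, params: AssemblyParams
) -> list[Read]:
    """The subset SR_p of short reads overlapping the pattern probe.

    A read joins when the better of the two overlap orientations against
    the probe scores at least theta (overlaps no shorter than gamma).
    """
    s = pattern_probe(p, params.gamma)
    seqs = [r.sequence for r in sr]
    scores = mutual_overlap_scores(s, seqs, params.gamma)
    return [r for r, t in zip(sr, scores) if t >= params.theta]


def _dedupe(reads: Iterable[Read]) -> list[tuple[str, tuple[str, ...]]]:
    """Collapse identical sequences, keeping all identifiers, sorted."""
    groups: dict[str, list[str]] = {}
    for r in reads:
        groups.setdefault(r.sequence, []).append(r.identifier)
    return [(seq, tuple(sorted(ids))) for seq, ids in sorted(groups.items())]


def greedy_assemble(
    reads: Sequence[Read],
    params: AssemblyParams,
    *,
    origin_pattern: str = "",
) -> list[Contig]:
    """Merge reads into contigs, best-scoring overlap first.

    The ordered score of (i -> j) is the overlap of a prefix of j against
    a suffix of i (merge: i followed by j's tail).  Merging stops when no
    ordered pair scores >= theta.  Ties prefer the longer overlap, then
    the lexicographically smaller merged sequence.
    """
    if not reads:
        return []
    lmin = params.min_merge_overlap
    units = _dedupe(reads)
    seqs = [seq for seq, _ in units]
    ids: list[tuple[str, ...]] = [rid for _, rid in units]
    alive = list(range(len(seqs)))
    # score[i][j] = ordered overlap score i -> j
    score: dict[int, dict[int, int]] = {i: {} for i in alive}

    def compute_scores_for(q: int, others: list[int]) -> None:
        if not others:
            return
        fwd, rev = directional_overlap_scores(
            seqs[q], [seqs[o] for o in others], lmin
        )
        for o, f, r in zip(others, fwd, rev):
            score[o][q] = int(f)  # prefix of q vs suffix of o
            score[q][o] = int(r)  # prefix of o vs suffix of q

    for pos, i in enumerate(alive):
        compute_scores_for(i, alive[pos + 1 :])

    while len(alive) > 1:
        best: Optional[tuple[int, int, int]] = None  # (score, i, j)
        for i in alive:
            row = score[i]
            for j in alive:
                if j == i:
                    continue
                t = row.get(j, -(10**9))
                if t >= params.merge_score_min and (best is None or t > best[0]):
                    best = (t, i, j)
        if best is None:
            break
        t_best = best[0]
        # Tie-break among all pairs at the best score.
        candidates = []
        for i in alive:
            for j in alive:
                if i != j and score[i].get(j, -(10**9)) == t_best:
                    s_merge, pref = overlap_max_arg(seqs[j], seqs[i], lmin)
                    merged = seqs[i] + seqs[j][pref:]
                    candidates.append((-pref, merged, i, j))
        candidates.sort()
        _, merged, i, j = candidates[0]
        new = len(seqs)
        seqs.append(merged)
        ids.append(tuple(sorted(set(ids[i]) | set(ids[j]))))
        score[new] = {}
        alive = [a for a in alive if a not in (i, j)]
        for a in alive:
            score[a].pop(i, None)
            score[a].pop(j, None)
        compute_scores_for(new, alive)
        alive.append(new)

    return [
        Contig(sequence=seqs[a], read_ids=ids[a], origin_pattern=origin_pattern)
        for a in sorted(alive, key=lambda a: seqs[a])
    ]


def contigs_to_seeds(
    contigs: Sequence[Contig],
    tr_hits: Sequence[Sequence[TandemRepeat]],
    params: AssemblyParams,
) -> tuple[list[Contig], list[Contig]]:
    """Split contigs into final contigs and seeds; drop repeat-free ones.

    A contig is a seed when some repeat starts or ends within
    ``edge_margin`` bases of a contig end — the repeat is then presumed
    truncated by the assembly.
    """
    kept: list[Contig] = []
    seeds: list[Contig] = []
    for contig, hits in zip(contigs, tr_hits):
        if not hits:
            continue
        m = params.edge_margin
        n = len(contig.sequence)
        at_edge = any(
            (t.start - 1) <= m or (n - t.end) <= m for t in hits
        )
        if at_edge:
            seeds.append(replace(contig, is_seed=True))
        else:
            kept.append(contig)
    return kept, seeds


class _KmerPrefilter:
    """Exact j-mer index over a read pool, used to shortlist extension
    candidates; j never exceeds the merge overlap, so an error-free read
    overlapping by >= min_merge_overlap is always shortlisted."""

    def __init__(self, reads: Sequence[Read], j: int):
        self.j = j
        self.reads = list(reads)
        self.index: dict[str, set[int]] = {}
        for idx, r in enumerate(self.reads):
            seq = r.sequence
            for i in range(len(seq) - j + 1):
                self.index.setdefault(seq[i : i + j], set()).add(idx)

    def candidates(self, region: str) -> list[int]:
        hits: set[int] = set()
        for i in range(len(region) - self.j + 1):
            hits |= self.index.get(region[i : i + self.j], set())
        return sorted(hits)


def extend_seeds(
    seeds: Sequence[Contig],
    sr: ReadSet,
    used_ids: set[str],
    params: AssemblyParams,
) -> list[Contig]:
    """Greedily grow each seed with reads not claimed by any pattern.

    Each seed is extended independently with the pool SR minus the union
    of all SR_p, one best-scoring extending merge at a time, until no read
    scores >= merge_score_min at an end or the per-side cap is reached.
    Seeds never shrink.
    """
    pool = sorted(
        (r for r in sr if r.identifier not in used_ids),
        key=lambda r: (r.sequence, r.identifier),
    )
    if not pool or not seeds:
        return list(seeds)
    j = min(12, params.min_merge_overlap)
    prefilter = _KmerPrefilter(pool, j)
    lmin = params.min_merge_overlap
    max_read = max(len(r.sequence) for r in pool)
    window = max_read + 60  # an end overlap never reaches deeper than this
    out: list[Contig] = []
    for seed in seeds:
        seq = seed.sequence
        members = set(seed.read_ids)
        grown_left = 0
        grown_right = 0
        banned: set[int] = set()
        while grown_left <= params.max_extension or grown_right <= params.max_extension:
            w_left = seq[: min(len(seq), window)]
            w_right = seq[-min(len(seq), window):]
            cand = [
                c
                for c in set(prefilter.candidates(w_left))
                | set(prefilter.candidates(w_right))
                if c not in banned
            ]
            if not cand:
                break
            cand_seqs = [pool[c].sequence for c in cand]
            # prefix of seed vs suffix of read -> read extends LEFT
            left_scores = overlap_scores_prefix(w_left, cand_seqs, lmin)
            # prefix of read vs suffix of seed -> read extends RIGHT
            right_scores = overlap_scores_suffix(w_right, cand_seqs, lmin)
            best = None  # (score, side, c)
            for c, f, r in zip(cand, left_scores, right_scores):
                if grown_left <= params.max_extension and f >= params.merge_score_min:
                    if best is None or f > best[0]:
                        best = (int(f), "L", c)
                if grown_right <= params.max_extension and r >= params.merge_score_min:
                    if best is None or r > best[0]:
                        best = (int(r), "R", c)
            if best is None:
                break
            _, side, c = best
            read_seq = pool[c].sequence
            if side == "L":
                _, pref = overlap_max_arg(w_left, read_seq, lmin)
                new_seq = read_seq + seq[pref:]
                gained = len(new_seq) - len(seq)
                grown_left += max(gained, 0)
            else:
                _, pref = overlap_max_arg(read_seq, w_right, lmin)
                new_seq = seq + read_seq[pref:]
                gained = len(new_seq) - len(seq)
                grown_right += max(gained, 0)
            banned.add(c)
            if gained <= 0:
                continue
            seq = new_seq
            members.add(pool[c].identifier)
        out.append(
            Contig(
                sequence=seq,
                read_ids=tuple(sorted(members)),
                origin_pattern=seed.origin_pattern,
                is_seed=True,
            )
        )
    return out
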