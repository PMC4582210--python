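"""End-to-end tandem repeat detection: graph, cycles, validation, assembly.

This module wires the three stages together behind one configuration
object:

1. **Pattern detection** — build the de Bruijn graph from the
   reverse-complement-augmented short reads, enumerate elementary cycles
   under the search budget, clean each cycle's arc frequencies for every
   flanking-arc couple, keep the cycles whose cleaned frequencies show the
   x / x - 1 tandem-repeat signature, and spell their patterns.
2. **Pattern validation** — require at least two adjacent approximate
   copies of each pattern in at least one long read.
3. **Sequence assembly** — per validated pattern, select the overlapping
   short reads, assemble them greedily, locate repeats in the contigs,
   extend seed contigs whose repeat touches a contig end, and report the
   repeats found.

Detection itself is deterministic; all randomness lives in the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import assemble as asm
from .assemble import AssemblyParams, Contig
from .cycle_analysis import (
    PatternCandidate,
    check_arc_frequency_property,
    clean_cycle_frequencies,
    flanking_arcs,
    make_candidate,
)
from .cycles import CycleRecord, SearchBudget, find_elementary_cycles
from .debruijn import (
    build_graph,
    eligible_start_vertices,
    long_read_kmer_index,
)
from .evaluate import dedupe_canonical
from .io import ReadSet, augment_with_reverse_complements, count_occurrences
from .trfind import (
    TandemRepeat,
    canonical_pattern,
    find_approx_tr,
    find_exact_tr,
)
from .validate import ValidatedPattern, ValidationParams, validate_pattern

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a detection run in one place.

    Defaults mirror a 100-bp short-read, 20x-coverage setting; sigma
    defaults to half the coverage depth when left unset.
    """

    k: int = 17
    delta: float = 20.0
    sigma: int | None = None
    eta: int = 10_000
    lambda_max_long: int = 100
    lambda_max_short: int = 20
    tau: float = 10.0
    gamma: int = 10
    theta: int = 10
    rho: float = 0.25
    coverage_tol: float = 0.5
    min_merge_overlap: int | None = None   # defaults to k
    edge_margin: int | None = None         # defaults to k
    copy_score_frac: float = 0.8
    max_couples_per_cycle: int = 64
    max_cycles: int = 100_000
    strict_algo1: bool = True
    min_read_support: int = 2  # physical short reads containing a reported repeat

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.lambda_max_short > self.lambda_max_long:
            raise ValueError("lambda_max_short must not exceed lambda_max_long")
        if self.sigma is None:
            self.sigma = max(2, round(self.delta / 2))
        if self.min_merge_overlap is None:
            # Short merge overlaps inside a repeat are phase-ambiguous and
            # collapse copies; a floor of ~20 bp (and never below k) keeps
            # merges anchored while deep true overlaps still dominate.
            self.min_merge_overlap = max(self.k, 20)
        if self.edge_margin is None:
            self.edge_margin = self.k

    @property
    def budget(self) -> SearchBudget:
        return SearchBudget(
            eta=self.eta,
            lambda_max_long=self.lambda_max_long,
            lambda_max_short=self.lambda_max_short,
        )

    @property
    def assembly_params(self) -> AssemblyParams:
        return AssemblyParams(
            gamma=self.gamma,
            theta=self.theta,
            min_merge_overlap=self.min_merge_overlap,
            edge_margin=self.edge_margin,
        )


@dataclass
class DetectionResult:
    candidates: list[PatternCandidate]
    validations: list[ValidatedPattern]
    contigs: list[Contig]
    repeats: list[TandemRepeat]
    cycles_found: int = 0

    @property
    def validated_patterns(self) -> list[str]:
        return [v.pattern for v in self.validations if v.is_validated]


def detect_patterns(
    sr: ReadSet, lr: ReadSet, cfg: RunConfig
) -> tuple[list[PatternCandidate], int]:
    """Stage 1: cycle-based pattern candidates from the short reads.

    ``sr`` and ``lr`` must already be reverse-complement augmented.
    Candidates are deduplicated by the canonical (rotation- and
    strand-invariant) form of their pattern.
    """
    g = build_graph(sr, cfg.k)
    lr_index = long_read_kmer_index(lr, cfg.k)
    starts = eligible_start_vertices(g, cfg.sigma, lr_index)
    logger.info(
        "graph: %d vertices, %d arcs, %d eligible starts",
        len(g.vertices), len(g.arcs), len(starts),
    )
    cycles = find_elementary_cycles(
        g, starts, cfg.budget, cfg.sigma, max_cycles=cfg.max_cycles
    )

    by_canon: dict[str, PatternCandidate] = {}
    for cyc in cycles:
        cand = _analyse_cycle(g, cyc, cfg)
        if cand is None:
            continue
        key = canonical_pattern(cand.pattern)
        if key not in by_canon:
            by_canon[key] = cand
    candidates = [by_canon[k] for k in sorted(by_canon)]
    logger.info("%d cycles -> %d pattern candidates", len(cycles), len(candidates))
    return candidates, len(cycles)


def _analyse_cycle(
    g, cyc: CycleRecord, cfg: RunConfig
) -> PatternCandidate | None:
    """Frequency-clean one cycle over its flanking-arc couples and spell a
    candidate from the first couple satisfying the repeat signature."""
    fl = flanking_arcs(g, cyc)
    if fl.a_in and fl.a_out:
        # Couples in descending flanking-arc frequency order.
        a_in_sorted = sorted(fl.a_in, key=lambda a: (-g.arcs[a], a))
        a_out_sorted = sorted(fl.a_out, key=lambda a: (-g.arcs[a], a))
        couples = [
            (ai, ao) for ai in a_in_sorted for ao in a_out_sorted
        ][: cfg.max_couples_per_cycle]
    elif not fl.a_in and not fl.a_out:
        couples = [(None, None)]
    else:
        # One-sided flanks: try each arc as the marker, the other side open.
        couples = (
            [(ai, None) for ai in fl.a_in]
            + [(None, ao) for ao in fl.a_out]
        )[: cfg.max_couples_per_cycle]

    for couple in couples:
        cc = clean_cycle_frequencies(
            g, cyc, fl, couple, strict=cfg.strict_algo1
        )
        verdict = check_arc_frequency_property(cc, cfg.rho, cfg.coverage_tol)
        if verdict.passes:
            v1 = verdict.v1 if verdict.v1 is not None else cyc.start_vertex
            cand = make_candidate(cyc, v1, x=verdict.x)
            if cand is not None:
                return cand
    return None


def validate_candidates(
    candidates: list[PatternCandidate], lr: ReadSet, cfg: RunConfig
) -> list[ValidatedPattern]:
    """Stage 2: long-read validation of every candidate."""
    params = ValidationParams(tau=cfg.tau)
    return [validate_pattern(c, lr, params) for c in candidates]


def assemble_repeats(
    validated: list[str], sr: ReadSet, cfg: RunConfig
) -> tuple[list[Contig], list[TandemRepeat]]:
    """Stage 3: local assemblies and repeat extraction.

    Returns the retained contigs (extended seeds included) and the
    deduplicated repeats found in them.
    """
    params = cfg.assembly_params
    pmax = cfg.lambda_max_long
    subsets: dict[str, list] = {}
    for p in sorted(set(validated)):
        subsets[p] = asm.select_overlapping_reads(p, sr, params)
    used_ids = {r.identifier for reads in subsets.values() for r in reads}

    all_contigs: list[Contig] = []
    all_seeds: list[Contig] = []
    for p, reads in subsets.items():
        if not reads:
            continue
        contigs = asm.greedy_assemble(reads, params, origin_pattern=p)
        hits = [
            find_approx_tr(
                c.sequence, 2, pmax, cfg.copy_score_frac, source=p
            )
            for c in contigs
        ]
        kept, seeds = asm.contigs_to_seeds(contigs, hits, params)
        all_contigs.extend(kept)
        all_seeds.extend(seeds)

    extended = asm.extend_seeds(all_seeds, sr, used_ids, params)
    final_contigs = all_contigs + extended

    repeats: list[TandemRepeat] = []
    for c in final_contigs:
        repeats.extend(
            find_approx_tr(
                c.sequence, 2, pmax, cfg.copy_score_frac,
                source=c.origin_pattern,
            )
        )
        # Exact cores are reported alongside approximate extensions: when
        # an extension absorbed a contig error and fails read support, the
        # clean core still stands as a (partial) detection.
        repeats.extend(
            find_exact_tr(c.sequence, 2, pmax, source=c.origin_pattern)
        )
    repeats = _supported_repeats(repeats, sr, cfg.min_read_support)
    return final_contigs, dedupe_canonical(repeats)


SUPPORT_WINDOW = 30


def _supported_repeats(
    repeats: list[TandemRepeat], sr: ReadSet, min_support: int
) -> list[TandemRepeat]:
    """Drop repeats whose sequence is not read-supported along its length.

    Every window of SUPPORT_WINDOW bases of a genuine repeat is contained
    in many reads at any reasonable depth, while a repeat sequence that
    incorporates a sequencing error has an unsupported window around the
    error (only the read carrying it matches).  Windows overlap by half
    so every base is covered.  The read set is RC-augmented, so one
    physical read contributes two occurrences.
    """
    if min_support <= 0 or not repeats:
        return repeats
    haystack = "#".join(sr.sequences())
    need = 2 * min_support
    out = []
    for t in repeats:
        seq = t.sequence
        w = min(len(seq), SUPPORT_WINDOW)
        starts = list(range(0, len(seq) - w + 1, max(1, w // 2)))
        if starts[-1] != len(seq) - w:
            starts.append(len(seq) - w)
        if all(
            count_occurrences(seq[s : s + w], haystack) >= need
            for s in starts
        ):
            out.append(t)
    return out


def run_detection(sr: ReadSet, lr: ReadSet, cfg: RunConfig) -> DetectionResult:
    """Run the full pipeline on raw (non-augmented) read sets."""
    sr_aug = sr if sr.rc_augmented else augment_with_reverse_complements(sr)
    lr_aug = lr if lr.rc_augmented else augment_with_reverse_complements(lr)
    candidates, n_cycles = detect_patterns(sr_aug, lr_aug, cfg)
    validations = validate_candidates(candidates, lr_aug, cfg)
    validated = [v.pattern for v in validations if v.is_validated]
    logger.info("%d / %d candidates validated", len(validated), len(candidates))
    contigs, repeats = assemble_repeats(validated, sr_aug, cfg)
    logger.info("%d contigs, %d repeats", len(contigs), len(repeats))
    return DetectionResult(
        candidates=candidates,
        validations=validations,
        contigs=contigs,
        repeats=repeats,
        cycles_found=n_cycles,
    )
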