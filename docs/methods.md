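# Methods

## Model

A *tandem repeat* (TR) of a pattern `p` (`|p| ≥ 2`, primitive: its
smallest period equals its length) is a run `ε` of two or more adjacent
copies of `p`; copies identical to `p` give an *exact* TR (ETR),
copies merely similar (alignment score against `p` above a threshold) an
*approximate* TR (ATR). The copy number is decimal,
`cn_p = (n_p − 1) + |p_{n_p}|/|p|`, crediting a partial last copy
fractionally. All alignment scores in the package use the fixed scheme
+1 match / −1 mismatch / −1 indel; three score variants are used:
global, maximum semi-global (query vs any substring of the target), and
maximum overlap (prefix of one string vs suffix of the other, both at
least `l_min` long).

The de Bruijn graph `G^k(SR)` over the reverse-complement-augmented
short reads has one vertex per distinct k-mer (with occurrence count)
and one arc per observed (k+1)-mer, with frequency
`f(α) = occ(α, SR)/δ`, interpreted as the number of times the arc must
be traversed to assemble the genome. An ETR with `|ε| ≥ |p| + k` forms
an elementary cycle of `|p|` vertices (one per distinct leading k-mer of
`ε`), and in the repeat-only graph the arc frequencies obey the
**arc-frequency signature**: arcs on the path `v₁ → v_e` (first to last
k-mer of `ε`) share a frequency `x`, arcs on the return path share
`x − 1` — the return arcs are traversed once less than the copy count.

Strands are handled by augmentation, not canonicalisation: every read is
present together with its reverse complement, so each repeat appears as
two mirror-image cycles; candidates, contigs and reported repeats are
deduplicated by the canonical form of a pattern (lexicographic minimum
over all rotations of `p` and of its reverse complement).

## Pipeline stages and their assumptions

**Cycle search.** A depth-first elementary-path search runs from each
eligible start vertex (occ `≥ σ` in SR — screening error k-mers — and at
least one exact occurrence in the long reads, so the pattern can later
be anchored). Starts are processed in descending occurrence order and
removed from the graph afterwards (Johnson's semantics), so each cycle
is reported from its highest-occurrence eligible vertex, which becomes
the pattern's anchor. Out-arcs are explored in descending frequency.
From each start the search first looks for cycles of up to `Λmax`
vertices; once `η` arcs have been traversed with arcs still unexplored,
it restarts with the tighter limit `λmax`. Johnson's blocked-set
machinery is omitted: it is purely an acceleration for exhaustive
enumeration, and under the arc budget the search is already bounded
(equivalence with a reference enumerator is asserted in the tests on
unbudgeted small graphs).

**Frequency cleaning.** Interspersed non-tandem occurrences of (parts
of) a repeat (AIR) share k-mers with the cycle and inflate its arc
frequencies. Every pair of one input and one output flanking arc is
treated as a potential marker of the genuine repeat's entry and exit;
all other flanking arcs are attributed to AIR, and a running balance of
AIR entries minus exits is subtracted from the cycle arcs while walking
from `v₁` (two passes; a residual balance wraps around). The published
pseudocode stores the post-clamp (always zero) deficit for the second
pass; the literal form is the default and the arguably intended
pre-clamp variant is available (`strict_algo1=False`). Both agree on
every fixture used here. Cycles with both flank sides empty (isolated
repeats) are checked against the best split over all rotations; with one
side empty, each available arc is tried as the marker.

**Signature check under non-homogeneous coverage.** Read placement makes
coverage fluctuate locally, and both frequency levels of a repeat scale
with the *local* coverage `c·δ`: the observed levels are `c·x` and
`c·(x−1)`, so a flat band around `mean − 1` misclassifies genuine
repeats wherever `c` dips. The check therefore derives both levels from
the cycle itself: forward arcs must be uniform within a relative
half-width `ρ` (default 0.25) of their mean `x_f`, return arcs within
`ρ` of their mean `x_r`, and the separation `x_f − x_r` must equal the
one-traversal difference within `coverage_tol` (default 0.5 frequency
units, absorbing ±50% local-coverage excursions). At `ρ = 0` with
homogeneous coverage this reduces exactly to `forward = x`,
`return = x − 1`. Uniform cycles (separation 0) always fail. Negative
cleaned frequencies fail the couple (the cleaning arithmetic overshoots
for wrong couples; the signature is the arbiter).

**Validation.** `τ` is a percentage threshold on the per-base
semi-global score of the grown search string against a `2|s|` window of
the read around the anchor (the window is twice the search string
because long-read errors are insertion-dominated). `τ` must track the
long-read error rate: ~10 for raw 16%-error reads, ~20 for corrected
reads, and high (≥ 80) for clean reads — with a permissive `τ` a single
copy plus chance flank matches can pass, so the two-adjacent-copies test
is only sharp when `τ` matches the error regime.

**Assembly.** Read selection uses the overlap score against a probe of
concatenated copies (`|probe| ≥ γ = 10`, score `≥ ϑ = 10`; both values
follow the published tuning for 100-bp reads). Selection is end-anchored,
so the selected set consists of reads whose ends fall inside the repeat;
contigs built from it typically terminate inside the repeat, which is
precisely what the seed mechanism expects. Greedy merging accepts the
highest-scoring overlap pair repeatedly, with two guards beyond the
selection thresholds:

- *Minimum merge overlap* `max(k, 20)`: overlaps shorter than ~20 bp
  inside a repeat are phase-ambiguous (a copy-shifted overlap always
  matches more) and collapse copies.
- *Merge acceptance score* `max(ϑ, 2 × min_merge_overlap)` (i.e. 40 by
  default): `ϑ = 10` alone admits 20-bp overlaps at 25% mismatch, and
  loci with similar patterns offer pattern-length stretches of
  cross-locus similarity — both chimerise contigs. True merge overlaps
  at ≥ 20× coverage run close to the read length and clear the floor
  easily.

Contigs without any repeat are dropped; a contig whose repeat starts or
ends within `edge_margin` (default `k`) of a contig end becomes a seed
and is extended on both ends with the reads not claimed by any pattern,
one best-scoring extending merge at a time. Extension is capped at 300 bp
per side (the missing part of a repeat is at most the repeat itself plus
an anchor's worth of flank) and candidates are shortlisted by an exact
12-mer index (12 ≤ minimum merge overlap, so error-free candidates are
never missed). Extension reuses the merge acceptance score. Interior
phase-collapse on repeats longer than roughly half a read remains
possible and yields partial (lower-copy) detections, consistent with the
incomplete detections the underlying method reports on long arrays.

**Repeat search.** The built-in search reports, for every period `q` in
`[2, Λmax]`, the maximal runs with `s[i] = s[i+q]`, at least two
complete copies, primitive pattern, fractional partial credit;
approximate repeats grow an exact core copy-by-copy while a flanking
`|p|`-window aligns to `p` at `copy_score_frac` (default 0.8) of the
maximum score, against the fixed pattern rather than a rolling
consensus. It is a deliberately small stand-in for a full repeat-finder:
no resolution parameter, exact-prefix partial credit only, overlapping
reports at different periods all emitted (deduplication is canonical, at
evaluation).

**Read-support verification.** The greedy assembler has no per-base
consensus, so a sequencing error carried by one read can survive into a
contig and fabricate a repeat sequence absent from the genome. Every
reported repeat must therefore have each 30-bp window of its sequence
present in at least `min_read_support = 2` physical reads (a genuine
window is covered by many reads at any reasonable depth; an error window
only by the read carrying the error). Exact cores are reported alongside
approximate extensions so that an extension absorbing a contig error is
dropped while its clean core stands as a partial detection.

## Evaluation semantics

Contig strand is unknown, so a repeat and its reverse complement are the
same repeat. A truth repeat is a TP when its full sequence is contained
(either orientation) in a detected repeat's sequence; a TPi when a
detected repeat with the same canonical pattern but lower copy number is
contained in it; an FN otherwise. A detected repeat is an FP iff its
sequence occurs in the target sequence in neither orientation. Each
detection credits at most one truth repeat (longest truth first).
Precision and sensitivity are `(TP+TPi)/(TP+TPi+FP)` and
`(TP+TPi)/(TP+TPi+FN)`, defined as 1 on an empty denominator.

## Simulator

The generator plants `n` primitive-pattern repeats (defaults: 10 repeats,
pattern lengths 5–20, copy numbers 3–6, exact copies) at well-separated
loci in an i.i.d.-uniform background, resampling the immediate flanking
bases so each run is maximal at its period and the recorded copy number
exact. Short reads are uniformly placed, fixed-length (100 bp), with
substitution errors only (default 1% — the Illumina regime); long reads
have uniform lengths in 1–20 kbp (clipped to the genome), total bases
matching the requested coverage, and per-base errors at 16% of which 70%
are insertions, the remainder split 2:1 deletions:substitutions (the
70% insertion share is the documented long-read error structure; the
remainder split is this package's choice). Placements are drawn before
errors, so a seed pins read positions across error models.

What the simulator does *not* model: coverage or GC bias beyond
placement randomness, quality scores, chimeric reads, indels in short
reads, structured error hotspots. Passing tests therefore demonstrate
the machinery under the stated error structure and approximately
homogeneous coverage, not performance on real instrument data.

## Problem sizes and numerical choices

The end-to-end suites use a 50-kb genome with 10 planted repeats at 20×
short- and long-read coverage, with `k = 10` (the shortest planted
repeat, 15 bp, bounds `k ≤ |ε| − |p| = 10`), `η = 1000`, `Λmax = 25`,
`λmax = 20`, `σ = 10`, and `τ = 80` (error-free runs) or `τ = 10` (raw
error rates); smaller 6–8-kb fixtures exercise the CLI and pipeline
plumbing. Frequencies are floats; band and separation checks carry a
1e-9 slack for float accumulation. Ties are broken lexicographically
everywhere (vertex order, arc order, merge candidates), which makes
detection deterministic and strand-flip invariant; the only randomness
in the package is the simulator's, driven by explicit seeds.

## Known limitations

- Patterns longer than `λmax` are found only within the arc budget, and
  patterns longer than `Λmax` not at all.
- Repeats shorter than `|p| + k` form no cycle and are invisible to
  stage 1 (they may still surface in contigs assembled for other
  patterns).
- Copy numbers of arrays approaching the read length collapse toward
  the minimum consistent with the reads (greedy phase ambiguity);
  detections remain, as partials.
- No base-level consensus: contigs inherit the bases of the first reads
  merged; the read-support filter removes fabricated repeat sequences
  but does not correct contigs.
- The anchor requires one exact k-mer occurrence in a long read; at
  error rates far above ~20% with long k this assumption degrades.
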