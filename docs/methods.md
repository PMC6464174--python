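# Methods

This note documents the models and procedures implemented in `mirssr`, the
parameters that matter, the design choices made where the protocol left
room, and what the synthetic fixtures do and do not demonstrate.

## Homology screen

Conserved-miRNA screens of de novo assemblies conventionally align known
mature miRNAs to transcripts and keep hits with zero mismatches, zero gaps
and alignment length ≥ 20 nt. Under those filters a hit *is* an exact
substring occurrence, so `mirssr` performs exact matching directly
(T↔U-normalized, forward strand by default with a `both_strands` option);
an e-value threshold is vacuous under exact matching and is not exposed.
Reference sets are first deduplicated at 100% identity: a mature identical
to, or a full-length substring of, another reference is dropped (keep the
longest, then the lexicographically smallest id). This mirrors
CD-HIT-style redundancy removal at c = 1 and is idempotent.

Each hit seeds a candidate window from `flank` (default 200) nt upstream of
the mature to `flank` nt downstream — about 400 nt plus the mature — clipped
at transcript ends; clipped candidates proceed but carry a `truncated` flag.
Because short contigs are common in transcriptome assemblies, clipping is
the norm rather than the exception.

**Coding filter.** Instead of a protein-database search (an external,
version-unstable dependency), a window is called protein-coding when it
overlaps an open reading frame of at least `min_orf_aa` = 100 codons in any
of the six frames of its host transcript. An ORF runs ATG-to-stop; at a
transcript boundary it may be open-ended (a truncated transcript need not
contain the start or the stop). The threshold is the same 100-aa cutoff
commonly used for ORF prediction on assemblies. Flagged candidates are
removed *before* folding, preserving the conventional stage order.

## RNA folding

Windows are folded by an in-package O(n³) dynamic program over
pseudoknot-free structures with Watson–Crick and G·U pairs and a minimum
hairpin loop of 3 nt (enforced for every pair). Two scoring models:

* `pair_count` — base-pair maximization (each pair scores 1; the reported
  |ΔG| is pairs × 1.0 kcal/mol surrogate). Simple enough to verify by
  exhaustive enumeration, which the test suite does on hundreds of random
  short sequences (`enumerate_structures`, capped at 14 nt).
* `stacking` (default) — free energy is the sum of published RNA
  nearest-neighbor stack terms for each pair lying directly on another
  pair. The ten Watson–Crick stack values are the standard set; the
  remaining combinations follow from rotational symmetry, and
  wobble-containing stacks use coarse representative values (−1.2 kcal/mol
  with one G·U in the stack, −0.5 with two). Loops and bulges carry no
  penalty; there are no dangling ends or coaxial terms.

This is deliberately the *smallest* model that yields kcal/mol-scaled ΔG
adequate for deciding hairpin-arm geometry and computing MFEI — it is not
the full Turner model, and its |ΔG| values are systematically larger than a
loop-penalized folder would give (loops are free, so random sequence folds
more than it should). Consequently |ΔG| and MFEI values are comparable
*within* a run but not quantity-for-quantity with mfold/RNAfold output, and
published per-candidate ΔG magnitudes are treated as worked-example inputs,
never as folding targets.

Determinism: the traceback leaves a base unpaired unless pairing strictly
improves the score, then chooses the smallest admissible partner, and
prefers helix continuation between equal-score branches. Under
`pair_count` pairing always strictly improves the score, so the "strictly
improves" clause only suppresses gratuitous zero-energy lone pairs in the
stacking model. Identical input always yields an identical structure.

## Hairpin acceptance criteria

Given the MFE structure and the mature span:

* **Terminal loop / longest stem.** Among all hairpin loops (pairs that
  enclose no other pair), the loop whose closing pair is enclosed by the
  most pairs is assigned to the main (longest) stem; ties break leftmost.
  Counting enclosing pairs rather than contiguous stacked runs makes the
  choice robust to bulges interrupting the stem.
* **Criterion 1 (arm).** `5p`/`3p` iff the mature does not intersect the
  terminal loop and every paired mature base pairs across it; a mature
  split between two stems, or sitting in the loop, gets `none`.
* **Criterion 2 (energy).** `AMFE = |ΔG|/L × 100`, `MFEI = AMFE/GC%`;
  accept iff MFEI ≥ `mfei_threshold` (default 0.70 — admits the published
  precursor range 0.71–0.83 while excluding typical mRNA at 0.62–0.66).
  |ΔG| and AMFE are reported but not independently thresholded, since the
  protocol states no ΔG cutoff. A GC-free window has undefined MFEI and
  auto-fails with a logged reason.
* **Criterion 3 (star mismatches).** The number of mature positions left
  unpaired in the MFE structure (bulges included) must be ≤ 6. This is the
  only structure-derived reading available when the star sequence itself is
  not independently known.
* **Criterion 4 (no loop or break).** The mature must not intersect the
  terminal loop and must contain no unpaired run longer than
  `max_internal_gap` = 3 nt.

The verdict is the conjunction of the four flags; each is monotone in its
threshold, so tightening any threshold can only shrink the accepted set.
When several references hit the same window, one evaluation per window is
kept (best MFEI). The MFEI summary reports n / mean / min / max with the
mean at two decimals, round-half-up, matching the convention of published
candidate tables.

## EST-SSR detection and primers

The scanner reports maximal tandem runs of primitive units (a unit that is
itself a tandem of a shorter unit is attributed to the shorter unit) with
minimum repeat counts {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}, scanning left
to right per unit size and skipping rotated restatements of a reported run;
a locus wholly contained in a longer locus is dropped. Loci separated by at
most 100 interrupting bases (the common compound-SSR convention) share a
compound id. Motif statistics use the canonical class — the lexicographic
minimum over all rotations of the motif and of its reverse complement
(`CT → AG/CT`, `CTT → AAG/CTT`) — and exclude mononucleotide loci by
default, which are unreliable under sequencing/assembly error. Internally
all coordinates are 0-based half-open; all reports are 1-based inclusive.

Melting temperatures use the unified SantaLucia (1998) nearest-neighbor
DNA parameters with terminal AT/GC initiation terms, the symmetry
correction for self-complementary oligos, the entropy salt correction
0.368·(N−1)·ln[Na⁺], and a primer-excess CT/4 concentration term. Defaults:
50 mM monovalent cation, 50 nM oligo. The test suite cross-checks this
implementation to < 10⁻⁶ °C against an independently coded calculator using
the same published table. Primer pairs must flank (never overlap) the run,
with length 18–25 nt, Tm 55–62 °C and product 100–300 bp; pairs are ranked
by |mean Tm − 57 °C| then by the intra-pair Tm difference. The 57 °C
optimum is configurable. An SSR whose flank cannot host a conforming primer
yields an empty list with a logged reason, not an exception.

## Synthetic fixtures

The generator emulates the *inputs* of an assembly-mining study: contig-like
transcripts carrying planted features, plus i.i.d. background of
configurable GC (held within ±2 percentage points for ≥ 1 kb transcripts).
Planted precursors are built as mature + terminal loop + star arm (the
reverse complement with a controlled number of positions substituted to
non-pairing bases), optionally sitting on a GC-rich closing stem below the
duplex, as real pre-miRNAs do. Decoys violate exactly one criterion each:

* *arm* — the mature is fully paired but split between two side-by-side
  stems inside an enclosing helix;
* *star_mismatch* — seven substitutions, placed so no unpaired run exceeds
  3 nt and no lone pair is stranded between bulges;
* *loop_break* — the star arm lacks the complement of five interior mature
  bases, creating a 5-nt bulge (≤ 6 mismatches, but a > 3 gap);
* *mfei* — a perfect but A/U-only (weak) duplex diluted by unpairable
  A/C-alphabet flanks, so the window's MFEI stays far below threshold while
  the structure remains a clean hairpin;
* *coding* — a structurally valid hairpin directly downstream of a planted
  151-codon ORF that overlaps the window.

Every construct is verified at generation time by running the actual
pipeline operations (hit search, window, coding flag, fold, criteria), and
draws are retried from a single seeded stream until the contract holds —
so identical (config, seed) always produces byte-identical FASTA and truth
tables. miRNA hosts are short contigs (~230–260 nt, above the usual 200-bp
assembly floor; the ORF decoy host is longer by construction), which keeps
candidate windows hairpin-dominated; that is why planted precursors show
MFEI well above the acceptance threshold. SSR hosts are 600-nt unigenes
with primer-friendly mid-GC flanks, screened so the only tandem runs
present are the planted ones.

**What the fixtures do not show.** Background is i.i.d., so there is no
assembly chimerism, no sequencing error, no paralogous near-matches, no
isoform redundancy, and no genome-scale motif-frequency structure; decoys
are single-violation by construction, whereas real rejected candidates
usually fail several criteria at once. Passing the fixture therefore
demonstrates correctness of the decision logic and coordinate bookkeeping,
not real-data sensitivity/specificity. Genome-scale frequency statistics
(e.g. which motif class dominates a full transcriptome) depend on the real
assembly and are out of scope; the summary operation computes the same
statistics on fixtures instead.

## Problem sizes and determinism

The folding DP is vectorized per diagonal and folds a 420-nt window in
well under a second; fixture windows are ~230–340 nt. The test suite's
oracle sweeps use 500 random ≤ 14-nt sequences (exhaustive enumeration),
200 random 10-kb sequences (regex SSR oracle) and 100 kb of transcript
(naive quadratic homology oracle). All randomness — generator, sweeps,
property tests — flows from explicit integer seeds; pipelines themselves
are deterministic, and reruns produce byte-identical outputs.

## Known limitations

* The folding model omits loop penalties and full Turner thermodynamics;
  MFEI values are internally consistent but model-specific, and the 0.70
  default threshold should be recalibrated if a different folding engine is
  substituted.
* Exact matching finds conserved miRNAs only; mismatch-tolerant homology is
  deliberately out of scope (a configuration hook is reserved).
* The ORF heuristic approximates a protein-database search; it cannot flag
  coding regions shorter than the codon threshold or non-ATG-initiated
  interior ORFs.
* Primer design checks thermodynamic and geometric constraints only — no
  self-dimer/hairpin screening and no genome-wide uniqueness check.
* Mature/star duplex "mismatches" are defined through the predicted
  structure; they need not equal mismatch counts against an external
  reference sequence.
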