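# mirssr

Conserved-miRNA precursor discovery and EST-SSR marker design for de novo
plant transcriptome assemblies.

When a non-model plant's transcriptome is assembled for the first time, two
standard mining steps follow: (1) a **homology screen for conserved miRNAs**
— known mature miRNAs are matched exactly against the contigs, candidate
precursor windows are cut and folded, and hairpins are kept only if they
look thermodynamically and structurally like real pre-miRNAs — and (2) an
**EST-SSR scan** for microsatellite marker development, with PCR primer
pairs designed around each locus. `mirssr` implements both pipelines as one
tested, dependency-light package, together with a synthetic-transcriptome
generator that plants precursors, criterion-violating decoys and SSR loci
with machine-readable truth, so every stage is verifiable without
downloading an assembly.

## The screen

A transcript containing an exact, ungapped occurrence (≥ 20 nt) of a known
mature miRNA yields a candidate window from 200 nt upstream of the mature to
200 nt downstream. Windows overlapping an open reading frame of ≥ 100 codons
(any of six frames) are discarded as protein-coding. Each surviving window
is folded to its minimum-free-energy (MFE) secondary structure by an
in-package dynamic program (nearest-neighbor helix stacking, G·U wobble
allowed, minimum hairpin loop 3 nt), and accepted only if, in that
structure:

1. the mature miRNA lies entirely within one arm of the hairpin;
2. the window is energetically miRNA-like:
   `AMFE = |ΔG| / L × 100` and `MFEI = AMFE / GC%` with **MFEI ≥ 0.70**
   (typical mRNA sits near 0.62–0.66, tRNA 0.64, rRNA 0.59);
3. at most **6** mature bases are unpaired against the miRNA\* arm
   ("mismatches", bulges included);
4. the mature neither intersects the terminal loop nor contains an unpaired
   run longer than 3 nt (no loop or break in the mature).

The SSR stage reports maximal tandem runs of primitive 1–6 nt units at
minimum repeat counts 10 / 6 / 5 / 5 / 5 / 5 (mono- through hexanucleotide),
groups nearby loci into compounds, summarizes motif classes in the usual
`AG/CT`-style rotation/reverse-complement canonical notation, and designs
flanking primer pairs (length 18–25 nt, Tm 55–62 °C by unified
nearest-neighbor thermodynamics, product 100–300 bp, ranked toward a
57 °C optimum).

## Worked example

Generate the standard planted-truth fixture (3 genuine precursors, 5 decoys
each violating exactly one criterion, 5 SSR loci, neutral background) and
run both pipelines:

```bash
mirssr fixture make --seed 7 --out fixture/
# wrote 15 transcripts, 11 references and 13 truth rows to fixture/

mirssr mirna run --transcripts fixture/transcripts.fasta \
                 --matures fixture/matures.fasta --out mirna_run/
# accepted 3 precursor(s) from 8 homology hit(s)
# MFEI: n=3 mean=1.30 min=1.22 max=1.39

mirssr ssr run --transcripts fixture/transcripts.fasta --out ssr_run/
# found 5 SSR locus/loci; designed 5 primer pair(s)
```

Exactly the three planted precursors survive: the eight homology hits shrink
to seven windows after the coding filter removes the ORF-hosted decoy, and
the four criteria remove the remaining four decoys. `mirna_run/candidates.tsv`
makes the cascade auditable per candidate:

```
transcript_id  mature_id    family  arm  star_mismatches  delta_g_mag  gc_pct  amfe   mfei  verdict
contig_0001    ath-miR319a  miR319  5p   0                158.36       53.91   68.85  1.28  True
contig_0002    cca-miR396c  miR396  3p   1                148.57       46.52   64.60  1.39  True
contig_0003    pde-miR159   miR159  5p   2                158.58       56.52   68.95  1.22  True
```

(`delta_g_mag` is the magnitude of the negative folding free energy in
kcal/mol; `mfei` ≥ 0.70 passes criterion 2. The planted hairpins sit on
short contigs, so their windows are hairpin-dominated and their MFEI values
run high.) The SSR report recovers all five planted loci at exact
coordinates, and every primer pair conforms:

```
ID           SSR      forward_primer           forward_tm  reverse_primer           reverse_tm  product_size
contig_0009  (AG)8    AGGATACGCTACGTTCGCGATGA  58.138      TACCCGCGTGAAGTTGTTTGTTT  55.862      169
contig_0010  (AAG)6   GTGGCCTCGGTAATGGGTTGATA  56.340      ACTGTCCCATGACCCGCGA      57.660      123
```

The same operations are available as a library
(`mirssr.fold_mfe`, `mirssr.find_homology_hits`, `mirssr.evaluate_candidate`,
`mirssr.scan_ssrs`, `mirssr.design_primer_pairs`,
`mirssr.generate_fixture`, ...).

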