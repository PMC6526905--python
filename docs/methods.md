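# Methods

This note documents the models, rules and numerical choices behind
`vestige`, what the synthetic worlds do and do not emulate, and the known
limitations.

## Coordinate and reporting conventions

All internal coordinates are 0-based, half-open; exon indices are 0-based
internally and 1-based in every table and report. Minus-strand gene
annotations are reverse-complemented at load time, so every downstream
stage sees a plus-strand model. Splice nomenclature: the *donor* is the GT
dinucleotide at the 5' end of an intron (the 3' boundary of the upstream
exon), the *acceptor* the AG at its 3' end; splice lesions carry both the
exon and the intron index to avoid ambiguity.

## Pairwise alignment

Exons (and reads) are aligned with a three-state affine-gap DP: the query
is global, the target window local (unaligned target prefix/suffix are
free). A gap of length L costs `gap_open + L·gap_extend`; defaults
match +2, mismatch −3, gap open −5, gap extend −2 — typical DNA values
where a single mismatch (−3 against +2) is cheaper than the shortest gap
(−7), so substitution-only divergence aligns gap-free. Tie-breaking is
deterministic: diagonal steps are preferred over gaps, and among
equal-scoring end positions the leftmost wins. IUPAC ambiguity codes
(including N) never match, so an all-N window has identity 0. The
implementation is numba-compiled; tests check its score against an
independently written pure-Python DP and, on tiny inputs, against
exhaustive enumeration of all alignments.

`identity` is matches over all alignment columns (indel columns included);
`coverage` is the fraction of the query aligned to target bases.

## Exon placement

Exons are placed longest-first so the most reliably mapped exons anchor
colinearity; each remaining exon is searched only between its placed
neighbours (windows on unbounded sides extend by 2x the reference
intron-plus-exon span). Placement repeats until stable, so an exon first
attempted against the whole locus is re-judged in its local window once
neighbours exist — this matters for the missing-versus-gap decision below.

An exon is **found** when identity ≥ 0.5, coverage ≥ 0.5 *and* the
alignment score is positive. The score criterion is what actually rejects
junk: gapped glocal alignments of a 120-nt exon against unrelated DNA
reach 52–57% identity (measured over 200 random trials) but always score
negative, while genuine orthologs at 20% divergence score ≥ +0.67 per
base. An unfound exon is **gap_unresolved** when ≥ 20% of its search
window is N (assembly gap — no claim possible) and **missing** otherwise
(deletion candidate: the region is sequenced, the exon is not there).

## Lesion calling

The found-exon alignments are stitched into a *virtual CDS* with a
per-base map back to reference CDS coordinates; insertions map to None,
deleted reference positions are recorded as unaligned.

* **Indels** come straight from alignment ops and are left-aligned against
  the reference CDS (VCF-style), making coordinates comparable across
  species; the normalizer is tested against exhaustive enumeration of
  equivalent placements. `frameshift = (length mod 3 ≠ 0)` always.
* **Premature stops**: the virtual CDS is scanned codon-wise. A stop is a
  genuine lesion when its three bases map to consecutive reference
  coordinates in the reference frame and precede the reference stop.
  Substitution-created stops additionally require ≥ 70% aligned identity
  in the 10 nt on both sides, so stops inside alignment noise are not
  called. A stop in a shifted frame is reported once, flagged
  `consequence=True`, and only when a called frameshifting lesion lies
  upstream to explain it: consequence stops are the frameshift's
  downstream effect, not independent evidence, so they are excluded from
  verdict counting and from cross-species matching (the frameshift
  signature is the event).
* **Splice sites**: the first/last 2 nt of each target intron are compared
  with the canonical GT/AG (GC donors can be allowed by configuration
  since GC–AG introns exist in mammals; a target dinucleotide equal to a
  non-canonical *reference* dinucleotide is inherited state, not a
  lesion).
* **Exon deletions**: missing exons become `exon_deletion` lesions with
  the exon's CDS span.

### Alignment-noise controls

Three rules suppress artifacts that background substitutions can paint
into an optimal alignment; all are configurable and were verified to leave
injected lesions untouched while driving false positives to zero over 500
simulated lesion-free clades:

1. Indels within 12 nt of an exon's alignment edge are not called —
   glocal boundary re-sync artifacts reach about that far into an exon.
2. An insertion and a deletion of equal length within 10 nt of each other
   are both dropped: a run of substitutions that mimics a shifted copy can
   make such a compensated pair score-equivalent to the true
   substitution-only alignment.
3. A splice-site call requires the adjacent exon boundary to have aligned
   cleanly (no indel ops within the edge-guard radius, terminal 10 nt at
   ≥ 70% identity): otherwise the aligner may have slid the boundary into
   the intron, and the "intron" dinucleotide read off the placement is
   meaningless.

The cost of (1) is a documented blind spot: genuine indels in the outer
12 nt of an exon are not reported.

## Verdict rules

Severity per lesion — **strong**: frameshifting indel or premature stop
with CDS coordinate before the 3'-terminal 10% of the CDS and not in the
last exon; deletion of a non-terminal exon; any stop upstream of an
annotated critical interval (e.g. an active site), regardless of position.
**medium**: splice-site lesion. **weak**: truncations confined to the
terminal region or last exon (termini tolerate frameshifts with little
functional cost), in-frame indels, last-exon deletions.

Verdict — `inactivated` with ≥ 1 strong or ≥ 2 medium-or-strong lesions;
`inconclusive` with one medium lesion, only weak lesions, or unresolved
assembly gaps without other evidence; `intact` only with no lesions and no
missing exons. These thresholds codify case-by-case reasoning that is
standard in manual pseudogene annotation, not a statistical estimator;
they are deliberately simple and exposed in configuration.

## Cross-species events and Dollo placement

Lesion signatures are `(gene, type, normalized CDS coordinate, length,
alternative allele)` and must match exactly (a ±3 nt fallback exists but
defaults off). Groups with ≥ 2 carriers become events; singletons are kept
for reporting. An event is placed on the branch above its carriers' MRCA
and marked *conserved* when every assayable leaf below that branch carries
it — species with unresolved gaps at the gene are excluded from the check,
Dollo-style missing data. Branches are named by the leaf set of the clade
below them (`A+B+C`), which makes placements comparable across tools and
with the simulator's truth table.

Synteny is assessed as ordered flanking-gene comparison: shared-neighbor
count plus an order flag that accepts complete reversal (a strand flip is
not a synteny break).

## Read evidence

A genomic read supports a lesion when it contains, in either orientation,
the mutant allele flanked by 20 exactly matching nt on each side (and
contradicts when the same holds for the reference allele); a read ending
inside the flank counts in neither bucket. Validation requires ≥ 2
supporting reads in ≥ 2 independent read sets when two or more sets are
provided, else 1 set. RNA reads are aligned both to the spliced transcript
and the unspliced locus: ≥ 10 nt of aligned intronic sequence with the
unspliced placement winning means *immature*; a spliced placement at ≥ 80%
identity means *mature*; ties with intron involvement and reads below the
identity floor are *ambiguous*. Paralog assignment picks the candidate
transcript with the fewest alignment errors and demands a margin of ≥ 2
errors over the runner-up, else the read is ambiguous and excluded from
per-gene counts.

## The synthetic worlds

The generator's defaults are the package's standard study: an 8-leaf
ultrametric tree (every root-to-leaf path 1.0, so the rate is directly the
expected divergence from the reference at the root), substitution rate
0.05 per site per unit length (~5% divergence — comfortably inside the
mammalian ortholog range the method targets), a 3-exon gene with
120/150/90 nt exons, 200 nt introns and 150 nt flanks, and six injected
lesions exercising every type: a 1-nt deletion on the clade stem, a 5-nt
insertion and a premature stop on internal branches, a donor GT→GC on a
cherry, and an acceptor AG→CT and a whole-exon deletion on terminal
branches. Injection coordinates sit mid-exon and codon-aligned. Reads
default to 100 nt at 20x depth with 0.5% substitution error (Illumina-like).

Background evolution is equal-rate substitution-only; every indel is an
explicit injection, so truth is unambiguous. Rejection sampling keeps the
background lesion-free *and* keeps the truth well-defined: substitutions
are resampled when they would create an in-frame stop, touch the terminal
stop codon, fall on a splice junction ± 4 nt of context, land within an
injected indel's left/right-shift equivalence tract ± 8 nt (a substitution
there can make a shifted gap placement score-equivalent and smear the
lesion's normalized coordinate across carriers), or fall in a planned
stop codon's ± 10 nt flank (the detector's flank window). Immature RNA
reads are drawn only from pre-mRNA start positions overlapping an intron
by ≥ 10 nt, because the class is *defined* by containing intronic
sequence — an unconditioned draw would label purely exonic fragments
"immature" that no classifier could, by definition, distinguish from
mature ones.

What the worlds do **not** emulate: background indel processes and
heterotachy, GC/rate heterogeneity, paralogous gene conversion, sequencing
error models beyond uniform substitution, real assembly artifacts beyond
N-masking, and local context remodeling around ancestral lesions. Passing
the end-to-end tests therefore shows the inference machinery is correct
under clean, identifiable conditions; on real genomes, lesion coordinates
near repeats, exon-edge indels and heavily diverged flanks still demand
the read-validation stage and, occasionally, manual review.

## Numerical and degenerate-input choices

Alignment ties resolve diagonal-first, then leftmost end; indel placement
ambiguity is removed by explicit left-alignment rather than relying on DP
tie-breaks. Empty sequences are rejected by the aligner; an empty search
window marks an exon missing/gap by N-fraction alone; a locus shorter than
every exon yields all-missing. The status matrix errors on duplicate
species×gene entries and fills unassayed cells explicitly. All randomness
flows from a single integer seed through numpy Generators; fixed seed
means byte-identical loci, reads and reports.

## Problem sizes

The standard study (8 species × 3 exons, ~1.1 kb loci) annotates in
~10 ms per species once the aligner is JIT-compiled; the full test suite
(140 tests, including 100 lesion-free control clades and 500-read RNA
mixtures) runs in ~12 s, and `scripts/acceptance.py` in ~10 s on one CPU.
These sizes were chosen to keep every stage's behaviour observable and
exactly checkable against truth; nothing in the implementation is specific
to them, and the mapper/detector scale linearly in locus length times exon
count.
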