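# vestige

Infer gene inactivation ("pseudogenization") from orthologous genomic loci,
and date shared loss events on a species tree.

Comparative genomics keeps turning up protein-coding genes that have been
rendered nonfunctional in particular lineages — gene *vestiges* whose loci
persist while the reading frame decays. Deciding that a gene is dead, and
*when* it died, takes more than a missing annotation: one must map the
reference exons onto each species' locus, call the ORF-disrupting mutations
(frameshift indels, premature stop codons, splice-site losses, whole-exon
deletions), separate genuine lesions from assembly gaps and alignment
noise, confirm the mutations in raw sequencing reads, and ask whether the
same lesion is shared across species — a shared lesion placed on the branch
above its carriers' most recent common ancestor (Dollo parsimony: a derived
loss arises once and is never regained) points to a single ancestral
inactivation event.

`vestige` implements this workflow as a tested, reusable library with a thin
CLI, for anyone studying lineage-specific gene loss (skin-gene decay in
cetaceans is the canonical shape of the problem: a multi-exon reference gene
from an outgroup, a clade of target genomes, genomic and RNA-seq read sets).

## What it computes

* **Exon mapping** — each reference CDS exon is placed in the target locus
  by glocal affine-gap alignment (exon global, window local; match +2,
  mismatch −3, gap open −5, gap extend −2). Unplaceable exons are
  `missing` (deletion candidates) when the search region is well sequenced
  and `gap_unresolved` when it is dominated by assembly Ns.
* **Lesion calling** — indels (left-aligned, VCF-style, so coordinates are
  comparable across species), premature stops found by translating the
  reconstructed virtual CDS (a stop is `premature` iff its reference CDS
  coordinate precedes the reference stop), non-canonical splice
  dinucleotides (donor GT / acceptor AG), and whole-exon deletions.
* **Verdicts** — lesions are graded strong / medium / weak (truncations in
  the 3'-terminal 10% of the CDS or in the last exon are weak; splice
  lesions medium; everything else disruptive is strong). A gene is
  `inactivated` with ≥1 strong or ≥2 medium-or-strong lesions,
  `inconclusive` with a single medium lesion, only weak lesions, or only
  assembly gaps, and `intact` otherwise.
* **Dollo dating** — lesions with identical signatures (gene, type,
  normalized CDS coordinate, length, alternative allele) across ≥2 species
  become one event on the branch above the carriers' MRCA.
* **Read evidence** — a genomic read supports a lesion if it carries the
  mutant allele with 20 exactly matching nt on each side (validation wants
  ≥2 supporting reads from ≥2 independent read sets when available); RNA
  reads are classified mature (exonic-only or junction-spanning) versus
  immature (containing ≥10 nt of intronic sequence), with paralog
  disambiguation by alignment-error margin.
* **Simulation** — a synthetic clade generator (toy multi-exon gene,
  substitution-only neutral divergence along a tree, lesions injected on
  chosen branches and inherited by all descendants, genomic/RNA read sets)
  with a machine-readable truth table, so the whole pipeline is testable
  offline.

## Worked example

Simulate the standard study — an 8-leaf clade at ~5% divergence from the
reference with six lesions injected on branches from the clade stem down to
single species — then annotate every locus and place the shared events:

```python
import vestige as v

world = v.simulate_world(v.SimSpec(seed=1))
ann = v.run_annotate(world.model, world.loci)
comp = v.run_compare(ann, world.tree)

for (species, gene), status in sorted(ann.statuses.items()):
    n = sum(not l.consequence for l in status.lesions)
    print(f"{species}: {status.verdict} ({n} lesions)")
for ev in comp.events:
    gene, typ, coord, length, alt = ev.signature
    print(f"shared {typ} at CDS {coord} in {len(ev.carrier_species)} species "
          f"-> branch {ev.assigned_branch} (conserved={ev.conserved})")
```

which prints:

```
A: inactivated (3 lesions)
B: inactivated (3 lesions)
C: inactivated (2 lesions)
D: inactivated (2 lesions)
E: inactivated (3 lesions)
F: inactivated (2 lesions)
G: inactivated (2 lesions)
H: inactivated (2 lesions)
shared premature_stop at CDS 30 in 3 species -> branch E+F+G (conserved=True)
shared insertion at CDS 60 in 4 species -> branch A+B+C+D (conserved=True)
shared splice_donor at CDS 120 in 2 species -> branch A+B (conserved=True)
shared deletion at CDS 189 in 8 species -> branch A+B+C+D+E+F+G+H (conserved=True)
```

Every species is called inactivated because a 1-nt frameshifting deletion
was injected on the clade stem; its signature (left-aligned to CDS
coordinate 189) is identical in all eight species, so Dollo parsimony puts
the event on the stem branch — the pattern that distinguishes one ancestral
pseudogenization from repeated independent losses. The premature stop,
5-nt insertion and donor GT→GC events land on exactly the internal branches
they were injected on; the two single-species lesions (an acceptor AG→CT
and a whole-exon deletion) are reported separately as terminal-branch
events.

The same flow is available from the shell:

```bash
vestige simulate --seed 1 --out sim/
vestige compare --gff3 sim/reference.gff3 --fasta sim/reference.fasta \
    --gene simgene --loci sim/loci.fasta --tree sim/tree.nwk --out run/
vestige full --seed 1 --out run_full/   # adds read validation
```

Real data enters the same way: a reference GFF3 + genomic FASTA, one FASTA
of per-species orthologous loci (record ids = species names, matching the
newick leaf labels), and optional FASTA/FASTQ read sets.

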