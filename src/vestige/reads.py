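"""Read-level evidence: lesion validation and RNA splicing maturity.

Genomic reads validate a called lesion when they carry the mutant allele
with a run of exactly matching bases on both sides; RNA reads are classified
as mature (consistent with spliced mRNA: exonic-only or junction-spanning)
or immature (retaining intronic sequence). Reads are always searched in both
orientations. All alignment goes through the package's own affine-gap
aligner; no external mapper is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import Alignment, align
from .config import DEFAULT_CONFIG
from .model import revcomp

MATURE = "mature"
IMMATURE = "immature"
AMBIGUOUS = "ambiguous"


@dataclass
class GeneStructure:
    """A gene's exon layout on its own (target) locus."""

    gene_id: str
    locus_seq: str
    #: exon intervals on locus_seq, ordered, 0-based half-open
    exons: list

    @property
    def transcript(self) -> str:
        return "".join(self.locus_seq[s:e] for s, e in self.exons)

    @property
    def introns(self) -> list:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    @property
    def pre_mrna(self) -> str:
        """Unspliced transcript: first exon start to last exon end."""
        return self.locus_seq[self.exons[0][0]:self.exons[-1][1]]

    @classmethod
    def from_alignments(cls, model, locus, alignments) -> "GeneStructure":
        exons = [ea.target_interval for ea in alignments
                 if ea.status == "found"]
        return cls(gene_id=model.gene_id, locus_seq=locus.seq, exons=exons)


@dataclass
class ReadSupport:
    lesion: object
    n_support: int
    n_contradict: int
    n_readsets_supporting: int
    validated: bool


@dataclass
class RnaReadCall:
    read_id: str
    gene_id: str
    klass: str
    intronic_overlap: int


# ---- genomic lesion support ------------------------------------------------

def _as_read_sets(reads):
    """Normalize input into a list of read sets, each a list of sequences."""
    if isinstance(reads, dict):
        first = next(iter(reads.values()), "")
        if isinstance(first, str):
            return [list(reads.values())]  # one set: {id: seq}
        return [_as_read_sets(v)[0] for v in reads.values()]
    reads = list(reads)
    if reads and isinstance(reads[0], str):
        return [reads]
    return [_as_read_sets(r)[0] for r in reads]


def lesion_windows(locus_seq: str, lesion, flank: int):
    """(mutant_window, reference_window) around a lesion on its locus.

    The mutant window is locus sequence as-is (the locus carries the mutant
    allele); the reference window substitutes the reference allele back in.
    """
    p = lesion.locus_pos
    if p is None:
        raise ValueError(f"lesion {lesion.type} at CDS {lesion.cds_coord} "
                         "has no locus anchor for read support")
    if lesion.type == "deletion":
        alt_len = 0
    elif lesion.type == "insertion":
        alt_len = lesion.length
    else:
        alt_len = len(lesion.alt_allele)
    if p - flank < 0 or p + alt_len + flank > len(locus_seq):
        raise ValueError("locus context too short for the requested flank")
    mutant = locus_seq[p - flank:p + alt_len + flank]
    ref = (locus_seq[p - flank:p] + lesion.ref_allele
           + locus_seq[p + alt_len:p + alt_len + flank])
    return mutant, ref


def support_for_lesion(reads, locus_context, lesion,
                       config=DEFAULT_CONFIG) -> ReadSupport:
    """Count reads carrying the mutant vs the reference allele.

    A read supports the lesion when it contains, in either orientation, the
    mutant allele with ``config.flank`` exactly matching nt on both sides;
    it contradicts when the same holds for the reference allele. ``reads``
    may be one read set or several independent sets; validation requires
    ``min_supporting_reads`` supporters in at least ``min_readsets``
    independent sets (capped at the number of sets provided).
    """
    locus_seq = locus_context.seq if hasattr(locus_context, "seq") else locus_context
    mutant, ref = lesion_windows(locus_seq.upper(), lesion, config.flank)
    sets = _as_read_sets(reads)
    n_support = n_contradict = n_sets_supporting = 0
    for readset in sets:
        set_hits = 0
        for read in readset:
            read = read.upper()
            both = (read, revcomp(read))
            if any(mutant in r for r in both):
                n_support += 1
                set_hits += 1
            elif any(ref in r for r in both):
                n_contradict += 1
        if set_hits:
            n_sets_supporting += 1
    need_sets = min(config.min_readsets, len(sets))
    validated = (n_support >= config.min_supporting_reads
                 and n_sets_supporting >= need_sets)
    return ReadSupport(lesion=lesion, n_support=n_support,
                       n_contradict=n_contradict,
                       n_readsets_supporting=n_sets_supporting,
                       validated=validated)


# ---- RNA maturity ----------------------------------------------------------

def _best_alignment(read: str, template: str, config):
    fwd = align(read, template, match=config.match, mismatch=config.mismatch,
                gap_open=config.gap_open, gap_extend=config.gap_extend)
    rev = align(revcomp(read), template, match=config.match,
                mismatch=config.mismatch, gap_open=config.gap_open,
                gap_extend=config.gap_extend)
    return fwd if fwd.score >= rev.score else rev


def _intronic_overlap(aln: Alignment, introns) -> int:
    """Aligned (match/mismatch) target positions falling inside introns."""
    total = 0
    t = aln.target_start
    for op, L in aln.ops:
        if op in ("M", "X"):
            for s, e in introns:
                lo, hi = max(t, s), min(t + L, e)
                if hi > lo:
                    total += hi - lo
            t += L
        elif op == "I":
            t += L
    return total


def classify_rna_read(read, structure: GeneStructure,
                      config=DEFAULT_CONFIG, read_id: str = "") -> RnaReadCall:
    """Mature / immature / ambiguous call for one RNA read.

    The read is aligned both to the spliced transcript and to the unspliced
    locus. Immature means the best placement retains at least
    ``min_intronic_overlap`` intronic nt; mature means the spliced placement
    explains the read (exonic-only or junction-spanning); ambiguous covers
    score ties with intron involvement and reads below the identity floor.
    """
    read = read.upper()
    t_aln = _best_alignment(read, structure.transcript, config)
    l_aln = _best_alignment(read, structure.locus_seq, config)
    overlap = _intronic_overlap(l_aln, structure.introns)
    if max(t_aln.identity, l_aln.identity) < config.rna_identity_floor:
        klass, overlap = AMBIGUOUS, 0
    elif overlap >= config.min_intronic_overlap and l_aln.score > t_aln.score:
        klass = IMMATURE
    elif overlap >= config.min_intronic_overlap and l_aln.score == t_aln.score:
        klass = AMBIGUOUS
    elif t_aln.identity >= config.rna_identity_floor:
        klass, overlap = MATURE, 0
    else:
        klass, overlap = AMBIGUOUS, 0
    return RnaReadCall(read_id=read_id, gene_id=structure.gene_id,
                       klass=klass, intronic_overlap=overlap)


def count_expression_evidence(reads_by_gene: dict, structures: dict,
                              config=DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-gene (mature, immature, total) read counts.

    Genes with no assigned reads are reported with zeros rather than being
    dropped. ``total`` counts every read assigned to the gene, including
    ambiguous calls.
    """
    rows = []
    for gene_id in sorted(structures):
        structure = structures[gene_id]
        reads = reads_by_gene.get(gene_id, {})
        items = reads.items() if isinstance(reads, dict) else \
            [(f"read{i}", r) for i, r in enumerate(reads)]
        counts = {MATURE: 0, IMMATURE: 0, AMBIGUOUS: 0}
        total = 0
        for rid, seq in items:
            call = classify_rna_read(seq, structure, config, read_id=rid)
            counts[call.klass] += 1
            total += 1
        rows.append({"gene": gene_id, "mature": counts[MATURE],
                     "immature": counts[IMMATURE],
                     "ambiguous": counts[AMBIGUOUS], "total": total})
    return pd.DataFrame(rows, columns=["gene", "mature", "immature",
                                       "ambiguous", "total"])


def assign_read_to_paralog(read, candidate_structures: dict,
                           config=DEFAULT_CONFIG) -> str:
    """Assign a read to the paralog it matches best.

    Candidates are compared by alignment errors (mismatches + indel bases)
    against each spliced transcript; a winner must beat the runner-up by at
    least ``paralog_min_margin`` errors, otherwise the read is ambiguous
    and should be excluded from per-gene counts.
    """
    if len(candidate_structures) < 2:
        raise ValueError("paralog assignment needs at least two candidates")
    read = read.upper()
    errors = {}
    for gene_id, structure in candidate_structures.items():
        aln = _best_alignment(read, structure.transcript, config)
        errors[gene_id] = aln.n_mismatch + aln.n_ins + aln.n_del
    ranked = sorted(errors.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) > 1 and ranked[1][1] - ranked[0][1] < config.paralog_min_margin:
        return AMBIGUOUS
    return ranked[0][0]
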