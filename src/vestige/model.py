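"""Reference gene models and target loci.

A :class:`GeneModel` is a protein-coding gene normalized to the plus strand:
an ordered set of CDS exon intervals on a genomic context sequence, with the
concatenated coding sequence ending in a stop codon. All coordinates are
0-based, half-open; exon indices are 0-based internally and reported 1-based
in user-facing tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """Raised when annotation cannot be assembled into a valid coding model."""


@dataclass
class GeneModel:
    gene_id: str
    species: str
    genomic_seq: str
    #: ordered CDS exon intervals on genomic_seq, 0-based half-open
    exons: list

    def __post_init__(self) -> None:
        self.genomic_seq = self.genomic_seq.upper()
        self.exons = [tuple(e) for e in self.exons]
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: no CDS exons")
        last = 0
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.genomic_seq)):
                raise GeneModelError(
                    f"{self.gene_id}: exon ({s}, {e}) outside sequence bounds")
            if s < last:
                raise GeneModelError(
                    f"{self.gene_id}: exons overlap or are out of order")
            last = e
        cds = self.cds_seq
        if len(cds) % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {len(cds)} is not a multiple of 3")
        if cds[-3:] not in STOP_CODONS:
            raise GeneModelError(f"{self.gene_id}: CDS does not end in a stop codon")
        for i in range(0, len(cds) - 3, 3):
            if cds[i:i + 3] in STOP_CODONS:
                raise GeneModelError(
                    f"{self.gene_id}: internal stop codon at CDS position {i}")

    # ---- derived structure -------------------------------------------------

    @cached_property
    def cds_seq(self) -> str:
        return "".join(self.genomic_seq[s:e] for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list:
        return [e - s for s, e in self.exons]

    @cached_property
    def cds_offsets(self) -> list:
        """CDS coordinate at which each exon starts."""
        offs, pos = [], 0
        for length in self.exon_lengths:
            offs.append(pos)
            pos += length
        return offs

    @property
    def cds_phase_per_exon(self) -> list:
        return [off % 3 for off in self.cds_offsets]

    @property
    def stop_coord(self) -> int:
        """CDS coordinate of the reference stop codon's first base."""
        return len(self.cds_seq) - 3

    @cached_property
    def introns(self) -> list:
        """Genomic intervals between consecutive CDS exons."""
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(self.n_exons - 1)]

    @property
    def intron_lengths(self) -> list:
        return [e - s for s, e in self.introns]

    def exon_seq(self, i: int) -> str:
        s, e = self.exons[i]
        return self.genomic_seq[s:e]

    def cds_end(self, i: int) -> int:
        """CDS coordinate one past the last base of exon i."""
        return self.cds_offsets[i] + self.exon_lengths[i]

    def exon_of_cds(self, c: int) -> int:
        for i in range(self.n_exons):
            if self.cds_offsets[i] <= c < self.cds_end(i):
                return i
        raise IndexError(f"CDS coordinate {c} outside CDS of length {len(self.cds_seq)}")

    def cds_to_genomic(self, c: int) -> int:
        i = self.exon_of_cds(c)
        return self.exons[i][0] + (c - self.cds_offsets[i])

    def genomic_to_cds(self, g: int):
        """CDS coordinate of genomic position g, or None if intronic/flanking."""
        for i, (s, e) in enumerate(self.exons):
            if s <= g < e:
                return self.cds_offsets[i] + (g - s)
        return None


@dataclass
class TargetLocus:
    """One species' orthologous genomic region for a gene."""

    species: str
    locus_id: str
    seq: str
    #: flanking gene symbols ordered 5'->3' (used for synteny checks)
    flanking_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.locus_id}: empty locus sequence")
        self.seq = self.seq.upper()
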