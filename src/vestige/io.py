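"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, GFF3 through gffutils, newick through
dendropy (wrapped in :class:`vestige.phylo.SpeciesTree`), tables through
pandas. Minus-strand gene annotations are normalized to the plus strand at
load time, so downstream modules never see strand.
"""

from __future__ import annotations

import os
import tempfile

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import GeneModel, GeneModelError, TargetLocus, revcomp


class FastaError(ValueError):
    pass


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    Sequences are uppercased; IUPAC letters are preserved. An empty file
    yields an empty map; malformed input raises :class:`FastaError` naming
    the offending line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, 1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}")
            break
    else:
        return {}
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path) -> dict:
    """Read FASTQ into an ordered ``{id: sequence}`` map (qualities dropped)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        out[rec.id] = str(rec.seq).upper()
    return out


def read_loci_fasta(path, species_of=None) -> dict:
    """Read per-species orthologous loci; record ids become species names
    unless ``species_of`` maps them explicitly."""
    seqs = read_fasta(path)
    loci = {}
    for name, seq in seqs.items():
        sp = species_of(name) if species_of else name
        loci[sp] = TargetLocus(species=sp, locus_id=name, seq=seq)
    return loci


# ---- gene models -----------------------------------------------------------

def build_gene_model(gff3_path, fasta_path, gene_id: str) -> GeneModel:
    """Assemble a plus-strand :class:`GeneModel` from GFF3 + genomic FASTA.

    Only CDS features descending from ``gene_id`` are used (UTR exons are
    ignored: the pipeline analyses reading frames). Minus-strand genes are
    reverse-complemented so the model is plus-strand.
    """
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise GeneModelError(f"gene {gene_id!r} not found in {gff3_path}") from exc
    cds = list(db.children(gene_id, featuretype="CDS", order_by="start"))
    if not cds:
        raise GeneModelError(f"gene {gene_id!r} has no CDS features")
    seqids = {f.seqid for f in cds}
    strands = {f.strand for f in cds}
    if len(seqids) != 1 or len(strands) != 1:
        raise GeneModelError(f"gene {gene_id!r}: CDS features span "
                             "multiple sequences or strands")
    seqid, strand = seqids.pop(), strands.pop()
    seqs = read_fasta(fasta_path)
    if seqid not in seqs:
        raise GeneModelError(f"sequence {seqid!r} not in {fasta_path}")
    seq = seqs[seqid]
    exons = [(f.start - 1, f.end) for f in cds]  # GFF3 is 1-based inclusive
    if strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        exons = sorted((L - e, L - s) for s, e in exons)
    species = gene.attributes.get("species", [seqid.split(":")[0]])[0]
    return GeneModel(gene_id=gene_id, species=species,
                     genomic_seq=seq, exons=exons)


def write_gene_model(model: GeneModel, gff3_path, fasta_path) -> None:
    """Emit a gene model as a minimal GFF3 (gene/mRNA/CDS) plus FASTA."""
    seqid = f"{model.gene_id}_locus"
    write_fasta({seqid: model.genomic_seq}, fasta_path)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        g0, g1 = model.exons[0][0], model.exons[-1][1]
        fh.write(f"{seqid}\tvestige\tgene\t{g0 + 1}\t{g1}\t.\t+\t.\t"
                 f"ID={model.gene_id};species={model.species}\n")
        mrna = f"{model.gene_id}.t1"
        fh.write(f"{seqid}\tvestige\tmRNA\t{g0 + 1}\t{g1}\t.\t+\t.\t"
                 f"ID={mrna};Parent={model.gene_id}\n")
        for i, ((s, e), phase) in enumerate(zip(model.exons,
                                                model.cds_phase_per_exon)):
            fh.write(f"{seqid}\tvestige\tCDS\t{s + 1}\t{e}\t.\t+\t{phase}\t"
                     f"ID={model.gene_id}.cds{i + 1};Parent={mrna}\n")


# ---- trees -----------------------------------------------------------------

def read_newick(path):
    """Read a rooted species tree (unique leaf labels enforced)."""
    from .phylo import SpeciesTree

    return SpeciesTree.from_file(path)


# ---- lesion tables ---------------------------------------------------------

LESION_COLUMNS = ["species", "gene", "exon", "intron", "type", "cds_coord",
                  "length", "ref_allele", "alt_allele", "frameshift",
                  "severity", "consequence"]


def lesions_to_frame(lesions) -> pd.DataFrame:
    """Tabulate lesions; exon/intron indices are 1-based in output and rows
    are deterministically ordered by (species, gene, cds_coord)."""
    rows = []
    for les in lesions:
        rows.append({
            "species": les.species,
            "gene": les.gene_id,
            "exon": les.exon_index + 1,
            "intron": "" if les.intron_index is None else les.intron_index + 1,
            "type": les.type,
            "cds_coord": les.cds_coord,
            "length": les.length,
            "ref_allele": les.ref_allele,
            "alt_allele": les.alt_allele,
            "frameshift": les.frameshift,
            "severity": les.severity if les.severity else "",
            "consequence": les.consequence,
        })
    df = pd.DataFrame(rows, columns=LESION_COLUMNS)
    if len(df):
        df = df.sort_values(["species", "gene", "cds_coord", "type"],
                            kind="mergesort").reset_index(drop=True)
    return df


def write_lesion_table(lesions, path) -> None:
    lesions_to_frame(lesions).to_csv(path, sep="\t", index=False)


def read_lesion_table(path):
    from .lesions import Lesion

    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"ref_allele": str, "alt_allele": str,
                            "intron": str, "severity": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(Lesion(
            type=row.type,
            exon_index=int(row.exon) - 1,
            intron_index=None if row.intron == "" else int(row.intron) - 1,
            cds_coord=int(row.cds_coord),
            length=int(row.length),
            ref_allele=row.ref_allele,
            alt_allele=row.alt_allele,
            frameshift=bool(row.frameshift),
            severity=row.severity or None,
            consequence=bool(row.consequence),
            species=row.species,
            gene_id=row.gene,
        ))
    return out
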