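"""Synthetic test worlds: a toy multi-exon gene, a clade of neutrally
diverged orthologous loci with inactivating lesions injected on chosen
branches, and genomic/RNA read sets — all with a machine-readable truth
table.

Design: background evolution is substitution-only under an equal-rate
model; any substitution that would create an in-frame stop, break a splice
GT/AG, touch the terminal stop codon, or remodel the immediate context of
a planned indel is rejected and resampled. All indels are therefore
explicit injections and every injected lesion has a well-defined,
clade-wide normalized coordinate: the truth table is unambiguous by
construction. An injection is applied once at its branch and inherited by
every descendant leaf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .lesions import (DELETION, EXON_DELETION, INSERTION, PREMATURE_STOP,
                      SPLICE_ACCEPTOR, SPLICE_DONOR, Lesion, left_align_indel,
                      lesion_severity, verdict_from_counts)
from .model import STOP_CODONS, GeneModel, TargetLocus, revcomp
from .phylo import SpeciesTree

BASES = "ACGT"

#: 8-leaf ultrametric tree; every root-to-leaf path has length 1.0, so the
#: substitution rate is directly the expected per-site divergence from the
#: reference (which sits at the root).
DEFAULT_NEWICK = ("(((((A:0.2,B:0.2):0.2,C:0.4):0.2,D:0.6):0.2,"
                  "((E:0.3,F:0.3):0.3,G:0.6):0.2):0.2,H:1.0);")

STEM = "A+B+C+D+E+F+G+H"


@dataclass(frozen=True)
class LesionSpec:
    """One planned inactivating event on a tree branch."""

    kind: str
    branch: str
    cds_coord: int = None
    length: int = 0
    insert_seq: str = None
    intron_index: int = None
    exon_index: int = None
    #: genomic interval to N-mask (kind="n_mask"); defaults to the exon
    interval: tuple = None


def default_lesions() -> tuple:
    """The standard six-event injection plan: one lesion of each type,
    spread from the clade stem down to terminal branches."""
    return (
        LesionSpec(kind=DELETION, branch=STEM, cds_coord=190, length=1),
        LesionSpec(kind=INSERTION, branch="A+B+C+D", cds_coord=60, length=5),
        LesionSpec(kind=PREMATURE_STOP, branch="E+F+G", cds_coord=30),
        LesionSpec(kind=SPLICE_DONOR, branch="A+B", intron_index=0),
        LesionSpec(kind=SPLICE_ACCEPTOR, branch="E", intron_index=1),
        LesionSpec(kind=EXON_DELETION, branch="H", exon_index=0),
    )


@dataclass(frozen=True)
class SimSpec:
    """Full description of a simulated study; defaults are the package's
    standard conditions (8 leaves, 3-exon gene, ~5% divergence from the
    reference, six injected lesions)."""

    newick: str = DEFAULT_NEWICK
    subs_per_site: float = 0.05
    lesions: tuple = field(default_factory=default_lesions)
    exon_lengths: tuple = (120, 150, 90)
    intron_lengths: tuple = (200, 200)
    flank: int = 150
    gene_id: str = "simgene"
    depth: float = 20.0
    read_len: int = 100
    error_rate: float = 0.005
    mature_fraction: float = 0.8
    seed: int = 0


@dataclass
class TruthTable:
    gene_id: str
    #: species -> {"lesions": [(type, exon, cds_coord, length, alt)],
    #:             "verdict": str, "gap_exons": [...]}
    per_species: dict = field(default_factory=dict)
    #: injection plan resolved to carriers: list of
    #: {"signature": tuple, "branch": str, "carriers": [...]}
    events: list = field(default_factory=list)
    #: read_id -> truth dict (origin/maturity)
    reads: dict = field(default_factory=dict)


@dataclass
class Clade:
    model: GeneModel
    tree: SpeciesTree
    leaf_seqs: dict
    #: per-leaf applied edits as (ref_pos, ref_len, alt_len), injection order
    edits: dict = field(default_factory=dict)
    truth: TruthTable = None

    def loci(self) -> dict:
        return {leaf: TargetLocus(species=leaf,
                                  locus_id=f"{self.model.gene_id}_{leaf}",
                                  seq=seq)
                for leaf, seq in self.leaf_seqs.items()}

    def to_leaf_pos(self, leaf: str, ref_pos: int) -> int:
        """Translate a reference genomic coordinate into leaf coordinates."""
        delta = 0
        for s, rl, al in self.edits.get(leaf, ()):
            if s + rl <= ref_pos:
                delta += al - rl
        return ref_pos + delta

    def gene_structure(self, leaf: str):
        """The leaf's true exon layout (deleted exons dropped)."""
        from .reads import GeneStructure

        exons = []
        for s, e in self.model.exons:
            gone = any(rl > 0 and es <= s and s + 1 <= es + rl and e <= es + rl
                       for es, rl, al in self.edits.get(leaf, ()))
            if gone:
                continue
            exons.append((self.to_leaf_pos(leaf, s), self.to_leaf_pos(leaf, e)))
        return GeneStructure(gene_id=self.model.gene_id,
                             locus_seq=self.leaf_seqs[leaf], exons=exons)


# ---- gene construction -----------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_toy_gene(n_exons: int, exon_lengths, intron_lengths, seed: int,
                  flank: int = 150, gene_id: str = "simgene") -> GeneModel:
    """Random multi-exon gene: stop-free CDS ending in a stop codon,
    canonical GT/AG at every intron. Same seed, same model."""
    exon_lengths = list(exon_lengths)
    intron_lengths = list(intron_lengths)
    if len(exon_lengths) != n_exons:
        raise ValueError("exon_lengths must have n_exons entries")
    if len(intron_lengths) != max(0, n_exons - 1):
        raise ValueError("need exactly n_exons - 1 intron lengths")
    if any(l < 3 for l in exon_lengths) or any(l < 4 for l in intron_lengths):
        raise ValueError("exons must be >= 3 nt and introns >= 4 nt")
    cds_len = sum(exon_lengths)
    if cds_len % 3 != 0:
        raise ValueError(f"total CDS length {cds_len} is not a multiple of 3")
    rng = np.random.default_rng(seed)
    sense = [a + b + c for a in BASES for b in BASES for c in BASES
             if a + b + c not in STOP_CODONS]
    n_codons = cds_len // 3
    cds = "".join(rng.choice(sense) for _ in range(n_codons - 1))
    cds += ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    pieces, exons, pos = [], [], 0
    if flank:
        pieces.append(_random_seq(rng, flank))
        pos = flank
    cpos = 0
    for i, elen in enumerate(exon_lengths):
        pieces.append(cds[cpos:cpos + elen])
        exons.append((pos, pos + elen))
        pos += elen
        cpos += elen
        if i < n_exons - 1:
            ilen = intron_lengths[i]
            pieces.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            pos += ilen
    if flank:
        pieces.append(_random_seq(rng, flank))
    return GeneModel(gene_id=gene_id, species="reference",
                     genomic_seq="".join(pieces), exons=exons)


# ---- neutral background evolution ------------------------------------------

#: genomic context preserved around each splice junction: the intron
#: dinucleotide plus a short run of flanking bases, so that exon boundaries
#: stay unambiguous under background divergence (substitution runs right at
#: a junction can otherwise shift the optimal exon placement by a base and
#: scramble the observed splice dinucleotide)
SPLICE_CONTEXT = 4


def _protected_sites(model: GeneModel) -> set:
    prot = set()
    for s, e in model.introns:
        prot.update(range(s - SPLICE_CONTEXT, s + SPLICE_CONTEXT))
        prot.update(range(e - SPLICE_CONTEXT, e + SPLICE_CONTEXT))
    for c in range(model.stop_coord, model.stop_coord + 3):
        prot.add(model.cds_to_genomic(c))
    return prot


def indel_context_guard(model: GeneModel, cds_coord: int, length: int,
                        allele: str, is_deletion: bool,
                        margin: int = 8) -> set:
    """Genomic positions that must stay invariant so an injected indel keeps
    a single, clade-wide normalized coordinate: its left/right-shift
    equivalence tract plus ``margin`` bases of context on each side (a
    substitution inside that context can make a shifted gap placement
    score-equivalent and smear the lesion's coordinate across carriers)."""
    cds = model.cds_seq
    lo, _ = left_align_indel(cds_coord, allele, cds, is_deletion)
    p = cds_coord
    if is_deletion:
        while p + length < len(cds) and cds[p] == cds[p + length]:
            p += 1
        hi = p + length
    else:
        seq = list(allele)
        while p < len(cds) and seq and cds[p] == seq[0]:
            seq.append(seq.pop(0))
            p += 1
        hi = p
    out = set()
    for c in range(max(0, lo - margin), min(len(cds), hi + margin)):
        out.add(model.cds_to_genomic(c))
    return out


def stop_context_guard(model: GeneModel, cds_coord: int,
                       flank: int = 10) -> set:
    """Positions held invariant around a planned stop codon so the injected
    stop stays attributable as an independent, well-anchored event."""
    c0 = cds_coord - cds_coord % 3
    out = set()
    for c in range(max(0, c0 - flank), min(len(model.cds_seq), c0 + 3 + flank)):
        out.add(model.cds_to_genomic(c))
    return out


def evolve_clade(model: GeneModel, tree: SpeciesTree, subs_per_site: float,
                 seed: int, protected_sites=()) -> dict:
    """Independent point substitutions along each branch (equal-rate model).

    Substitutions creating an in-frame stop, hitting a protected site
    (splice junction context, the terminal stop, caller-supplied positions)
    are rejected, so background divergence is lesion-free by construction.
    Returns ``{leaf: TargetLocus}``; use :func:`simulate_world` when
    injections are planned.
    """
    seqs = _evolve_seqs(model, tree, subs_per_site, seed, protected_sites)
    return {leaf: TargetLocus(species=leaf,
                              locus_id=f"{model.gene_id}_{leaf}", seq=seq)
            for leaf, seq in seqs.items()}


def _evolve_seqs(model: GeneModel, tree: SpeciesTree, subs_per_site: float,
                 seed: int, protected_sites=()) -> dict:
    if not 0.0 <= subs_per_site <= 0.3:
        raise ValueError("subs_per_site must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    L = len(model.genomic_seq)
    prot = _protected_sites(model) | set(protected_sites)
    g_of_c = [model.cds_to_genomic(c) for c in range(len(model.cds_seq))]
    c_of_g = {g: c for c, g in enumerate(g_of_c)}
    node_seq = {id(tree.root): list(model.genomic_seq)}
    leaf_seqs = {}
    for parent, child, elen in tree.preorder_edges():
        seq = list(node_seq[id(parent)])
        p = 1.0 - math.exp(-subs_per_site * elen)
        if p > 0:
            hits = np.flatnonzero(rng.random(L) < p)
            for g in hits:
                g = int(g)
                if g in prot:
                    continue
                current = seq[g]
                options = [b for b in BASES if b != current]
                options = [options[k] for k in rng.permutation(3)]
                for b in options:
                    if _creates_stop(seq, g, b, c_of_g, g_of_c, model):
                        continue
                    seq[g] = b
                    break
        node_seq[id(child)] = seq
        if child.is_leaf():
            leaf_seqs[child.taxon.label] = "".join(seq)
    return leaf_seqs


def _creates_stop(seq, g, b, c_of_g, g_of_c, model) -> bool:
    c = c_of_g.get(g)
    if c is None or c >= model.stop_coord:
        return False
    c0 = c - c % 3
    codon = "".join(b if gg == g else seq[gg]
                    for gg in (g_of_c[c0], g_of_c[c0 + 1], g_of_c[c0 + 2]))
    return codon in STOP_CODONS


# ---- lesion injection ------------------------------------------------------

class InjectionError(ValueError):
    pass


def _resolve_insert_seq(spec: LesionSpec, rng) -> LesionSpec:
    if spec.kind == INSERTION and spec.insert_seq is None:
        return replace(spec, insert_seq=_random_seq(rng, spec.length))
    return spec


def _truth_lesion(spec: LesionSpec, model: GeneModel) -> tuple:
    """(type, exon_index, normalized cds_coord, length, alt_allele)."""
    cds = model.cds_seq
    if spec.kind == DELETION:
        pos, _ = left_align_indel(spec.cds_coord,
                                  cds[spec.cds_coord:spec.cds_coord + spec.length],
                                  cds, True)
        return (DELETION, model.exon_of_cds(pos), pos, spec.length, "")
    if spec.kind == INSERTION:
        pos, seq = left_align_indel(spec.cds_coord, spec.insert_seq, cds, False)
        return (INSERTION, model.exon_of_cds(min(pos, len(cds) - 1)), pos,
                spec.length, seq)
    if spec.kind == PREMATURE_STOP:
        c0 = spec.cds_coord - spec.cds_coord % 3
        return (PREMATURE_STOP, model.exon_of_cds(c0), c0, 0, "TGA")
    if spec.kind == SPLICE_DONOR:
        i = spec.intron_index
        return (SPLICE_DONOR, i, model.cds_end(i), 0, "GC")
    if spec.kind == SPLICE_ACCEPTOR:
        i = spec.intron_index
        return (SPLICE_ACCEPTOR, i + 1, model.cds_offsets[i + 1], 0, "CT")
    if spec.kind == EXON_DELETION:
        i = spec.exon_index
        return (EXON_DELETION, i, model.cds_offsets[i],
                model.exon_lengths[i], "")
    return None  # n_mask carries no lesion


def _spec_edit(spec: LesionSpec, model: GeneModel):
    """(ref_pos, ref_len, alt_len, replacement) in reference genomic coords."""
    if spec.kind == DELETION:
        e0 = model.exon_of_cds(spec.cds_coord)
        if model.exon_of_cds(spec.cds_coord + spec.length - 1) != e0:
            raise InjectionError("deletion may not span an exon boundary")
        g = model.cds_to_genomic(spec.cds_coord)
        return g, spec.length, 0, ""
    if spec.kind == INSERTION:
        return model.cds_to_genomic(spec.cds_coord), 0, spec.length, spec.insert_seq
    if spec.kind == PREMATURE_STOP:
        c0 = spec.cds_coord - spec.cds_coord % 3
        g = model.cds_to_genomic(c0)
        if model.cds_to_genomic(c0 + 2) != g + 2:
            raise InjectionError("stop codon injection must not span exons")
        return g, 3, 3, "TGA"
    if spec.kind == SPLICE_DONOR:
        s, _ = model.introns[spec.intron_index]
        return s, 2, 2, "GC"
    if spec.kind == SPLICE_ACCEPTOR:
        _, e = model.introns[spec.intron_index]
        return e - 2, 2, 2, "CT"
    if spec.kind == EXON_DELETION:
        s, e = model.exons[spec.exon_index]
        return s, e - s, 0, ""
    if spec.kind == "n_mask":
        s, e = spec.interval if spec.interval else model.exons[spec.exon_index]
        return s, e - s, e - s, "N" * (e - s)
    raise InjectionError(f"unknown lesion kind {spec.kind!r}")


def inject_lesion(clade: Clade, spec: LesionSpec, rng=None) -> Clade:
    """Apply one planned lesion on its branch; every descendant leaf
    inherits it. Overlapping injections are an error."""
    if rng is None:
        rng = np.random.default_rng(0)
    spec = _resolve_insert_seq(spec, rng)
    model = clade.model
    node = clade.tree.node_for_branch(spec.branch)
    carriers = (clade.tree.clade_leaves(node) if not node.is_leaf()
                else [node.taxon.label])
    s, ref_len, alt_len, replacement = _spec_edit(spec, model)
    for leaf in carriers:
        for es, erl, _eal in clade.edits.get(leaf, ()):
            lo, hi = es, es + max(erl, 1)
            nlo, nhi = s, s + max(ref_len, 1)
            if nlo < hi and lo < nhi:
                raise InjectionError(
                    f"injection at {s} overlaps an earlier edit in {leaf}")
        lp = clade.to_leaf_pos(leaf, s)
        seq = clade.leaf_seqs[leaf]
        clade.leaf_seqs[leaf] = seq[:lp] + replacement + seq[lp + ref_len:]
        clade.edits.setdefault(leaf, []).append((s, ref_len, alt_len))
    truth = _truth_lesion(spec, model)
    if clade.truth is None:
        clade.truth = TruthTable(gene_id=model.gene_id)
    for leaf in clade.tree.leaves:
        clade.truth.per_species.setdefault(
            leaf, {"lesions": [], "verdict": None, "gap_exons": []})
    for leaf in carriers:
        if truth is not None:
            clade.truth.per_species[leaf]["lesions"].append(truth)
        elif spec.kind == "n_mask" and spec.exon_index is not None:
            clade.truth.per_species[leaf]["gap_exons"].append(spec.exon_index)
    if truth is not None:
        clade.truth.events.append({
            "signature": (model.gene_id,) + (truth[0],) + truth[2:],
            "branch": spec.branch,
            "carriers": sorted(carriers),
        })
    return clade


def _finalize_truth(clade: Clade, config) -> None:
    """Expected per-leaf verdicts from the injected lesions, graded with the
    same severity rule table the classifier documents."""
    model = clade.model
    if clade.truth is None:
        clade.truth = TruthTable(gene_id=model.gene_id)
    for leaf in clade.tree.leaves:
        entry = clade.truth.per_species.setdefault(
            leaf, {"lesions": [], "verdict": None, "gap_exons": []})
        counts = {"strong": 0, "medium": 0, "weak": 0}
        for typ, exon, coord, length, alt in entry["lesions"]:
            ref = ("GT" if typ == SPLICE_DONOR
                   else "AG" if typ == SPLICE_ACCEPTOR else "")
            les = Lesion(type=typ, exon_index=exon, cds_coord=coord,
                         length=length, alt_allele=alt, ref_allele=ref,
                         frameshift=(typ in (INSERTION, DELETION)
                                     and length % 3 != 0))
            sev = lesion_severity(les, model, config)
            if sev:
                counts[sev] += 1
        entry["verdict"] = verdict_from_counts(
            counts["strong"], counts["medium"], counts["weak"],
            bool(entry["gap_exons"]))


# ---- read simulation -------------------------------------------------------

def _mutate_read(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < error_rate):
        arr[int(i)] = BASES[(BASES.index(arr[int(i)])
                             + int(rng.integers(1, 4))) % 4] \
            if arr[int(i)] in BASES else arr[int(i)]
    return "".join(arr)


def simulate_genomic_reads(locus_seq: str, depth: float, read_len: int,
                           error_rate: float, seed: int, prefix: str = "g"):
    """Uniform-start genomic reads at the requested depth; returns
    ``({read_id: seq}, {read_id: truth})``."""
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if read_len > len(locus_seq):
        raise ValueError("read length exceeds the template")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    n = int(math.ceil(depth * len(locus_seq) / read_len))
    reads, truth = {}, {}
    for k in range(n):
        start = int(rng.integers(0, len(locus_seq) - read_len + 1))
        seq = locus_seq[start:start + read_len]
        rc = bool(rng.integers(0, 2))
        if rc:
            seq = revcomp(seq)
        seq = _mutate_read(seq, rng, error_rate)
        rid = f"{prefix}{k}"
        reads[rid] = seq
        truth[rid] = {"start": start, "revcomp": rc}
    return reads, truth


def simulate_rna_reads(structure, n_reads: int, read_len: int,
                       error_rate: float, mature_fraction: float, seed: int,
                       prefix: str = "r", min_intronic_overlap: int = 10):
    """Mature (spliced) / immature (unspliced) RNA read mixture.

    Each read draws its template with probability ``mature_fraction`` for
    the spliced transcript, else the unspliced pre-mRNA. Immature reads are
    drawn from start positions that cover at least
    ``min_intronic_overlap`` intronic nt — an immature read is *defined* by
    containing intronic sequence, so a pre-mRNA fragment lying entirely
    within one exon would not be one. Per-read truth records the class.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    mature_t = structure.transcript
    immature_t = structure.pre_mrna
    if read_len > len(mature_t) or read_len > len(immature_t):
        raise ValueError("read length exceeds a template")
    offset = structure.exons[0][0]
    introns_local = [(s - offset, e - offset) for s, e in structure.introns]

    def intron_cover(s):
        return sum(max(0, min(s + read_len, e) - max(s, b))
                   for b, e in introns_local)

    immature_starts = [s for s in range(len(immature_t) - read_len + 1)
                       if intron_cover(s) >= min_intronic_overlap]
    if not immature_starts and mature_fraction < 1.0:
        raise ValueError("no immature start position covers an intron")
    rng = np.random.default_rng(seed)
    reads, truth = {}, {}
    for k in range(n_reads):
        mature = bool(rng.random() < mature_fraction)
        if mature:
            tpl = mature_t
            start = int(rng.integers(0, len(tpl) - read_len + 1))
        else:
            tpl = immature_t
            start = immature_starts[int(rng.integers(0, len(immature_starts)))]
        seq = tpl[start:start + read_len]
        rc = bool(rng.integers(0, 2))
        if rc:
            seq = revcomp(seq)
        seq = _mutate_read(seq, rng, error_rate)
        rid = f"{prefix}{k}"
        reads[rid] = seq
        truth[rid] = {"maturity": "mature" if mature else "immature",
                      "start": start, "revcomp": rc}
    return reads, truth


def simulate_reads(locus_or_structure, depth, read_len, error_rate,
                   mature_fraction, seed):
    """Dispatch: genomic mode for a locus/sequence, RNA mode for a
    :class:`~vestige.reads.GeneStructure`."""
    if hasattr(locus_or_structure, "transcript"):
        n = max(1, int(round(depth)))
        return simulate_rna_reads(locus_or_structure, n, read_len,
                                  error_rate, mature_fraction, seed)
    seq = getattr(locus_or_structure, "seq", locus_or_structure)
    return simulate_genomic_reads(seq, depth, read_len, error_rate, seed)


# ---- world assembly --------------------------------------------------------

@dataclass
class World:
    spec: SimSpec
    model: GeneModel
    tree: SpeciesTree
    clade: Clade
    loci: dict
    truth: TruthTable


def simulate_world(spec: SimSpec = None, config=None) -> World:
    """Build the full study: gene, clade, injections, truth table."""
    from .config import DEFAULT_CONFIG

    if spec is None:
        spec = SimSpec()
    if config is None:
        config = DEFAULT_CONFIG
    master = np.random.default_rng(spec.seed)
    seed_gene, seed_evo, seed_inject = (int(s) for s in
                                        master.integers(0, 2 ** 31, size=3))
    model = make_toy_gene(len(spec.exon_lengths), spec.exon_lengths,
                          spec.intron_lengths, seed_gene, flank=spec.flank,
                          gene_id=spec.gene_id)
    tree = SpeciesTree.from_string(spec.newick)
    inject_rng = np.random.default_rng(seed_inject)
    specs = [_resolve_insert_seq(s, inject_rng) for s in spec.lesions]
    guard = set()
    for s in specs:
        if s.kind == DELETION:
            guard |= indel_context_guard(
                model, s.cds_coord, s.length,
                model.cds_seq[s.cds_coord:s.cds_coord + s.length], True)
        elif s.kind == INSERTION:
            guard |= indel_context_guard(model, s.cds_coord, s.length,
                                         s.insert_seq, False)
        elif s.kind == PREMATURE_STOP:
            guard |= stop_context_guard(model, s.cds_coord)
    leaf_seqs = _evolve_seqs(model, tree, spec.subs_per_site, seed_evo,
                             protected_sites=guard)
    clade = Clade(model=model, tree=tree, leaf_seqs=leaf_seqs)
    for s in specs:
        inject_lesion(clade, s, rng=inject_rng)
    _finalize_truth(clade, config)
    return World(spec=spec, model=model, tree=tree, clade=clade,
                 loci=clade.loci(), truth=clade.truth)
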