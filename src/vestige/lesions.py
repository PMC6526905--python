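"""Call ORF-disrupting lesions from per-exon alignments and grade genes.

A gene is inactivated by frameshifting indels, premature stop codons, loss
of canonical splice dinucleotides (GT donor / AG acceptor) or deletion of
whole exons. The detector reconstructs the target's virtual coding sequence
in reference CDS coordinates, emits one lesion per disruptive event, and a
verdict rule turns the lesion list into intact / inactivated / inconclusive.

Noise controls (each configurable): indels are only called away from exon
alignment edges; an equal-length insertion+deletion pair within a short
span is suppressed as an alignment-ambiguity artifact of substitution runs;
and substitution-created stop codons require well-aligned flanks. Stops
downstream of an unrestored frameshift are reported once, flagged as a
consequence of the frameshift, and do not count as independent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG
from .mapper import FOUND, GAP_UNRESOLVED, MISSING
from .model import STOP_CODONS, GeneModel, TargetLocus

INSERTION = "insertion"
DELETION = "deletion"
PREMATURE_STOP = "premature_stop"
SPLICE_DONOR = "splice_donor"
SPLICE_ACCEPTOR = "splice_acceptor"
EXON_DELETION = "exon_deletion"

STRONG = "strong"
MEDIUM = "medium"
WEAK = "weak"

INTACT = "intact"
INACTIVATED = "inactivated"
INCONCLUSIVE = "inconclusive"


@dataclass
class Lesion:
    """One inactivating mutation, in reference CDS coordinates."""

    type: str
    exon_index: int
    cds_coord: int
    length: int = 0
    ref_allele: str = ""
    alt_allele: str = ""
    frameshift: bool = False
    #: intron index for splice lesions (donor of intron i sits at the 3'
    #: boundary of exon i; acceptor at the 5' boundary of exon i+1)
    intron_index: int = None
    severity: str = None
    #: True for a premature stop that merely realises an upstream frameshift
    consequence: bool = False
    species: str = ""
    gene_id: str = ""
    #: position on the target locus (read-support lookups); None if n/a
    locus_pos: int = None

    def __post_init__(self) -> None:
        if self.type in (INSERTION, DELETION):
            expect = self.length % 3 != 0
            if self.frameshift != expect:
                raise ValueError("frameshift flag must equal (length % 3 != 0)")
        if self.type in (SPLICE_DONOR, SPLICE_ACCEPTOR):
            if len(self.ref_allele) != 2 or len(self.alt_allele) != 2:
                raise ValueError("splice lesions carry 2-nt alleles")

    @property
    def signature(self) -> tuple:
        return (self.gene_id, self.type, self.cds_coord, self.length,
                self.alt_allele)


@dataclass
class GeneStatus:
    species: str
    gene_id: str
    verdict: str
    lesions: list = field(default_factory=list)
    missing_exons: list = field(default_factory=list)
    gap_exons: list = field(default_factory=list)


# ---- indel normalization ---------------------------------------------------

def left_align_indel(pos: int, seq: str, ref: str, is_deletion: bool):
    """Shift an indel to its leftmost equivalent placement (VCF-style).

    For a deletion, ``seq`` is ``ref[pos:pos+len(seq)]``; for an insertion,
    ``seq`` is inserted before ``ref[pos]``. Idempotent.
    """
    seq = list(seq)
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq.insert(0, ref[pos - 1])
        seq.pop()
        pos -= 1
    return pos, "".join(seq)


def normalize_indel(lesion: Lesion, ref_cds: str) -> Lesion:
    """Return the lesion with its CDS coordinate/alleles left-aligned against
    the reference CDS; non-indels pass through unchanged."""
    if lesion.type == DELETION:
        pos, seq = left_align_indel(lesion.cds_coord, lesion.ref_allele,
                                    ref_cds, True)
        lesion.cds_coord, lesion.ref_allele = pos, seq
    elif lesion.type == INSERTION:
        pos, seq = left_align_indel(lesion.cds_coord, lesion.alt_allele,
                                    ref_cds, False)
        lesion.cds_coord, lesion.alt_allele = pos, seq
    return lesion


# ---- virtual CDS reconstruction --------------------------------------------

@dataclass
class VirtualCds:
    """Target coding sequence stitched from found-exon alignments.

    ``ref_map[k]`` is the reference CDS coordinate aligned to virtual base k
    (None for inserted bases); ``match_by_ref[r]`` records whether reference
    CDS position r was aligned as a match. Missing/gap exons contribute no
    sequence but are recorded.
    """

    seq: str
    ref_map: list
    #: target-locus coordinate of each virtual base
    tgt_map: list
    match_by_ref: dict
    missing_exons: list
    gap_exons: list


def reconstruct_cds(alignments, model: GeneModel) -> VirtualCds:
    seq_parts, ref_map, tgt_map = [], [], []
    match_by_ref = {}
    missing, gaps = [], []
    for ea in alignments:
        i = ea.exon_index
        if ea.status == MISSING:
            missing.append(i)
            continue
        if ea.status == GAP_UNRESOLVED:
            gaps.append(i)
            continue
        ref = model.cds_offsets[i]
        t = 0
        t0 = ea.target_interval[0]
        tseq = ea.target_seq
        for op, L in ea.alignment.ops:
            if op in ("M", "X"):
                seq_parts.append(tseq[t:t + L])
                ref_map.extend(range(ref, ref + L))
                tgt_map.extend(range(t0 + t, t0 + t + L))
                for r in range(ref, ref + L):
                    match_by_ref[r] = op == "M"
                ref += L
                t += L
            elif op == "I":
                seq_parts.append(tseq[t:t + L])
                ref_map.extend([None] * L)
                tgt_map.extend(range(t0 + t, t0 + t + L))
                t += L
            else:  # D
                for r in range(ref, ref + L):
                    match_by_ref[r] = False
                ref += L
    return VirtualCds(seq="".join(seq_parts), ref_map=ref_map,
                      tgt_map=tgt_map, match_by_ref=match_by_ref,
                      missing_exons=missing, gap_exons=gaps)


def _flank_identity(v: VirtualCds, r0: int, cds_len: int, window: int):
    """Per-side aligned identity around reference codon starting at r0."""
    def side(lo, hi):
        coords = range(max(0, lo), min(cds_len, hi))
        if not len(coords):
            return 1.0
        return sum(1 for r in coords if v.match_by_ref.get(r, False)) / len(coords)

    return side(r0 - window, r0), side(r0 + 3, r0 + 3 + window)


# ---- lesion calling --------------------------------------------------------

def _boundary_clean(ea, side: str, config) -> bool:
    """True when a found exon's terminal alignment region is trustworthy:
    no indel ops within ``indel_edge_guard`` reference nt of the boundary
    (the reach of glocal boundary re-sync artifacts) and flank identity at
    least the stop-flank floor over the terminal window."""
    exon_len = ea.alignment.query_len
    guard = config.indel_edge_guard
    window = config.stop_flank_window
    glo, ghi = (0, min(guard, exon_len)) if side == "left" else \
        (max(0, exon_len - guard), exon_len)
    ilo, ihi = (0, min(window, exon_len)) if side == "left" else \
        (max(0, exon_len - window), exon_len)
    ref = 0
    n_match = n_col = 0
    for op, L in ea.alignment.ops:
        if op in ("M", "X"):
            ov = min(ref + L, ihi) - max(ref, ilo)
            if ov > 0:
                n_col += ov
                if op == "M":
                    n_match += ov
            ref += L
        elif op == "D":
            if min(ref + L, ghi) - max(ref, glo) > 0:
                return False
            ref += L
        else:  # I between ref-1 and ref
            if glo < ref <= ghi if side == "right" else glo <= ref < ghi:
                return False
    if n_col == 0:
        return False
    return n_match / n_col >= config.stop_flank_min_identity


def _raw_indels(alignments, model, config):
    """Per-exon indel extraction with edge and compensated-pair suppression."""
    raw = []
    for ea in alignments:
        if ea.status != FOUND:
            continue
        i = ea.exon_index
        ref = model.cds_offsets[i]
        t = ea.target_interval[0]
        exon_lo, exon_hi = model.cds_offsets[i], model.cds_end(i)
        exon_raw = []
        for op, L in ea.alignment.ops:
            if op in ("M", "X"):
                ref += L
                t += L
            elif op == "I":
                exon_raw.append({"kind": INSERTION, "ref": ref, "len": L,
                                 "seq": None, "tpos": t, "exon": i})
                t += L
            else:  # D
                exon_raw.append({"kind": DELETION, "ref": ref, "len": L,
                                 "seq": model.cds_seq[ref:ref + L],
                                 "tpos": t, "exon": i})
                ref += L
        kept = []
        for item in exon_raw:
            left = item["ref"] - exon_lo
            right = exon_hi - (item["ref"] + (item["len"]
                                              if item["kind"] == DELETION else 0))
            if min(left, right) >= config.indel_edge_guard:
                kept.append(item)
        # suppress compensated insertion+deletion pairs of equal length
        dropped = set()
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if a in dropped or b in dropped:
                    continue
                x, y = kept[a], kept[b]
                if (x["kind"] != y["kind"] and x["len"] == y["len"]
                        and abs(x["ref"] - y["ref"]) <= config.compensated_indel_window):
                    dropped.update((a, b))
        raw.extend(item for k, item in enumerate(kept) if k not in dropped)
    return raw


def call_lesions(alignments, model: GeneModel, locus: TargetLocus,
                 config=DEFAULT_CONFIG) -> list:
    """Emit every inactivating lesion implied by the exon alignments."""
    lesions = []
    placed = {ea.exon_index: ea.target_interval
              for ea in alignments if ea.status == FOUND}

    # indels
    for item in _raw_indels(alignments, model, config):
        L = item["len"]
        if item["kind"] == INSERTION:
            les = Lesion(type=INSERTION, exon_index=item["exon"],
                         cds_coord=item["ref"], length=L,
                         alt_allele=locus.seq[item["tpos"]:item["tpos"] + L],
                         frameshift=L % 3 != 0, locus_pos=item["tpos"])
        else:
            les = Lesion(type=DELETION, exon_index=item["exon"],
                         cds_coord=item["ref"], length=L,
                         ref_allele=item["seq"], frameshift=L % 3 != 0,
                         locus_pos=item["tpos"])
        les = normalize_indel(les, model.cds_seq)
        les.exon_index = model.exon_of_cds(min(les.cds_coord,
                                               len(model.cds_seq) - 1))
        lesions.append(les)

    # splice dinucleotides: donor = first 2 nt of each intron, acceptor = last
    # 2. A call is only made when the adjacent exon boundary aligned cleanly
    # (no indels, decent identity in the terminal window): a boundary the
    # aligner slid into the intron would otherwise masquerade as a splice loss
    by_index = {ea.exon_index: ea for ea in alignments}
    donor_ok = {"GT", "GC"} if config.allow_gc_donor else {"GT"}
    for i in range(model.n_exons - 1):
        if i not in placed or (i + 1) not in placed:
            continue
        if not _boundary_clean(by_index[i], "right", config) or \
                not _boundary_clean(by_index[i + 1], "left", config):
            continue
        intron = locus.seq[placed[i][1]:placed[i + 1][0]]
        if len(intron) < 4:
            continue
        ref_intron_s, ref_intron_e = model.introns[i]
        ref_donor = model.genomic_seq[ref_intron_s:ref_intron_s + 2]
        ref_acceptor = model.genomic_seq[ref_intron_e - 2:ref_intron_e]
        donor, acceptor = intron[:2], intron[-2:]
        if donor not in donor_ok and donor != ref_donor:
            lesions.append(Lesion(type=SPLICE_DONOR, exon_index=i,
                                  intron_index=i, cds_coord=model.cds_end(i),
                                  ref_allele=ref_donor, alt_allele=donor,
                                  locus_pos=placed[i][1]))
        if acceptor != "AG" and acceptor != ref_acceptor:
            lesions.append(Lesion(type=SPLICE_ACCEPTOR, exon_index=i + 1,
                                  intron_index=i,
                                  cds_coord=model.cds_offsets[i + 1],
                                  ref_allele=ref_acceptor, alt_allele=acceptor,
                                  locus_pos=placed[i + 1][0] - 2))

    # whole-exon deletions
    virt = reconstruct_cds(alignments, model)
    for i in virt.missing_exons:
        L = model.exon_lengths[i]
        lesions.append(Lesion(type=EXON_DELETION, exon_index=i,
                              cds_coord=model.cds_offsets[i], length=L,
                              frameshift=L % 3 != 0))

    # premature stop codons on the virtual CDS; a frame-shifted stop is only
    # reported (as a consequence) when a called frameshifting lesion sits
    # upstream to explain it
    fs_coords = sorted(l.cds_coord for l in lesions if l.frameshift)
    lesions.extend(_call_stops(virt, model, config, fs_coords))

    for les in lesions:
        les.species = locus.species
        les.gene_id = model.gene_id
    lesions.sort(key=lambda l: (l.cds_coord, l.type))
    return lesions


def _call_stops(virt: VirtualCds, model: GeneModel, config,
                fs_coords=()) -> list:
    out = []
    cds_len = len(model.cds_seq)
    consequence_done = False
    v = virt.seq
    for k in range(0, len(v) - len(v) % 3, 3):
        codon = v[k:k + 3]
        if codon not in STOP_CODONS:
            continue
        r = virt.ref_map[k:k + 3]
        in_frame = (r[0] is not None and r[1] == r[0] + 1 and r[2] == r[0] + 2
                    and (k - r[0]) % 3 == 0)
        if in_frame:
            if r[0] >= model.stop_coord:
                continue
            left, right = _flank_identity(virt, r[0], cds_len,
                                          config.stop_flank_window)
            if min(left, right) >= config.stop_flank_min_identity:
                out.append(Lesion(type=PREMATURE_STOP,
                                  exon_index=model.exon_of_cds(r[0]),
                                  cds_coord=r[0],
                                  ref_allele=model.cds_seq[r[0]:r[0] + 3],
                                  alt_allele=codon,
                                  locus_pos=virt.tgt_map[k]))
        elif not consequence_done:
            anchor = next((x for x in r if x is not None), None)
            if anchor is None:
                anchor = next((x for x in virt.ref_map[k + 3:]
                               if x is not None), None)
            if (anchor is not None and anchor < model.stop_coord
                    and any(c <= anchor for c in fs_coords)):
                out.append(Lesion(type=PREMATURE_STOP,
                                  exon_index=model.exon_of_cds(anchor),
                                  cds_coord=anchor, alt_allele=codon,
                                  consequence=True, locus_pos=virt.tgt_map[k]))
                consequence_done = True
    return out


# ---- gene-level verdict ----------------------------------------------------

def lesion_severity(les: Lesion, model: GeneModel, config=DEFAULT_CONFIG,
                    critical_intervals=None):
    """Grade one lesion; returns strong/medium/weak, or None for stops that
    only restate an upstream frameshift.

    Truncations confined to the CDS' 3' terminal fraction or the last exon
    are weak (terminal regions tolerate frameshifts with little functional
    cost); a stop upstream of an annotated critical interval (e.g. an
    active site) is always strong.
    """
    if les.consequence:
        return None
    cds_len = len(model.cds_seq)
    cutoff = (1.0 - config.terminal_fraction) * cds_len
    last = model.n_exons - 1
    if les.type in (INSERTION, DELETION):
        if not les.frameshift:
            return WEAK
        return STRONG if (les.cds_coord < cutoff and les.exon_index != last) else WEAK
    if les.type == PREMATURE_STOP:
        if critical_intervals and any(les.cds_coord < s
                                      for s, _ in critical_intervals):
            return STRONG
        return STRONG if (les.cds_coord < cutoff and les.exon_index != last) else WEAK
    if les.type in (SPLICE_DONOR, SPLICE_ACCEPTOR):
        return MEDIUM
    if les.type == EXON_DELETION:
        return STRONG if les.exon_index != last else WEAK
    raise ValueError(f"unknown lesion type {les.type!r}")


def verdict_from_counts(n_strong: int, n_medium: int, n_weak: int,
                        has_gap: bool) -> str:
    """Verdict rule: inactivated if >=1 strong lesion or >=2
    medium-or-strong; a single medium or only weak lesions (or unresolved
    assembly gaps alone) is inconclusive; otherwise intact."""
    if n_strong >= 1 or (n_strong + n_medium) >= 2:
        return INACTIVATED
    if n_strong + n_medium + n_weak > 0 or has_gap:
        return INCONCLUSIVE
    return INTACT


def classify_gene(lesions, missing_exons, gap_exons, model: GeneModel,
                  config=DEFAULT_CONFIG, critical_intervals=None) -> GeneStatus:
    """Grade each lesion and apply :func:`verdict_from_counts`."""
    n_strong = n_medium = n_weak = 0
    for les in lesions:
        sev = lesion_severity(les, model, config, critical_intervals)
        les.severity = sev
        if sev == STRONG:
            n_strong += 1
        elif sev == MEDIUM:
            n_medium += 1
        elif sev == WEAK:
            n_weak += 1
    verdict = verdict_from_counts(n_strong, n_medium, n_weak, bool(gap_exons))
    if verdict == INTACT and (lesions or missing_exons):
        # e.g. only consequence-flagged records: no positive evidence of
        # inactivation, but not a clean intact gene either
        verdict = INCONCLUSIVE
    species = lesions[0].species if lesions else ""
    return GeneStatus(species=species, gene_id=model.gene_id, verdict=verdict,
                      lesions=list(lesions), missing_exons=list(missing_exons),
                      gap_exons=list(gap_exons))
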