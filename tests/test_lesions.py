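"""Lesion calling: reconstruction, indel normalization, stops, splice
sites, and the verdict rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vestige as v
from vestige.lesions import (DELETION, EXON_DELETION, INSERTION,
                             PREMATURE_STOP, SPLICE_ACCEPTOR, SPLICE_DONOR,
                             Lesion, left_align_indel)
from conftest import (enumerate_equivalent_deletions,
                      enumerate_equivalent_insertions, random_dna,
                      reference_locus)


def _annotate(model, seq, config=v.DEFAULT_CONFIG, species="t"):
    locus = v.TargetLocus(species=species, locus_id=species, seq=seq)
    alignments = v.locate_exons(model, locus, config)
    return alignments, locus


def _edit_genomic(model, cds_pos, ref_len, replacement):
    g = model.cds_to_genomic(cds_pos)
    s = model.genomic_seq
    return s[:g] + replacement + s[g + ref_len:]


# ---- virtual CDS reconstruction --------------------------------------------

def test_identity_reconstruction_equals_reference(toy_model):
    alignments, _ = _annotate(toy_model, toy_model.genomic_seq)
    virt = v.reconstruct_cds(alignments, toy_model)
    assert virt.seq == toy_model.cds_seq
    assert virt.ref_map == list(range(len(toy_model.cds_seq)))


def test_deletion_shifts_downstream_frame_by_minus_one(toy_model):
    # remove one base mid exon 2: every exon-3 position maps 1 ahead
    seq = _edit_genomic(toy_model, 190, 1, "")
    alignments, _ = _annotate(toy_model, seq)
    virt = v.reconstruct_cds(alignments, toy_model)
    exon3_cds_start = toy_model.cds_offsets[2]
    for k, r in enumerate(virt.ref_map):
        if r is not None and r >= exon3_cds_start:
            assert k - r == -1


def test_insertion_shifts_downstream_frame_by_plus_five(toy_model):
    seq = _edit_genomic(toy_model, 60, 0, "CATCA")
    alignments, _ = _annotate(toy_model, seq)
    virt = v.reconstruct_cds(alignments, toy_model)
    tail = [(k, r) for k, r in enumerate(virt.ref_map)
            if r is not None and r >= 100]
    assert all((k - r) % 3 == 2 and k - r == 5 for k, r in tail)


# ---- indel calls and normalization -----------------------------------------

def test_deletion_called_at_normalized_coordinate(toy_model, config):
    seq = _edit_genomic(toy_model, 190, 1, "")
    alignments, locus = _annotate(toy_model, seq)
    lesions = v.call_lesions(alignments, toy_model, locus, config)
    dels = [l for l in lesions if l.type == DELETION]
    assert len(dels) == 1
    expected_pos, _ = left_align_indel(190, toy_model.cds_seq[190], toy_model.cds_seq, True)
    assert dels[0].cds_coord == expected_pos
    assert dels[0].frameshift is True and dels[0].length == 1


def test_left_align_matches_spec_example():
    # deleting one A from CAAAT at position 3 normalizes to position 1
    assert left_align_indel(3, "A", "CAAAT", True) == (1, "A")


def test_left_align_fixed_point_in_unique_context():
    assert left_align_indel(2, "G", "ACGTA", True) == (2, "G")


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.text(alphabet="ACG", min_size=4, max_size=20),
       st.integers(min_value=0, max_value=15), st.integers(1, 3))
def test_left_align_is_idempotent_and_minimal(ref, pos, length):
    pos = min(pos, len(ref) - length)
    allele = ref[pos:pos + length]
    got_pos, got_allele = left_align_indel(pos, allele, ref, True)
    assert left_align_indel(got_pos, got_allele, ref, True) == (got_pos, got_allele)
    assert got_pos == min(enumerate_equivalent_deletions(ref, pos, length))


def test_insertion_left_align_matches_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(100):
        ref = random_dna(rng, 12).replace("G", "A").replace("T", "C")
        pos = int(rng.integers(0, len(ref) + 1))
        ins = random_dna(rng, int(rng.integers(1, 4))).replace("G", "A")
        got_pos, got_seq = left_align_indel(pos, ins, ref, False)
        best = min(enumerate_equivalent_insertions(ref, pos, ins))
        assert (got_pos, got_seq) == best


# ---- premature stops -------------------------------------------------------

def test_substitution_stop_called_by_direct_translation():
    # single-exon toy: ATG GCT TAC GGA TAA; mutate codon 2 to TAA
    model = v.GeneModel(gene_id="mini", species="ref",
                        genomic_seq="CCCATGGCTTACGGATAACCC", exons=[(3, 18)])
    target = "CCCATGTAATACGGATAACCC"
    alignments, locus = _annotate(model, target)
    lesions = v.call_lesions(alignments, model, locus)
    stops = [l for l in lesions if l.type == PREMATURE_STOP]
    assert len(stops) == 1
    assert stops[0].cds_coord == 3 and stops[0].alt_allele == "TAA"
    assert stops[0].consequence is False


def test_stop_coordinates_agree_with_codon_scan(world, annotated):
    """Translation oracle: every genuine stop call sits on an in-frame stop
    codon of the reconstructed virtual CDS, upstream of the reference stop."""
    model = world.model
    for (sp, _g), st_ in annotated.statuses.items():
        alignments = annotated.alignments[(sp, model.gene_id)]
        virt = v.reconstruct_cds(alignments, model)
        inframe = set()
        for k in range(0, len(virt.seq) - len(virt.seq) % 3, 3):
            r = virt.ref_map[k:k + 3]
            if (virt.seq[k:k + 3] in {"TAA", "TAG", "TGA"} and r[0] is not None
                    and r[1] == r[0] + 1 and r[2] == r[0] + 2
                    and (k - r[0]) % 3 == 0 and r[0] < model.stop_coord):
                inframe.add(r[0])
        called = {l.cds_coord for l in st_.lesions
                  if l.type == PREMATURE_STOP and not l.consequence}
        assert called <= inframe


# ---- splice sites ----------------------------------------------------------

def test_donor_gt_to_gc_called(toy_model, config):
    s, _ = toy_model.introns[0]
    seq = toy_model.genomic_seq
    seq = seq[:s] + "GC" + seq[s + 2:]
    alignments, locus = _annotate(toy_model, seq)
    donors = [l for l in v.call_lesions(alignments, toy_model, locus, config)
              if l.type == SPLICE_DONOR]
    assert len(donors) == 1
    assert (donors[0].ref_allele, donors[0].alt_allele) == ("GT", "GC")
    assert donors[0].intron_index == 0 and donors[0].exon_index == 0


def test_gc_donor_tolerated_when_configured(toy_model):
    s, _ = toy_model.introns[0]
    seq = toy_model.genomic_seq
    seq = seq[:s] + "GC" + seq[s + 2:]
    cfg = v.RunConfig(allow_gc_donor=True)
    alignments, locus = _annotate(toy_model, seq, cfg)
    lesions = v.call_lesions(alignments, toy_model, locus, cfg)
    assert [l for l in lesions if l.type == SPLICE_DONOR] == []


def test_acceptor_ag_to_ct_called(toy_model, config):
    _, e = toy_model.introns[1]
    seq = toy_model.genomic_seq
    seq = seq[:e - 2] + "CT" + seq[e:]
    alignments, locus = _annotate(toy_model, seq)
    acceptors = [l for l in v.call_lesions(alignments, toy_model, locus, config)
                 if l.type == SPLICE_ACCEPTOR]
    assert len(acceptors) == 1
    assert (acceptors[0].ref_allele, acceptors[0].alt_allele) == ("AG", "CT")
    assert acceptors[0].intron_index == 1 and acceptors[0].exon_index == 2


# ---- frameshift law and false-positive control ------------------------------

@pytest.mark.parametrize("length", range(1, 10))
def test_frameshift_flag_equals_length_mod_three(length, config):
    spec = v.SimSpec(seed=200 + length, lesions=(
        v.LesionSpec(kind=DELETION, branch="A+B", cds_coord=60, length=length),
        v.LesionSpec(kind=INSERTION, branch="E+F+G", cds_coord=190,
                     length=length),
    ))
    world = v.simulate_world(spec)
    ann = v.run_annotate(world.model, world.loci, config)
    indels = [l for st_ in ann.statuses.values() for l in st_.lesions
              if l.type in (DELETION, INSERTION)]
    assert indels, "expected indel calls"
    for les in indels:
        assert les.frameshift == (les.length % 3 != 0)
        assert les.length == length


def test_lesion_free_divergence_classifies_intact():
    for seed in range(10):
        world = v.simulate_world(v.SimSpec(seed=300 + seed, lesions=()))
        ann = v.run_annotate(world.model, world.loci)
        for st_ in ann.statuses.values():
            assert st_.verdict == "intact"
            assert st_.lesions == []


# ---- verdict rules ----------------------------------------------------------

def _classify(model, lesions, missing=(), gaps=(), **kw):
    return v.classify_gene(list(lesions), list(missing), list(gaps), model,
                           **kw)


def test_early_stop_alone_inactivates(toy_model):
    les = Lesion(type=PREMATURE_STOP, exon_index=0,
                 cds_coord=int(0.2 * len(toy_model.cds_seq)))
    status = _classify(toy_model, [les])
    assert les.severity == "strong"
    assert status.verdict == "inactivated"


def test_last_exon_frameshift_is_weak_and_inconclusive(toy_model):
    # 4-nt deletion near the very end of the CDS: terminal-region rationale
    les = Lesion(type=DELETION, exon_index=2, length=4, frameshift=True,
                 cds_coord=len(toy_model.cds_seq) - 10, ref_allele="ACGT")
    status = _classify(toy_model, [les])
    assert les.severity == "weak"
    assert status.verdict == "inconclusive"


def test_single_splice_lesion_is_inconclusive(toy_model):
    les = Lesion(type=SPLICE_ACCEPTOR, exon_index=2, intron_index=1,
                 cds_coord=toy_model.cds_offsets[2], ref_allele="AG",
                 alt_allele="CT")
    status = _classify(toy_model, [les])
    assert les.severity == "medium"
    assert status.verdict == "inconclusive"


def test_two_splice_lesions_inactivate(toy_model):
    lesions = [
        Lesion(type=SPLICE_DONOR, exon_index=0, intron_index=0,
               cds_coord=toy_model.cds_end(0), ref_allele="GT", alt_allele="GC"),
        Lesion(type=SPLICE_ACCEPTOR, exon_index=2, intron_index=1,
               cds_coord=toy_model.cds_offsets[2], ref_allele="AG",
               alt_allele="CT"),
    ]
    assert _classify(toy_model, lesions).verdict == "inactivated"


def test_no_lesions_is_intact(toy_model):
    assert _classify(toy_model, []).verdict == "intact"


def test_gap_exon_alone_is_inconclusive(toy_model):
    assert _classify(toy_model, [], gaps=[1]).verdict == "inconclusive"


def test_nonterminal_exon_deletion_is_strong(toy_model):
    les = Lesion(type=EXON_DELETION, exon_index=1, length=150, cds_coord=120)
    status = _classify(toy_model, [les])
    assert les.severity == "strong" and status.verdict == "inactivated"


def test_stop_upstream_of_critical_interval_is_always_strong(toy_model):
    # a truncation that would otherwise be terminal/weak becomes strong when
    # it removes an annotated critical region (active-site style argument)
    coord = len(toy_model.cds_seq) - 12
    weak_les = Lesion(type=PREMATURE_STOP, exon_index=2, cds_coord=coord)
    assert _classify(toy_model, [weak_les]).lesions[0].severity == "weak"
    strong_les = Lesion(type=PREMATURE_STOP, exon_index=2, cds_coord=coord)
    strong = _classify(toy_model, [strong_les],
                       critical_intervals=[(coord + 3, coord + 9)])
    assert strong_les.severity == "strong"
    assert strong.verdict == "inactivated"


def test_consequence_stop_not_counted_as_evidence(toy_model):
    cons = Lesion(type=PREMATURE_STOP, exon_index=2, cds_coord=300,
                  consequence=True)
    status = _classify(toy_model, [cons])
    assert cons.severity is None
    # no positive evidence, but the record keeps the gene from being intact
    assert status.verdict == "inconclusive"
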