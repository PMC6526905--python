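"""Read-level evidence: lesion support, RNA maturity, paralog assignment."""

import math

import numpy as np
import pytest

import vestige as v
from vestige.model import revcomp
from vestige.reads import GeneStructure
from vestige.sim import simulate_genomic_reads, simulate_rna_reads


@pytest.fixture(scope="module")
def stem_world():
    return v.simulate_world(v.SimSpec(seed=17))


@pytest.fixture(scope="module")
def stem_deletion(stem_world):
    ann = v.run_annotate(stem_world.model, stem_world.loci)
    st = ann.statuses[("C", stem_world.model.gene_id)]
    les = [l for l in st.lesions if l.type == "deletion"]
    assert len(les) == 1
    return stem_world.loci["C"], les[0]


def test_mutant_reads_validate_lesion(stem_deletion, config):
    locus, lesion = stem_deletion
    reads, _ = simulate_genomic_reads(locus.seq, depth=20, read_len=100,
                                      error_rate=0.0, seed=5)
    sup = v.support_for_lesion(list(reads.values()), locus, lesion, config)
    assert sup.n_support >= config.min_supporting_reads
    assert sup.n_contradict == 0
    assert sup.validated is True


def test_reference_haplotype_reads_contradict(stem_world, stem_deletion, config):
    locus, lesion = stem_deletion
    ref_seq = stem_world.model.genomic_seq
    reads, _ = simulate_genomic_reads(ref_seq, depth=20, read_len=100,
                                      error_rate=0.0, seed=6)
    sup = v.support_for_lesion(list(reads.values()), locus, lesion, config)
    assert sup.n_support == 0
    assert sup.validated is False
    # the reference around the lesion has diverged from the target locus, so
    # not every overlapping read contradicts exactly, but none supports


def test_read_ending_inside_flank_counts_in_neither_bucket(stem_deletion, config):
    locus, lesion = stem_deletion
    p = lesion.locus_pos
    # covers the lesion but only 10 of the 20 required flanking nt
    short = locus.seq[p - config.flank:p + 10]
    sup = v.support_for_lesion([short], locus, lesion, config)
    assert sup.n_support == 0 and sup.n_contradict == 0


def test_two_readsets_required_when_available(stem_deletion, config):
    locus, lesion = stem_deletion
    reads, _ = simulate_genomic_reads(locus.seq, depth=20, read_len=100,
                                      error_rate=0.0, seed=7)
    supporting = list(reads.values())
    empty = ["A" * 100]
    two_sets = v.support_for_lesion([supporting, empty], locus, lesion, config)
    assert two_sets.n_readsets_supporting == 1
    assert two_sets.validated is False  # needs 2 of the 2 provided sets
    both = v.support_for_lesion([supporting, supporting], locus, lesion, config)
    assert both.validated is True


# ---- RNA maturity ----------------------------------------------------------

@pytest.fixture(scope="module")
def structure(stem_world):
    m = stem_world.model
    return GeneStructure(gene_id=m.gene_id, locus_seq=m.genomic_seq,
                         exons=list(m.exons))


def test_junction_spanning_read_is_mature(structure, config):
    t = structure.transcript
    read = t[80:180]  # spans the exon1|exon2 junction (exon 1 is 120 nt)
    call = v.classify_rna_read(read, structure, config)
    assert call.klass == "mature"


def test_intron_running_read_is_immature(structure, config):
    s0, e0 = structure.exons[0]
    read = structure.locus_seq[e0 - 70:e0 + 30]  # 30 nt into intron 1
    call = v.classify_rna_read(read, structure, config)
    assert call.klass == "immature"
    assert call.intronic_overlap >= config.min_intronic_overlap


def test_exonic_read_is_mature(structure, config):
    s1, e1 = structure.exons[1]
    read = structure.locus_seq[s1 + 10:s1 + 30]  # 20 nt inside exon 2
    assert v.classify_rna_read(read, structure, config).klass == "mature"


def test_classification_symmetric_under_revcomp(structure, config):
    s0, e0 = structure.exons[0]
    for read in (structure.transcript[80:180],
                 structure.locus_seq[e0 - 70:e0 + 30]):
        fwd = v.classify_rna_read(read, structure, config)
        rev = v.classify_rna_read(revcomp(read), structure, config)
        assert fwd.klass == rev.klass


def test_unrelated_read_is_ambiguous(structure, config):
    rng = np.random.default_rng(9)
    junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    assert v.classify_rna_read(junk, structure, config).klass == "ambiguous"


def test_expression_counts_recover_simulated_mixture(structure, config):
    reads, truth = simulate_rna_reads(structure, n_reads=100, read_len=100,
                                      error_rate=0.0, mature_fraction=0.8,
                                      seed=21)
    table = v.count_expression_evidence({structure.gene_id: reads},
                                        {structure.gene_id: structure}, config)
    row = table.iloc[0]
    n_true_mature = sum(t["maturity"] == "mature" for t in truth.values())
    assert row["total"] == 100
    assert row["mature"] == n_true_mature
    assert row["immature"] == 100 - n_true_mature


def test_zero_reads_reported_as_zero(structure, config):
    table = v.count_expression_evidence({}, {structure.gene_id: structure},
                                        config)
    row = table.iloc[0]
    assert (row["mature"], row["immature"], row["total"]) == (0, 0, 0)


def test_recovered_mature_fraction_within_binomial_noise(structure, config):
    for p in (0.2, 0.8):
        reads, _ = simulate_rna_reads(structure, n_reads=200, read_len=100,
                                      error_rate=0.005, mature_fraction=p,
                                      seed=31)
        table = v.count_expression_evidence({structure.gene_id: reads},
                                            {structure.gene_id: structure},
                                            config)
        row = table.iloc[0]
        p_hat = row["mature"] / row["total"]
        assert abs(p_hat - p) <= 3 * math.sqrt(p * (1 - p) / 200)


# ---- paralog assignment ----------------------------------------------------

def _diverge(seq, rate, rng):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[int(i)] = "ACGT"[("ACGT".index(out[int(i)]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


@pytest.fixture(scope="module")
def paralog_pair(stem_world):
    rng = np.random.default_rng(13)
    m = stem_world.model
    a = GeneStructure(gene_id="geneA", locus_seq=m.genomic_seq,
                      exons=list(m.exons))
    b = GeneStructure(gene_id="geneB", locus_seq=_diverge(m.genomic_seq, 0.05, rng),
                      exons=list(m.exons))
    return a, b


def test_clear_winner_assigned(paralog_pair, config):
    a, b = paralog_pair
    read = a.transcript[50:150]
    assert v.assign_read_to_paralog(read, {"geneA": a, "geneB": b},
                                    config) == "geneA"


def test_equal_candidates_are_ambiguous(paralog_pair, config):
    a, _ = paralog_pair
    read = a.transcript[50:150]
    twin = GeneStructure(gene_id="twin", locus_seq=a.locus_seq,
                         exons=a.exons)
    assert v.assign_read_to_paralog(read, {"geneA": a, "twin": twin},
                                    config) == "ambiguous"


def test_single_candidate_rejected(paralog_pair, config):
    a, _ = paralog_pair
    with pytest.raises(ValueError):
        v.assign_read_to_paralog("ACGT" * 25, {"geneA": a}, config)


def test_paralog_assignment_accuracy_at_five_percent_divergence(paralog_pair, config):
    a, b = paralog_pair
    candidates = {"geneA": a, "geneB": b}
    reads, _ = simulate_rna_reads(a, n_reads=60, read_len=100,
                                  error_rate=0.005, mature_fraction=1.0,
                                  seed=41)
    assigned = [v.assign_read_to_paralog(r, candidates, config)
                for r in reads.values()]
    unambiguous = [x for x in assigned if x != "ambiguous"]
    assert unambiguous, "expected some confident assignments"
    correct = sum(x == "geneA" for x in unambiguous)
    assert correct / len(unambiguous) >= 0.95
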