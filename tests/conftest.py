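import numpy as np
import pytest

import vestige as v


@pytest.fixture(scope="session")
def config():
    return v.DEFAULT_CONFIG


@pytest.fixture(scope="session")
def toy_model():
    """3-exon random gene (120/150/90 nt exons, 200 nt introns)."""
    return v.make_toy_gene(3, [120, 150, 90], [200, 200], seed=7)


@pytest.fixture(scope="session")
def world():
    """Standard simulated study: 8 leaves, six injected lesions."""
    return v.simulate_world(v.SimSpec(seed=3))


@pytest.fixture(scope="session")
def annotated(world):
    return v.run_annotate(world.model, world.loci)


def reference_locus(model, species="self"):
    return v.TargetLocus(species=species, locus_id=f"{model.gene_id}_{species}",
                         seq=model.genomic_seq)


def gotoh_glocal_score(ref, tgt, match=2, mismatch=-3, gap_open=-5,
                       gap_extend=-2):
    """Independent scoring oracle: textbook three-state affine DP, query
    global / target local, pure Python, score only."""
    NEG = float("-inf")
    m, n = len(ref), len(tgt)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (target insert)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target (query delete)
    for j in range(n + 1):
        M[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            Y[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          Y[i - 1][j] + gap_extend,
                          X[i - 1][j] + gap_open + gap_extend)
            if j:
                ok = ref[i - 1] == tgt[j - 1] and ref[i - 1] in "ACGT"
                s = match if ok else mismatch
                M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1],
                                  Y[i - 1][j - 1])
                X[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                              X[i][j - 1] + gap_extend,
                              Y[i][j - 1] + gap_open + gap_extend)
    return max(max(M[m][j], Y[m][j]) for j in range(n + 1))


def enumerate_alignments_best(ref, tgt, match=2, mismatch=-3, gap_open=-5,
                              gap_extend=-2):
    """Exhaustive brute force over every glocal alignment path (tiny inputs
    only): the definitive oracle for the aligner's optimum."""
    best = float("-inf")

    def rec(i, j, state, score):
        nonlocal best
        if score + 2 * (len(ref) - i) <= best - 0.5:  # admissible bound
            return
        if i == len(ref):
            best = max(best, score)
            return
        if j < len(tgt):
            ok = ref[i] == tgt[j] and ref[i] in "ACGT"
            rec(i + 1, j + 1, "M", score + (match if ok else mismatch))
            rec(i, j + 1, "I", score + (gap_extend if state == "I"
                                        else gap_open + gap_extend))
        rec(i + 1, j, "D", score + (gap_extend if state == "D"
                                    else gap_open + gap_extend))

    for j0 in range(len(tgt) + 1):
        rec(0, j0, "S", 0)
    return best


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def enumerate_equivalent_deletions(ref, pos, length):
    """All positions q where deleting ref[q:q+length] gives the same string."""
    target = ref[:pos] + ref[pos + length:]
    return [q for q in range(len(ref) - length + 1)
            if ref[:q] + ref[q + length:] == target]


def enumerate_equivalent_insertions(ref, pos, seq):
    """All (q, s) placements inserting s at q that give the same string."""
    target = ref[:pos] + seq + ref[pos:]
    out = []
    for q in range(len(ref) + 1):
        s = target[q:q + len(seq)]
        if ref[:q] + s + ref[q:] == target:
            out.append((q, s))
    return out
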