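"""Locate reference exons within an orthologous target locus.

Exons are placed in decreasing length order so the longest, most reliably
mapped exons anchor colinearity; each remaining exon is searched only
between its already-placed neighbours. An exon that fails the identity or
coverage thresholds is reported as ``missing`` (deletion candidate) when
its search window is well sequenced, and as ``gap_unresolved`` when the
window is dominated by assembly Ns — that distinction encodes the argument
that a fully sequenced region with an absent exon implies a real deletion,
while an N-run leaves the call open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .align import Alignment, align_exon
from .config import DEFAULT_CONFIG
from .model import GeneModel, TargetLocus

FOUND = "found"
MISSING = "missing"
GAP_UNRESOLVED = "gap_unresolved"

_N_RUN = re.compile(r"N+")


@dataclass
class ExonAlignment:
    exon_index: int
    status: str
    #: aligned interval on the target locus (found exons only)
    target_interval: tuple = None
    alignment: Alignment = None
    #: target subsequence covered by the alignment (found exons only)
    target_seq: str = None
    identity: float = 0.0
    coverage: float = 0.0
    #: N fraction of the search window, recorded for gap diagnostics
    window_n_fraction: float = 0.0


def detect_assembly_gaps(locus_seq: str, interval) -> list:
    """Maximal runs of N within ``interval`` (0-based half-open), sorted."""
    s, e = interval
    if not (0 <= s <= e <= len(locus_seq)):
        raise ValueError(f"interval {interval} outside locus of length {len(locus_seq)}")
    return [(s + m.start(), s + m.end())
            for m in _N_RUN.finditer(locus_seq[s:e])]


def _window(model, idx, placed, locus_len, factor):
    """Search window for exon idx given already-placed exons."""
    prev = max((i for i in placed if i < idx), default=None)
    nxt = min((i for i in placed if i > idx), default=None)
    exon_len = model.exon_lengths[idx]
    if prev is not None:
        lo = placed[prev][1]
    elif nxt is not None:
        ref_gap = model.exons[nxt][0] - model.exons[idx][0]
        lo = max(0, placed[nxt][0] - int(factor * ref_gap) - exon_len)
    else:
        lo = 0
    if nxt is not None:
        hi = placed[nxt][0]
    elif prev is not None:
        ref_gap = model.exons[idx][1] - model.exons[prev][1]
        hi = min(locus_len, placed[prev][1] + int(factor * ref_gap) + exon_len)
    else:
        hi = locus_len
    return lo, hi


def locate_exons(model: GeneModel, locus: TargetLocus,
                 config=DEFAULT_CONFIG) -> list:
    """Place every reference exon in ``locus``; one entry per exon."""
    n = model.n_exons
    order = sorted(range(n), key=lambda i: (-model.exon_lengths[i], i))
    placed = {}
    results = {}

    def attempt(idx):
        lo, hi = _window(model, idx, placed, len(locus.seq),
                         config.window_intron_factor)
        window = locus.seq[lo:hi]
        n_frac = window.count("N") / len(window) if window else 1.0
        aln = None
        if len(window) >= 1:
            aln = align_exon(model.exon_seq(idx), window, config)
        ok = (aln is not None
              and aln.score >= config.min_score
              and aln.identity >= config.min_identity
              and aln.coverage >= config.min_coverage
              and aln.target_end > aln.target_start)
        if ok:
            interval = (lo + aln.target_start, lo + aln.target_end)
            placed[idx] = interval
            results[idx] = ExonAlignment(
                exon_index=idx, status=FOUND, target_interval=interval,
                alignment=aln, target_seq=locus.seq[interval[0]:interval[1]],
                identity=aln.identity, coverage=aln.coverage,
                window_n_fraction=n_frac)
            return True
        status = GAP_UNRESOLVED if n_frac >= config.gap_n_fraction else MISSING
        results[idx] = ExonAlignment(exon_index=idx, status=status,
                                     alignment=aln, window_n_fraction=n_frac)
        return False

    # place anchors first (longest exons), then retry unplaced exons until
    # stable: once neighbours are anchored, the search window — and hence the
    # missing-vs-gap decision — is the local region, not the whole locus
    changed = True
    while changed:
        changed = False
        for idx in order:
            if idx in placed:
                continue
            if attempt(idx):
                changed = True
    out = [results[i] for i in range(n)]
    _assert_colinear(out)
    return out


def _assert_colinear(alignments) -> None:
    last_end = -1
    for ea in alignments:
        if ea.status != FOUND:
            continue
        s, e = ea.target_interval
        if s < last_end:
            # window construction should make this unreachable; demote rather
            # than emit an inconsistent placement
            ea.status = MISSING
            ea.target_interval = None
            ea.target_seq = None
            continue
        last_end = e


def alignments_to_frame(alignments, species: str = "", gene: str = ""):
    """Debug dump of per-exon placements as a DataFrame (1-based exons)."""
    import pandas as pd

    rows = []
    for ea in alignments:
        s, e = ea.target_interval if ea.target_interval else ("", "")
        rows.append({"species": species, "gene": gene,
                     "exon": ea.exon_index + 1, "status": ea.status,
                     "target_start": s, "target_end": e,
                     "identity": round(ea.identity, 4),
                     "coverage": round(ea.coverage, 4),
                     "window_n_fraction": round(ea.window_n_fraction, 4)})
    return pd.DataFrame(rows)
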