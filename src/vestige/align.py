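"""Affine-gap glocal pairwise alignment.

The query (a reference exon, or a read) is aligned globally; the target
window is local, i.e. unaligned target prefix and suffix are free. Scoring
is affine: a gap of length L costs ``gap_open + L * gap_extend``. This is
the Gotoh three-state recursion with deterministic tie-breaking: on equal
scores a diagonal (match/mismatch) step is preferred over opening or
extending a gap, and among equally scoring end positions the leftmost is
chosen, so indels come out left-shifted before explicit normalization.

Ambiguity codes (including N) never match anything, so an all-N window
aligns with identity 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = -(10 ** 9)

_M, _IX, _IY = 0, 1, 2

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Alignment:
    """Result of one glocal alignment.

    ``ops`` is a run-length list of (op, length) with op one of
    ``M`` (match), ``X`` (mismatch), ``I`` (insertion relative to the
    query, i.e. extra target bases) and ``D`` (deletion, query bases
    absent from the target). ``target_start``/``target_end`` delimit the
    aligned target span.
    """

    score: int
    ops: tuple
    target_start: int
    target_end: int
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int
    query_len: int

    @property
    def n_columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_ins + self.n_del

    @property
    def identity(self) -> float:
        return self.n_match / self.n_columns if self.n_columns else 0.0

    @property
    def coverage(self) -> float:
        """Fraction of the query aligned to target bases (not deleted)."""
        return (self.n_match + self.n_mismatch) / self.query_len


@njit(cache=False)
def _fill(r, t, ma, mi, go, ge):  # pragma: no cover - exercised via align()
    m, n = r.size, t.size
    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    Ix = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    Iy = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pIx = np.zeros((m + 1, n + 1), dtype=np.int8)
    pIy = np.zeros((m + 1, n + 1), dtype=np.int8)
    for j in range(n + 1):
        M[0, j] = 0  # free target prefix: alignment may start after column j
    for i in range(1, m + 1):
        for j in range(n + 1):
            # Iy: query base i-1 deleted (no target consumed)
            best = M[i - 1, j] + go + ge
            ptr = _M
            v = Iy[i - 1, j] + ge
            if v > best:
                best, ptr = v, _IY
            v = Ix[i - 1, j] + go + ge
            if v > best:
                best, ptr = v, _IX
            Iy[i, j] = best
            pIy[i, j] = ptr
            if j > 0:
                s = ma if (r[i - 1] >= 0 and r[i - 1] == t[j - 1]) else mi
                best = M[i - 1, j - 1]
                ptr = _M
                v = Iy[i - 1, j - 1]
                if v > best:
                    best, ptr = v, _IY
                v = Ix[i - 1, j - 1]
                if v > best:
                    best, ptr = v, _IX
                M[i, j] = best + s
                pM[i, j] = ptr
                # Ix: extra target base j-1 inserted
                best = M[i, j - 1] + go + ge
                ptr = _M
                v = Ix[i, j - 1] + ge
                if v > best:
                    best, ptr = v, _IX
                v = Iy[i, j - 1] + go + ge
                if v > best:
                    best, ptr = v, _IY
                Ix[i, j] = best
                pIx[i, j] = ptr
    return M, Ix, Iy, pM, pIx, pIy


def align(query: str, target: str, *, match: int = 2, mismatch: int = -3,
          gap_open: int = -5, gap_extend: int = -2) -> Alignment:
    """Glocal alignment of ``query`` (global) within ``target`` (local)."""
    if not query or not target:
        raise ValueError("align() requires non-empty sequences")
    r, t = encode(query), encode(target)
    M, Ix, Iy, pM, pIx, pIy = _fill(r, t, match, mismatch, gap_open, gap_extend)
    m, n = r.size, t.size

    # end selection: leftmost j among ties, diagonal state preferred over a
    # trailing deletion
    best, endj, state = NEG - 1, 0, _M
    for j in range(n + 1):
        if M[m, j] > best:
            best, endj, state = int(M[m, j]), j, _M
        if Iy[m, j] > best:
            best, endj, state = int(Iy[m, j]), j, _IY

    raw = []  # per-column ops, built backwards
    i, j = m, endj
    while i > 0:
        if state == _M:
            nxt = pM[i, j]
            raw.append("M" if (r[i - 1] >= 0 and r[i - 1] == t[j - 1]) else "X")
            i, j = i - 1, j - 1
        elif state == _IY:
            nxt = pIy[i, j]
            raw.append("D")
            i -= 1
        else:
            nxt = pIx[i, j]
            raw.append("I")
            j -= 1
        state = nxt
    raw.reverse()
    start = j

    ops, counts = [], {"M": 0, "X": 0, "I": 0, "D": 0}
    for op in raw:
        counts[op] += 1
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])
    return Alignment(score=best, ops=tuple((o, l) for o, l in ops),
                     target_start=start, target_end=endj,
                     n_match=counts["M"], n_mismatch=counts["X"],
                     n_ins=counts["I"], n_del=counts["D"], query_len=m)


def align_exon(exon_seq: str, window_seq: str, config=None, **scores) -> Alignment:
    """Place one reference exon inside a search window.

    ``config`` may be a :class:`vestige.config.RunConfig`; explicit score
    keywords override it.
    """
    kw = {}
    if config is not None:
        kw = dict(match=config.match, mismatch=config.mismatch,
                  gap_open=config.gap_open, gap_extend=config.gap_extend)
    kw.update(scores)
    return align(exon_seq, window_seq, **kw)
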