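"""Run configuration: every threshold the pipeline consults lives here.

All defaults are the package's own working values; the alignment scores are
typical DNA glocal settings and the exon-found thresholds only guard against
spurious placements (mammalian ortholog divergence sits far above them).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass(frozen=True)
class RunConfig:
    # -- pairwise alignment scoring (affine gaps: a gap of length L costs
    #    gap_open + L * gap_extend)
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    # -- exon placement
    min_identity: float = 0.5
    min_coverage: float = 0.5
    #: a placement must additionally score above the empty-alignment null;
    #: gapped alignments of unrelated DNA score negative under the default
    #: scheme while genuine orthologs stay strongly positive
    min_score: int = 1
    #: an unlocated exon whose search window is >= this fraction N is reported
    #: as gap_unresolved (assembly gap) rather than missing (deletion candidate)
    gap_n_fraction: float = 0.2
    #: search windows around expected exon positions extend by this multiple of
    #: the reference intron span on unbounded sides
    window_intron_factor: float = 2.0

    # -- lesion calling
    #: fraction of the CDS (at each terminus conceptually; applied to the 3'
    #: end) treated as under relaxed constraint when grading truncations
    terminal_fraction: float = 0.1
    #: substitution-created stop codons require this identity in the
    #: stop_flank_window aligned nt on both sides
    stop_flank_window: int = 10
    stop_flank_min_identity: float = 0.7
    #: indels closer than this (reference nt) to an exon's alignment edge are
    #: treated as edge noise and not called (boundary re-sync artifacts of
    #: glocal alignment reach about this far into an exon)
    indel_edge_guard: int = 12
    #: an insertion and a deletion of equal length within this many reference
    #: nt of each other are suppressed as a compensated alignment artifact
    compensated_indel_window: int = 10
    #: GC donors are non-canonical by default (GC-AG introns exist in mammals,
    #: so this is a switch rather than a hard rule)
    allow_gc_donor: bool = False

    # -- shared-lesion matching
    #: coordinate slack for signature matching; 0 = exact (left-alignment is
    #: expected to remove jitter upstream)
    shared_coord_tolerance: int = 0

    # -- read evidence
    flank: int = 20
    min_supporting_reads: int = 2
    #: required independent read sets; capped at the number provided
    min_readsets: int = 2
    min_intronic_overlap: int = 10
    rna_identity_floor: float = 0.8
    #: minimum mismatch margin between best and second-best paralog
    paralog_min_margin: int = 2

    # -- reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "gap_n_fraction",
                     "terminal_fraction", "stop_flank_min_identity",
                     "rna_identity_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("match", "mismatch", "gap_open", "gap_extend"):
            v = getattr(self, name)
            if not isinstance(v, int):
                raise ValueError(f"{name} must be an integer score, got {v!r}")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be below match score")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


DEFAULT_CONFIG = RunConfig()
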