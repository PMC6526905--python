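"""Cross-species lesion matching, Dollo dating and synteny checks.

A lesion shared identically (same gene, type, left-aligned CDS coordinate,
length and alternative allele) by two or more species is treated as a
single ancestral event: under Dollo parsimony the derived state arises once
and is never regained, so the event is placed on the branch above the MRCA
of the carrier species. Premature stops that merely realise an upstream
frameshift are excluded from matching — the frameshift signature is the
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .lesions import GeneStatus, Lesion
from .phylo import SpeciesTree

NOT_ASSAYED = "not_assayed"


@dataclass
class SharedLesionEvent:
    signature: tuple
    carrier_species: frozenset
    lesion: Lesion = None
    assigned_branch: str = None
    #: True when every assayable leaf below the assigned branch is a carrier
    conserved: bool = None


def match_shared_lesions(per_species_lesions: dict, *, tolerance: int = 0):
    """Group left-aligned lesions across species by exact signature.

    Returns ``(events, singletons)``: events have >=2 carriers; singleton
    groups are retained separately for reporting. ``tolerance`` (off by
    default) merges signatures whose coordinates differ by at most that
    many nt; when used it should be logged by the caller.
    """
    groups = {}
    for species, lesions in per_species_lesions.items():
        for les in lesions:
            if les.consequence:
                continue
            groups.setdefault(les.signature, {})[species] = les
    if tolerance:
        groups = _merge_close(groups, tolerance)
    events, singletons = [], []
    for sig in sorted(groups, key=lambda s: (s[0], s[2], s[1])):
        carriers = groups[sig]
        ev = SharedLesionEvent(signature=sig,
                               carrier_species=frozenset(carriers),
                               lesion=next(iter(carriers.values())))
        (events if len(carriers) >= 2 else singletons).append(ev)
    return events, singletons


def _merge_close(groups, tolerance):
    merged = {}
    for sig in sorted(groups, key=lambda s: (s[0], s[1], s[3], s[4], s[2])):
        gene, typ, coord, length, alt = sig
        home = None
        for msig in merged:
            if (msig[0], msig[1], msig[3], msig[4]) == (gene, typ, length, alt) \
                    and abs(msig[2] - coord) <= tolerance:
                home = msig
                break
        if home is None:
            merged[sig] = dict(groups[sig])
        else:
            merged[home].update(groups[sig])
    return merged


def assign_loss_branch(event: SharedLesionEvent, tree: SpeciesTree,
                       missing_data=()) -> str:
    """Dollo placement: the branch above the carriers' MRCA.

    ``missing_data`` lists species that could not be assayed at the lesion
    locus (e.g. gap_unresolved); they are excluded from the conservation
    check, Dollo-style. Returns the branch label and annotates the event.
    """
    carriers = sorted(event.carrier_species)
    if not carriers:
        raise ValueError("event has no carrier species")
    node = tree.mrca(carriers)
    label = tree.branch_label(node)
    below = set(tree.clade_leaves(node)) if not node.is_leaf() else {label}
    assayable = below - set(missing_data)
    event.assigned_branch = label
    event.conserved = assayable <= set(event.carrier_species)
    return label


def check_synteny(target_flanks, reference_flanks):
    """Ordered flanking-gene comparison for orthology assessment.

    Returns ``(shared_count, order_conserved)`` where order is conserved
    when the shared genes appear in the same relative order in both lists,
    in either orientation (a strand flip is not a synteny break).
    """
    if not target_flanks or not reference_flanks:
        raise ValueError("flanking gene lists must be non-empty")
    shared = set(target_flanks) & set(reference_flanks)
    if not shared:
        return 0, False
    in_ref = [g for g in reference_flanks if g in shared]
    in_tgt = [g for g in target_flanks if g in shared]
    conserved = in_tgt == in_ref or in_tgt == in_ref[::-1]
    return len(shared), conserved


def build_status_matrix(statuses) -> pd.DataFrame:
    """Species x gene verdict matrix with explicit ``not_assayed`` cells.

    ``statuses`` is an iterable of :class:`GeneStatus`; duplicate
    species x gene entries are an error.
    """
    cells = {}
    for st in statuses:
        key = (st.species, st.gene_id)
        if key in cells:
            raise ValueError(f"duplicate status for species={st.species!r} "
                             f"gene={st.gene_id!r}")
        cells[key] = st.verdict
    species = sorted({s for s, _ in cells})
    genes = sorted({g for _, g in cells})
    df = pd.DataFrame(NOT_ASSAYED, index=species, columns=genes)
    for (s, g), v in cells.items():
        df.loc[s, g] = v
    df.index.name = "species"
    return df


def write_status_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_status_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="species")
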