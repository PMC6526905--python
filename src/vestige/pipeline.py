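"""Orchestration: annotate loci, compare across species, validate with
reads, and assemble a deterministic JSON run report.

The report contains nothing that is not a stage output: per species x gene
exon placements, lesions and verdicts; shared events with their Dollo
branches; read-support tables; the configuration echo and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .comparative import (SharedLesionEvent, assign_loss_branch,
                          build_status_matrix, match_shared_lesions)
from .config import DEFAULT_CONFIG
from .io import lesions_to_frame
from .lesions import call_lesions, classify_gene
from .mapper import FOUND, GAP_UNRESOLVED, MISSING, locate_exons
from .model import GeneModel, TargetLocus
from .phylo import SpeciesTree
from .reads import support_for_lesion


class PipelineError(RuntimeError):
    pass


@dataclass
class AnnotationResult:
    #: (species, gene_id) -> GeneStatus
    statuses: dict
    #: (species, gene_id) -> list[ExonAlignment]
    alignments: dict

    def all_lesions(self):
        for st in self.statuses.values():
            yield from st.lesions

    def per_species_lesions(self) -> dict:
        out = {}
        for (species, _gene), st in self.statuses.items():
            out.setdefault(species, []).extend(st.lesions)
        return out


@dataclass
class CompareResult:
    events: list
    singletons: list
    matrix: pd.DataFrame


def _as_gene_map(reference):
    if isinstance(reference, GeneModel):
        return {reference.gene_id: reference}
    return dict(reference)


def run_annotate(reference, loci, config=DEFAULT_CONFIG,
                 critical_intervals=None) -> AnnotationResult:
    """locate_exons -> call_lesions -> classify_gene per species x gene.

    ``reference`` is a GeneModel or {gene_id: GeneModel}; ``loci`` maps
    species to a TargetLocus (single gene) or {gene_id: TargetLocus}.
    ``critical_intervals`` optionally maps gene_id to CDS intervals whose
    upstream truncation is always strong (e.g. an enzyme's active site).
    """
    models = _as_gene_map(reference)
    statuses, alignments = {}, {}
    for species in sorted(loci):
        entry = loci[species]
        if isinstance(entry, TargetLocus):
            if len(models) != 1:
                raise PipelineError(f"{species}: single locus given but "
                                    f"{len(models)} gene models supplied")
            entry = {next(iter(models)): entry}
        for gene_id in sorted(entry):
            locus = entry[gene_id]
            model = models[gene_id]
            crit = (critical_intervals or {}).get(gene_id)
            try:
                aln = locate_exons(model, locus, config)
                lesions = call_lesions(aln, model, locus, config)
                missing = [ea.exon_index for ea in aln if ea.status == MISSING]
                gaps = [ea.exon_index for ea in aln
                        if ea.status == GAP_UNRESOLVED]
                status = classify_gene(lesions, missing, gaps, model, config,
                                       critical_intervals=crit)
                status.species = species
            except Exception as exc:
                raise PipelineError(
                    f"annotation failed for species={species} "
                    f"gene={gene_id}: {exc}") from exc
            statuses[(species, gene_id)] = status
            alignments[(species, gene_id)] = aln
    return AnnotationResult(statuses=statuses, alignments=alignments)


def run_compare(annotation: AnnotationResult, tree: SpeciesTree,
                config=DEFAULT_CONFIG) -> CompareResult:
    """Match lesions across species, Dollo-date shared events, and build
    the species x gene status matrix."""
    species = sorted({s for s, _ in annotation.statuses})
    if len(species) < 2:
        raise PipelineError("comparison needs at least two species")
    missing_from_tree = set(species) - set(tree.leaves)
    if missing_from_tree:
        raise PipelineError(
            f"species not in tree: {sorted(missing_from_tree)}")
    events, singletons = match_shared_lesions(
        annotation.per_species_lesions(),
        tolerance=config.shared_coord_tolerance)
    # species with unresolved assembly gaps in a gene are missing data for
    # that gene's events (Dollo-style exclusion from the conservation check)
    gaps_by_gene = {}
    for (sp, gene), st in annotation.statuses.items():
        if st.gap_exons:
            gaps_by_gene.setdefault(gene, set()).add(sp)
    for ev in events + singletons:
        gene = ev.signature[0]
        assign_loss_branch(ev, tree,
                           missing_data=gaps_by_gene.get(gene, ()))
    matrix = build_status_matrix(annotation.statuses.values())
    return CompareResult(events=events, singletons=singletons, matrix=matrix)


def run_validate(read_sets_by_species: dict, annotation: AnnotationResult,
                 loci: dict, config=DEFAULT_CONFIG) -> pd.DataFrame:
    """Read support for every anchored lesion, per species.

    Lesions with no overlapping reads come back unvalidated, not as an
    error; lesions without a locus anchor (whole-exon deletions) are
    skipped.
    """
    rows = []
    for (species, gene), st in sorted(annotation.statuses.items()):
        readsets = read_sets_by_species.get(species)
        if readsets is None:
            continue
        entry = loci[species]
        locus = entry if isinstance(entry, TargetLocus) else entry[gene]
        for les in st.lesions:
            if les.locus_pos is None or les.consequence:
                continue
            sup = support_for_lesion(readsets, locus, les, config)
            rows.append({"species": species, "gene": gene, "type": les.type,
                         "cds_coord": les.cds_coord,
                         "n_support": sup.n_support,
                         "n_contradict": sup.n_contradict,
                         "n_readsets_supporting": sup.n_readsets_supporting,
                         "validated": sup.validated})
    return pd.DataFrame(rows, columns=["species", "gene", "type", "cds_coord",
                                       "n_support", "n_contradict",
                                       "n_readsets_supporting", "validated"])


# ---- report ----------------------------------------------------------------

def build_report(annotation: AnnotationResult, compare: CompareResult = None,
                 validation: pd.DataFrame = None, config=DEFAULT_CONFIG,
                 seed: int = None) -> dict:
    """Deterministic, JSON-serializable run report."""
    report = {
        "tool": {"name": "vestige", "version": __version__},
        "seed": seed,
        "config": config.to_dict(),
        "genes": {},
    }
    for (species, gene), st in sorted(annotation.statuses.items()):
        aln = annotation.alignments[(species, gene)]
        entry = {
            "verdict": st.verdict,
            "missing_exons": [i + 1 for i in st.missing_exons],
            "gap_exons": [i + 1 for i in st.gap_exons],
            "exons": [{"exon": ea.exon_index + 1, "status": ea.status,
                       "identity": round(ea.identity, 4),
                       "coverage": round(ea.coverage, 4)} for ea in aln],
            "lesions": lesions_to_frame(st.lesions).to_dict(orient="records"),
        }
        report["genes"].setdefault(gene, {})[species] = entry
    if compare is not None:
        report["shared_events"] = [_event_dict(ev) for ev in compare.events]
        report["singleton_lesions"] = [_event_dict(ev)
                                       for ev in compare.singletons]
        report["status_matrix"] = {
            sp: dict(row) for sp, row in compare.matrix.iterrows()}
    if validation is not None:
        report["read_support"] = validation.to_dict(orient="records")
    return report


def _event_dict(ev: SharedLesionEvent) -> dict:
    gene, typ, coord, length, alt = ev.signature
    return {"gene": gene, "type": typ, "cds_coord": coord, "length": length,
            "alt_allele": alt, "carriers": sorted(ev.carrier_species),
            "branch": ev.assigned_branch, "conserved": ev.conserved}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
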