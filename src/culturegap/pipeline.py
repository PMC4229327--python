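"""End-to-end orchestration of the analysis stages over in-memory objects.

The CLI wraps these functions with file I/O; tests and the acceptance
script call them directly.  Stage order mirrors the analysis: orient ->
derive anchors -> trim -> region filter -> per-dataset clustering ->
chimera removal -> cultured-pool clustering -> common-window trim ->
universal OTUs -> tree -> nearest-cultured distances -> TMM abundance ->
scaling and classification -> candidate selection -> reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .abundance import TMMFactors, summarize_abundance, tmm_factors
from .clustering import (
    ChimeraParams,
    Cluster,
    IdentityParams,
    UniversalOTU,
    build_universal_otus,
    detect_chimeras,
    greedy_cluster,
    trim_representatives_to_common_window,
)
from .culturability import ClassificationThresholds, classify, scale_metrics, select_candidates
from .io_formats import CULTURED_DATASET, SequenceRecord, TaxonomyAssignment
from .phylogeny import (
    PhyloTree,
    nearest_cultured_distances,
    nearest_results_frame,
    nj_tree,
    p_distance_matrix,
    partition_clades,
    prune_tree,
)
from .preprocess import (
    RegionReport,
    TrimReport,
    TrimSpec,
    check_region_overlap,
    derive_anchors,
    orient_reads,
    trim_to_anchors,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    identity: IdentityParams = field(default_factory=IdentityParams)
    chimera: ChimeraParams = field(default_factory=ChimeraParams)
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds
    )
    conservation_threshold: float = 0.9
    anchor_length: int = 12
    orientation_k: int = 12
    required_region: tuple[int, int] | None = None
    clade_max_within_distance: float = 0.25
    max_anchor_profile_reads: int = 500


@dataclass
class PipelineResult:
    trim_reports: dict[str, TrimReport]
    region_reports: dict[str, RegionReport]
    dataset_clusters: dict[str, list[Cluster]]
    chimeric_read_ids: dict[str, list[str]]
    cultured_clusters: list[Cluster]
    universal_otus: list[UniversalOTU]
    counts: pd.DataFrame
    tmm: TMMFactors
    abundance_summary: pd.DataFrame
    tree: PhyloTree
    nearest: pd.DataFrame
    metrics: pd.DataFrame
    rumen_tree: PhyloTree
    clades: dict[str, str]
    otu_taxonomy: dict[str, TaxonomyAssignment]
    candidates: pd.DataFrame
    needs_cultivation: pd.DataFrame


def preprocess_dataset(
    reads: Sequence[SequenceRecord],
    reference: str,
    params: PipelineParams,
    trimspec: TrimSpec | None = None,
) -> tuple[list[SequenceRecord], TrimReport, RegionReport]:
    """Orient, derive anchors (from tier-0 cluster representatives), trim,
    and map one dataset onto the reference."""
    oriented = orient_reads(reads, reference, k=params.orientation_k)
    if trimspec is None:
        # profile stand-in: representatives of a quick pre-trim clustering,
        # restricted to the modal length (no-indel amplicons align as-is)
        sample = oriented[: params.max_anchor_profile_reads]
        tier0 = greedy_cluster(sample, params.identity)
        reps = [c.rep_seq for c in tier0]
        lengths = [len(r) for r in reps]
        modal = max(set(lengths), key=lengths.count)
        profile = [r for r in reps if len(r) == modal]
        trimspec = derive_anchors(
            profile,
            conservation_threshold=params.conservation_threshold,
            anchor_length=params.anchor_length,
        )
    trimmed, trim_report = trim_to_anchors(oriented, trimspec)
    required = params.required_region or (1, len(reference))
    region = check_region_overlap(trimmed, reference, required)
    return trimmed, trim_report, region


def cluster_dataset(
    trimmed: Sequence[SequenceRecord],
    params: PipelineParams,
) -> tuple[list[Cluster], list[str]]:
    """Cluster one dataset at the identity threshold and drop chimeric clusters.

    Chimera screening runs on cluster representatives (a chimera of two
    sufficiently divergent parents founds its own cluster); all reads of a
    flagged representative's cluster are discarded.
    """
    clusters = greedy_cluster(trimmed, params.identity)
    reps = [
        SequenceRecord(id=c.rep_id, dataset_id=c.dataset_id, residues=c.rep_seq)
        for c in clusters
    ]
    abundances = {c.rep_id: c.size for c in clusters}
    _, chimeric_reps = detect_chimeras(
        reps, abundances, params.chimera, params.identity
    )
    bad = {r.id for r in chimeric_reps}
    kept = [c for c in clusters if c.rep_id not in bad]
    removed_reads = [rid for c in clusters if c.rep_id in bad
                     for rid in c.member_ids]
    return kept, removed_reads


def counts_from_otus(
    otus: Sequence[UniversalOTU], dataset_ids: Sequence[str]
) -> pd.DataFrame:
    """OTU x survey-dataset count matrix over OTUs with rumen-survey members."""
    rows = {}
    for otu in otus:
        if not otu.contains_rumen_survey:
            continue
        rows[otu.otu_id] = [otu.members_by_dataset.get(ds, 0) for ds in dataset_ids]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(dataset_ids))


def run_pipeline(
    datasets: Mapping[str, Sequence[SequenceRecord]],
    cultured: Sequence[SequenceRecord],
    reference: str,
    taxonomy_by_source: Mapping[str, TaxonomyAssignment] | None = None,
    read_to_taxon: Mapping[str, str] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run every stage and return all intermediate and final artifacts.

    ``taxonomy_by_source`` maps source sequence ids (cultured references or
    community taxa) to taxonomy; ``read_to_taxon`` maps read ids to taxon
    ids so universal OTUs inherit taxonomy through their representative,
    standing in for an external classifier.
    """
    params = params or PipelineParams()

    trim_reports: dict[str, TrimReport] = {}
    region_reports: dict[str, RegionReport] = {}
    dataset_clusters: dict[str, list[Cluster]] = {}
    chimeric_ids: dict[str, list[str]] = {}
    retained: list[str] = []
    for ds in sorted(datasets):
        trimmed, trep, rrep = preprocess_dataset(datasets[ds], reference, params)
        trim_reports[ds] = trep
        region_reports[ds] = rrep
        if not rrep.overlaps_required_region:
            logger.warning("dataset %s does not cover the required region; "
                           "excluded from the analysis", ds)
            continue
        clusters, removed = cluster_dataset(trimmed, params)
        dataset_clusters[ds] = clusters
        chimeric_ids[ds] = removed
        retained.append(ds)
    if not retained:
        raise ValueError("no dataset covers the required region")

    cultured_clusters = greedy_cluster(list(cultured), params.identity)

    sliced = trim_representatives_to_common_window(
        {**dataset_clusters, CULTURED_DATASET: cultured_clusters}, reference
    )
    otus = build_universal_otus(
        {ds: sliced[ds] for ds in retained}, sliced[CULTURED_DATASET],
        params.identity,
    )

    counts = counts_from_otus(otus, retained)
    tmm = tmm_factors(counts)
    summary = summarize_abundance(counts, tmm)

    rep_seqs = {o.otu_id: o.rep_seq for o in otus}
    tree = nj_tree(p_distance_matrix(rep_seqs))
    cultured_tips = {o.otu_id for o in otus if o.contains_cultured}
    nearest = nearest_results_frame(
        nearest_cultured_distances(tree, cultured_tips)
    )

    rumen_ids = [o.otu_id for o in otus if o.contains_rumen_survey]
    metrics = scale_metrics(nearest.loc[rumen_ids], summary.loc[rumen_ids])
    metrics = classify(metrics, params.thresholds, n_datasets=len(retained))

    rumen_tree = prune_tree(tree, rumen_ids) if len(rumen_ids) >= 2 else tree
    clades = partition_clades(rumen_tree, params.clade_max_within_distance)

    otu_taxonomy = assign_otu_taxonomy(
        otus, taxonomy_by_source or {}, read_to_taxon or {}
    )
    candidates, effort = select_candidates(metrics, otu_taxonomy,
                                           params.thresholds)
    return PipelineResult(
        trim_reports=trim_reports,
        region_reports=region_reports,
        dataset_clusters=dataset_clusters,
        chimeric_read_ids=chimeric_ids,
        cultured_clusters=cultured_clusters,
        universal_otus=otus,
        counts=counts,
        tmm=tmm,
        abundance_summary=summary,
        tree=tree,
        nearest=nearest,
        metrics=metrics,
        rumen_tree=rumen_tree,
        clades=clades,
        otu_taxonomy=otu_taxonomy,
        candidates=candidates,
        needs_cultivation=effort,
    )


def assign_otu_taxonomy(
    otus: Sequence[UniversalOTU],
    taxonomy_by_source: Mapping[str, TaxonomyAssignment],
    read_to_taxon: Mapping[str, str],
) -> dict[str, TaxonomyAssignment]:
    """Propagate source taxonomy to universal OTUs via their representative."""
    out: dict[str, TaxonomyAssignment] = {}
    for otu in otus:
        rep = otu.representative
        source = read_to_taxon.get(rep, rep)
        tax = taxonomy_by_source.get(source)
        if tax is None:
            out[otu.otu_id] = TaxonomyAssignment(otu_id=otu.otu_id,
                                                 ranks=["unclassified"])
        else:
            out[otu.otu_id] = TaxonomyAssignment(
                otu_id=otu.otu_id,
                ranks=list(tax.ranks),
                similarity_to_nearest_cultured=tax.similarity_to_nearest_cultured,
                nearest_cultured_id=tax.nearest_cultured_id,
            )
    return out


def read_to_taxon_map(truth_reads: pd.DataFrame) -> dict[str, str]:
    """read_id -> taxon_id (chimeras keep their composite label)."""
    return dict(zip(truth_reads["read_id"], truth_reads["taxon_id"]))


def otu_taxon_sets(
    result: PipelineResult, truth_reads: pd.DataFrame
) -> dict[str, set[str]]:
    """Taxa whose non-chimeric survey reads each universal OTU contains.

    Ground-truth bookkeeping for recovery checks: walks tier-1 membership
    back to read provenance.
    """
    clean = truth_reads[~truth_reads["is_chimera"]]
    read_taxon = dict(zip(clean["read_id"], clean["taxon_id"]))
    members = {
        (ds, cl.rep_id): cl.member_ids
        for ds, cls in result.dataset_clusters.items()
        for cl in cls
    }
    out: dict[str, set[str]] = {}
    for otu in result.universal_otus:
        taxa: set[str] = set()
        for source, rep in otu.tier1_members:
            if source == CULTURED_DATASET:
                continue
            for rid in members.get((source, rep), []):
                taxon = read_taxon.get(rid)
                if taxon is not None:
                    taxa.add(taxon)
        out[otu.otu_id] = taxa
    return out
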