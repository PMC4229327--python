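"""Greedy identity clustering, chimera screening and the two-tier OTU merge.

Species-level OTUs are formed per dataset by greedy incremental clustering
at 97% identity (longest sequence first; a read joins the first cluster
whose representative it matches at or above the threshold, otherwise it
founds a new cluster).  Representatives from every dataset, together with
representatives of the cultured-isolate pool, are then clustered again at
the same threshold to give *universal* OTUs whose per-dataset membership
tallies and contains-cultured flags drive all downstream metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from ._util import kmer_set
from .io_formats import CULTURED_DATASET, SequenceRecord
from .preprocess import map_to_reference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentityParams:
    """Definition of percent identity used by every clustering step.

    Identity = identical aligned positions / denominator, from a global
    alignment with affine gap costs (match +1, mismatch -1, open -5,
    extend -1).  The default denominator is the shorter sequence length,
    the convention of greedy clustering tools for mixed-length reads.
    """

    threshold: float = 0.97
    word_size: int = 8
    denominator_rule: str = "shorter_sequence"  # or "alignment_length"

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0.5, 1]")
        if self.denominator_rule not in ("shorter_sequence", "alignment_length"):
            raise ValueError(f"unknown denominator_rule {self.denominator_rule!r}")


@dataclass
class Cluster:
    rep_id: str
    member_ids: list[str]
    dataset_id: str
    rep_seq: str = ""

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class UniversalOTU:
    """A second-tier cluster over per-dataset and cultured representatives."""

    otu_id: str
    members_by_dataset: dict[str, int]
    contains_cultured: bool
    representative: str
    rep_seq: str = ""
    #: (source dataset, tier-1 representative id) of every merged cluster
    tier1_members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def contains_rumen_survey(self) -> bool:
        return any(
            n > 0 for ds, n in self.members_by_dataset.items()
            if ds != CULTURED_DATASET
        )


@dataclass(frozen=True)
class ChimeraParams:
    p_hi: float = 0.99
    p_lo: float = 0.97
    min_parent_fold: float = 2.0
    min_segment: int = 30
    max_parents: int | None = None  # cap on candidate parents; None = all


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _align(a: str, b: str):
    return _ALIGNER.align(a, b)[0]


def pairwise_identity(a, b, params: IdentityParams = IdentityParams()) -> float:
    """Fraction of identical aligned positions between two sequences."""
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    if sa == sb:
        return 1.0
    aln = _align(sa, sb)
    counts = aln.counts()
    if params.denominator_rule == "shorter_sequence":
        denom = min(len(sa), len(sb))
    else:
        denom = aln.length
    return counts.identities / denom


def _word_filter_reject(
    shared: int, min_n: int, k: int, threshold: float
) -> bool:
    """True when the shared-word count rigorously rules out ``threshold``.

    If the optimal alignment reaches identity >= t over the shorter
    sequence (length n), at most (1-t)n of its positions are non-identical,
    and each such position breaks at most k of the n-k+1 k-mer windows, so
    the sequences share at least n-(k-1) - k(1-t)n exact words.  A count
    below that (minus a small slack for repeated words) proves the pair is
    under the threshold without aligning — the word-filter idea of greedy
    clustering tools.
    """
    required = min_n - (k - 1) - k * (1.0 - threshold) * min_n - k
    return shared < required


def greedy_cluster(
    reads: Sequence[SequenceRecord],
    params: IdentityParams = IdentityParams(),
) -> list[Cluster]:
    """Greedy incremental clustering at ``params.threshold`` identity.

    Input order is canonicalized (longest first, ties by id) so results are
    independent of file order.  Identical sequences are deduplicated before
    alignment, which keeps desk-scale datasets fast without changing the
    outcome.
    """
    if not reads:
        raise ValueError("greedy_cluster requires at least one read")
    ordered = sorted(reads, key=lambda r: (-len(r.residues), r.id))
    dataset_ids = {r.dataset_id for r in reads}
    dataset_id = dataset_ids.pop() if len(dataset_ids) == 1 else "universal"

    # representative sequences in founding order
    clusters: list[Cluster] = []
    rep_kmers: list[set[str]] = []
    seq_to_cluster: dict[str, int] = {}
    k = params.word_size
    for read in ordered:
        seq = read.residues
        idx = seq_to_cluster.get(seq)
        if idx is None:
            kmers = kmer_set(seq, k) if len(seq) >= k else {seq}
            for j, cl in enumerate(clusters):
                min_n = min(len(seq), len(cl.rep_seq))
                if min_n >= k and _word_filter_reject(
                    len(kmers & rep_kmers[j]), min_n, k, params.threshold
                ):
                    continue
                if pairwise_identity(seq, cl.rep_seq, params) >= params.threshold:
                    idx = j
                    break
            if idx is None:
                clusters.append(
                    Cluster(rep_id=read.id, member_ids=[], dataset_id=dataset_id,
                            rep_seq=seq)
                )
                rep_kmers.append(kmers)
                idx = len(clusters) - 1
            seq_to_cluster[seq] = idx
        clusters[idx].member_ids.append(read.id)
    return clusters


def _match_profile(query: str, parent: str) -> np.ndarray:
    """cum[i] = identical positions among the first i query positions when
    query is globally aligned to parent."""
    n = len(query)
    match = np.zeros(n, dtype=bool)
    if len(query) == len(parent):
        qa = np.frombuffer(query.encode(), dtype=np.uint8)
        pa = np.frombuffer(parent.encode(), dtype=np.uint8)
        match = qa == pa
    else:
        aln = _align(query, parent)
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            seg_t = query[ts:te]
            seg_q = parent[qs:qe]
            for off, (x, y) in enumerate(zip(seg_t, seg_q)):
                if x == y:
                    match[ts + off] = True
    cum = np.zeros(n + 1, dtype=np.int64)
    cum[1:] = np.cumsum(match)
    return cum


def detect_chimeras(
    reads: Sequence[SequenceRecord],
    cluster_abundances: Mapping[str, int],
    params: ChimeraParams = ChimeraParams(),
    identity_params: IdentityParams = IdentityParams(),
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split reads into (clean, chimeric) by the parent-crossover rule.

    A read is chimeric when some split position and pair of candidate
    parents (A, B) exist such that its prefix matches A and its suffix
    matches B at >= ``p_hi`` identity while its full length stays at
    <= ``p_lo`` identity to both — the signature of a PCR crossover between
    two more-abundant templates.  Candidate parents must carry at least
    ``min_parent_fold`` times the query's cluster abundance.
    """
    clean: list[SequenceRecord] = []
    chimeric: list[SequenceRecord] = []
    by_abundance = sorted(
        reads, key=lambda r: (-cluster_abundances.get(r.id, 1), r.id)
    )
    k = identity_params.word_size
    kmers = {r.id: kmer_set(r.residues, k) for r in reads}
    for query in reads:
        q_ab = cluster_abundances.get(query.id, 1)
        parents = [
            p for p in by_abundance
            if p.id != query.id
            and cluster_abundances.get(p.id, 1) >= params.min_parent_fold * q_ab
        ]
        if params.max_parents is not None:
            parents = parents[: params.max_parents]
        if len(parents) < 2:
            clean.append(query)
            continue
        n = len(query.residues)
        profiles = {}
        usable = []
        for p in parents:
            min_n = min(n, len(p.residues))
            # word filter can certify full identity < p_lo without aligning
            if min_n >= k and _word_filter_reject(
                len(kmers[query.id] & kmers[p.id]), min_n, k, params.p_lo
            ):
                full = 0.0
            else:
                full = pairwise_identity(query.residues, p.residues,
                                         identity_params)
            if full <= params.p_lo:
                profiles[p.id] = _match_profile(query.residues, p.residues)
                usable.append(p)
        is_chimera = False
        if len(usable) >= 2 and n >= 2 * params.min_segment:
            splits = np.arange(params.min_segment, n - params.min_segment + 1)
            pref = {
                p.id: profiles[p.id][splits] / splits for p in usable
            }
            suff = {
                p.id: (profiles[p.id][n] - profiles[p.id][splits]) / (n - splits)
                for p in usable
            }
            for pa in usable:
                if is_chimera:
                    break
                ok_a = pref[pa.id] >= params.p_hi
                if not ok_a.any():
                    continue
                for pb in usable:
                    if pb.id == pa.id:
                        continue
                    if np.any(ok_a & (suff[pb.id] >= params.p_hi)):
                        is_chimera = True
                        break
        (chimeric if is_chimera else clean).append(query)
    logger.info(
        "detect_chimeras: %d reads screened, %d flagged chimeric",
        len(reads), len(chimeric),
    )
    return clean, chimeric


def trim_representatives_to_common_window(
    clusters_by_source: Mapping[str, Sequence[Cluster]],
    reference_16s: str,
    min_overlap: int = 50,
) -> dict[str, list[Cluster]]:
    """Slice every representative to the reference window shared by all sources.

    Each representative is placed on the reference by its best ungapped
    mapping; a dataset's covered interval is the *modal* mapped interval of
    its representatives, so rare mis-trimmed fragments cannot shrink it;
    the common window is the intersection over survey datasets (the
    cultured pool spans the full gene and does not constrain it).
    Representatives that do not cover the window are dropped with a warning.
    """

    def _mode(values: list[int]) -> int:
        return max(sorted(set(values)), key=values.count)

    placements: dict[str, list[tuple[Cluster, int, int]]] = {}
    starts, ends = [], []
    for source, clusters in clusters_by_source.items():
        placed = []
        for cl in clusters:
            hit = map_to_reference(cl.rep_seq, reference_16s)
            if hit is None:
                logger.warning("representative %s longer than reference; dropped",
                               cl.rep_id)
                continue
            placed.append((cl, hit[0], hit[1]))
        placements[source] = placed
        if source != CULTURED_DATASET and placed:
            starts.append(_mode([p[1] for p in placed]))
            ends.append(_mode([p[2] for p in placed]))
    if not starts:
        raise ValueError("no survey representatives to define a common window")
    win_lo, win_hi = max(starts), min(ends)
    if win_hi - win_lo + 1 < min_overlap:
        raise ValueError(
            f"common window [{win_lo}, {win_hi}] shorter than {min_overlap} nt"
        )
    logger.info("common representative window on reference: [%d, %d]",
                win_lo, win_hi)
    out: dict[str, list[Cluster]] = {}
    for source, placed in placements.items():
        kept = []
        for cl, s, e in placed:
            if s > win_lo or e < win_hi:
                logger.warning(
                    "representative %s (%s) does not cover the common window; dropped",
                    cl.rep_id, source,
                )
                continue
            sliced = cl.rep_seq[win_lo - s : win_hi - s + 1]
            kept.append(
                Cluster(rep_id=cl.rep_id, member_ids=list(cl.member_ids),
                        dataset_id=cl.dataset_id, rep_seq=sliced)
            )
        out[source] = kept
    return out


def build_universal_otus(
    dataset_clusters: Mapping[str, Sequence[Cluster]],
    cultured_clusters: Sequence[Cluster],
    params: IdentityParams = IdentityParams(),
    min_rep_length: int = 50,
) -> list[UniversalOTU]:
    """Cluster tier-1 representatives into universal OTUs.

    Representatives of all per-dataset clusters and of the cultured pool
    (already trimmed to a shared homologous region) are greedily clustered
    at the same identity threshold; member tallies are aggregated per source
    dataset and an OTU contains a cultured isolate iff any cultured
    representative merged into it.
    """
    pseudo: list[SequenceRecord] = []
    meta: dict[str, tuple[str, int, bool]] = {}
    sources = dict(dataset_clusters)
    sources[CULTURED_DATASET] = list(cultured_clusters)
    for source in sorted(sources):
        for cl in sources[source]:
            if len(cl.rep_seq) < min_rep_length:
                logger.warning(
                    "representative %s (%s) shorter than %d nt; excluded",
                    cl.rep_id, source, min_rep_length,
                )
                continue
            pid = f"{source}|{cl.rep_id}"
            pseudo.append(
                SequenceRecord(id=pid, dataset_id=source, residues=cl.rep_seq,
                               is_cultured=source == CULTURED_DATASET)
            )
            meta[pid] = (source, cl.size, source == CULTURED_DATASET)
    tier2 = greedy_cluster(pseudo, params)
    otus: list[UniversalOTU] = []
    for i, cl in enumerate(tier2):
        tally: dict[str, int] = {}
        cultured = False
        tier1: list[tuple[str, str]] = []
        for pid in cl.member_ids:
            source, size, is_cult = meta[pid]
            tally[source] = tally.get(source, 0) + size
            cultured = cultured or is_cult
            tier1.append((source, pid.split("|", 1)[1]))
        otus.append(
            UniversalOTU(
                otu_id=f"UOTU{i + 1:05d}",
                members_by_dataset=tally,
                contains_cultured=cultured,
                representative=cl.rep_id.split("|", 1)[1],
                rep_seq=cl.rep_seq,
                tier1_members=tier1,
            )
        )
    return otus
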