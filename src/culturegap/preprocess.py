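"""Per-dataset read cleaning: orientation, conserved-anchor trimming, length
and region filters.

Amplicon surveys deposit reads in mixed orientations and over different 16S
windows.  This stage (i) flips reads onto the reference strand by k-mer
voting, (ii) derives short conserved anchor motifs from an alignment of the
dataset's sequences and trims every read to the homologous span strictly
between its anchor matches, and (iii) checks that the dataset's covered
region contains the required reference interval (the V1+V2 window by
default) so that surveys over disjoint windows are excluded before any
cross-dataset comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import encode, kmer_set, revcomp
from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class TrimSpec:
    """Anchor motifs delimiting the homologous region of one dataset."""

    anchor5: str
    anchor3: str
    max_mismatches: int = 2
    min_length: int = 1

    def __post_init__(self) -> None:
        if not self.anchor5 or not self.anchor3:
            raise ValueError("anchors must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class RegionReport:
    """Where a dataset's consensus maps on the reference 16S (1-based)."""

    dataset_id: str
    covered_start: int
    covered_end: int
    overlaps_required_region: bool

    def __post_init__(self) -> None:
        if self.covered_start > self.covered_end:
            raise ValueError("interval start must be <= end")


@dataclass
class TrimReport:
    dataset_id: str
    n_input: int
    n_kept: int
    n_missing_anchor: int
    n_anchor_conflict: int
    n_too_short: int
    mean_length_before: float
    mean_length_after: float

    @property
    def fraction_discarded(self) -> float:
        return 0.0 if self.n_input == 0 else 1.0 - self.n_kept / self.n_input


class AnchorDerivationError(ValueError):
    """No sufficiently conserved run exists; anchors must be supplied manually."""


def orient_reads(
    reads: Sequence[SequenceRecord],
    reference_16s: str,
    k: int = 12,
) -> list[SequenceRecord]:
    """Return reads flipped onto the reference strand, dropping unorientable ones.

    Each read is compared to the reference by the number of shared k-mers in
    its given and reverse-complemented orientation; the richer orientation
    wins.  Reads sharing zero k-mers both ways (or tying) cannot be oriented
    and are dropped.
    """
    if k < 5:
        raise ValueError("k must be >= 5")
    if k > len(reference_16s):
        raise ValueError(
            f"k={k} exceeds reference length {len(reference_16s)}"
        )
    ref_kmers = kmer_set(reference_16s.upper(), k)
    oriented: list[SequenceRecord] = []
    n_flipped = n_dropped = 0
    for read in reads:
        fwd = len(kmer_set(read.residues, k) & ref_kmers)
        rc_seq = revcomp(read.residues)
        rev = len(kmer_set(rc_seq, k) & ref_kmers)
        if fwd == 0 and rev == 0 or fwd == rev:
            n_dropped += 1
            continue
        if rev > fwd:
            n_flipped += 1
            read = SequenceRecord(
                id=read.id,
                dataset_id=read.dataset_id,
                residues=rc_seq,
                is_cultured=read.is_cultured,
                is_rumen_origin=read.is_rumen_origin,
                description=read.description,
            )
        oriented.append(read)
    logger.info(
        "orient_reads: %d reads, %d flipped, %d dropped as unorientable",
        len(reads), n_flipped, n_dropped,
    )
    return oriented


def _consensus(columns: np.ndarray) -> str:
    """Majority residue per column of a (n_seqs, n_cols) byte matrix."""
    out = []
    for j in range(columns.shape[1]):
        vals, counts = np.unique(columns[:, j], return_counts=True)
        out.append(chr(vals[np.argmax(counts)]))
    return "".join(out)


def derive_anchors(
    alignment: Sequence[str],
    conservation_threshold: float = 0.9,
    anchor_length: int = 12,
    max_mismatches: int = 2,
    min_length: int | None = None,
) -> TrimSpec:
    """Derive 5' and 3' anchor motifs from an alignment of a dataset's sequences.

    A column is conserved when its modal residue (gaps excluded) reaches
    ``conservation_threshold``.  The 5' anchor is the consensus of the first
    ``anchor_length`` columns of the first maximal conserved run of at least
    that length; the 3' anchor is the last such columns of the last run.
    ``min_length`` defaults to half the inter-anchor span, the dataset-specific
    floor applied after trimming.
    """
    if not 0.5 < conservation_threshold <= 1.0:
        raise ValueError("conservation_threshold must be in (0.5, 1]")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    (ncol,) = lengths
    mat = np.vstack([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in alignment])
    n = mat.shape[0]
    conserved = np.zeros(ncol, dtype=bool)
    for j in range(ncol):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        keep = vals != ord("-")
        if not keep.any():
            continue
        conserved[j] = counts[keep].max() / n >= conservation_threshold

    # maximal runs of conserved columns of sufficient length
    runs: list[tuple[int, int]] = []
    start = None
    for j in range(ncol + 1):
        if j < ncol and conserved[j]:
            if start is None:
                start = j
        elif start is not None:
            if j - start >= anchor_length:
                runs.append((start, j))
            start = None
    if not runs:
        raise AnchorDerivationError(
            "no conserved run of length >= "
            f"{anchor_length} at threshold {conservation_threshold}; "
            "supply anchors manually"
        )
    first, last = runs[0], runs[-1]
    a5_cols = (first[0], first[0] + anchor_length)
    a3_cols = (last[1] - anchor_length, last[1])
    anchor5 = _consensus(mat[:, a5_cols[0] : a5_cols[1]])
    anchor3 = _consensus(mat[:, a3_cols[0] : a3_cols[1]])
    if min_length is None:
        span = max(a3_cols[0] - a5_cols[1], 2)
        min_length = max(1, span // 2)
    return TrimSpec(
        anchor5=anchor5,
        anchor3=anchor3,
        max_mismatches=max_mismatches,
        min_length=min_length,
    )


def _best_match(read_codes: np.ndarray, anchor_codes: np.ndarray, rightmost: bool):
    """(start, mismatches) of the best Hamming match of anchor in read.

    Ties go to the leftmost window unless ``rightmost``.  Returns None when
    the anchor is longer than the read.
    """
    m = anchor_codes.size
    if read_codes.size < m:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(read_codes, m)
    mism = (windows != anchor_codes).sum(axis=1)
    if rightmost:
        idx = mism.size - 1 - int(np.argmin(mism[::-1]))
    else:
        idx = int(np.argmin(mism))
    return idx, int(mism[idx])


def trim_to_anchors(
    reads: Sequence[SequenceRecord],
    spec: TrimSpec,
    dataset_id: str | None = None,
) -> tuple[list[SequenceRecord], TrimReport]:
    """Trim each read to the span strictly between its anchor matches.

    Reads lacking either anchor (more than ``max_mismatches`` at every
    offset), whose anchors match in conflicting order, or whose trimmed
    length falls under ``min_length`` are excluded and tallied separately.
    """
    a5 = encode(spec.anchor5)
    a3 = encode(spec.anchor3)
    kept: list[SequenceRecord] = []
    n_missing = n_conflict = n_short = 0
    len_before: list[int] = []
    len_after: list[int] = []
    for read in reads:
        len_before.append(len(read))
        codes = encode(read.residues)
        hit5 = _best_match(codes, a5, rightmost=False)
        hit3 = _best_match(codes, a3, rightmost=True)
        if (
            hit5 is None or hit3 is None
            or hit5[1] > spec.max_mismatches or hit3[1] > spec.max_mismatches
        ):
            n_missing += 1
            continue
        start = hit5[0] + len(spec.anchor5)
        end = hit3[0]
        if start > end:
            n_conflict += 1
            continue
        trimmed = read.residues[start:end]
        if len(trimmed) < spec.min_length:
            n_short += 1
            continue
        len_after.append(len(trimmed))
        kept.append(
            SequenceRecord(
                id=read.id,
                dataset_id=read.dataset_id,
                residues=trimmed,
                is_cultured=read.is_cultured,
                is_rumen_origin=read.is_rumen_origin,
                description=read.description,
            )
        )
    report = TrimReport(
        dataset_id=dataset_id or (reads[0].dataset_id if reads else ""),
        n_input=len(reads),
        n_kept=len(kept),
        n_missing_anchor=n_missing,
        n_anchor_conflict=n_conflict,
        n_too_short=n_short,
        mean_length_before=float(np.mean(len_before)) if len_before else 0.0,
        mean_length_after=float(np.mean(len_after)) if len_after else 0.0,
    )
    return kept, report


def map_to_reference(seq: str, reference: str) -> tuple[int, int, float] | None:
    """Best ungapped placement of ``seq`` on ``reference``.

    Returns 1-based inclusive (start, end) and the match fraction, or None
    when the sequence is longer than the reference.
    """
    s = encode(seq)
    r = encode(reference)
    if s.size > r.size:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(r, s.size)
    matches = (windows == s).sum(axis=1)
    off = int(np.argmax(matches))
    frac = matches[off] / s.size
    return off + 1, off + s.size, float(frac)


def check_region_overlap(
    trimmed_reads: Sequence[SequenceRecord],
    reference_16s: str,
    required_interval: tuple[int, int],
    min_map_fraction: float = 0.5,
) -> RegionReport:
    """Map the dataset consensus onto the reference and test containment.

    ``covered_region`` is the reference interval (1-based, inclusive)
    spanned by the best ungapped mapping of the dataset's consensus;
    ``overlaps_required_region`` is True iff it contains
    ``required_interval`` entirely.
    """
    lo, hi = required_interval
    if not (1 <= lo <= hi <= len(reference_16s)):
        raise ValueError("required_interval must lie within the reference")
    dataset_id = trimmed_reads[0].dataset_id if trimmed_reads else ""
    # consensus over the modal read length
    lengths = [len(r) for r in trimmed_reads]
    if not lengths:
        return RegionReport(dataset_id, 1, 1, False)
    modal = max(set(lengths), key=lengths.count)
    subset = [r.residues for r in trimmed_reads if len(r) == modal]
    mat = np.vstack([encode(s) for s in subset])
    consensus = []
    for j in range(modal):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        consensus.append(vals[np.argmax(counts)])
    cons = np.array(consensus, dtype=np.uint8)
    from ._util import decode

    hit = map_to_reference(decode(cons), reference_16s)
    if hit is None or hit[2] < min_map_fraction:
        logger.warning(
            "dataset %s: consensus unmappable on reference (best fraction %s)",
            dataset_id, None if hit is None else round(hit[2], 3),
        )
        return RegionReport(dataset_id, 1, 1, False)
    start, end, _ = hit
    return RegionReport(
        dataset_id=dataset_id,
        covered_start=start,
        covered_end=end,
        overlaps_required_region=(start <= lo and end >= hi),
    )
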