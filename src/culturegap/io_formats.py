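"""Readers and writers for the external formats the pipeline touches.

FASTA carries reads and reference sequences, newick carries trees, and all
tabular artifacts (counts, taxonomy, metrics, truth tables) are
tab-separated files with a header line; lines starting with ``#`` are
comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from ._util import IUPAC_DNA

#: dataset_id reserved for the cultured-isolate reference pool.
CULTURED_DATASET = "cultured"


@dataclass
class SequenceRecord:
    """One oriented DNA read or reference sequence with dataset provenance."""

    id: str
    dataset_id: str
    residues: str
    is_cultured: bool = False
    is_rumen_origin: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TaxonomyAssignment:
    """Externally produced taxonomy for one OTU (or reference taxon).

    ``ranks`` is ordered phylum -> genus; any suffix may be "unclassified".
    ``similarity_to_nearest_cultured`` is a percent identity in [0, 100]
    against the nearest cultured *rumen* isolate, when known.
    """

    otu_id: str
    ranks: list[str] = field(default_factory=lambda: ["unclassified"])
    similarity_to_nearest_cultured: float | None = None
    nearest_cultured_id: str | None = None

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError(f"{self.otu_id}: taxonomy needs at least a phylum")
        s = self.similarity_to_nearest_cultured
        if s is not None and not (0.0 <= s <= 100.0):
            raise ValueError(f"{self.otu_id}: similarity {s} outside [0, 100]")

    @property
    def phylum(self) -> str:
        return self.ranks[0]


RANK_NAMES = ["phylum", "class", "order", "family", "genus"]


def read_fasta(
    path,
    dataset_id: str,
    cultured: bool = False,
    rumen_origin: bool = False,
) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; the
    remainder is kept as a free-text description.  Residues are upper-cased.
    Duplicate ids within one file and empty sequences are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {entry.id!r} has an empty sequence")
        desc = entry.description[len(entry.id) :].strip()
        records.append(
            SequenceRecord(
                id=entry.id,
                dataset_id=dataset_id,
                residues=seq,
                is_cultured=cultured,
                is_rumen_origin=rumen_origin,
                description=desc,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n{rec.residues}\n")


def read_newick(path):
    """Read a single-tree newick file into a :class:`~culturegap.phylogeny.PhyloTree`.

    Missing branch lengths are set to 1.0 with a warning; duplicate tip
    labels are a hard error.
    """
    from .phylogeny import PhyloTree

    return PhyloTree.from_newick_file(path)


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


# ---------------------------------------------------------------------------
# tab-separated tables


def read_counts_table(path) -> pd.DataFrame:
    """Read an OTU x dataset count table (rows = OTU ids).

    Counts must be non-negative integers; violations are hard errors naming
    the offending cell.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        series = df[col]
        for otu, val in series.items():
            fval = float(val)
            if fval < 0 or fval != int(fval):
                raise ValueError(
                    f"{path}: count for OTU {otu!r} in dataset {col!r} is "
                    f"{val!r}; counts must be non-negative integers"
                )
    return df.astype(int)


def write_counts_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="otu_id")


def write_metrics_table(metrics: pd.DataFrame, path) -> None:
    """Write a per-OTU metrics table; floats keep >= 6 significant digits."""
    metrics.to_csv(path, sep="\t", index_label="otu_id", float_format="%.8g")


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_taxonomy_table(path) -> dict[str, TaxonomyAssignment]:
    """Read a taxonomy TSV (id, phylum..genus, similarity, nearest id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out: dict[str, TaxonomyAssignment] = {}
    for _, row in df.iterrows():
        ranks = [row.get(r, "") or "unclassified" for r in RANK_NAMES]
        sim = row.get("similarity_to_nearest_cultured", "")
        near = row.get("nearest_cultured_id", "") or None
        out[row["id"]] = TaxonomyAssignment(
            otu_id=row["id"],
            ranks=ranks,
            similarity_to_nearest_cultured=float(sim) if sim else None,
            nearest_cultured_id=near,
        )
    return out


def write_taxonomy_table(assignments: Mapping[str, TaxonomyAssignment], path) -> None:
    rows = []
    for key in assignments:
        tax = assignments[key]
        ranks = list(tax.ranks) + ["unclassified"] * (len(RANK_NAMES) - len(tax.ranks))
        row = {"id": key}
        row.update(dict(zip(RANK_NAMES, ranks)))
        row["similarity_to_nearest_cultured"] = (
            "" if tax.similarity_to_nearest_cultured is None
            else f"{tax.similarity_to_nearest_cultured:.4f}"
        )
        row["nearest_cultured_id"] = tax.nearest_cultured_id or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
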