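"""Synthetic multi-survey 16S communities with full ground truth.

The generator emulates the statistical structure the analysis assumes:
several amplicon surveys covering overlapping but non-identical windows of
a master 16S-like gene, log-normal taxon abundances with a shared core
taxon set, a cultured-isolate reference pool, community lineages at
controlled divergence from that pool, plus planted chimeras and
reverse-complemented reads.

The master gene alternates conserved and hypervariable blocks, as real 16S
does; divergence is applied at variable sites only.  Conserved flanks at
the window edges are therefore exactly the anchors the trimming stage must
rediscover, and divergence parameters are expressed as expected
substitutions per site over the whole gene.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._util import decode, revcomp
from .io_formats import (
    CULTURED_DATASET,
    SequenceRecord,
    TaxonomyAssignment,
    ensure_dir,
    write_fasta,
    write_taxonomy_table,
)

# conserved (C) / hypervariable (V) block layout of the master gene
_BLOCKS = [
    ("C", 120), ("V", 80), ("C", 100), ("V", 120), ("C", 150), ("V", 100),
    ("C", 150), ("V", 120), ("C", 160), ("V", 100), ("C", 150), ("V", 80),
    ("C", 170),
]
MASTER_LENGTH = sum(n for _, n in _BLOCKS)

#: V1 and V2 analogue: the first two hypervariable blocks (0-based, half-open)
V1_SPAN = (120, 200)
V2_SPAN = (300, 420)
#: required reference interval, 1-based inclusive, for the region filter
REQUIRED_REGION = (V1_SPAN[0] + 1, V2_SPAN[1])

# Windows emulate V1+V2-spanning primer pairs: short conserved flanks
# around the two hypervariable blocks, never running deep into the long
# conserved stretch downstream (which would dilute the informative sites).
_DEFAULT_WINDOWS = [
    (85, 455), (90, 450), (80, 470), (95, 480), (70, 460), (88, 445), (100, 475),
]

_PHYLA = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Spirochaetes", "Fibrobacteres"]
_PHYLA_W = [0.45, 0.30, 0.10, 0.05, 0.05, 0.05]


def _variable_mask() -> np.ndarray:
    mask = np.zeros(MASTER_LENGTH, dtype=bool)
    pos = 0
    for kind, n in _BLOCKS:
        if kind == "V":
            mask[pos : pos + n] = True
        pos += n
    return mask


@dataclass
class SimulationConfig:
    """Parameters of one simulated multi-survey study.

    Divergences are expected substitutions/site over the whole gene;
    fractions are per-read probabilities.  Defaults give seven surveys of
    2000 reads each over windows all covering the V1+V2 analogue, a
    30-sequence cultured pool, 25 community lineages within clustering
    range of the pool and 8 novel lineages well outside it, with a shared
    core taxon set planted in every survey.
    """

    seed: int = 0
    n_datasets: int = 7
    reads_per_dataset: int = 2000
    n_cultured_refs: int = 30
    rumen_origin_fraction: float = 0.5
    n_near_taxa: int = 25
    n_novel_lineages: int = 8
    cultured_pool_divergence: float = 0.04
    near_divergence: float = 0.01
    novel_divergence: float = 0.20
    core_fraction: float = 0.30
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.2
    core_jitter_sigma: float = 0.3
    min_relative_abundance: float = 0.005
    max_noncore_presence: int = 4
    per_base_error_rate: float = 0.0
    chimera_fraction: float = 0.05
    revcomp_fraction: float = 0.10
    anchorless_fraction: float = 0.17
    anchor_length: int = 12
    novel_scaled_cutoff: float = 0.25
    abundant_scaled_cutoff: float = 0.25
    amplicon_windows: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        for name in ("rumen_origin_fraction", "core_fraction",
                     "per_base_error_rate", "chimera_fraction",
                     "revcomp_fraction", "anchorless_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_near_taxa > self.n_cultured_refs:
            raise ValueError("n_near_taxa cannot exceed n_cultured_refs")
        if self.amplicon_windows is None:
            self.amplicon_windows = [
                _DEFAULT_WINDOWS[i % len(_DEFAULT_WINDOWS)]
                for i in range(self.n_datasets)
            ]
        if len(self.amplicon_windows) != self.n_datasets:
            raise ValueError("need one amplicon window per dataset")
        lo = max(w[0] for w in self.amplicon_windows)
        hi = min(w[1] for w in self.amplicon_windows)
        if lo >= hi:
            raise ValueError("amplicon windows share no common overlap")
        req_lo, req_hi = REQUIRED_REGION[0] - 1, REQUIRED_REGION[1]
        for ws, we in self.amplicon_windows:
            if not (ws <= req_lo - self.anchor_length
                    and we >= req_hi + self.anchor_length):
                raise ValueError(
                    f"window ({ws}, {we}) does not cover the required region "
                    f"plus conserved flanks"
                )

    @property
    def dataset_ids(self) -> list[str]:
        return [f"ds{i:02d}" for i in range(self.n_datasets)]


@dataclass
class TruthTable:
    """Generator bookkeeping: per-read provenance and per-taxon labels."""

    reads: pd.DataFrame   # read_id, dataset_id, taxon_id, is_chimera, ...
    taxa: pd.DataFrame    # indexed by taxon_id; labels + per-dataset abundances
    trim_intervals: dict[str, tuple[int, int]]  # master coords per dataset
    anchors: dict[str, tuple[str, str]]         # planted (anchor5, anchor3)
    pool_radius: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: str
    cultured: list[SequenceRecord]
    datasets: dict[str, list[SequenceRecord]]
    taxonomy: dict[str, TaxonomyAssignment]
    truth: TruthTable


def _evolve(codes: np.ndarray, divergence: float, var_mask: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions at variable sites so the whole-gene
    expected divergence equals ``divergence``."""
    if divergence <= 0:
        return codes.copy()
    frac_var = var_mask.mean()
    rate = min(divergence / frac_var, 0.75)
    hit = var_mask & (rng.random(codes.size) < rate)
    out = codes.copy()
    # shift by 1..3 so a substitution always changes the base
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _apply_errors(codes: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    hit = rng.random(codes.size) < rate
    if not hit.any():
        return codes
    out = codes.copy()
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def simulate(config: SimulationConfig, out_dir=None) -> SimulationResult:
    """Generate a full synthetic study; optionally write it to ``out_dir``.

    Fully reproducible from ``config.seed``: two calls with equal configs
    produce identical records and files.
    """
    rng = np.random.default_rng(config.seed)
    var_mask = _variable_mask()
    master = rng.integers(0, 4, size=MASTER_LENGTH).astype(np.uint8)

    # --- cultured pool -----------------------------------------------------
    n_refs = config.n_cultured_refs
    ref_codes = [
        _evolve(master, config.cultured_pool_divergence, var_mask, rng)
        for _ in range(n_refs)
    ]
    ref_ids = [f"iso{i + 1:04d}" for i in range(n_refs)]
    rumen_flags = rng.random(n_refs) < config.rumen_origin_fraction
    if not rumen_flags.any():
        rumen_flags[0] = True
    ref_phyla = list(rng.choice(_PHYLA, size=n_refs, p=_PHYLA_W))

    ref_mat = np.vstack(ref_codes)
    # pool radius: median nearest-neighbour divergence within the pool
    pool_nn = []
    for i in range(n_refs):
        d = (ref_mat != ref_mat[i]).mean(axis=1)
        d[i] = np.inf
        pool_nn.append(d.min())
    pool_radius = float(np.median(pool_nn))

    # --- community taxa ----------------------------------------------------
    taxon_codes: list[np.ndarray] = []
    taxon_ids: list[str] = []
    taxon_phyla: list[str] = []
    is_novel_lineage: list[bool] = []
    source_ref: list[str | None] = []
    near_sources = rng.choice(n_refs, size=config.n_near_taxa, replace=False)
    for j, ridx in enumerate(near_sources):
        taxon_codes.append(
            _evolve(ref_codes[ridx], config.near_divergence, var_mask, rng)
        )
        taxon_ids.append(f"tax{j + 1:03d}")
        taxon_phyla.append(ref_phyla[ridx])
        is_novel_lineage.append(False)
        source_ref.append(ref_ids[ridx])
    for j in range(config.n_novel_lineages):
        taxon_codes.append(
            _evolve(master, config.novel_divergence, var_mask, rng)
        )
        taxon_ids.append(f"tax{config.n_near_taxa + j + 1:03d}")
        taxon_phyla.append(str(rng.choice(_PHYLA, p=_PHYLA_W)))
        is_novel_lineage.append(True)
        source_ref.append(None)
    n_taxa = len(taxon_ids)
    taxon_mat = np.vstack(taxon_codes)

    # nearest cultured reference per taxon (actual p-distance, whole gene)
    nearest_div = np.empty(n_taxa)
    nearest_ref = []
    rumen_sim = np.empty(n_taxa)
    rumen_nearest = []
    rumen_idx = np.flatnonzero(rumen_flags)
    for t in range(n_taxa):
        d = (ref_mat != taxon_mat[t]).mean(axis=1)
        k = int(np.argmin(d))
        nearest_div[t] = d[k]
        nearest_ref.append(ref_ids[k])
        kr = rumen_idx[int(np.argmin(d[rumen_idx]))]
        rumen_sim[t] = 100.0 * (1.0 - d[kr])
        rumen_nearest.append(ref_ids[kr])

    # --- presence and abundances -------------------------------------------
    n_core = max(1, round(config.core_fraction * n_taxa))
    core_idx = set(rng.choice(n_taxa, size=n_core, replace=False).tolist())
    D = config.n_datasets
    core_min = int(np.ceil(5.0 / 7.0 * D))
    # non-core taxa stay strictly under the core prevalence rule
    noncore_max = max(1, min(config.max_noncore_presence, core_min - 1))
    present = np.zeros((n_taxa, D), dtype=bool)
    base_w = rng.lognormal(config.abundance_lognormal_mu,
                           config.abundance_lognormal_sigma, size=n_taxa)
    for t in range(n_taxa):
        if t in core_idx:
            present[t, :] = True
        else:
            k = int(rng.integers(1, noncore_max + 1))
            cols = rng.choice(D, size=k, replace=False)
            present[t, cols] = True
    rel = np.zeros((n_taxa, D))
    for d_i in range(D):
        w = np.zeros(n_taxa)
        for t in range(n_taxa):
            if not present[t, d_i]:
                continue
            if t in core_idx:
                w[t] = base_w[t] * rng.lognormal(0.0, config.core_jitter_sigma)
            else:
                w[t] = rng.lognormal(config.abundance_lognormal_mu,
                                     config.abundance_lognormal_sigma)
        w = w / w.sum()
        # every planted taxon stays detectable at the configured depth:
        # taxa below the sampling floor would be absent by chance and the
        # planted labels would not describe the community actually emitted
        floor = config.min_relative_abundance
        w[(w > 0) & (w < floor)] = floor
        rel[:, d_i] = w / w.sum()

    # --- reads --------------------------------------------------------------
    datasets: dict[str, list[SequenceRecord]] = {}
    read_rows: list[dict] = []
    trim_intervals: dict[str, tuple[int, int]] = {}
    anchors: dict[str, tuple[str, str]] = {}
    L_anch = config.anchor_length
    c2_end = 570  # end of the conserved block after the V2 analogue
    for d_i, ds in enumerate(config.dataset_ids):
        ws, we = config.amplicon_windows[d_i]
        a3_end = min(we, c2_end)
        trim_intervals[ds] = (ws + L_anch, a3_end - L_anch)
        anchors[ds] = (
            decode(master[ws : ws + L_anch]),
            decode(master[a3_end - L_anch : a3_end]),
        )
        n = config.reads_per_dataset
        taxa_for_reads = rng.choice(n_taxa, size=n, p=rel[:, d_i])
        is_chim = rng.random(n) < config.chimera_fraction
        is_anchorless = (~is_chim) & (rng.random(n) < config.anchorless_fraction)
        is_rc = rng.random(n) < config.revcomp_fraction
        reads: list[SequenceRecord] = []
        for i in range(n):
            rid = f"{ds}_r{i:05d}"
            if is_chim[i]:
                # both parents drawn by abundance: crossover probability
                # tracks template concentration during PCR
                t_a = int(taxa_for_reads[i])
                t_b = t_a
                for _ in range(50):
                    t_b = int(rng.choice(n_taxa, p=rel[:, d_i]))
                    if t_b != t_a:
                        break
                split = int(rng.integers(int(0.3 * (we - ws)),
                                         int(0.7 * (we - ws))))
                codes = np.concatenate(
                    [taxon_mat[t_a, ws : ws + split], taxon_mat[t_b, ws + split : we]]
                )
                taxon_label = f"{taxon_ids[t_a]}+{taxon_ids[t_b]}"
            else:
                t_a = int(taxa_for_reads[i])
                if is_anchorless[i]:
                    delta = int(rng.integers(0, 20))
                    start = V1_SPAN[0] + delta
                else:
                    start = ws
                codes = taxon_mat[t_a, start:we]
                taxon_label = taxon_ids[t_a]
            codes = _apply_errors(codes, config.per_base_error_rate, rng)
            seq = decode(codes)
            if is_rc[i]:
                seq = revcomp(seq)
            reads.append(SequenceRecord(id=rid, dataset_id=ds, residues=seq))
            read_rows.append(
                {
                    "read_id": rid, "dataset_id": ds, "taxon_id": taxon_label,
                    "is_chimera": bool(is_chim[i]),
                    "was_revcomp": bool(is_rc[i]),
                    "has_anchors": bool(is_chim[i] or not is_anchorless[i]),
                }
            )
        datasets[ds] = reads

    # --- truth labels -------------------------------------------------------
    true_mean_percent = 100.0 * rel.mean(axis=1)
    scaled_ab = true_mean_percent / true_mean_percent.max()
    # effective distance: zero for lineages within clustering range of the
    # pool (they merge with a cultured representative), else the actual
    # nearest-cultured divergence
    eff = np.where(is_novel_lineage, nearest_div, 0.0)
    beyond_pool = eff > pool_radius
    eff = np.where(beyond_pool, eff, 0.0)
    max_eff = eff.max()
    scaled_eff = eff / max_eff if max_eff > 0 else eff
    true_novel = scaled_eff > config.novel_scaled_cutoff
    n_present = present.sum(axis=1)
    taxa_df = pd.DataFrame(
        {
            "phylum": taxon_phyla,
            "is_novel_lineage": is_novel_lineage,
            "source_ref": [s or "" for s in source_ref],
            "nearest_cultured_id": nearest_ref,
            "nearest_cultured_divergence": nearest_div,
            "nearest_rumen_id": rumen_nearest,
            "nearest_rumen_similarity_percent": rumen_sim,
            "n_datasets_present": n_present,
            "true_core": n_present >= core_min,
            "true_novel": true_novel,
            "true_abundant": scaled_ab > config.abundant_scaled_cutoff,
            "true_mean_percent": true_mean_percent,
        },
        index=pd.Index(taxon_ids, name="taxon_id"),
    )
    for d_i, ds in enumerate(config.dataset_ids):
        taxa_df[f"rel_{ds}"] = rel[:, d_i]

    cultured_records = [
        SequenceRecord(
            id=ref_ids[i], dataset_id=CULTURED_DATASET,
            residues=decode(ref_codes[i]), is_cultured=True,
            is_rumen_origin=bool(rumen_flags[i]),
        )
        for i in range(n_refs)
    ]

    taxonomy: dict[str, TaxonomyAssignment] = {}
    for i, rid in enumerate(ref_ids):
        taxonomy[rid] = TaxonomyAssignment(
            otu_id=rid,
            ranks=[ref_phyla[i], "unclassified", "unclassified",
                   f"family{i % 9 + 1:02d}", "unclassified"],
            similarity_to_nearest_cultured=100.0 if rumen_flags[i] else None,
            nearest_cultured_id=rid if rumen_flags[i] else None,
        )
    for t, tid in enumerate(taxon_ids):
        taxonomy[tid] = TaxonomyAssignment(
            otu_id=tid,
            ranks=[taxon_phyla[t], "unclassified", "unclassified",
                   "unclassified" if is_novel_lineage[t] else f"family{t % 9 + 1:02d}",
                   "unclassified"],
            similarity_to_nearest_cultured=float(rumen_sim[t]),
            nearest_cultured_id=rumen_nearest[t],
        )

    truth = TruthTable(
        reads=pd.DataFrame(read_rows),
        taxa=taxa_df,
        trim_intervals=trim_intervals,
        anchors=anchors,
        pool_radius=pool_radius,
    )
    result = SimulationResult(
        config=config,
        reference=decode(master),
        cultured=cultured_records,
        datasets=datasets,
        taxonomy=taxonomy,
        truth=truth,
    )
    if out_dir is not None:
        write_simulation(result, out_dir)
    return result


def write_simulation(result: SimulationResult, out_dir) -> None:
    """Write FASTA/TSV/JSON artifacts for the CLI pipeline."""
    out = ensure_dir(out_dir)
    with open(out / "reference.fasta", "w") as fh:
        fh.write(f">reference_16s\n{result.reference}\n")
    write_fasta(result.cultured, out / "cultured.fasta")
    for ds, reads in result.datasets.items():
        write_fasta(reads, out / f"reads_{ds}.fasta")
    write_taxonomy_table(result.taxonomy, out / "taxonomy.tsv")
    result.truth.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    result.truth.taxa.to_csv(out / "truth_taxa.tsv", sep="\t",
                             float_format="%.8g")
    cfg = asdict(result.config)
    cfg["amplicon_windows"] = [list(w) for w in cfg["amplicon_windows"]]
    meta = {
        "config": cfg,
        "trim_intervals": {k: list(v) for k, v in result.truth.trim_intervals.items()},
        "anchors": {k: list(v) for k, v in result.truth.anchors.items()},
        "pool_radius": result.truth.pool_radius,
        "required_region": list(REQUIRED_REGION),
    }
    with open(out / "simulation.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
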