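"""Scaling, Euclidean ranking, and core/abundant/novel classification.

Nearest-cultured distances and mean percent abundances are each scaled by
their dataset-wide maximum so that every OTU lands in the unit square; the
Euclidean distance from the origin then ranks OTUs jointly by novelty and
abundance.  Flags: *core* = observed in at least five of seven surveys
(generalized to ceil(5/7 x D)); *abundant* / *novel* = scaled value
strictly greater than 0.25.  Flagged OTUs with >93% identity to a cultured
rumen isolate are sequencing candidates (one per isolate); the rest need
new cultivation effort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import TaxonomyAssignment


@dataclass
class ClassificationThresholds:
    novel_cutoff: float = 0.25
    abundant_cutoff: float = 0.25
    core_min_datasets: int | None = None  # None -> ceil(5/7 x D)
    candidate_similarity: float = 93.0

    def __post_init__(self) -> None:
        for name in ("novel_cutoff", "abundant_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.candidate_similarity < 100.0:
            raise ValueError("candidate_similarity must be a percent in (0, 100)")

    def core_min(self, n_datasets: int) -> int:
        if self.core_min_datasets is not None:
            if not 1 <= self.core_min_datasets <= n_datasets:
                raise ValueError("core_min_datasets outside [1, D]")
            return self.core_min_datasets
        return math.ceil(5.0 / 7.0 * n_datasets)


def scale_metrics(
    nearest_distances: pd.DataFrame,
    abundance_summary: pd.DataFrame,
) -> pd.DataFrame:
    """Join distances and abundances into a scaled per-OTU metrics table.

    ``nearest_distances`` needs columns distance (and optionally
    nearest_cultured_otu_id); ``abundance_summary`` needs
    mean_percent_abundance and prevalence.  Both must cover the same OTUs.
    Scaled values are ratios to the respective maxima; when every distance
    is zero all scaled distances are zero.
    """
    set_d = set(nearest_distances.index)
    set_a = set(abundance_summary.index)
    if set_d != set_a:
        diff = sorted(set_d.symmetric_difference(set_a))
        raise ValueError(f"OTU sets differ between inputs: {diff}")
    otus = sorted(set_d)
    dist = nearest_distances.loc[otus, "distance"].astype(float)
    abund = abundance_summary.loc[otus, "mean_percent_abundance"].astype(float)
    if not (abund > 0).any():
        raise ValueError("at least one OTU must have positive abundance")
    max_d = dist.max()
    scaled_d = dist / max_d if max_d > 0 else dist * 0.0
    scaled_a = abund / abund.max()
    out = pd.DataFrame(
        {
            "scaled_distance": scaled_d,
            "scaled_abundance": scaled_a,
            "prevalence": abundance_summary.loc[otus, "prevalence"].astype(float),
            "euclidean": np.hypot(scaled_d, scaled_a),
        },
        index=pd.Index(otus, name="otu_id"),
    )
    if "nearest_cultured_otu_id" in nearest_distances.columns:
        out["nearest_cultured_otu_id"] = nearest_distances.loc[
            otus, "nearest_cultured_otu_id"
        ]
    return out


def classify(
    metrics: pd.DataFrame,
    thresholds: ClassificationThresholds,
    n_datasets: int,
) -> pd.DataFrame:
    """Set is_core / is_abundant / is_novel flags (independent; overlap allowed).

    Cut-offs are strict inequalities; an OTU sitting exactly on 0.25 is not
    flagged.
    """
    out = metrics.copy()
    core_min = thresholds.core_min(n_datasets)
    # small tolerance so prevalence k/D stored as float compares exactly
    out["is_core"] = out["prevalence"] * n_datasets >= core_min - 1e-9
    out["is_abundant"] = out["scaled_abundance"] > thresholds.abundant_cutoff
    out["is_novel"] = out["scaled_distance"] > thresholds.novel_cutoff
    return out


def select_candidates(
    metrics: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyAssignment],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split flagged OTUs into sequencing candidates and cultivation targets.

    Among OTUs flagged core, abundant, or novel: those with similarity to a
    cultured rumen isolate above ``candidate_similarity`` become culture
    candidates, de-duplicated by nearest-isolate id (keeping the
    highest-similarity OTU, ties to the smaller OTU id); the remainder are
    emitted as requiring cultivation effort.
    """
    flagged = metrics[
        metrics["is_core"] | metrics["is_abundant"] | metrics["is_novel"]
    ]
    cand_rows, effort_rows = [], []
    for otu in flagged.index:
        tax = taxonomy.get(otu)
        sim = tax.similarity_to_nearest_cultured if tax else None
        near = tax.nearest_cultured_id if tax else None
        row = {
            "otu_id": otu,
            "similarity_to_nearest_cultured": sim,
            "nearest_cultured_id": near,
            "phylum": tax.phylum if tax else "unclassified",
        }
        if sim is not None and sim > thresholds.candidate_similarity:
            cand_rows.append(row)
        else:
            effort_rows.append(row)
    candidates = pd.DataFrame(
        cand_rows,
        columns=["otu_id", "similarity_to_nearest_cultured",
                 "nearest_cultured_id", "phylum"],
    )
    if not candidates.empty:
        candidates = (
            candidates.sort_values(
                ["nearest_cultured_id", "similarity_to_nearest_cultured", "otu_id"],
                ascending=[True, False, True],
            )
            .groupby("nearest_cultured_id", as_index=False)
            .first()[candidates.columns]
            .reset_index(drop=True)
        )
    effort = pd.DataFrame(
        effort_rows,
        columns=["otu_id", "similarity_to_nearest_cultured",
                 "nearest_cultured_id", "phylum"],
    )
    return candidates, effort
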