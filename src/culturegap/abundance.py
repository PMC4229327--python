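"""TMM count normalization, average percentage abundance, and prevalence.

Surveys differ enormously in sequencing depth, so raw per-dataset OTU
counts are not comparable.  Library sizes are rescaled by the trimmed mean
of M-values (TMM): against a reference dataset, per-OTU log2 fold-changes
(M) and average log2 abundances (A) are computed over OTUs observed in
both; the most extreme 30% of M and 5% of A are discarded; and the scaling
factor is two to the precision-weighted mean of the surviving M values,
with inverse delta-method variances as weights.  Factors are rescaled to
geometric mean one.  An OTU's abundance summary is then its mean percent
abundance over *all* datasets (absence counts as zero) and its prevalence,
the fraction of datasets in which it was observed at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TMMFactors:
    reference_dataset: str
    factors: pd.Series              # geometric mean 1 across datasets
    effective_library_sizes: pd.Series  # column sum x factor

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    colsums = counts.sum(axis=0)
    dead = list(colsums[colsums == 0].index)
    if dead:
        raise ValueError(f"datasets with all-zero counts: {dead}")
    return counts


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float,
    min_shared: int = 5,
) -> float | None:
    """Log2 TMM factor of ``obs`` against ``ref``; None -> too few shared OTUs."""
    n_obs, n_ref = obs.sum(), ref.sum()
    shared = (obs > 0) & (ref > 0)
    if shared.sum() < min_shared:
        return None
    o = obs[shared].astype(float)
    r = ref[shared].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> TMMFactors:
    """Trimmed-mean-of-M scaling factors for an OTU x dataset count table.

    The reference is the dataset whose upper-quartile relative abundance is
    closest to the mean of upper-quartiles.  A dataset sharing fewer than 5
    OTUs with the reference keeps factor 1 with a warning.
    """
    counts = _validate_counts(counts)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 datasets")
    rel = counts / counts.sum(axis=0)
    uq = rel.quantile(0.75, axis=0)
    ref_name = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy()
    log_factors = {}
    for ds in counts.columns:
        if ds == ref_name:
            log_factors[ds] = 0.0
            continue
        f = _tmm_pair(counts[ds].to_numpy(), ref, trim_m, trim_a)
        if f is None:
            logger.warning(
                "dataset %s shares <5 OTUs with reference %s; factor set to 1",
                ds, ref_name,
            )
            f = 0.0
        log_factors[ds] = f
    factors = pd.Series({ds: 2.0 ** f for ds, f in log_factors.items()})
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    factors = factors[counts.columns]
    return TMMFactors(
        reference_dataset=str(ref_name),
        factors=factors,
        effective_library_sizes=counts.sum(axis=0) * factors,
    )


def summarize_abundance(counts: pd.DataFrame, factors: TMMFactors) -> pd.DataFrame:
    """Mean percent abundance (over all datasets) and prevalence per OTU."""
    missing = set(counts.columns) - set(factors.factors.index)
    if missing:
        raise ValueError(f"factors missing for datasets: {sorted(missing)}")
    eff = factors.effective_library_sizes[counts.columns]
    percents = 100.0 * counts / eff
    return pd.DataFrame(
        {
            "mean_percent_abundance": percents.mean(axis=1),
            "prevalence": (counts > 0).mean(axis=1),
        },
        index=counts.index,
    )
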