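"""Taxonomic roll-ups: per-phylum summaries and flagged-category breakdowns.

These tables compare the cultured fraction of the community against
survey-derived OTUs phylum by phylum, and break the core / abundant /
novel categories down by phylum and by prevalence stratum.  Percentages
are rounded half-up to whole percent; report generation is pure, so equal
inputs give byte-identical output.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import TaxonomyAssignment


def round_half_up_percent(count: float, total: float) -> int:
    """100 x count / total rounded half-up to a whole percent."""
    if total == 0:
        return 0
    frac = Decimal(str(count)) * 100 / Decimal(str(total))
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def load_cultured_census() -> pd.DataFrame:
    """Packaged census of cultivated rumen bacteria by phylum.

    Columns: cultured_genera, cultured_isolates, and species-level OTU
    counts per phylum from two 16S meta-analyses of the rumen.
    """
    ref = resources.files("culturegap.data") / "rumen_culture_census.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", index_col="phylum")


def summarize_by_phylum(
    otu_ids: Iterable[str],
    taxonomy: Mapping[str, TaxonomyAssignment],
) -> pd.DataFrame:
    """Count OTUs per phylum with half-up whole percents and a totals row."""
    counts: dict[str, int] = {}
    for otu in otu_ids:
        tax = taxonomy.get(otu)
        phylum = tax.phylum if tax else "unclassified"
        counts[phylum] = counts.get(phylum, 0) + 1
    return tabulate_phylum_counts(counts)


def tabulate_phylum_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Render phylum -> count into the standard n / percent / totals layout."""
    total = sum(counts.values())
    rows = [
        {"phylum": ph, "n": n, "percent": round_half_up_percent(n, total)}
        for ph, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    rows.append({"phylum": "Total", "n": total,
                 "percent": 100 if total else 0})
    return pd.DataFrame(rows, columns=["phylum", "n", "percent"])


def census_summary(census: pd.DataFrame | None = None) -> dict[str, float]:
    """Headline arithmetic over the cultured census table.

    Totals of cultured genera and isolates, the number of phyla with
    cultured representatives, and the share of isolates contributed by the
    three collection-dominating phyla.
    """
    if census is None:
        census = load_cultured_census()
    genera = census["cultured_genera"]
    isolates = census["cultured_isolates"]
    top3 = isolates.sort_values(ascending=False).head(3).sum()
    return {
        "cultured_genera_total": int(genera.sum()),
        "cultured_isolates_total": int(isolates.sum()),
        "phyla_with_cultured_genera": int((genera > 0).sum()),
        "phyla_with_cultured_isolates": int((isolates > 0).sum()),
        "top3_phyla_isolate_share_percent": round_half_up_percent(
            top3, isolates.sum()
        ),
    }


def summarize_flags(
    metrics: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyAssignment],
    n_datasets: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-flag phylum breakdowns plus prevalence strata for the core set.

    Returns one table per flag (core / abundant / novel) in the
    :func:`tabulate_phylum_counts` layout, and a ``core_prevalence``
    table of how many core OTUs appear in exactly k datasets.
    """
    out: dict[str, pd.DataFrame] = {}
    for flag in ("is_core", "is_abundant", "is_novel"):
        subset = (
            metrics.loc[metrics[flag].astype(bool)]
            if flag in metrics.columns else metrics.iloc[0:0]
        )
        name = flag.removeprefix("is_")
        counts: dict[str, int] = {}
        for otu in subset.index:
            tax = taxonomy.get(otu)
            phylum = tax.phylum if tax else "unclassified"
            counts[phylum] = counts.get(phylum, 0) + 1
        out[name] = tabulate_phylum_counts(counts)
    if "is_core" in metrics.columns and n_datasets:
        core = metrics.loc[metrics["is_core"].astype(bool)]
        k_values = (core["prevalence"] * n_datasets).round().astype(int)
        strata = (
            k_values.value_counts().sort_index().rename_axis("n_datasets_present")
            .reset_index(name="n_core_otus")
        )
        out["core_prevalence"] = strata
    return out


def render_table(df: pd.DataFrame, title: str = "") -> str:
    """Deterministic aligned-text rendering of a summary table."""
    lines = []
    if title:
        lines.append(f"# {title}")
    cols = list(df.columns)
    widths = [
        max(len(str(c)), *(len(str(v)) for v in df[c])) if len(df) else len(str(c))
        for c in cols
    ]
    lines.append("  ".join(str(c).ljust(w) for c, w in zip(cols, widths)))
    for _, row in df.iterrows():
        lines.append("  ".join(str(row[c]).ljust(w) for c, w in zip(cols, widths)))
    return "\n".join(lines) + "\n"
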