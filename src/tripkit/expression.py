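"""Normalized transcriptional activity per barcode and the TRIP filter.

The activity of a transgene is the ratio of its barcode's abundance
among transcripts (expression/cDNA library) to its abundance in the
cell population (normalization/gDNA library).  Abundances are taken as
within-library parts-per-million so the statistic is independent of
sequencing depth:

    normalized_expression = (expr_count / total_expr) / (norm_count / total_norm)

in arbitrary units (a.u.).  A transgene with zero expression reads is
"completely silent".  Reliable transgenes satisfy the TRIP filter

    norm_count >= 5  AND  reads_r >= 10  AND  freq1_r > 0.60

combining DNA-abundance evidence with mapping reliability.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping

import numpy as np
import pandas as pd

from .barcodes import BarcodeCountTable


def normalized_expression(
    expr_count: float, total_expr: float, norm_count: float, total_norm: float
) -> float:
    """Depth-normalized expression ratio for one barcode (a.u.).

    Scale-invariant in both library totals.  ``norm_count`` must be
    positive: a barcode without DNA evidence has no defined activity.
    """
    if norm_count <= 0:
        raise ValueError("norm_count must be >= 1 (no_dna_evidence otherwise)")
    if expr_count == 0:
        return 0.0
    return (expr_count / total_expr) / (norm_count / total_norm)


def build_expression_table(
    norm_counts: Mapping[tuple[str, str], int],
    expr_counts: Mapping[tuple[str, str], int],
    norm_min: int = 5,
) -> pd.DataFrame:
    """Join per-(promoter, barcode) counts into an expression table.

    The barcode universe is the normalization library: barcodes seen
    only in cDNA lack DNA evidence and are excluded (they appear in the
    ``excluded_no_dna_evidence`` frame attribute).  ``expr_count``
    defaults to 0 for barcodes without expression reads.
    """
    total_norm = sum(norm_counts.values())
    total_expr = sum(expr_counts.values())
    rows = []
    for (prom, bc), nc in sorted(norm_counts.items()):
        ec = expr_counts.get((prom, bc), 0)
        rows.append((prom, bc, nc, ec))
    df = pd.DataFrame(rows, columns=["promoter", "barcode", "norm_count", "expr_count"])
    scale_norm = 1e6 / total_norm if total_norm else np.nan
    scale_expr = 1e6 / total_expr if total_expr else np.nan
    df["norm_ppm"] = df["norm_count"] * scale_norm
    df["expr_ppm"] = df["expr_count"] * scale_expr
    with np.errstate(invalid="ignore"):
        df["normalized_expression"] = np.where(
            df["expr_count"] == 0, 0.0, df["expr_ppm"] / df["norm_ppm"]
        )
    df["passes_norm_filter"] = df["norm_count"] >= norm_min
    excluded = sorted(set(expr_counts) - set(norm_counts))
    df.attrs["excluded_no_dna_evidence"] = excluded
    return df


def table_from_counts(
    norm_table: BarcodeCountTable, expr_table: BarcodeCountTable, norm_min: int = 5
) -> pd.DataFrame:
    """Expression table from two collapsed :class:`BarcodeCountTable` objects."""

    def flat(table: BarcodeCountTable) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for (_lib, prom), counter in table.counts.items():
            for bc, c in counter.items():
                out[(prom, bc)] = out.get((prom, bc), 0) + c
        return out

    return build_expression_table(flat(norm_table), flat(expr_table), norm_min)


def classify_silent(df: pd.DataFrame, silence_threshold: float = 0.0) -> pd.DataFrame:
    """Mark transgenes with activity <= threshold as silent.

    The default threshold of 0 reads "completely silent" literally:
    zero expression reads.
    """
    df = df.copy()
    df["is_silent"] = df["normalized_expression"] <= silence_threshold
    return df


def apply_trip_filters(
    records: pd.DataFrame,
    calls: pd.DataFrame,
    norm_min: int = 5,
    reads_r_min: int = 10,
    freq1_min: float = 0.60,
) -> pd.DataFrame:
    """Join expression records with insertion calls and apply the TRIP filter.

    Retains rows with ``norm_count >= norm_min AND reads_r >= reads_r_min
    AND freq1_r > freq1_min`` (note the strict inequality on freq1_r).
    Barcodes lacking an insertion call are dropped with reason
    ``unmapped``; the returned frame records drop tallies in
    ``df.attrs["drop_reasons"]`` and is ordered by (promoter, barcode).
    """
    if calls.duplicated(subset=["promoter", "barcode"]).any():
        dup = calls[calls.duplicated(subset=["promoter", "barcode"], keep=False)]
        raise ValueError(
            "duplicate insertion calls for barcode(s): "
            + ", ".join(dup["barcode"].unique()[:5])
        )
    merged = records.merge(
        calls[["promoter", "barcode", "chrom", "position", "strand", "reads_r", "freq1_r"]],
        on=["promoter", "barcode"],
        how="left",
    )
    unmapped = merged["reads_r"].isna()
    keep = (
        ~unmapped
        & (merged["norm_count"] >= norm_min)
        & (merged["reads_r"] >= reads_r_min)
        & (merged["freq1_r"] > freq1_min)
    )
    out = merged[keep].sort_values(["promoter", "barcode"], ignore_index=True)
    out["reads_r"] = out["reads_r"].astype(int)
    out["position"] = out["position"].astype(int)
    out.attrs["drop_reasons"] = {
        "unmapped": int(unmapped.sum()),
        "failed_filter": int((~keep & ~unmapped).sum()),
        "retained": int(keep.sum()),
    }
    return out


def top_decile(df: pd.DataFrame, top_fraction: float = 0.10) -> pd.DataFrame:
    """The ceil(top_fraction * n) most active records, ties broken by barcode."""
    if df.empty:
        return df
    n_top = ceil(top_fraction * len(df))
    ranked = df.sort_values(
        ["normalized_expression", "barcode"], ascending=[False, True]
    )
    return ranked.head(n_top)


@dataclass(frozen=True)
class PromoterSummaryOptions:
    top_fraction: float = 0.10
    baseline_promoter: str = "long_EF1a"


def promoter_summary(
    df: pd.DataFrame, options: PromoterSummaryOptions = PromoterSummaryOptions()
) -> pd.DataFrame:
    """Per-promoter activity statistics over a (filtered) transgene table.

    Medians/means are computed over *expressed* records only, matching
    median-line style summaries; ``fold_vs_baseline`` is each
    promoter's expressed-median over the baseline promoter's.  The
    top-decile share is each promoter's fraction among the
    ceil(top_fraction*n) most active records of the whole table.
    Promoters with no expressed records report NaN statistics, not 0.
    """
    df = df if "is_silent" in df.columns else classify_silent(df)
    top = top_decile(df[~df["is_silent"]], options.top_fraction)
    n_top = len(top)
    rows = []
    base_median = np.nan
    expressed = df[~df["is_silent"]]
    base = expressed[expressed["promoter"] == options.baseline_promoter]
    if len(base):
        base_median = base["normalized_expression"].median()
    for prom, grp in df.groupby("promoter"):
        ex = grp[~grp["is_silent"]]
        med = ex["normalized_expression"].median() if len(ex) else np.nan
        rows.append(
            {
                "promoter": prom,
                "n": len(grp),
                "n_silent": int(grp["is_silent"].sum()),
                "n_expressed": len(ex),
                "median_expression": med,
                "mean_expression": ex["normalized_expression"].mean() if len(ex) else np.nan,
                "fold_vs_baseline": med / base_median if len(ex) and base_median else np.nan,
                "top_decile_share": (top["promoter"] == prom).sum() / n_top
                if n_top
                else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("promoter", ignore_index=True)
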