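"""Differential-expression filtering and COG-category summaries.

Transcriptional evidence enters the pipeline as a table of per-gene log2
fold changes (coculture vs monoculture) with raw or FDR-adjusted p-values
and an optional COG functional category.  This module applies the standard
significance gate — adjusted p < 0.05 and absolute fold change > 2
(|log2FC| > 1), both strict — and summarises the retained genes per COG
category (mean log2FC and gene count), the quantities behind
category-level bubble summaries of coculture responses.

P-values are consumed, not derived: the DE test that produced them is out
of scope here.  When only raw p-values are given they are adjusted by the
Benjamini-Hochberg step-up procedure within each (isolate, condition)
family.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["bh_adjust", "filter_de", "cog_summary"]

REQUIRED_COLUMNS = ("isolate", "gene", "condition", "log2_fold_change")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Adjusted p for the i-th smallest of m values is
    min_{j >= i} ( m * p_(j) / j ), capped at 1; the cumulative minimum
    from the largest p enforces monotonicity, so adjusted values preserve
    the input ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _ensure_adjusted(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    if "p_adjusted" in records.columns and records["p_adjusted"].notna().all():
        return records
    if "p_raw" not in records.columns:
        raise ValueError("transcription records need 'p_adjusted' or 'p_raw'")
    # BH family: all genes of one isolate in one coculture condition
    records["p_adjusted"] = (
        records.groupby(["isolate", "condition"], sort=False)["p_raw"]
        .transform(lambda s: bh_adjust(s.to_numpy()))
    )
    return records


def filter_de(
    records: pd.DataFrame, alpha: float = 0.05, log2fc_cutoff: float = 1.0
) -> pd.DataFrame:
    """Significantly differentially expressed genes.

    Retains records with p_adjusted < alpha and |log2_fold_change| >
    log2fc_cutoff, both strict, matching the "adjusted p < 0.05 and fold
    change > 2" convention.  Missing adjusted p-values are computed from
    raw ones per (isolate, condition) family.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"transcription table lacks columns {missing}")
    records = _ensure_adjusted(records)
    fc = records["log2_fold_change"].to_numpy(dtype=float)
    if np.any(~np.isfinite(fc)):
        raise ValueError("log2 fold changes must be finite")
    keep = (records["p_adjusted"].to_numpy(dtype=float) < alpha) & (np.abs(fc) > log2fc_cutoff)
    return records.loc[keep].reset_index(drop=True)


def de_counts(de: pd.DataFrame) -> pd.DataFrame:
    """DE-gene counts per isolate and coculture condition."""
    return (
        de.groupby(["isolate", "condition"], sort=True)
        .size()
        .rename("n_de_genes")
        .reset_index()
    )


def cog_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Mean log2FC and gene count per COG category.

    Grouped by (isolate, condition, cog_category); records without a
    category are pooled under ``unassigned``.  An empty DE set yields an
    empty table.  Rows are sorted for deterministic output.
    """
    if de.empty:
        return pd.DataFrame(
            columns=["isolate", "condition", "cog_category", "mean_log2fc", "n_genes"]
        )
    de = de.copy()
    if "cog_category" not in de.columns:
        de["cog_category"] = "unassigned"
    de["cog_category"] = de["cog_category"].fillna("unassigned").replace("", "unassigned")
    out = (
        de.groupby(["isolate", "condition", "cog_category"], sort=True)["log2_fold_change"]
        .agg(mean_log2fc="mean", n_genes="size")
        .reset_index()
    )
    out["n_genes"] = out["n_genes"].astype(int)
    return out
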