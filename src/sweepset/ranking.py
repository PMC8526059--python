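"""Gene-centered windows, window-mean |scores| and genome-wide gene ranks.

Genes are summarized by windows centered half-way between the most upstream
transcript start and the most downstream transcript stop, at several window
sizes (50 kb to 1 Mb by default, since sweep footprints vary in size).  The
per-gene signal in a window is the arithmetic mean of |standardized score|
over the SNPs it contains, and genes are ranked genome-wide within each
(statistic, window size, population) stratum, rank 1 being the strongest
putative sweep.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError

WINDOW_SIZES = (50_000, 100_000, 200_000, 500_000, 1_000_000)

GENE_COLUMNS = ["gene_id", "chrom", "span_start", "span_end", "center", "is_focal", "n_disease_variants"]


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    """Check GeneTable invariants; returns the table sorted by (chrom, center)."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValidationError(f"gene table missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id: {dup}")
    if (genes["span_start"] >= genes["span_end"]).any():
        raise ValidationError("span_start must be < span_end for every gene")
    if (genes["n_disease_variants"] < 0).any():
        raise ValidationError("n_disease_variants must be >= 0")
    expect = (genes["span_start"] + genes["span_end"]) / 2.0
    if not np.allclose(genes["center"], expect, atol=1.0):
        raise ValidationError("center must be the midpoint of the transcript span")
    return genes.sort_values(["chrom", "center"], kind="mergesort").reset_index(drop=True)


def gene_window(center: float, size: int, chrom_length: int | None = None) -> tuple[int, int, bool]:
    """Half-open 0-based interval [center - size/2, center + size/2).

    Clipped at the chromosome ends; the returned flag is True when clipping
    occurred.
    """
    start = int(round(center - size / 2))
    end = int(round(center + size / 2))
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = int(chrom_length), True
    return start, end, clipped


def window_mean_abs(
    positions: np.ndarray, std: np.ndarray, start: int, end: int, min_snps: int = 10
) -> float:
    """Mean |standardized score| over SNPs in [start, end); NaN if < min_snps.

    ``positions`` must be sorted ascending; NaN scores (unscorable sites)
    are excluded before counting.
    """
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    vals = std[lo:hi]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_snps:
        return np.nan
    return float(np.abs(vals).mean())


def build_score_table(
    genes: pd.DataFrame,
    snp_scores: pd.DataFrame,
    window_sizes: tuple[int, ...] = WINDOW_SIZES,
    population: str = "pop",
    min_snps: int = 10,
) -> pd.DataFrame:
    """Window-average per-SNP scores around every gene.

    ``snp_scores`` is tidy with columns (chrom, pos_bp, stat, std).  Returns
    a long table keyed by (gene_id, stat, window_size, population) with the
    ``mean_abs`` signal; genes whose window holds fewer than ``min_snps``
    scored SNPs get NaN and are excluded from ranking downstream.
    """
    rows = []
    for (chrom, stat), grp in snp_scores.groupby(["chrom", "stat"], sort=False):
        grp = grp.sort_values("pos_bp")
        pos = grp["pos_bp"].to_numpy()
        std = grp["std"].to_numpy(dtype=float)
        sub = genes[genes["chrom"] == chrom]
        for gene_id, center in zip(sub["gene_id"], sub["center"]):
            for w in window_sizes:
                start, end, _ = gene_window(center, w)
                m = window_mean_abs(pos, std, start, end, min_snps=min_snps)
                rows.append((gene_id, stat, w, population, m))
    return pd.DataFrame(rows, columns=["gene_id", "stat", "window_size", "population", "mean_abs"])


def rank_genes(score_table: pd.DataFrame) -> pd.DataFrame:
    """Assign genome-wide ranks within each (stat, window_size, population).

    Descending mean_abs maps to ascending rank (1 = strongest signal); ties
    are broken by lexicographic gene_id so ranking is order-independent.
    Genes with NaN mean_abs in a stratum receive no rank there.
    """
    out = score_table.reset_index(drop=True).copy()
    out["rank"] = np.nan
    for _, idx in out.groupby(["stat", "window_size", "population"]).groups.items():
        sub = out.loc[idx]
        ok = sub["mean_abs"].notna()
        sub = sub[ok].sort_values(["mean_abs", "gene_id"], ascending=[False, True], kind="mergesort")
        out.loc[sub.index, "rank"] = np.arange(1, len(sub) + 1, dtype=float)
    return out


def complete_genes(ranked: pd.DataFrame) -> pd.DataFrame:
    """Drop genes missing a rank in any stratum (genes "with sweep data").

    The analysis uses only genes rankable in every (stat, window, population)
    stratum, so all strata compare the same gene universe.
    """
    bad = ranked.loc[ranked["rank"].isna(), "gene_id"].unique()
    return ranked[~ranked["gene_id"].isin(bad)].reset_index(drop=True)


def rank_matrix(ranked: pd.DataFrame, genes_order: pd.Series) -> tuple[np.ndarray, list[tuple]]:
    """Pivot a ranked long table into an (n_genes x n_strata) array.

    Row order follows ``genes_order`` (gene_ids in genomic order); column
    labels are returned alongside.  All listed genes must be rank-complete.
    """
    wide = ranked.pivot_table(
        index="gene_id", columns=["stat", "window_size", "population"], values="rank"
    )
    wide = wide.loc[genes_order]
    if wide.isna().any().any():
        raise ValidationError("rank matrix contains missing ranks; call complete_genes first")
    return wide.to_numpy(dtype=np.int64), list(wide.columns)


def variants_in_windows(genes: pd.DataFrame, window: int = 500_000) -> pd.Series:
    """Disease-variant counts aggregated over gene-centered windows.

    For each gene, sums the per-gene disease-variant counts of every gene
    (itself included) whose center lies within the ``window`` centered on
    the focal gene, because recessive disease variants at close neighbors
    can also interfere with local adaptation.
    """
    counts = pd.Series(0, index=genes["gene_id"], dtype=int)
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("center")
        centers = sub["center"].to_numpy(dtype=float)
        own = sub["n_disease_variants"].to_numpy()
        csum = np.concatenate([[0], np.cumsum(own)])
        lo = np.searchsorted(centers, centers - window / 2, side="left")
        hi = np.searchsorted(centers, centers + window / 2, side="right")
        counts.loc[sub["gene_id"]] = csum[hi] - csum[lo]
    return counts
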