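"""Block-randomized-genome null and the false positive risk (FPR).

Sweeps are wide: one sweep can cover several neighboring genes, so gene-level
sweep signals are spatially autocorrelated and a naive permutation of genes
would be anti-conservative.  The null used here shuffles *blocks* of
consecutive genes whose boundaries never split a cluster of genes sharing a
putative sweep (genes whose largest analysis windows overlap).  Each shuffle
keeps every gene's label and confounders but reassigns to it the rank tuple
of the genomic position it lands on, preserving both the multiset of rank
tuples and their within-block adjacency.  The FPR of an observed
enrichment/deficit score is the (add-one-corrected) fraction of randomized
genomes whose score is at least as extreme, one-sided.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_THRESHOLDS


@dataclass
class BlockPartition:
    """Ordered blocks of consecutive analyzed genes (positional indices)."""

    blocks: list[np.ndarray]
    cluster_id: np.ndarray
    target_block_size: int
    largest_window: int

    @property
    def n_genes(self) -> int:
        return int(sum(len(b) for b in self.blocks))

    def validate(self) -> None:
        concat = np.concatenate(self.blocks)
        if not np.array_equal(concat, np.arange(self.n_genes)):
            raise AssertionError("blocks do not partition the gene list in order")


@dataclass
class FprEstimate:
    observed_score: float
    null_scores: np.ndarray
    n_rand: int
    k: int
    fpr: float
    side: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed_score,
            "n_rand": self.n_rand,
            "k": self.k,
            "fpr": self.fpr,
            "side": self.side,
            "seed": self.seed,
        }


def partition_blocks(
    genes: pd.DataFrame,
    largest_window: int = 1_000_000,
    target_block_size: int = 20,
) -> BlockPartition:
    """Group analyzed genes (in genomic order) into shuffle blocks.

    Two consecutive genes belong to the same cluster when their windows of
    the largest analyzed size overlap (center distance < largest_window),
    i.e. when they may sit in the same putative sweep.  Blocks grow to
    ``target_block_size`` genes but a boundary is always pushed forward to
    the end of the current cluster, and chromosome ends always close a
    block.
    """
    chrom = genes["chrom"].to_numpy()
    center = genes["center"].to_numpy(dtype=float)
    n = len(genes)
    cluster = np.zeros(n, dtype=np.int64)
    cid = 0
    for i in range(1, n):
        if chrom[i] != chrom[i - 1] or (center[i] - center[i - 1]) >= largest_window:
            cid += 1
        cluster[i] = cid
    blocks: list[np.ndarray] = []
    cur: list[int] = []
    for i in range(n):
        cur.append(i)
        cluster_ends = i == n - 1 or cluster[i + 1] != cluster[i]
        chrom_ends = i == n - 1 or chrom[i + 1] != chrom[i]
        if cluster_ends and (len(cur) >= target_block_size or chrom_ends):
            blocks.append(np.asarray(cur, dtype=np.int64))
            cur = []
    if cur:  # trailing genes (cluster ran past the end of the list)
        blocks.append(np.asarray(cur, dtype=np.int64))
    part = BlockPartition(
        blocks=blocks,
        cluster_id=cluster,
        target_block_size=target_block_size,
        largest_window=largest_window,
    )
    part.validate()
    return part


def randomize_genome(
    partition: BlockPartition, rank_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One block-shuffled reassignment of rank tuples to genes.

    ``rank_matrix`` holds one row per gene in genomic order (columns are
    strata).  Block order is permuted uniformly; the positional sequence of
    rank rows stays fixed, so the gene arriving at position j acquires rank
    row j.  Returns the per-gene rank matrix under the shuffle (row i =
    ranks now assigned to the gene originally at position i).
    """
    perm = rng.permutation(len(partition.blocks))
    order = np.concatenate([partition.blocks[i] for i in perm])
    out = np.empty_like(rank_matrix)
    out[order] = rank_matrix
    return out


def make_score_fn(
    focal_idx: np.ndarray,
    control_sets_idx: list[np.ndarray],
    thresholds=DEFAULT_THRESHOLDS,
    n_ranked: int | None = None,
):
    """Closure computing the FPR score from a per-gene rank matrix.

    ``focal_idx`` / ``control_sets_idx`` are positional gene indices (rows
    of the rank matrix); control sets keep multiplicity.  The score is the
    plain sum of (D_t - C_t) over all rank-matrix columns (strata) and
    thresholds, with C_t the exact mean across control sets.
    """
    thresholds = np.asarray(thresholds, dtype=np.int64)
    if n_ranked is not None:
        thresholds = np.minimum(thresholds, n_ranked)
    n_sets = len(control_sets_idx)
    all_ctrl = np.concatenate(control_sets_idx)

    def score(rank_matrix: np.ndarray) -> float:
        fr = rank_matrix[focal_idx]  # (nf, S)
        D = (fr[:, :, None] <= thresholds[None, None, :]).sum(axis=0)  # (S, T)
        cr = rank_matrix[all_ctrl]
        C_total = (cr[:, :, None] <= thresholds[None, None, :]).sum(axis=0)
        return float((D * n_sets - C_total).sum() / n_sets)

    return score


def estimate_fpr(
    observed: float,
    score_fn,
    partition: BlockPartition,
    rank_matrix: np.ndarray,
    n_rand: int,
    side: str,
    seed: int | None = None,
) -> FprEstimate:
    """FPR of an observed score against the block-randomized null.

    ``score_fn`` recomputes the FPR score from a per-gene rank matrix (the
    bootstrap control sets are reused, not rebuilt, so only sweep locations
    move).  With k the number of null scores >= observed (side
    "enrichment") or <= observed (side "deficit"), the estimate is the
    add-one form (k + 1) / (n_rand + 1), never exactly 0.  The side must be
    stated explicitly: the hypotheses tested are one-sided.
    """
    if side not in ("enrichment", "deficit"):
        raise ValueError("side must be 'enrichment' or 'deficit' (no two-sided default)")
    if n_rand < 100:
        warnings.warn(f"n_rand={n_rand} is small; FPR resolution is 1/{n_rand + 1}", stacklevel=2)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_rand, dtype=float)
    for i in range(n_rand):
        nulls[i] = score_fn(randomize_genome(partition, rank_matrix, rng))
    if side == "enrichment":
        k = int((nulls >= observed).sum())
    else:
        k = int((nulls <= observed).sum())
    fpr = (k + 1) / (n_rand + 1)
    return FprEstimate(
        observed_score=float(observed),
        null_scores=nulls,
        n_rand=n_rand,
        k=k,
        fpr=fpr,
        side=side,
        seed=seed,
    )
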