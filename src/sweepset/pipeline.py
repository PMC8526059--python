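"""End-to-end orchestration: scores -> ranks -> controls -> curves -> FPR.

The pipeline compares a focal gene set (e.g. mendelian disease genes)
against confounder-matched bootstrap control sets along whole sliding-rank
enrichment curves, and assesses the cumulated enrichment/deficit score
against a block-randomized-genome null.  All randomness derives from one
master seed through fixed per-stage streams, so a rerun with the same
configuration reproduces the report exactly.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_seed
from .enrichment import DEFAULT_THRESHOLDS, enrichment_curve, fpr_score, per_gene_score
from .matching import build_control_sets, eligible_pool
from .nulls import estimate_fpr, make_score_fn, partition_blocks
from .ranking import (
    WINDOW_SIZES,
    complete_genes,
    rank_genes,
    rank_matrix,
    validate_gene_table,
    variants_in_windows,
)

SUBSETS = (
    "all",
    "low_recomb",
    "high_recomb",
    "many_variants",
    "few_variants",
    "low_recomb_many_variants",
    "low_recomb_few_variants",
    "high_recomb_many_variants",
    "high_recomb_few_variants",
)


@dataclass
class PipelineConfig:
    """Tunable parameters of one enrichment analysis."""

    window_sizes: tuple[int, ...] = WINDOW_SIZES
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    min_distance: int = 300_000
    n_control_sets: int = 100
    tolerance: float = 0.05
    max_iter: int = 50_000
    n_rand: int = 1000
    side: str = "deficit"
    min_snps: int = 10
    target_block_size: int = 20
    subset: str = "all"
    recomb_factor: str = "recomb_50kb"
    variant_count_threshold: int = 5
    variant_window: int = 500_000
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def focal_subsets(
    genes: pd.DataFrame,
    confounders: pd.DataFrame,
    recomb_factor: str = "recomb_50kb",
    variant_count_threshold: int = 5,
    variant_window: int = 500_000,
) -> dict[str, np.ndarray]:
    """Partition the focal set by recombination and disease-variant count.

    The recombination split is at the median recombination rate over the
    analyzed genes; the variant split counts disease variants within a
    gene-centered window (neighboring genes' variants included) against
    ``variant_count_threshold``.  Both splits partition the focal set
    exactly (no overlap, no omission), as do the four pairwise
    intersections.
    """
    conf = confounders.set_index("gene_id")
    focal = genes[genes["is_focal"]]
    recomb = conf.loc[genes["gene_id"], recomb_factor]
    median = float(recomb.median())
    focal_recomb = conf.loc[focal["gene_id"], recomb_factor].to_numpy()
    low = focal_recomb < median
    counts = variants_in_windows(genes, window=variant_window).loc[focal["gene_id"]].to_numpy()
    many = counts >= variant_count_threshold
    ids = focal["gene_id"].to_numpy()
    return {
        "all": ids,
        "low_recomb": ids[low],
        "high_recomb": ids[~low],
        "many_variants": ids[many],
        "few_variants": ids[~many],
        "low_recomb_many_variants": ids[low & many],
        "low_recomb_few_variants": ids[low & ~many],
        "high_recomb_many_variants": ids[~low & many],
        "high_recomb_few_variants": ids[~low & ~many],
    }


def run_pipeline(
    genes: pd.DataFrame,
    confounders: pd.DataFrame,
    scores: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full enrichment analysis and return the report.

    ``scores`` is the long per-gene score table (gene_id, stat,
    window_size, population, mean_abs); per-SNP scores should be window-
    averaged with :func:`sweepset.ranking.build_score_table` first.  Stage
    order: ranks -> eligible pool -> control sets -> curves -> FPR score ->
    block-randomized FPR.  When ``outdir`` is given every stage's outputs
    are persisted there.
    """
    from . import __version__
    from . import io as sio

    config = config or PipelineConfig()
    if config.subset not in SUBSETS:
        raise ValueError(f"unknown subset {config.subset!r}; choose from {SUBSETS}")
    genes = validate_gene_table(genes)

    # stage 1: ranks, restricted to genes rankable in every stratum
    scores = scores[scores["window_size"].isin(config.window_sizes)]
    ranked = complete_genes(rank_genes(scores))
    genes = genes[genes["gene_id"].isin(ranked["gene_id"])].reset_index(drop=True)
    n_ranked = genes["gene_id"].nunique()
    thresholds = tuple(min(t, n_ranked) for t in config.thresholds)

    # stage 2: focal subset and eligible control pool (controls stay at
    # least min_distance from *every* focal gene, subset or not)
    subsets = focal_subsets(
        genes,
        confounders,
        recomb_factor=config.recomb_factor,
        variant_count_threshold=config.variant_count_threshold,
        variant_window=config.variant_window,
    )
    focal_ids = subsets[config.subset]
    if len(focal_ids) == 0:
        raise ValueError(f"focal subset {config.subset!r} is empty")
    pool = eligible_pool(genes, min_distance=config.min_distance)

    # stage 3: confounder-matched bootstrap control sets
    controls = build_control_sets(
        focal_ids,
        pool,
        confounders[confounders["gene_id"].isin(genes["gene_id"])],
        n_sets=config.n_control_sets,
        tolerance=config.tolerance,
        max_iter=config.max_iter,
        seed=derive_seed(config.seed, "matching"),
    )

    # stage 4: enrichment curves per stratum and the cumulated score
    strata_ranks = {
        key: grp.set_index("gene_id")["rank"]
        for key, grp in ranked.groupby(["stat", "window_size", "population"])
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # thresholds pre-clipped above
        curves = [
            enrichment_curve(focal_ids, controls.sets, r, thresholds, stratum=key)
            for key, r in strata_ranks.items()
        ]
    score = fpr_score(curves)
    pgs = per_gene_score(score, len(focal_ids))

    # stage 5: block-randomized-genome FPR (control sets reused); blocks
    # cover the analyzed genes only (the focal subset plus the eligible
    # pool), in genomic order
    analyzed = genes[
        genes["gene_id"].isin(set(focal_ids) | set(pool))
    ].reset_index(drop=True)
    genes_order = analyzed["gene_id"]
    rmat, strata_cols = rank_matrix(
        ranked[ranked["gene_id"].isin(genes_order)], genes_order
    )
    gene_pos = pd.Series(np.arange(len(genes_order)), index=genes_order)
    focal_idx = gene_pos.loc[focal_ids].to_numpy()
    control_idx = [gene_pos.loc[s].to_numpy() for s in controls.sets]
    partition = partition_blocks(
        analyzed,
        largest_window=max(config.window_sizes),
        target_block_size=config.target_block_size,
    )
    score_fn = make_score_fn(focal_idx, control_idx, thresholds, n_ranked=n_ranked)
    observed = score_fn(rmat)
    if not np.isclose(observed, score.score):
        raise AssertionError("curve-based and matrix-based FPR scores disagree")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fpr = estimate_fpr(
            observed,
            score_fn,
            partition,
            rmat,
            n_rand=config.n_rand,
            side=config.side,
            seed=derive_seed(config.seed, "nulls"),
        )

    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "subset": config.subset,
        "n_genes_analyzed": int(n_ranked),
        "n_focal": int(len(focal_ids)),
        "n_pool": int(len(pool)),
        "n_strata": len(curves),
        "fpr_score": score.score,
        "fpr_score_per_gene": pgs,
        "fpr": fpr.fpr,
        "fpr_k": fpr.k,
        "n_rand": fpr.n_rand,
        "side": config.side,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_table(genes, outdir / "genes.tsv")
        sio.write_table(ranked, outdir / "ranked_scores.tsv")
        sio.write_control_sets(controls.sets, outdir / "control_sets.tsv")
        sio.write_table(controls.report, outdir / "match_report.tsv")
        curve_frames = []
        for c in curves:
            f = c.to_frame()
            f.insert(0, "stratum", "|".join(map(str, c.stratum)))
            curve_frames.append(f)
        sio.write_table(pd.concat(curve_frames, ignore_index=True), outdir / "curves.tsv")
        sio.write_table(
            pd.DataFrame({"null_score": fpr.null_scores}), outdir / "null_scores.tsv"
        )
        sio.write_json_report(report | fpr.to_dict(), outdir / "report.json")
    return report
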