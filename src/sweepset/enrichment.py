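"""Sliding-rank-threshold enrichment curves and the FPR score.

Instead of a single outlier cutoff, the enrichment of focal genes among
putative sweeps is evaluated along a whole curve of rank thresholds t (top
5000 down to top 10): D_t is the number of focal genes among the top-t
ranked genes, C_t the mean count for the bootstrap control sets (control
genes drawn several times count with multiplicity), and D_t / C_t the
relative enrichment (deficit when < 1).  The summary statistic for
significance testing ("FPR score") is the plain sum of differences

    score = sum over strata and thresholds of (D_t - C_t),

which is algebraically identical to the weighted form
sum (d_t - c_t) * (n + 1 - t) over first-appearance increments d_t, c_t:
a gene entering the curve at the most restrictive threshold is counted in
all n thresholds, hence carries weight n, so stronger sweep signals weigh
more.  Both forms are computed here from exact integer count totals and
must agree bit-for-bit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# The default sliding thresholds, from the least to the most restrictive
# end of the published list (stored descending, as the curve is read).
DEFAULT_THRESHOLDS = (
    5000, 4000, 3000, 2500, 2000, 1500, 1000, 900, 800, 700, 600, 500, 450,
    400, 350, 300, 250, 200, 150, 100, 90, 80, 70, 60, 50, 40, 30, 25, 20, 15, 10,
)


@dataclass
class EnrichmentCurve:
    """Counts along the rank-threshold curve for one stratum."""

    thresholds: np.ndarray  # descending
    D: np.ndarray  # focal counts, int
    C_total: np.ndarray  # summed control counts over sets, int
    n_sets: int
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    stratum: tuple = ()

    @property
    def C(self) -> np.ndarray:
        return self.C_total / self.n_sets

    @property
    def rel(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.C_total > 0, self.D / self.C, np.nan)
        return r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "D": self.D,
                "C": self.C,
                "rel": self.rel,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


@dataclass
class FprScoreValue:
    """Signed enrichment/deficit score summed over strata and thresholds."""

    score: float
    n_thresholds: int
    strata: list = field(default_factory=list)
    n_sets: int = 1
    score_int: int = 0  # score * n_sets, exact integer form


def _counts_at_thresholds(ranks: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Number of entries with rank <= t for each t (ranks may repeat)."""
    return (ranks[:, None] <= thresholds[None, :]).sum(axis=0)


def enrichment_curve(
    focal_ids: np.ndarray,
    control_sets: list[np.ndarray],
    ranks: pd.Series,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    stratum: tuple = (),
) -> EnrichmentCurve:
    """Build the enrichment/deficit curve for one ranking stratum.

    ``ranks`` maps gene_id -> genome-wide rank (1 = strongest signal) and
    must cover every focal and control gene.  Thresholds exceeding the
    ranked universe are clipped with a warning.  The 95% interval is the
    2.5-97.5 percentile of D_t / C_t^(set) across control sets.
    """
    thresholds = np.asarray(thresholds, dtype=np.int64)
    n_ranked = len(ranks)
    if (thresholds > n_ranked).any():
        warnings.warn(
            f"thresholds above the ranked universe ({n_ranked}) are clipped", stacklevel=2
        )
        thresholds = np.minimum(thresholds, n_ranked)
    rank_map = ranks
    missing = [g for g in focal_ids if g not in rank_map.index]
    if missing:
        raise ValueError(f"ranks missing for focal genes, e.g. {missing[:3]}")
    focal_ranks = rank_map.loc[focal_ids].to_numpy(dtype=np.int64)
    D = _counts_at_thresholds(focal_ranks, thresholds)
    per_set = []
    for s in control_sets:
        cr = rank_map.loc[s].to_numpy(dtype=np.int64)  # with multiplicity
        per_set.append(_counts_at_thresholds(cr, thresholds))
    per_set = np.asarray(per_set, dtype=np.int64)
    C_total = per_set.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(per_set > 0, D[None, :] / per_set, np.nan)
    ci_lo = np.nanpercentile(ratios, 2.5, axis=0)
    ci_hi = np.nanpercentile(ratios, 97.5, axis=0)
    return EnrichmentCurve(
        thresholds=thresholds,
        D=D.astype(np.int64),
        C_total=C_total,
        n_sets=len(control_sets),
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        stratum=stratum,
    )


def _weighted_score_int(curve: EnrichmentCurve) -> int:
    """Weighted-form score * n_sets for one curve, exact integer arithmetic.

    Thresholds sorted ascending (most restrictive first); d_t is the count
    increment first appearing at threshold index t (1-based) and carries
    weight n + 1 - t.
    """
    order = np.argsort(curve.thresholds)
    D = curve.D[order]
    C = curve.C_total[order]
    n = len(curve.thresholds)
    dD = np.diff(np.concatenate([[0], D]))
    dC = np.diff(np.concatenate([[0], C]))
    weights = n + 1 - np.arange(1, n + 1)
    return int(np.sum((dD * curve.n_sets - dC) * weights))


def fpr_score(curves: list[EnrichmentCurve]) -> FprScoreValue:
    """Sum of (D_t - C_t) over all strata and thresholds.

    The plain and weighted formulas are both evaluated (in exact integer
    arithmetic, with C kept as the rational total/n_sets) and must agree;
    a mismatch raises, as it would indicate corrupted counts.
    """
    if not curves:
        raise ValueError("no curves supplied")
    t0 = curves[0].thresholds
    n_sets = curves[0].n_sets
    for c in curves[1:]:
        if not np.array_equal(c.thresholds, t0):
            raise ValueError("all curves must share the same thresholds")
        if c.n_sets != n_sets:
            raise ValueError("all curves must share the same number of control sets")
    plain_int = sum(int(np.sum(c.D * c.n_sets - c.C_total)) for c in curves)
    weighted_int = sum(_weighted_score_int(c) for c in curves)
    if plain_int != weighted_int:
        raise AssertionError(
            f"plain ({plain_int}) and weighted ({weighted_int}) FPR-score forms disagree"
        )
    return FprScoreValue(
        score=plain_int / n_sets,
        n_thresholds=len(t0),
        strata=[c.stratum for c in curves],
        n_sets=n_sets,
        score_int=plain_int,
    )


def per_gene_score(score: FprScoreValue | float, n_focal: int) -> float:
    """FPR score divided by the focal-set size, making gene groups comparable."""
    if n_focal <= 0:
        raise ValueError("n_focal must be positive")
    val = score.score if isinstance(score, FprScoreValue) else float(score)
    return val / n_focal


def plot_curve(curve: EnrichmentCurve, ax=None):
    """Minimal rendering of one enrichment/deficit curve (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(curve.thresholds))
    ax.fill_between(x, curve.ci_lo, curve.ci_hi, color="0.8", label="95% CI")
    ax.plot(x, curve.rel, color="C3")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xticks(x[::5])
    ax.set_xticklabels(curve.thresholds[::5])
    ax.set_xlabel("rank threshold (top t)")
    ax.set_ylabel("relative enrichment D/C")
    return ax
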