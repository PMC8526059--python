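"""Bootstrap control sets of non-focal genes matched on confounder averages.

Focal (disease) and non-focal genes differ systematically in expression,
constraint, recombination and other gene-level covariates that could by
themselves change sweep prevalence.  Rather than matching genes one-to-one
(which would shrink the usable pool drastically), control sets are random
with-replacement samples of non-focal genes, accepted only when every
confounding factor's set mean matches the focal set's mean within a
relative tolerance.  Controls are additionally restricted to genes far
enough (300 kb by default) from every focal gene so that a single sweep
cannot cover both a focal gene and its own control.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError

EPS = 1e-9


class MatchingError(RuntimeError):
    pass


@dataclass
class ControlSets:
    """Accepted bootstrap control sets.

    sets
        list of arrays of gene_ids; each set has exactly |focal| members,
        sampled with replacement (a gene may appear several times and then
        counts with multiplicity downstream).
    report
        per-(set, factor) DataFrame of focal mean, control mean and
        relative deviation.
    factors
        the factor names that were matched.
    tolerance
        the per-factor relative tolerance every accepted set satisfies.
    """

    sets: list[np.ndarray]
    report: pd.DataFrame
    factors: list[str]
    tolerance: float

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def eligible_pool(genes: pd.DataFrame, min_distance: int = 300_000) -> np.ndarray:
    """Non-focal genes whose center is >= min_distance from every focal center.

    Distance is measured between gene centers on the same chromosome; genes
    on chromosomes without any focal gene are all eligible.
    """
    keep = []
    diag = {}
    for chrom, sub in genes.groupby("chrom"):
        focal_centers = np.sort(sub.loc[sub["is_focal"], "center"].to_numpy(dtype=float))
        nonf = sub[~sub["is_focal"]]
        if focal_centers.size == 0:
            keep.append(nonf["gene_id"].to_numpy())
            diag[chrom] = (len(nonf), len(nonf))
            continue
        centers = nonf["center"].to_numpy(dtype=float)
        pos = np.searchsorted(focal_centers, centers)
        left = np.where(pos > 0, centers - focal_centers[np.maximum(pos - 1, 0)], np.inf)
        right = np.where(
            pos < focal_centers.size,
            focal_centers[np.minimum(pos, focal_centers.size - 1)] - centers,
            np.inf,
        )
        ok = np.minimum(left, right) >= min_distance
        keep.append(nonf.loc[ok, "gene_id"].to_numpy())
        diag[chrom] = (int(ok.sum()), len(nonf))
    pool = np.concatenate(keep) if keep else np.array([], dtype=object)
    if pool.size == 0:
        detail = ", ".join(f"{c}: {k}/{n}" for c, (k, n) in sorted(diag.items()))
        raise ValidationError(
            f"empty control pool at min_distance={min_distance} (eligible/non-focal per chromosome: {detail})"
        )
    return pool


def _relative_dev(control_means: np.ndarray, focal_means: np.ndarray) -> np.ndarray:
    return np.abs(control_means - focal_means) / (np.abs(focal_means) + EPS)


def build_control_sets(
    focal_ids: np.ndarray,
    pool_ids: np.ndarray,
    confounders: pd.DataFrame,
    n_sets: int = 100,
    tolerance: float = 0.05,
    max_iter: int = 50_000,
    seed: int | None = None,
) -> ControlSets:
    """Build ``n_sets`` confounder-matched bootstrap control sets.

    Each set starts as a uniform with-replacement sample of ``pool_ids`` of
    size |focal|, then a stochastic greedy search swaps members for random
    pool genes, accepting swaps that reduce the worst per-factor relative
    deviation, until every factor mean is within ``tolerance`` of the focal
    mean.  Binary factors are matched as proportions by the same machinery.
    Deterministic under ``seed``.

    Raises MatchingError when a set cannot be matched within ``max_iter``
    swap proposals, naming the factors that most often remained out of
    tolerance.
    """
    focal_ids = np.asarray(focal_ids)
    pool_ids = np.asarray(pool_ids)
    if confounders.isna().any().any():
        raise ValidationError("confounder table contains missing values")
    factors = [c for c in confounders.columns if c != "gene_id"]
    conf = confounders.set_index("gene_id")
    missing = set(focal_ids) - set(conf.index)
    missing |= set(pool_ids) - set(conf.index)
    if missing:
        raise ValidationError(f"confounders missing for {len(missing)} genes, e.g. {sorted(missing)[:3]}")
    focal_vals = conf.loc[focal_ids, factors].to_numpy(dtype=float)
    pool_vals = conf.loc[pool_ids, factors].to_numpy(dtype=float)
    focal_means = focal_vals.mean(axis=0)
    n = len(focal_ids)
    rng = np.random.default_rng(seed)

    sets = []
    report_rows = []
    fail_counts = np.zeros(len(factors), dtype=int)
    for set_i in range(n_sets):
        members = rng.integers(0, len(pool_ids), size=n)  # indices into pool, with replacement
        sums = pool_vals[members].sum(axis=0)
        it = 0
        while True:
            dev = _relative_dev(sums / n, focal_means)
            worst = float(dev.max())
            if worst <= tolerance:
                break
            if it >= max_iter:
                fail_counts[np.argsort(dev)[::-1][:3]] += 1
                bad = [factors[j] for j in np.argsort(dev)[::-1][:3]]
                raise MatchingError(
                    f"control set {set_i} not matched within {max_iter} proposals; "
                    f"worst factors: {bad} (relative deviations {np.sort(dev)[::-1][:3].round(4)})"
                )
            it += 1
            # propose: replace a random current member with a random pool gene,
            # accept only if the worst relative deviation strictly decreases
            slot = rng.integers(0, n)
            cand = rng.integers(0, len(pool_ids))
            new_sums = sums - pool_vals[members[slot]] + pool_vals[cand]
            new_worst = float(_relative_dev(new_sums / n, focal_means).max())
            if new_worst < worst:
                members[slot] = cand
                sums = new_sums
        chosen = pool_ids[members]
        sets.append(chosen)
        means = sums / n
        dev = _relative_dev(means, focal_means)
        for j, f in enumerate(factors):
            report_rows.append((set_i, f, focal_means[j], means[j], dev[j]))
    report = pd.DataFrame(
        report_rows, columns=["set", "factor", "focal_mean", "control_mean", "rel_dev"]
    )
    return ControlSets(sets=sets, report=report, factors=factors, tolerance=tolerance)
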