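"""Eligible-pool construction and confounder-matched bootstrap control sets."""
import numpy as np
import pandas as pd
import pytest

from sweepset.matching import (
    EPS,
    MatchingError,
    build_control_sets,
    eligible_pool,
)
from sweepset._util import ValidationError


def _genes(centers_focal, centers_ctrl, chrom="chr1"):
    rows = []
    for i, c in enumerate(centers_focal):
        rows.append((f"f{i}", chrom, c - 5000, c + 5000, float(c), True, 1))
    for i, c in enumerate(centers_ctrl):
        rows.append((f"c{i}", chrom, c - 5000, c + 5000, float(c), False, 0))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "span_start", "span_end", "center", "is_focal", "n_disease_variants"],
    )


class TestEligiblePool:
    def test_distance_rule_with_boundary(self):
        genes = _genes([1_000_000], [1_250_000, 1_300_000, 2_000_000])
        pool = set(eligible_pool(genes, min_distance=300_000))
        assert "c0" not in pool  # 250 kb away: excluded
        assert "c1" in pool  # exactly 300 kb: the >= rule includes it
        assert "c2" in pool

    def test_zero_distance_keeps_all_nonfocal(self):
        genes = _genes([1_000_000], [1_000_100, 1_500_000])
        assert len(eligible_pool(genes, min_distance=0)) == 2

    def test_empty_pool_reports_per_chromosome(self):
        genes = _genes([1_000_000], [1_100_000])
        with pytest.raises(ValidationError, match="chr1"):
            eligible_pool(genes, min_distance=300_000)

    def test_other_chromosomes_unaffected(self):
        genes = pd.concat(
            [_genes([1_000_000], [1_100_000]), _genes([], [500_000], chrom="chr2")]
        ).reset_index(drop=True)
        assert set(eligible_pool(genes, 300_000)) == {"c0"}


def _confounders(gene_ids, rng, shift=None):
    n = len(gene_ids)
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expression": rng.normal(5, 2, n),
            "gc": rng.normal(41, 3, n),
            "recomb": rng.normal(1.2, 0.5, n).clip(0.01),
            "is_immune": (rng.random(n) < 0.1).astype(float),
        }
    )
    if shift:
        for col, delta in shift.items():
            df[col] += delta
    return df


class TestBuildControlSets:
    def test_accepted_sets_honor_the_tolerance_contract(self):
        rng = np.random.default_rng(0)
        focal = np.array([f"f{i}" for i in range(80)])
        pool = np.array([f"p{i}" for i in range(150)])
        conf = pd.concat(
            [_confounders(focal, rng), _confounders(pool, rng)], ignore_index=True
        )
        cs = build_control_sets(focal, pool, conf, n_sets=20, tolerance=0.05, seed=1)
        assert cs.n_sets == 20
        vals = conf.set_index("gene_id")
        factors = cs.factors
        fmeans = vals.loc[focal, factors].mean()
        for s in cs.sets:
            assert len(s) == len(focal)
            assert set(s) <= set(pool)  # never a focal gene
            cmeans = vals.loc[s, factors].mean()  # multiplicity respected by loc
            dev = (cmeans - fmeans).abs() / (fmeans.abs() + EPS)
            assert (dev <= 0.05 + 1e-12).all()

    def test_shifted_factor_named_in_failure(self):
        rng = np.random.default_rng(2)
        focal = np.array([f"f{i}" for i in range(50)])
        pool = np.array([f"p{i}" for i in range(100)])
        conf = pd.concat(
            [
                _confounders(focal, rng),
                _confounders(pool, rng, shift={"expression": 6.0}),  # +3 sd
            ],
            ignore_index=True,
        )
        with pytest.raises(MatchingError, match="expression"):
            build_control_sets(focal, pool, conf, n_sets=2, tolerance=0.01, max_iter=300, seed=3)

    def test_same_seed_reproduces_sets(self):
        rng = np.random.default_rng(4)
        focal = np.array([f"f{i}" for i in range(40)])
        pool = np.array([f"p{i}" for i in range(90)])
        conf = pd.concat([_confounders(focal, rng), _confounders(pool, rng)], ignore_index=True)
        a = build_control_sets(focal, pool, conf, n_sets=5, seed=7)
        b = build_control_sets(focal, pool, conf, n_sets=5, seed=7)
        for x, y in zip(a.sets, b.sets):
            assert np.array_equal(x, y)

    def test_missing_confounders_rejected(self):
        rng = np.random.default_rng(5)
        focal = np.array(["f0", "f1"])
        pool = np.array(["p0", "p1"])
        conf = pd.concat([_confounders(focal, rng), _confounders(pool, rng)], ignore_index=True)
        conf.loc[0, "gc"] = np.nan
        with pytest.raises(ValidationError):
            build_control_sets(focal, pool, conf, n_sets=1, seed=0)
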