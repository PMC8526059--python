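"""Enrichment curves and the two algebraic forms of the FPR score."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepset.enrichment import (
    DEFAULT_THRESHOLDS,
    _weighted_score_int,
    enrichment_curve,
    fpr_score,
    per_gene_score,
)


def _ranks(n):
    return pd.Series(np.arange(1, n + 1), index=[f"g{i}" for i in range(1, n + 1)])


class TestEnrichmentCurve:
    def test_hand_counted_example(self):
        """20 ranked genes, focal at ranks {1,3,5}, one control set at
        {2,4,20}, thresholds {10,5}: D={3,3}, C={2,2}, rel=1.5."""
        ranks = _ranks(20)
        focal = np.array(["g1", "g3", "g5"])
        controls = [np.array(["g2", "g4", "g20"])]
        c = enrichment_curve(focal, controls, ranks, thresholds=(10, 5))
        assert list(c.D) == [3, 3]
        assert list(c.C) == [2.0, 2.0]
        assert list(c.rel) == [1.5, 1.5]

    def test_control_multiplicity_counts_twice(self):
        ranks = _ranks(20)
        c = enrichment_curve(
            np.array(["g1"]), [np.array(["g2", "g2", "g15"])], ranks, thresholds=(10,)
        )
        assert c.C_total[0] == 2

    def test_self_comparison_is_flat_at_one(self):
        ranks = _ranks(50)
        focal = np.array([f"g{i}" for i in range(1, 51, 5)])
        c = enrichment_curve(focal, [focal, focal], ranks, thresholds=(40, 20, 10))
        assert np.allclose(c.rel, 1.0)
        assert fpr_score([c]).score == 0.0

    def test_threshold_clipping_warns(self):
        ranks = _ranks(10)
        with pytest.warns(UserWarning, match="clipped"):
            c = enrichment_curve(np.array(["g1"]), [np.array(["g2"])], ranks, thresholds=(50, 5))
        assert list(c.thresholds) == [10, 5]

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        ranks = _ranks(200)
        focal = rng.choice(ranks.index, 40, replace=False)
        sets = [rng.choice(np.setdiff1d(ranks.index, focal), 40) for _ in range(5)]
        c = enrichment_curve(focal, sets, ranks, thresholds=(150, 100, 50, 10))
        assert np.all(np.diff(c.D) <= 0)  # thresholds stored descending
        assert np.all(np.diff(c.C_total) <= 0)


class TestFprScore:
    def test_hand_example_and_per_gene(self):
        ranks = _ranks(20)
        c = enrichment_curve(
            np.array(["g1", "g3", "g5"]), [np.array(["g2", "g4", "g20"])], ranks, (10, 5)
        )
        score = fpr_score([c])
        assert score.score == 2.0  # (3-2)+(3-2)
        assert per_gene_score(score, 3) == pytest.approx(2 / 3)

    def test_label_swap_flips_sign(self):
        ranks = _ranks(30)
        a = np.array(["g1", "g4", "g9"])
        b = np.array(["g2", "g8", "g30"])
        s_ab = fpr_score([enrichment_curve(a, [b], ranks, (20, 10, 5))]).score
        s_ba = fpr_score([enrichment_curve(b, [a], ranks, (20, 10, 5))]).score
        assert s_ab == -s_ba

    def test_strata_order_invariance(self):
        rng = np.random.default_rng(1)
        ranks = _ranks(100)
        curves = []
        for k in range(4):
            focal = rng.choice(ranks.index, 20, replace=False)
            sets = [rng.choice(ranks.index, 20) for _ in range(3)]
            curves.append(enrichment_curve(focal, sets, ranks, (80, 40, 10), stratum=(k,)))
        assert fpr_score(curves).score == fpr_score(curves[::-1]).score

    def test_mismatched_thresholds_error(self):
        ranks = _ranks(30)
        a = enrichment_curve(np.array(["g1"]), [np.array(["g2"])], ranks, (20, 10))
        b = enrichment_curve(np.array(["g1"]), [np.array(["g2"])], ranks, (20, 5))
        with pytest.raises(ValueError, match="thresholds"):
            fpr_score([a, b])

    def test_per_gene_requires_positive_count(self):
        with pytest.raises(ValueError):
            per_gene_score(1.0, 0)


class TestPlainWeightedEquivalence:
    """The plain sum over thresholds and the first-appearance weighted sum
    are the same number, exactly, for any counts configuration."""

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=1000, deadline=None)
    def test_equivalence_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(10, 300))
        ranks = _ranks(n_genes)
        n_focal = int(rng.integers(1, max(2, n_genes // 3)))
        focal = rng.choice(ranks.index, n_focal, replace=False)
        n_sets = int(rng.integers(1, 6))
        sets = [rng.choice(ranks.index, n_focal, replace=True) for _ in range(n_sets)]
        k = int(rng.integers(1, 12))
        thresholds = tuple(
            sorted(set(rng.integers(1, n_genes + 1, size=k).tolist()), reverse=True)
        )
        curve = enrichment_curve(focal, sets, ranks, thresholds)
        score = fpr_score([curve])  # raises internally on any mismatch
        assert _weighted_score_int(curve) == score.score_int
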