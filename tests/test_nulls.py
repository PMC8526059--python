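"""Block partition, block shuffling and the FPR estimator."""
import numpy as np
import pandas as pd
import pytest

from sweepset.nulls import (
    estimate_fpr,
    make_score_fn,
    partition_blocks,
    randomize_genome,
)


def _genes(centers, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(centers))],
            "chrom": chrom,
            "center": centers,
        }
    )


class TestPartitionBlocks:
    def test_spaced_genes_form_singleton_clusters_and_target_blocks(self):
        genes = _genes(np.arange(30) * 2_000_000)
        part = partition_blocks(genes, largest_window=1_000_000, target_block_size=10)
        assert (part.cluster_id == np.arange(30)).all()
        assert [len(b) for b in part.blocks] == [10, 10, 10]

    def test_tight_cluster_never_split(self):
        centers = [0, 100_000, 200_000, 5_000_000, 5_100_000]
        part = partition_blocks(_genes(centers), largest_window=1_000_000, target_block_size=2)
        for block in part.blocks:
            clusters = set(part.cluster_id[block])
            for c in clusters:  # every cluster is fully inside one block
                assert set(np.flatnonzero(part.cluster_id == c)) <= set(block)

    def test_concatenation_reproduces_input_order(self):
        rng = np.random.default_rng(0)
        centers = np.cumsum(rng.integers(50_000, 2_000_000, size=57))
        part = partition_blocks(_genes(centers), 1_000_000, 5)
        assert np.array_equal(np.concatenate(part.blocks), np.arange(57))

    def test_chromosome_boundary_ends_block(self):
        genes = pd.concat(
            [_genes([0, 100_000], "chr1"), _genes([0, 100_000], "chr2")]
        ).reset_index(drop=True)
        part = partition_blocks(genes, 1_000_000, 10)
        assert [list(b) for b in part.blocks] == [[0, 1], [2, 3]]


class TestRandomizeGenome:
    def test_single_block_is_identity(self):
        part = partition_blocks(_genes([0, 100_000, 200_000]), 1_000_000, 10)
        rmat = np.arange(6).reshape(3, 2)
        out = randomize_genome(part, rmat, np.random.default_rng(0))
        assert np.array_equal(out, rmat)

    def test_rank_tuples_conserved_as_multiset(self):
        rng = np.random.default_rng(1)
        genes = _genes(np.arange(24) * 2_000_000)
        part = partition_blocks(genes, 1_000_000, 4)
        rmat = rng.integers(1, 100, size=(24, 3))
        out = randomize_genome(part, rmat, rng)
        assert sorted(map(tuple, out)) == sorted(map(tuple, rmat))

    def test_three_singleton_blocks_uniform_over_permutations(self):
        """All 6 block orders appear with frequency 1/6 within 3 binomial SE
        over 6000 draws."""
        genes = _genes([0, 2_000_000, 4_000_000])
        part = partition_blocks(genes, 1_000_000, 1)
        assert len(part.blocks) == 3
        rmat = np.array([[1], [2], [3]])
        rng = np.random.default_rng(2)
        counts = {}
        n = 6000
        for _ in range(n):
            key = tuple(randomize_genome(part, rmat, rng)[:, 0])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for k, v in counts.items():
            assert abs(v / n - 1 / 6) < 3 * se, (k, v / n)


class TestEstimateFpr:
    @staticmethod
    def _setup(n=40, seed=0):
        rng = np.random.default_rng(seed)
        genes = _genes(np.arange(n) * 2_000_000)
        part = partition_blocks(genes, 1_000_000, 1)
        rmat = np.arange(1, n + 1).reshape(-1, 1)
        focal = rng.choice(n, 10, replace=False)
        ctrl = [rng.choice(np.setdiff1d(np.arange(n), focal), 10) for _ in range(4)]
        fn = make_score_fn(focal, ctrl, thresholds=(30, 20, 10, 5), n_ranked=n)
        return part, rmat, fn

    def test_extreme_observation_hits_add_one_floor(self):
        part, rmat, fn = self._setup()
        est = estimate_fpr(-1e18, fn, part, rmat, n_rand=999, side="deficit", seed=1)
        assert est.fpr == pytest.approx(1 / 1000)
        est = estimate_fpr(1e18, fn, part, rmat, n_rand=999, side="enrichment", seed=1)
        assert est.fpr == pytest.approx(1 / 1000)

    def test_null_median_observation_gives_half(self):
        part, rmat, fn = self._setup()
        ref = estimate_fpr(0.0, fn, part, rmat, n_rand=501, side="deficit", seed=2)
        med = float(np.median(ref.null_scores))
        est = estimate_fpr(med, fn, part, rmat, n_rand=501, side="deficit", seed=2)
        assert abs(est.fpr - 0.5) < 0.05

    def test_side_is_mandatory(self):
        part, rmat, fn = self._setup()
        with pytest.raises(ValueError, match="side"):
            estimate_fpr(0.0, fn, part, rmat, n_rand=100, side="both", seed=0)

    def test_seed_reproducibility(self):
        part, rmat, fn = self._setup()
        a = estimate_fpr(1.0, fn, part, rmat, n_rand=200, side="deficit", seed=9)
        b = estimate_fpr(1.0, fn, part, rmat, n_rand=200, side="deficit", seed=9)
        assert np.array_equal(a.null_scores, b.null_scores)
        assert a.fpr == b.fpr

    def test_score_conservation_under_shuffling(self):
        """Summed over every rank position, focal + control counts do not
        change when rank tuples are reassigned."""
        part, rmat, fn = self._setup()
        rng = np.random.default_rng(3)
        full_t = (40,)
        focal = np.arange(10)
        ctrl = [np.arange(10, 20)]
        fn_all = make_score_fn(focal, ctrl, thresholds=full_t, n_ranked=40)
        base = fn_all(rmat)
        for _ in range(5):
            assert fn_all(randomize_genome(part, rmat, rng)) == base
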