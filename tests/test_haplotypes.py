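"""Haplotype sweep statistics: hand-checked examples, brute-force oracle
agreement, and distributional behavior on simulated data."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepset.haplotypes import (
    HaplotypeMatrix,
    InsufficientCarriersError,
    MonomorphicSiteError,
    ehh_curve,
    ihs_raw,
    nsl_raw,
    score_haplotypes,
    standardize,
)
from sweepset.synth import SynthHaplotypeSpec, synth_haplotypes

from conftest import make_hap
from _oracles import brute_ehh, brute_ihs, brute_nsl


class TestEhh:
    def test_identical_carriers_keep_ehh_one(self):
        # 4 derived carriers identical over all 3 flanking sites
        hap = make_hap(["1110", "1110", "1110", "1110", "0001", "0001"])
        idx, vals = ehh_curve(hap, 0, 1, "right")
        assert np.allclose(vals, 1.0)

    def test_two_two_split_gives_two_sixths(self):
        # carriers split 2/2 at the first flanking site: C(2,2)+C(2,2) of C(4,2)
        hap = make_hap(["10", "10", "11", "11", "00", "01"])
        _, vals = ehh_curve(hap, 0, 1, "right")
        assert vals[0] == pytest.approx(2 / 6)

    def test_full_decay_stays_zero(self):
        hap = make_hap(["100", "110", "000", "000"])
        _, vals = ehh_curve(hap, 0, 1, "right")
        assert np.all(vals == 0.0)

    def test_errors(self):
        hap = make_hap(["10", "00", "00", "00"])
        with pytest.raises(InsufficientCarriersError):
            ehh_curve(hap, 0, 1, "right")
        hap = make_hap(["00", "01", "00", "01"])
        with pytest.raises(MonomorphicSiteError):
            ehh_curve(hap, 0, 1, "right")

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_monotone_bounded_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_hap, n_sites = rng.integers(4, 14), rng.integers(3, 9)
        alleles = rng.integers(0, 2, size=(n_hap, n_sites), dtype=np.int8)
        core = int(rng.integers(0, n_sites))
        col = alleles[:, core]
        allele = 1 if (col == 1).sum() >= 2 else 0
        if (col == allele).sum() < 2 or col.min() == col.max():
            return
        hap = HaplotypeMatrix(
            alleles, np.arange(n_sites) * 100 + 1, np.arange(n_sites) * 0.01
        )
        for direction in ("left", "right"):
            idx, vals = ehh_curve(hap, core, allele, direction)
            assert np.all((vals >= 0) & (vals <= 1))
            assert np.all(np.diff(vals) <= 1e-12)  # non-increasing outward
            for j, v in zip(idx, vals):
                assert v == pytest.approx(brute_ehh(alleles, core, allele, j))


class TestIhsRaw:
    def test_mirror_symmetry_gives_zero(self):
        # swapping 0/1 off-core maps ancestral carriers onto derived ones
        hap = make_hap(["00101", "01100", "11010", "10011"])
        assert ihs_raw(hap, 2) == pytest.approx(0.0, abs=1e-12)

    def test_longer_derived_haplotypes_negative_on_toy(self):
        # derived pair identical across the flanks, ancestral pair decays at
        # the first flanking site on each side; expected value from the
        # brute-force trapezoid oracle
        rows = ["0111110", "1111111", "0000100", "0110010"]
        hap = make_hap(rows)
        got = ihs_raw(hap, 3, ehh_floor=0.05)
        expected = brute_ihs(hap.alleles, hap.positions_cM, 3, 0.05)
        assert got < 0
        assert got == pytest.approx(expected, abs=1e-12)

    def test_row_permutation_invariance(self):
        base = None
        for seed in range(20):  # find a matrix where iHS is defined
            rng = np.random.default_rng(seed)
            alleles = rng.integers(0, 2, size=(12, 11), dtype=np.int8)
            alleles[:6, 5] = 1
            alleles[6:, 5] = 0
            cm = np.arange(11) * 0.02
            hap = HaplotypeMatrix(alleles, np.arange(11) * 500 + 1, cm)
            base = ihs_raw(hap, 5)
            if np.isfinite(base):
                break
        assert np.isfinite(base)
        perm = rng.permutation(12)
        hap2 = HaplotypeMatrix(alleles[perm], np.arange(11) * 500 + 1, cm)
        assert ihs_raw(hap2, 5) == pytest.approx(base, abs=1e-12)

    def test_unbounded_integral_scored_missing(self):
        # identical carriers to the data edge: EHH never decays below floor
        hap = make_hap(["110", "110", "001", "011"])
        assert np.isnan(ihs_raw(hap, 0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, size=(10, 8), dtype=np.int8)
        core = 4
        if min((alleles[:, core] == 0).sum(), (alleles[:, core] == 1).sum()) < 2:
            return
        cm = np.cumsum(rng.uniform(0.005, 0.05, size=8))
        hap = HaplotypeMatrix(alleles, np.arange(8) * 700 + 1, cm)
        got = ihs_raw(hap, core)
        expected = brute_ihs(alleles, cm, core)
        if expected is None:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-6)


class TestNslRaw:
    def test_mirror_symmetry_gives_zero(self):
        hap = make_hap(["00101", "01100", "11010", "10011"])
        assert nsl_raw(hap, 2) == pytest.approx(0.0, abs=1e-12)

    def test_map_rescaling_is_ignored(self):
        rng = np.random.default_rng(2)
        alleles = rng.integers(0, 2, size=(10, 7), dtype=np.int8)
        alleles[:5, 3], alleles[5:, 3] = 1, 0
        pos = np.arange(7) * 300 + 1
        a = nsl_raw(HaplotypeMatrix(alleles, pos, np.arange(7) * 0.01), 3)
        b = nsl_raw(HaplotypeMatrix(alleles, pos, np.arange(7) * 3.7), 3)
        assert a == b

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, size=(9, 8), dtype=np.int8)
        core = 3
        if min((alleles[:, core] == 0).sum(), (alleles[:, core] == 1).sum()) < 2:
            return
        hap = HaplotypeMatrix(alleles, np.arange(8) * 400 + 1, np.arange(8) * 0.01)
        assert nsl_raw(hap, core) == pytest.approx(brute_nsl(alleles, core), abs=1e-6)


class TestStandardize:
    def test_two_point_bin_maps_to_unit_scores(self):
        df = pd.DataFrame({"freq": [0.311, 0.319], "raw": [-1.0, 1.0]})
        out = standardize(df, n_bins=50)
        assert list(out["std"]) == [-1.0, 1.0]  # population sd

    def test_degenerate_bin_becomes_missing_with_warning(self):
        df = pd.DataFrame({"freq": [0.5, 0.5], "raw": [2.0, 2.0]})
        with pytest.warns(UserWarning, match="zero sd"):
            out = standardize(df)
        assert out["std"].isna().all()

    def test_grand_mean_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"freq": rng.uniform(0.05, 0.95, 2000), "raw": rng.normal(0, 1, 2000)})
        out = standardize(df, n_bins=20)
        assert abs(out["std"].mean()) < 0.05


class TestSimulatedHaplotypes:
    def test_neutral_scores_standardized_and_positions_sorted(self):
        hap = synth_haplotypes(SynthHaplotypeSpec(n_haplotypes=60, seed=7))
        assert np.all(np.diff(hap.positions_bp) > 0)
        df = score_haplotypes(hap, stats=("nSL",), maf_floor=0.05)
        finite = df["std"].dropna()
        assert len(finite) > 20
        # standardization centers each frequency bin; the grand mean follows
        assert abs(finite.mean()) < 3 * finite.std() / np.sqrt(len(finite)) + 0.15

    def test_incomplete_sweep_elevates_center_scores(self):
        """Across replicates, |standardized| scores in the swept window
        exceed those of a neutral reference region standardized jointly
        with it (one-sided binomial test at 0.01).

        Standardization pools the sweep and neutral regions (as genome-wide
        standardization would); standardizing the sweep region alone would
        absorb its own signal into the bin means.
        """
        rng = np.random.default_rng(0)
        wins = 0
        n_rep = 50
        for r in range(n_rep):
            frames = []
            for region, s in (("sweep", 0.05), ("neutral", None)):
                hap = synth_haplotypes(
                    SynthHaplotypeSpec(
                        n_haplotypes=50,
                        sequence_length=120_000,
                        mutation_rate=2.5e-8,
                        sweep_s=s,
                        sweep_end_frequency=0.6,
                        seed=(1000 if region == "sweep" else 9000) + r,
                    )
                )
                maf = np.minimum(hap.derived_freq(), 1 - hap.derived_freq())
                eligible = np.flatnonzero(maf >= 0.05)
                if region == "sweep":  # every eligible SNP in the swept window
                    inside = hap.positions_bp[eligible]
                    cores = eligible[(inside >= 40_000) & (inside <= 80_000)]
                else:
                    cores = np.sort(
                        rng.choice(eligible, size=min(80, eligible.size), replace=False)
                    )
                df = score_haplotypes(hap, stats=("nSL",), sites=cores)
                frames.append(df.drop(columns="std").assign(region=region))
            both = standardize(pd.concat(frames, ignore_index=True), n_bins=20)
            a = both.loc[both["region"] == "sweep", "std"].abs().mean()
            b = both.loc[both["region"] == "neutral", "std"].abs().mean()
            if np.isfinite(a) and np.isfinite(b) and a > b:
                wins += 1
        # under the null wins ~ Binomial(50, 0.5); 34+ rejects at p < 0.01
        assert wins >= 34, f"swept window elevated in only {wins}/{n_rep} replicates"
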