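import numpy as np
import pytest
from scipy import stats

from _utils import (haplotypes_to_matrix, ld_prune_oracle, make_matrix,
                    pi_windows_oracle, tajimas_d_oracle)
from panelsmith import popgen


class TestWindowedPi:
    def test_no_segregating_sites(self):
        m = make_matrix([["0/0", "0/0"]], positions=[10])
        track = popgen.windowed_pi(m, window_bp=50, contig_lengths={"c1": 100})
        assert track["pi"].tolist() == [0.0, 0.0]
        assert track["s"].tolist() == [0, 0]

    def test_single_het_pair(self):
        # 1 biallelic site, 2 haplotypes (one diploid 0/1): the single pair
        # differs -> site value 1, window pi = 1/50
        m = make_matrix([["0/1"]], positions=[10])
        track = popgen.windowed_pi(m, window_bp=50, contig_lengths={"c1": 50})
        assert track["pi"][0] == pytest.approx(0.02)

    def test_balanced_counts(self):
        # allele counts {ref:2, alt:2}: 2*2*2/(4*3) = 2/3 per site
        m = make_matrix([["0/0", "1/1"]], positions=[0])
        track = popgen.windowed_pi(m, window_bp=50, contig_lengths={"c1": 50})
        assert track["pi"][0] == pytest.approx((2 * 2 * 2 / (4 * 3)) / 50)

    def test_site_with_single_allele_skipped(self):
        m = make_matrix([["0/.", "./."]], positions=[0])
        track = popgen.windowed_pi(m, window_bp=50, contig_lengths={"c1": 50})
        assert track["pi"][0] == 0.0
        assert track["n_skipped"][0] == 1

    def test_matches_haplotype_pair_oracle(self):
        """pi equals the average per-bp Hamming distance over all phased
        haplotype pairs, for <=6 haplotypes (100 random instances)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_hap = int(rng.choice([2, 4, 6]))
            n_var = int(rng.integers(1, 15))
            length = 200
            haps = rng.integers(0, 2, size=(n_hap, n_var))
            positions = np.sort(rng.choice(length, size=n_var, replace=False))
            m = haplotypes_to_matrix(haps, positions=positions)
            track = popgen.windowed_pi(m, window_bp=50,
                                       contig_lengths={"c1": length})
            expected = pi_windows_oracle(haps, positions, 50, length)
            np.testing.assert_allclose(track["pi"].to_numpy(), expected,
                                       atol=1e-12)


class TestTajimasD:
    def test_no_segregating_sites_is_null(self):
        m = make_matrix([["0/0", "0/0"]])
        assert popgen.tajimas_d(m) is None

    def test_fewer_than_four_haplotypes_is_null(self):
        m = make_matrix([["0/1"]])
        assert popgen.tajimas_d(m) is None

    def test_three_singletons_in_six_haplotypes(self):
        # 3 singleton sites among n=6: k = 3 * 2*1*5/(6*5) = 1.0, S = 3
        haps = np.zeros((6, 3), dtype=int)
        for j in range(3):
            haps[j, j] = 1
        m = haplotypes_to_matrix(haps)
        d = popgen.tajimas_d(m)
        expected = tajimas_d_oracle(haps)
        assert d < 0
        assert d == pytest.approx(expected, abs=1e-9)

    def test_matches_constants_oracle_on_random_configurations(self):
        """100 random site-frequency configurations agree to 1e-9 with an
        independently coded textbook-formula oracle."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.choice([4, 6, 8, 10, 16, 20]))
            s = int(rng.integers(1, 12))
            haps = np.zeros((n, s), dtype=int)
            for j in range(s):
                count = int(rng.integers(1, n))
                haps[rng.choice(n, size=count, replace=False), j] = 1
            m = haplotypes_to_matrix(haps)
            expected = tajimas_d_oracle(haps)
            got = popgen.tajimas_d(m)
            assert got == pytest.approx(expected, abs=1e-9)


class TestMalecotF:
    def test_all_het_gives_minus_one(self):
        m = make_matrix([["0/1", "0/1", "0/1", "0/1"]])
        assert popgen.malecot_f(m) == pytest.approx(-1.0)

    def test_no_hets_gives_one(self):
        m = make_matrix([["0/0", "0/0", "1/1", "1/1"]])
        assert popgen.malecot_f(m) == pytest.approx(1.0)

    def test_hardy_weinberg_counts(self):
        # {AA, AT, AT, TT}: Hobs = 0.5, p = 0.5, Hexp = 0.5 -> f = 0
        m = make_matrix([["0/0", "0/1", "0/1", "1/1"]])
        assert popgen.malecot_f(m) == pytest.approx(0.0)

    def test_monomorphic_is_null(self):
        m = make_matrix([["0/0", "0/0"]])
        assert popgen.malecot_f(m) is None


class TestGenotypeR2:
    def test_identical_vectors(self):
        assert popgen.genotype_r2([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert popgen.genotype_r2([0, 1, 2], [2, 1, 0]) == pytest.approx(1.0)

    def test_matches_pearson(self):
        x, y = [0, 0, 1, 2], [0, 1, 1, 2]
        r, _ = stats.pearsonr(x, y)
        assert popgen.genotype_r2(x, y) == pytest.approx(r ** 2, abs=1e-12)

    def test_zero_variance_is_null(self):
        assert popgen.genotype_r2([1, 1, 1], [0, 1, 2]) is None

    def test_missing_handled_pairwise_complete(self):
        x = [0, np.nan, 1, 2]
        y = [0, 1, 1, 2]
        r, _ = stats.pearsonr([0, 1, 2], [0, 1, 2])
        assert popgen.genotype_r2(x, y) == pytest.approx(r ** 2)


class TestLdPrune:
    def test_uncorrelated_all_retained(self):
        rng = np.random.default_rng(0)
        # orthogonal-ish dosages with r2 <= threshold is hard at random;
        # use explicit zero-correlation pairs
        dosage = np.array([[0, 0, 2, 2], [0, 2, 0, 2]], dtype=float)
        kept = popgen.ld_prune(dosage, r2_max=0.01, window_snps=10, step_snps=5)
        assert kept.tolist() == [0, 1]

    def test_duplicate_column_removed(self):
        dosage = np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=float)
        kept = popgen.ld_prune(dosage, r2_max=0.01, window_snps=10, step_snps=5)
        assert kept.tolist() == [0]

    def test_matches_bruteforce_oracle(self):
        """Retained set identical to an exhaustive scan re-implementation on
        random 40-variant x 20-sample matrices."""
        rng = np.random.default_rng(11)
        for trial in range(25):
            dosage = rng.integers(0, 3, size=(40, 20)).astype(float)
            # correlate some neighbours to make pruning non-trivial
            for j in range(1, 40, 3):
                dosage[j] = dosage[j - 1]
            kept = popgen.ld_prune(dosage, r2_max=0.01, window_snps=10,
                                   step_snps=5)
            expected = ld_prune_oracle(dosage, 0.01, 10, 5)
            assert kept.tolist() == expected

    def test_no_retained_pair_in_window_exceeds_threshold(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(60, 15)).astype(float)
        kept = popgen.ld_prune(dosage, r2_max=0.2, window_snps=12, step_snps=6)
        kept = kept.tolist()
        for start in range(0, 60, 6):
            inside = [k for k in kept if start <= k < start + 12]
            for a_i, a in enumerate(inside):
                for b in inside[a_i + 1:]:
                    r2 = popgen.genotype_r2(dosage[a], dosage[b])
                    assert r2 is None or r2 <= 0.2


def _sim_pair_matrix(rng, kind, n_sites=1000, n_background=20):
    """Matrix with background samples plus a pair of given relatedness."""
    p = rng.uniform(0.1, 0.9, size=n_sites)
    cols = [rng.binomial(1, p, size=(2, n_sites)).T
            for _ in range(n_background)]
    a = rng.binomial(1, p, size=(2, n_sites)).T
    if kind == "duplicate":
        b = a.copy()
    elif kind == "unrelated":
        b = rng.binomial(1, p, size=(2, n_sites)).T
    elif kind == "parent_offspring":
        transmitted = a[np.arange(n_sites), rng.integers(0, 2, n_sites)]
        other = rng.binomial(1, p)
        b = np.stack([transmitted, other], axis=1)
    calls = np.stack(cols + [a, b], axis=1).astype(np.int8)
    n_samp = n_background + 2
    from panelsmith.genotypes import GenotypeMatrix
    return GenotypeMatrix(
        contigs=np.array(["c1"] * n_sites, dtype=object),
        positions=np.arange(n_sites, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=[("T",)] * n_sites,
        calls=calls,
        dp=np.full((n_sites, n_samp), 100, np.int32),
        gq=np.full((n_sites, n_samp), 99, np.int32),
        phased=np.zeros((n_sites, n_samp), bool),
        samples=[f"bg{i}" for i in range(n_background)] + ["pa", "pb"],
    )


class TestIbdPiHat:
    @pytest.mark.parametrize("kind,lo,hi", [
        ("duplicate", 0.95, 1.0),
        ("unrelated", 0.0, 0.10),
        ("parent_offspring", 0.4, 0.6),
    ])
    def test_relationship_recovery(self, kind, lo, hi):
        rng = np.random.default_rng(123)
        m = _sim_pair_matrix(rng, kind)
        est = popgen.ibd_pi_hat(m, "pa", "pb")
        assert lo <= est.pi_hat <= hi
        assert est.z0 + est.z1 + est.z2 == pytest.approx(1.0)

    def test_symmetric_under_sample_swap(self):
        rng = np.random.default_rng(9)
        m = _sim_pair_matrix(rng, "parent_offspring")
        ab = popgen.ibd_pi_hat(m, "pa", "pb")
        ba = popgen.ibd_pi_hat(m, "pb", "pa")
        assert ab.pi_hat == pytest.approx(ba.pi_hat)
        assert ab.z0 == pytest.approx(ba.z0)

    def test_too_few_sites_is_null(self):
        rng = np.random.default_rng(1)
        m = _sim_pair_matrix(rng, "unrelated", n_sites=50)
        assert popgen.ibd_pi_hat(m, "pa", "pb", min_sites=200) is None
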