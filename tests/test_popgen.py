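import numpy as np
import pandas as pd
import pytest

from specstruct.popgen import (
    filter_missingness,
    genetic_and_euclidean,
    geographic_km,
    ibd_slope,
    linearize_fst,
    mtdna_distances,
    nucleotide_diversity,
    pairwise_fst,
    read_vcf,
)

NA = np.nan


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self, toy_genotypes):
        f = pairwise_fst(toy_genotypes([[0] * 6, [2] * 6]), min_cotyped=1)
        assert f[0, 1] == pytest.approx(1.0)

    def test_identical_homozygotes_give_zero(self, toy_genotypes):
        f = pairwise_fst(toy_genotypes([[0, 2, 0, 2], [0, 2, 0, 2]]), min_cotyped=1)
        assert f[0, 1] == pytest.approx(0.0)

    def test_four_site_toy_matches_bruteforce(self, toy_genotypes):
        g = toy_genotypes([[0, 2, 1, 1], [2, 2, 1, 0]])
        val = pairwise_fst(g, min_cotyped=1)[0, 1]
        p1, p2 = np.array([0, 1, 0.5, 0.5]), np.array([1, 1, 0.5, 0.0])
        num = (p1 - p2) ** 2 - p1 * (1 - p1) - p2 * (1 - p2)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert val == pytest.approx(num[den > 0].sum() / den[den > 0].sum(), abs=1e-15)

    def test_pair_below_cotyped_floor_flagged(self, toy_genotypes):
        g = toy_genotypes([[0, NA, NA], [NA, 1, NA], [0, 1, 2]])
        f = pairwise_fst(g, min_cotyped=1)
        assert np.isnan(f[0, 1])  # zero co-typed sites
        assert not np.isnan(f[0, 2])

    def test_missingness_monotone(self, toy_genotypes):
        """Masking extra calls never changes the statistic on the co-typed set."""
        full = toy_genotypes([[0, 2, 1, 1, 2], [2, 2, 1, 0, 0]])
        masked = toy_genotypes([[0, 2, 1, 1, NA], [2, 2, 1, 0, NA]])
        sub = toy_genotypes([[0, 2, 1, 1], [2, 2, 1, 0]])
        assert pairwise_fst(masked, 1)[0, 1] == pytest.approx(
            pairwise_fst(sub, 1)[0, 1], abs=1e-15
        )
        assert pairwise_fst(masked, 1)[0, 1] != pytest.approx(
            pairwise_fst(full, 1)[0, 1]
        )


class TestNucleotideDiversity:
    def test_monomorphic_is_zero(self, toy_genotypes):
        assert nucleotide_diversity(toy_genotypes([[0, 0], [0, 0]])) == 0.0

    def test_unbiased_three_diploids(self, toy_genotypes):
        # site 1: alt count 2 of 6 copies -> 2*(1/3)(2/3)*(6/5) = 8/15; site 2: 0
        pi = nucleotide_diversity(toy_genotypes([[0, 0], [1, 0], [1, 0]]))
        assert pi == pytest.approx((8 / 15) / 2, abs=1e-12)

    def test_haploid_coded_pair(self, toy_genotypes):
        # two individuals differing at 1 of 4 sites, coded hom: per-site
        # unbiased pi at the variant site is 2*(1/2)(1/2)*(4/3) = 2/3
        pi = nucleotide_diversity(toy_genotypes([[0, 0, 0, 0], [2, 0, 0, 0]]))
        assert pi == pytest.approx((2 / 3) / 4, abs=1e-12)

    def test_no_eligible_sites_errors(self, toy_genotypes):
        with pytest.raises(ValueError):
            nucleotide_diversity(toy_genotypes([[NA, NA], [NA, NA], [0, 0]][:1]))


class TestGeneticEuclidean:
    def test_identical_individuals(self, toy_genotypes):
        g, e = genetic_and_euclidean(toy_genotypes([[0, 1, 2], [0, 1, 2]]), 1)
        assert g[0, 1] == 0.0 and e[0, 1] == 0.0

    def test_maximal_difference(self, toy_genotypes):
        g, e = genetic_and_euclidean(toy_genotypes([[0, 0], [2, 2]]), 1)
        assert g[0, 1] == pytest.approx(1.0)
        assert e[0, 1] == pytest.approx(2.0)

    def test_het_vs_homref_single_site(self, toy_genotypes):
        g, e = genetic_and_euclidean(toy_genotypes([[1], [0]]), 1)
        assert g[0, 1] == pytest.approx(0.5)
        assert e[0, 1] == pytest.approx(1.0)


class TestMtdnaDistances:
    def _recs(self, seqs):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        return [SeqRecord(Seq(s), id=f"s{i}") for i, s in enumerate(seqs)]

    def test_identical_sequences(self):
        D, ids, mean = mtdna_distances(self._recs(["ACGT", "ACGT"]))
        assert D[0, 1] == 0.0 and mean == 0.0

    def test_one_quarter(self):
        D, _, _ = mtdna_distances(self._recs(["ACGT", "ACGA"]))
        assert D[0, 1] == pytest.approx(0.25)

    def test_gap_positions_excluded(self):
        D, _, _ = mtdna_distances(self._recs(["AC-T", "ACGT"]))
        assert D[0, 1] == pytest.approx(0.0)

    def test_unaligned_lengths_error(self):
        with pytest.raises(ValueError, match="aligned"):
            mtdna_distances(self._recs(["ACGT", "ACG"]))


class TestGeographicKm:
    def test_identical_points(self):
        c = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [10.0, 10.0]})
        assert geographic_km(c)[0, 1] == pytest.approx(0.0)

    def test_antipodal_half_circumference(self):
        c = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0.0, 180.0]})
        assert geographic_km(c)[0, 1] == pytest.approx(np.pi * 6371.0088, rel=1e-9)

    def test_one_degree_at_equator(self):
        c = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0.0, 1.0]})
        assert geographic_km(c)[0, 1] == pytest.approx(111.19493, abs=1e-3)


class TestFilterMissingness:
    def test_threshold_removes_site(self, toy_genotypes):
        calls = np.zeros((10, 2))
        calls[:3, 0] = NA  # 30% missing at site 0
        g = filter_missingness(toy_genotypes(calls), 0.2)
        assert g.n_sites == 1

    def test_monotone_in_threshold(self, toy_genotypes):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(10, 50)).astype(float)
        calls[rng.uniform(size=calls.shape) < 0.3] = NA
        g = toy_genotypes(calls)
        kept = [filter_missingness(g, th).n_sites for th in (0.2, 0.4, 0.6)]
        assert kept == sorted(kept)

    def test_zero_threshold_identity_on_complete(self, toy_genotypes):
        g = toy_genotypes([[0, 1], [2, 1]])
        assert filter_missingness(g, 0.0).n_sites == 2

    def test_all_removed_errors(self, toy_genotypes):
        calls = np.full((4, 3), NA)
        calls[0] = 0
        with pytest.raises(ValueError, match="threshold"):
            filter_missingness(toy_genotypes(calls), 0.2)


class TestIBDSlope:
    def _geo(self, n, seed=0):
        rng = np.random.default_rng(seed)
        c = pd.DataFrame(
            {"latitude": -19 + rng.uniform(0, 1, n), "longitude": 47 + rng.uniform(0, 1, n)}
        )
        return geographic_km(c)

    def test_exact_linear_recovery(self):
        geo = self._geo(8)
        iu = np.triu_indices(8, 1)
        y = np.zeros((8, 8))
        y[iu] = 0.01 + 0.07 * np.log(geo[iu])
        y = y + y.T
        r = ibd_slope(y, geo, permutations=99, seed=1)
        assert r.beta == pytest.approx(0.07, abs=1e-10)
        assert r.intercept == pytest.approx(0.01, abs=1e-10)
        assert r.p_perm == pytest.approx(1 / 100)

    def test_permutation_p_seed_deterministic(self):
        geo = self._geo(8)
        rng = np.random.default_rng(5)
        y = rng.uniform(size=(8, 8))
        y = (y + y.T) / 2
        np.fill_diagonal(y, 0)
        a = ibd_slope(y, geo, permutations=199, seed=11)
        b = ibd_slope(y, geo, permutations=199, seed=11)
        assert a.p_perm == b.p_perm and a.beta == b.beta

    def test_constant_distance_errors(self):
        geo = np.full((4, 4), 5.0)
        np.fill_diagonal(geo, 0)
        y = np.zeros((4, 4))
        with pytest.raises(ValueError, match="slope undefined"):
            ibd_slope(y, geo, permutations=9, seed=0)

    def test_zero_distance_pairs_dropped_and_counted(self):
        c = pd.DataFrame(
            {"latitude": [0.0, 0.0, 0.1, 0.2], "longitude": [10.0, 10.0, 10.1, 10.3]}
        )
        geo = geographic_km(c)
        rng = np.random.default_rng(2)
        y = rng.uniform(size=(4, 4))
        y = (y + y.T) / 2
        np.fill_diagonal(y, 0)
        r = ibd_slope(y, geo, permutations=9, seed=0)
        assert r.dropped_zero_distance_pairs == 1
        assert r.n_pairs == 5

    def test_linearize_caps_and_counts(self):
        f = np.array([[0.0, 0.9995], [0.9995, 0.0]])
        lin, n = linearize_fst(f)
        assert n == 1
        assert np.isfinite(lin).all()


class TestReadVCF:
    VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t1\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t2\t.\tA\tG,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t3\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t./.\t./.
1\t4\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t./1\t1/1
"""

    def _write(self, tmp_path, coords_ids=("s1", "s2", "s3")):
        v = tmp_path / "x.vcf"
        v.write_text(self.VCF)
        c = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "individual_id": coords_ids,
                "species": "sp",
                "latitude": [-19.0] * len(coords_ids),
                "longitude": [47.0, 47.1, 47.2][: len(coords_ids)],
            }
        ).to_csv(c, index=False)
        return v, c

    def test_dosages_and_filters(self, tmp_path):
        v, c = self._write(tmp_path)
        g = read_vcf(v, c)
        # multiallelic site dropped, all-missing site dropped
        assert g.dropped_multiallelic == 1
        assert g.dropped_all_missing == 1
        assert g.n_sites == 2
        assert list(g.calls[:, 0]) == [0.0, 1.0, 2.0]
        # half-call treated as missing
        assert np.isnan(g.calls[1, 1])

    def test_sample_missing_from_coords_errors(self, tmp_path):
        v, c = self._write(tmp_path, coords_ids=("s1", "s2"))
        with pytest.raises(ValueError, match="s3"):
            read_vcf(v, c)
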