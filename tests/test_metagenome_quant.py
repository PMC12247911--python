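import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raidpop.formats import AbundanceTable, AlleleCountMatrix, ValidationError
from raidpop.marker_snps import StrainMarkerSet
from raidpop.metagenome_quant import (
    SnpSite,
    bin_days_into_groups,
    braycurtis_permanova,
    cooccurrence_rank_test,
    correlate_gene_species,
    detect_gene,
    detect_metagenome_variants,
    flag_outlier_marker_genes,
    normalize_gene_abundance,
    site_allele_frequencies,
    strain_marker_trajectory,
)

from _oracles import brute_force_variant_sites


class TestNormalizeAbundance:
    def test_unit_case(self):
        t = normalize_gene_abundance(
            pd.DataFrame([[1000]], index=["g1"], columns=["s1"]),
            {"g1": 1000}, {"s1": 1_000_000},
        )
        assert t.values.loc["g1", "s1"] == pytest.approx(1000.0)

    def test_zero_reads_and_library_scaling(self):
        raw = pd.DataFrame([[0, 500]], index=["g1"], columns=["s1", "s2"])
        t1 = normalize_gene_abundance(raw, {"g1": 2000}, {"s1": 1_000_000, "s2": 1_000_000})
        t2 = normalize_gene_abundance(raw, {"g1": 2000}, {"s1": 2_000_000, "s2": 2_000_000})
        assert t1.values.loc["g1", "s1"] == 0.0
        assert (t1.values.to_numpy() == 2 * t2.values.to_numpy()).all()

    def test_zero_library_rejected(self):
        raw = pd.DataFrame([[1]], index=["g1"], columns=["s1"])
        with pytest.raises(ValidationError):
            normalize_gene_abundance(raw, {"g1": 100}, {"s1": 0})


class TestDetectGene:
    def test_strictly_positive_rule_and_monotonicity(self):
        t = AbundanceTable(
            pd.DataFrame([[0.0, 0.5, 2.0]], index=["g"], columns=["a", "b", "c"]),
            collection_days=[0, 1, 2], library_sizes=[1, 1, 1],
        )
        d0 = detect_gene(t)
        assert list(d0.loc["g"]) == [False, True, True]  # 0 is not detected
        d1 = detect_gene(t, min_value=1.0)
        assert d1.to_numpy().sum() <= d0.to_numpy().sum()


class TestSiteFrequencies:
    def _acm(self, positions, counts):
        return AlleleCountMatrix(
            sites=[("g1", p) for p in positions],
            samples=["s1"],
            counts=np.array(counts).reshape(len(positions), 1, 4),
        )

    def test_end_trim_keeps_interior_positions(self):
        acm = self._acm([1, 10, 11, 90, 91, 100], [[5, 0, 0, 0]] * 6)
        out = site_allele_frequencies(acm, {"g1": 100})
        assert [o["pos"] for o in out] == [11, 90]

    def test_frequencies_and_missing_coverage(self):
        acm = self._acm([50, 60], [[9, 0, 1, 0], [0, 0, 0, 0]])
        out = site_allele_frequencies(acm, {"g1": 100})
        assert out[0]["freqs"][0] == pytest.approx([0.9, 0, 0.1, 0])
        assert np.isnan(out[1]["freqs"][0]).all()  # zero coverage -> missing, not 0

    def test_too_short_gene_dropped(self):
        acm = self._acm([5], [[3, 0, 0, 0]])
        assert site_allele_frequencies(acm, {"g1": 20}) == []


class TestVariantDetection:
    def test_low_coverage_never_emits(self):
        counts = np.tile([2, 2, 0, 0], (1, 10, 1))
        acm = AlleleCountMatrix([("g", 20)], [f"s{i}" for i in range(10)], counts)
        assert detect_metagenome_variants(acm) == []

    def test_boundary_sample_fraction_inclusive(self):
        # qualifies in exactly 1 of 10 samples = 10%
        counts = np.zeros((1, 10, 4), dtype=int)
        counts[0, 0] = [3, 2, 0, 0]  # coverage 5, minor 2
        acm = AlleleCountMatrix([("g", 20)], [f"s{i}" for i in range(10)], counts)
        (site,) = detect_metagenome_variants(acm)
        assert (site.ref_base, site.alt_base) == ("A", "C")
        assert site.alt_freq[0] == pytest.approx(0.4)
        assert np.isnan(site.alt_freq[1:]).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n_sites, n_samples = int(rng.integers(3, 30)), int(rng.integers(2, 12))
            counts = rng.integers(0, 7, size=(n_sites, n_samples, 4))
            sites = [("g", int(p)) for p in rng.choice(500, n_sites, replace=False)]
            acm = AlleleCountMatrix(sites, [f"s{j}" for j in range(n_samples)], counts)
            got = [(acm.sites.index((s.gene_id, s.position)), s.ref_base, s.alt_base)
                   for s in detect_metagenome_variants(acm)]
            assert got == brute_force_variant_sites(counts, sites, 5, 2, 0.10)


class TestTrajectory:
    def _site(self, pos, alt_freq, ref="A", alt="G"):
        f = np.asarray(alt_freq, dtype=float)
        return SnpSite("g", pos, ref, alt, np.full(len(f), 100), f)

    def _markers(self, snps):
        return StrainMarkerSet("S1", snps, [1.0] * len(snps), [0.0] * len(snps))

    def test_single_marker_passthrough_and_mean(self):
        sites = [self._site(5, [0.4, 0.2]), self._site(9, [0.4, 0.6])]
        m1 = self._markers([("g", 5, "A", "G")])
        traj, n = strain_marker_trajectory(m1, sites)
        assert traj == pytest.approx([0.4, 0.2]) and list(n) == [1, 1]
        m2 = self._markers([("g", 5, "A", "G"), ("g", 9, "A", "G")])
        traj, n = strain_marker_trajectory(m2, sites)
        assert traj == pytest.approx([0.4, 0.4]) and list(n) == [2, 2]

    def test_swapped_orientation_uses_complement_frequency(self):
        sites = [self._site(5, [0.9, 0.8], ref="G", alt="A")]  # marker alt G is site ref
        m = self._markers([("g", 5, "A", "G")])
        traj, _ = strain_marker_trajectory(m, sites)
        assert traj == pytest.approx([0.1, 0.2])

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValidationError):
            strain_marker_trajectory(self._markers([("g", 99, "A", "G")]), [self._site(5, [0.4])])


class TestOutlierGenes:
    def _sites(self, profile, gene, n):
        return [
            SnpSite(gene, 10 + i, "A", "G", np.full(len(profile), 50), np.asarray(profile, float))
            for i in range(n)
        ]

    def test_concordant_genes_not_excluded(self):
        up = [0.1, 0.3, 0.5, 0.7]
        sites = self._sites(up, "g1", 3) + self._sites(up, "g2", 4) + self._sites(up, "g3", 3)
        assert flag_outlier_marker_genes(sites) == []

    def test_inverted_high_load_gene_excluded_order_invariantly(self):
        up, down = [0.1, 0.3, 0.5, 0.7], [0.9, 0.7, 0.5, 0.3]
        sites = (
            self._sites(up, "g1", 3) + self._sites(up, "g2", 4)
            + self._sites(up, "g3", 3) + self._sites(down, "bad", 20)
        )
        assert flag_outlier_marker_genes(sites) == ["bad"]
        rng = np.random.default_rng(0)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        assert flag_outlier_marker_genes(shuffled) == ["bad"]

    def test_needs_three_genes(self):
        with pytest.raises(ValidationError):
            flag_outlier_marker_genes(self._sites([0.1, 0.2], "g1", 2))


class TestRankTest:
    def test_identical_groups_null_center(self):
        x = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        det = np.array([True, True, True, True, False, False, False, False])
        u, p, n1, n0 = cooccurrence_rank_test(x, det)
        assert p > 0.9 and (n1, n0) == (4, 4)

    def test_complete_separation(self):
        x = np.array([1.0, 2, 3, 10, 11, 12])
        det = np.array([True, True, True, False, False, False])
        u, p, _, _ = cooccurrence_rank_test(x, det)
        assert u == 0.0 and p < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            cooccurrence_rank_test(np.array([1.0, 2.0]), np.array([True, True]))

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=40)
            det = np.zeros(40, dtype=bool)
            det[rng.choice(40, 20, replace=False)] = True
            _, p, _, _ = cooccurrence_rank_test(x, det)
            rejections += p < 0.05
        lo, hi = stats.binom.interval(0.99, n_sim, 0.05)
        assert lo <= rejections <= hi


def _community_table(X, days=None):
    n = X.shape[1]
    return AbundanceTable(
        pd.DataFrame(X, index=[f"sp{i}" for i in range(X.shape[0])],
                     columns=[f"s{j}" for j in range(n)]),
        collection_days=days if days is not None else np.arange(n, dtype=float),
        library_sizes=np.full(n, 1000),
    )


class TestPermanova:
    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(8)
        X = rng.dirichlet(np.ones(6), size=12).T  # taxa x samples
        groups = np.array(["a"] * 6 + ["b"] * 6)
        f_ours, _ = braycurtis_permanova(_community_table(X), groups, n_perm=9, seed=0)
        dm = skbio.DistanceMatrix(squareform(pdist(X.T, "braycurtis")))
        res = skbio.stats.distance.permanova(dm, grouping=list(groups), permutations=0)
        assert f_ours == pytest.approx(float(res["test statistic"]), rel=1e-9)

    def test_disjoint_communities_detected(self):
        rng = np.random.default_rng(9)
        a = rng.dirichlet([10, 1, 1, 1, 1, 1], size=10)
        b = rng.dirichlet([1, 1, 1, 1, 1, 10], size=10)
        X = np.vstack([a, b]).T
        groups = np.array(["a"] * 10 + ["b"] * 10)
        f, p = braycurtis_permanova(_community_table(X), groups, n_perm=999, seed=1)
        assert p <= 0.01

    def test_seeded_determinism_and_small_group_error(self):
        rng = np.random.default_rng(10)
        X = rng.dirichlet(np.ones(5), size=8).T
        groups = np.array(["a"] * 4 + ["b"] * 4)
        r1 = braycurtis_permanova(_community_table(X), groups, n_perm=99, seed=7)
        r2 = braycurtis_permanova(_community_table(X), groups, n_perm=99, seed=7)
        assert r1 == r2
        with pytest.raises(ValidationError):
            braycurtis_permanova(_community_table(X), np.array(["a"] * 7 + ["b"]))

    def test_day_binning_gives_equal_ordered_groups(self):
        days = np.array([30.0, 0.0, 60.0, 10.0, 50.0, 20.0])
        labels = bin_days_into_groups(days, n_bins=3)
        assert list(labels[np.argsort(days)]) == ["T1", "T1", "T2", "T2", "T3", "T3"]


class TestGeneSpeciesCorrelation:
    def test_exact_linear_relations(self):
        x = np.arange(10, dtype=float)
        assert correlate_gene_species(2 * x, x)[0] == pytest.approx(1.0)
        assert correlate_gene_species(-x, x)[0] == pytest.approx(-1.0)

    def test_independent_noise_is_uncorrelated(self):
        rng = np.random.default_rng(11)
        r, p, n = correlate_gene_species(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1 and n == 1000

    def test_zero_variance_is_missing_and_nan_pairs_dropped(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        r, p, n = correlate_gene_species(x, np.array([1.0, 2, 3, 4]))
        assert np.isnan(r)
        a = np.array([1.0, np.nan, 2, 3, 4])
        b = np.array([2.0, 5, 4, 6, 8])
        r, p, n = correlate_gene_species(a, b)
        assert n == 4
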