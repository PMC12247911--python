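import numpy as np
import pytest
from scipy import stats

from raidpop.formats import ValidationError
from raidpop.genome_screen import gc_fraction
from raidpop.selection import classify_snp_effect
from raidpop.synthetic import (
    CommunitySpec,
    StrainGenotypeSpec,
    genotype_matrix_from_diagnostics,
    simulate_community,
    simulate_marker_genomes,
    simulate_pileup,
    simulate_raid_genomes,
    simulate_selection_gene,
)

from _oracles import brute_force_window_counts


class TestMarkerGenomes:
    def test_zero_noise_isolates_carry_exactly_their_strains_snps(self, two_strain_isolates):
        iso = two_strain_isolates
        for gid, strain in iso.strain_labels.items():
            for owner, snps in iso.diagnostic_snps.items():
                for gene, pos, ref, alt in snps:
                    base = iso.orthologs[gid][gene][pos - 1]
                    assert base == (alt if owner == strain else ref)

    def test_same_seed_is_byte_identical(self):
        spec = StrainGenotypeSpec(n_marker_genes=2, gene_length=300, n_diagnostic_snps=5, seed=9)
        a = simulate_marker_genomes(spec, {"S1": 3, "S2": 3})
        b = simulate_marker_genomes(spec, {"S1": 3, "S2": 3})
        assert a.ref_genes == b.ref_genes and a.orthologs == b.orthologs
        assert a.diagnostic_snps == b.diagnostic_snps

    def test_noisy_carriage_fraction_within_binomial_bounds(self):
        # per-SNP in-strain carriage over many isolates ~ Binomial(n, 0.95)
        spec = StrainGenotypeSpec(
            n_marker_genes=2, gene_length=600, n_diagnostic_snps=10,
            within_strain_noise_rate=0.05, seed=0,
        )
        iso = simulate_marker_genomes(spec, {"S1": 100, "S2": 100})
        carried = total = 0
        for strain, snps in iso.diagnostic_snps.items():
            members = [g for g, s in iso.strain_labels.items() if s == strain]
            for gene, pos, ref, alt in snps:
                carried += sum(iso.orthologs[g][gene][pos - 1] == alt for g in members)
                total += len(members)
        lo, hi = stats.binom.interval(0.99, total, 0.95)
        assert lo <= carried <= hi

    def test_too_many_snps_rejected(self):
        with pytest.raises(ValidationError):
            StrainGenotypeSpec(n_marker_genes=1, gene_length=9, n_diagnostic_snps=10)


class TestCommunity:
    def test_single_constant_strain_is_always_one(self):
        spec = CommunitySpec(
            sampling_days=[0, 10, 20], trajectories=[("constant", {"level": 2.0})],
        )
        assert np.allclose(simulate_community(spec), 1.0)

    def test_bloom_strain_rises_and_proportions_normalize(self):
        days = list(np.linspace(0, 540, 28))
        spec = CommunitySpec(
            sampling_days=days,
            trajectories=[
                ("constant", {"level": 1.0}),
                ("logistic_bloom", {"baseline": 1e-3, "bloom_day": 200.0, "growth_rate": 0.05}),
            ],
        )
        props = simulate_community(spec)
        assert np.allclose(props.sum(axis=0), 1.0)
        bloom = props[1]
        pre = np.array(days) < 200.0
        assert (bloom[pre] < 0.05).all()
        post = np.flatnonzero(~pre)
        assert (np.diff(bloom[post]) > 0).all()
        assert bloom[0] < bloom[-1]

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ValidationError):
            CommunitySpec(sampling_days=[0, 10, 10], trajectories=[("constant", {})])

    def test_oscillation_amplitude_must_stay_positive(self):
        spec = CommunitySpec(
            sampling_days=[0.0, 10.0],
            trajectories=[("oscillating", {"base": 1.0, "amplitude": 1.5, "period": 30})],
        )
        with pytest.raises(ValidationError):
            simulate_community(spec)


class TestPileup:
    SITES = [("g1", 50, "A", "G"), ("g1", 80, "C", "T")]

    def test_error_free_single_strain_reads_are_all_alt(self):
        G = np.array([[1.0, 1.0]])
        ab = np.array([[1.0, 1.0, 1.0]])
        acm = simulate_pileup(G, self.SITES, ab, depth_mean=50, error_rate=0.0, seed=1)
        for i, (_, _, ref, alt) in enumerate(self.SITES):
            alt_i = "ACGT".index(alt)
            assert (acm.counts[i, :, alt_i] == acm.totals()[i]).all()

    def test_mixture_allele_frequency_concentrates(self):
        G = np.array([[1.0, 1.0], [0.0, 0.0]])
        ab = np.array([[0.3], [0.7]])
        acm = simulate_pileup(G, self.SITES, ab, depth_mean=1000, error_rate=0.0, seed=2)
        for i in range(2):
            alt_i = "ACGT".index(self.SITES[i][3])
            f = acm.counts[i, 0, alt_i] / acm.totals()[i, 0]
            assert abs(f - 0.3) < 0.05

    def test_same_seed_identical_and_bad_inputs_rejected(self):
        G = np.array([[1.0, 0.0]])
        ab = np.array([[1.0]])
        a = simulate_pileup(G, self.SITES, ab, 30, 0.01, seed=3)
        b = simulate_pileup(G, self.SITES, ab, 30, 0.01, seed=3)
        assert (a.counts == b.counts).all()
        with pytest.raises(ValidationError):
            simulate_pileup(G, self.SITES, ab, 30, 0.80, seed=3)
        with pytest.raises(ValidationError):
            simulate_pileup(np.array([[0.5, 0.0]]), self.SITES, ab, 30, 0.01, seed=3)


class TestSelectionGene:
    def test_no_requested_snps_gives_empty_list(self):
        _, snps, _ = simulate_selection_gene(300, 0, 60, 0, seed=0, cluster_margin=0)
        assert snps == []

    def test_planted_effects_verify_by_translation(self):
        cds, snps, (c0, c1) = simulate_selection_gene(seed=21)
        for s in snps:
            got = classify_snp_effect(cds, s.position, s.alt_base)
            assert got.effect == s.effect and got.ref_base == s.ref_base
            if s.effect == "non-synonymous":
                assert c0 <= s.position <= c1
            else:
                assert s.position < c0 or s.position > c1

    def test_cluster_dominates_flanking_windows(self):
        # brute-force window scan: the max pseudo-counted ratio must sit in a
        # window overlapping the planted cluster
        cds, snps, (c0, c1) = simulate_selection_gene(seed=33)
        counts = brute_force_window_counts(snps, len(cds), 200, 25)
        ratios = [(s, e, (ns + 1) / (sy + 1)) for s, e, ns, sy in counts]
        best = max(ratios, key=lambda t: t[2])
        assert best[0] <= c1 and best[1] >= c0
        outside = [r for s, e, r in ratios if e < c0 or s > c1]
        assert max(outside, default=0.0) < best[2]


class TestRaidGenomes:
    def test_truth_counts_and_decoy_labels(self):
        fasta, genes, hits, truth = simulate_raid_genomes(3, 0, seed=4)
        assert sum(t.is_system for t in truth) == 3 and len(truth) == 3
        fasta, genes, hits, truth = simulate_raid_genomes(2, 3, seed=4)
        violations = sorted(t.violation for t in truth if not t.is_system)
        assert violations == ["count", "gc", "orientation"]

    def test_emitted_member_gc_below_rule_threshold(self):
        fasta, genes, hits, truth = simulate_raid_genomes(4, 2, seed=5)
        seq = fasta["syncontig_1"]
        by_tag = {g.locus_tag: g for g in genes}
        for t in truth:
            for tag in t.member_loci:
                g = by_tag[tag]
                assert gc_fraction(seq[g.start : g.end]) < 0.41

    def test_same_seed_identical_and_param_validation(self):
        a = simulate_raid_genomes(2, 2, seed=6)
        b = simulate_raid_genomes(2, 2, seed=6)
        assert a[0] == b[0] and a[1] == b[1]
        with pytest.raises(ValidationError):
            simulate_raid_genomes(1, 1, gc_low=0.45, gc_high=0.55, seed=0)
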