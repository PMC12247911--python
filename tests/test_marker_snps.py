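import dendropy
import numpy as np
import pytest

from raidpop.formats import HomologyHit, ValidationError
from raidpop.marker_snps import (
    MarkerOrtholog,
    accept_marker_genomes,
    assign_strains_from_tree,
    call_genome_variants,
    identify_strain_markers,
)
from raidpop.synthetic import StrainGenotypeSpec, simulate_marker_genomes

from conftest import orthologs_by_gene


def _marker_hits(genome, n_passing, n_failing):
    hits = []
    for i in range(n_passing):
        hits.append(HomologyHit(f"m{i}", f"{genome}_g{i}", 95.0, 95, 100, 1e-40, 300.0))
    for i in range(n_failing):
        hits.append(HomologyHit(f"m{n_passing + i}", f"{genome}_h{i}", 50.0, 95, 100, 1e-5, 60.0))
    return hits


class TestAcceptMarkerGenomes:
    def test_80_of_100_boundary_inclusive(self):
        hbg = {"gA": _marker_hits("gA", 80, 20), "gB": _marker_hits("gB", 79, 21)}
        assert accept_marker_genomes(hbg, 100) == {"gA"}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        hbg = {}
        for g in range(20):
            n_pass = int(rng.integers(0, 11))
            hbg[f"g{g}"] = _marker_hits(f"g{g}", n_pass, 10 - n_pass)
        got = accept_marker_genomes(hbg, 10)
        expected = {
            g
            for g, hits in hbg.items()
            if sum(h.pct_identity >= 90 and h.aln_length / h.query_length >= 0.9 for h in hits)
            >= 8
        }
        assert got == expected


class TestCallVariants:
    def test_identical_sequences_have_no_snps(self):
        orths = {"g": [MarkerOrtholog("a", "g", "ACGTACGT"), MarkerOrtholog("b", "g", "ACGTACGT")]}
        var = call_genome_variants(orths)
        assert var == {"a": set(), "b": set()}

    def test_single_substitution_located(self):
        orths = {
            "g": [
                MarkerOrtholog("a", "g", "ACGTACGT"),
                MarkerOrtholog("b", "g", "ACGTACGT"),
                MarkerOrtholog("c", "g", "ACGTACTT"),  # column 7 G->T
            ]
        }
        var = call_genome_variants(orths)
        assert var["c"] == {("g", 7, "G", "T")} and var["a"] == set()

    def test_gap_carries_no_call_and_gappy_columns_drop(self):
        orths = {
            "g": [
                MarkerOrtholog("a", "g", "A-GT"),
                MarkerOrtholog("b", "g", "A-GT"),
                MarkerOrtholog("c", "g", "ACGA"),
            ]
        }
        var = call_genome_variants(orths)
        # column 2 is 2/3 gaps -> excluded; ungapped consensus positions are 1,2,3
        assert var["c"] == {("g", 3, "T", "A")}
        assert var["a"] == set()

    def test_consensus_tie_breaks_to_smallest_base(self):
        orths = {
            "g": [MarkerOrtholog("a", "g", "T"), MarkerOrtholog("b", "g", "C")]
        }
        var = call_genome_variants(orths)
        assert var == {"a": {("g", 1, "C", "T")}, "b": set()}

    def test_explicit_reference_overrides_consensus(self):
        orths = {
            "g": [MarkerOrtholog("a", "g", "T"), MarkerOrtholog("b", "g", "T")]
        }
        var = call_genome_variants(orths, reference={"g": "C"})
        assert var == {"a": {("g", 1, "C", "T")}, "b": {("g", 1, "C", "T")}}

    def test_zero_length_alignment_rejected(self):
        orths = {"g": [MarkerOrtholog("a", "g", ""), MarkerOrtholog("b", "g", "")]}
        with pytest.raises(ValidationError):
            call_genome_variants(orths)

    def test_zero_noise_synthetic_calls_equal_planted(self, two_strain_isolates):
        iso = two_strain_isolates
        var = call_genome_variants(orthologs_by_gene(iso), reference=iso.ref_genes)
        for gid, strain in iso.strain_labels.items():
            assert var[gid] == iso.diagnostic_snps[strain]


class TestAssignStrains:
    TREE = "((a,b),(c,d));"

    def _tree(self):
        return dendropy.Tree.get(data=self.TREE, schema="newick")

    def test_single_anchor_is_its_own_smallest_clade(self):
        got = assign_strains_from_tree(self._tree(), {"S1": ["a"], "S2": ["c"]})
        assert got == {"a": "S1", "c": "S2"}  # b and d stay unassigned

    def test_two_anchors_pull_in_their_clade(self):
        got = assign_strains_from_tree(self._tree(), {"S1": ["a", "b"]})
        assert got == {"a": "S1", "b": "S1"}

    def test_overlapping_clades_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            assign_strains_from_tree(self._tree(), {"S1": ["a", "c"], "S2": ["b"]})

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValidationError, match="missing|not in tree"):
            assign_strains_from_tree(self._tree(), {"S1": ["z"]})


class TestIdentifyMarkers:
    def _variants(self, spec):
        """spec: {genome: carries_snp} over one SNP."""
        snp = ("g", 5, "A", "G")
        return {g: ({snp} if c else set()) for g, c in spec.items()}, snp

    def test_full_presence_and_absence_elsewhere_is_marker(self):
        genomes = {f"s1_{i}": True for i in range(10)} | {f"s2_{i}": False for i in range(8)}
        var, snp = self._variants(genomes)
        smap = {g: ("S1" if g.startswith("s1") else "S2") for g in genomes}
        sets = {m.strain_label: set(m.snps) for m in identify_strain_markers(var, smap)}
        assert sets == {"S1": {snp}, "S2": set()}

    def test_eight_of_ten_misses_presence_threshold(self):
        genomes = {f"s1_{i}": i < 8 for i in range(10)} | {f"s2_{i}": False for i in range(8)}
        var, snp = self._variants(genomes)
        smap = {g: ("S1" if g.startswith("s1") else "S2") for g in genomes}
        sets = {m.strain_label: set(m.snps) for m in identify_strain_markers(var, smap)}
        assert sets == {"S1": set(), "S2": set()}

    def test_exclusivity_condition_can_be_disabled(self):
        # a SNP fixed in both strains is a marker for both only without exclusivity
        genomes = {f"s1_{i}": True for i in range(5)} | {f"s2_{i}": True for i in range(5)}
        var, snp = self._variants(genomes)
        smap = {g: ("S1" if g.startswith("s1") else "S2") for g in genomes}
        strict = identify_strain_markers(var, smap)
        assert all(not m.snps for m in strict)
        loose = identify_strain_markers(var, smap, max_presence_elsewhere=1.0)
        assert all(set(m.snps) == {snp} for m in loose)

    def test_empty_strain_rejected(self):
        var, _ = self._variants({"a": True})
        with pytest.raises(ValidationError):
            identify_strain_markers(var, {"a": "S1", "ghost": "S2"})

    def test_zero_noise_fixture_recovers_planted_sets_exactly(self, two_strain_isolates):
        iso = two_strain_isolates
        var = call_genome_variants(orthologs_by_gene(iso), reference=iso.ref_genes)
        sets = {m.strain_label: set(m.snps) for m in identify_strain_markers(var, iso.strain_labels)}
        assert sets == {s: set(v) for s, v in iso.diagnostic_snps.items()}

    def test_marker_sets_disjoint_and_order_invariant(self):
        spec = StrainGenotypeSpec(
            n_marker_genes=2, gene_length=300, n_diagnostic_snps=5,
            within_strain_noise_rate=0.05, seed=11,
        )
        iso = simulate_marker_genomes(spec, {"S1": 12, "S2": 12})
        var = call_genome_variants(orthologs_by_gene(iso), reference=iso.ref_genes)
        sets = identify_strain_markers(var, iso.strain_labels)
        s1, s2 = (set(m.snps) for m in sets)
        assert not s1 & s2  # exclusivity threshold < presence threshold
        # permuting genome order changes nothing
        var_rev = dict(reversed(list(var.items())))
        sets_rev = identify_strain_markers(var_rev, iso.strain_labels)
        assert [set(m.snps) for m in sets_rev] == [s1, s2]
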