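import numpy as np
import pytest

from raidpop.marker_snps import MarkerOrtholog
from raidpop.synthetic import (
    CommunitySpec,
    StrainGenotypeSpec,
    genotype_matrix_from_diagnostics,
    simulate_community,
    simulate_marker_genomes,
    simulate_pileup,
)


@pytest.fixture(scope="session")
def two_strain_isolates():
    """Zero-noise two-strain isolate panel (10 + 10) with planted diagnostics."""
    spec = StrainGenotypeSpec(
        n_marker_genes=4, gene_length=900, n_diagnostic_snps=20,
        within_strain_noise_rate=0.0, seed=42,
    )
    return simulate_marker_genomes(spec, {"S1": 10, "S2": 10})


@pytest.fixture(scope="session")
def bloom_community():
    """Two-strain mixture over 30 timepoints with a mid-series bloom, plus
    the deep pileup counts simulated from it."""
    iso_spec = StrainGenotypeSpec(
        n_marker_genes=4, gene_length=900, n_diagnostic_snps=20, seed=7,
    )
    iso = simulate_marker_genomes(iso_spec, {"S1": 10, "S2": 10})
    days = np.linspace(0.0, 540.0, 30)
    cspec = CommunitySpec(
        sampling_days=list(days),
        trajectories=[
            ("constant", {"level": 1.0}),
            ("logistic_bloom", {"baseline": 1e-3, "bloom_day": 270.0, "growth_rate": 0.05}),
        ],
        seed=7,
    )
    props = simulate_community(cspec)
    G, sites = genotype_matrix_from_diagnostics(iso.diagnostic_snps, ["S1", "S2"])
    acm = simulate_pileup(
        G, sites, props, depth_mean=1000.0, error_rate=0.005, seed=7, collection_days=days,
    )
    return {"iso": iso, "days": days, "props": props, "G": G, "sites": sites, "acm": acm}


def orthologs_by_gene(iso):
    """Arrange a SimulatedIsolates bundle as call_genome_variants input."""
    return {
        g: [
            MarkerOrtholog(gid, g, seqs[g])
            for gid, seqs in sorted(iso.orthologs.items())
        ]
        for g in sorted(iso.ref_genes)
    }
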