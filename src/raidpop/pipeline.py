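"""Reproducible end-to-end runs over the bundled synthetic study.

A run takes a single ``RunConfig`` (every threshold used anywhere in the
pipeline lives here, so the analysis parameters are auditable in one
place) and a single seed.  Per-stage random substreams are derived from
the run seed via ``numpy.random.SeedSequence(seed).spawn``: stage i uses
child i, so stages are independent yet the whole run is a pure function of
(config, inputs).  Rerunning with the same config reproduces byte-identical
TSV outputs; a manifest records the config hash, seed, and per-stage row
counts and file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formats, genome_screen, marker_snps, metagenome_quant, selection, strain_dynamics
from . import synthetic
from .formats import ValidationError

logger = logging.getLogger(__name__)

_STAGES = ["simulate", "screen", "markers", "variants", "trajectories", "dnds", "trends", "strains"]


@dataclass
class RunConfig:
    """All pipeline thresholds, synthetic-study sizes, and the run seed."""

    seed: int = 0
    # homology filtering
    min_identity: float = 90.0
    min_coverage: float = 0.90
    # rAID rule
    gc_max: float = 0.41
    min_members: int = 2
    # marker-genome / strain-marker rules
    min_marker_fraction: float = 0.80
    min_presence: float = 0.90
    max_presence_elsewhere: float = 0.10
    # metagenomic variant filters
    end_trim: int = 10
    min_site_coverage: int = 5
    min_minor: int = 2
    min_sample_fraction: float = 0.10
    # selection scan
    window: int = 200
    step: int = 25
    pseudo: float = 1.0
    flag_threshold: float = 3.0
    # strain reconstruction / K-selection
    recon_low: float = 0.25
    recon_high: float = 0.75
    r_min: float = 0.3
    # synthetic study sizes
    n_marker_genes: int = 4
    gene_length: int = 900
    n_diagnostic_snps: int = 20
    n_isolates_per_strain: int = 10
    within_strain_noise_rate: float = 0.0
    n_timepoints: int = 30
    final_day: float = 540.0
    bloom_day: float = 270.0
    depth_mean: float = 1000.0
    error_rate: float = 0.005
    n_raid_systems: int = 3
    n_raid_decoys: int = 3

    def validate(self) -> None:
        checks = [
            (0 <= self.min_identity <= 100, "min_identity must be in [0, 100]"),
            (0 < self.min_coverage <= 1, "min_coverage must be in (0, 1]"),
            (0 < self.gc_max <= 1, "gc_max must be in (0, 1]"),
            (self.min_members >= 1, "min_members must be >= 1"),
            (0 < self.min_marker_fraction <= 1, "min_marker_fraction must be in (0, 1]"),
            (0 < self.min_presence <= 1, "min_presence must be in (0, 1]"),
            (0 <= self.max_presence_elsewhere <= 1, "max_presence_elsewhere must be in [0, 1]"),
            (self.end_trim >= 0, "end_trim must be >= 0"),
            (self.min_site_coverage >= 0, "min_site_coverage must be >= 0"),
            (self.min_minor >= 0, "min_minor must be >= 0"),
            (0 <= self.min_sample_fraction <= 1, "min_sample_fraction must be in [0, 1]"),
            (self.window >= 1 and self.step >= 1, "window and step must be >= 1"),
            (self.pseudo > 0, "pseudo must be > 0"),
            (self.flag_threshold > 0, "flag_threshold must be > 0"),
            (0 <= self.recon_low < self.recon_high <= 1, "need 0 <= recon_low < recon_high <= 1"),
            (0 <= self.error_rate < 0.75, "error_rate must be in [0, 0.75)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed).spawn(len(_STAGES))[_STAGES.index(stage)]


def _child_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on a freshly simulated study; return the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in files.items()},
            "row_counts": counts,
        }
        logger.info("stage %s done: %s", stage, counts)

    # ---- simulate -------------------------------------------------------
    sim_ss = _stage_seed(config.seed, "simulate")
    gspec = synthetic.StrainGenotypeSpec(
        n_marker_genes=config.n_marker_genes,
        gene_length=config.gene_length,
        n_diagnostic_snps=config.n_diagnostic_snps,
        within_strain_noise_rate=config.within_strain_noise_rate,
        seed=_child_int(sim_ss),
    )
    iso = synthetic.simulate_marker_genomes(
        gspec, {"S1": config.n_isolates_per_strain, "S2": config.n_isolates_per_strain}
    )
    days = np.linspace(0.0, config.final_day, config.n_timepoints)
    cspec = synthetic.CommunitySpec(
        sampling_days=list(days),
        trajectories=[
            ("constant", {"level": 1.0}),
            ("logistic_bloom", {"baseline": 1e-3, "bloom_day": config.bloom_day, "growth_rate": 0.05}),
        ],
        seed=_child_int(sim_ss),
    )
    true_props = synthetic.simulate_community(cspec)
    G, site_meta = synthetic.genotype_matrix_from_diagnostics(iso.diagnostic_snps, ["S1", "S2"])
    acm = synthetic.simulate_pileup(
        G, site_meta, true_props, config.depth_mean, config.error_rate,
        seed=_child_int(sim_ss), collection_days=days,
    )
    cds, planted, cluster = synthetic.simulate_selection_gene(seed=_child_int(sim_ss))
    fasta, raid_genes, rec_hits, raid_truth = synthetic.simulate_raid_genomes(
        config.n_raid_systems, config.n_raid_decoys, seed=_child_int(sim_ss)
    )

    f_counts = outdir / "allele_counts.tsv"
    formats.write_allele_counts(acm, f_counts)
    f_fasta = outdir / "raid_genome.fasta"
    formats.write_fasta(fasta, f_fasta)
    f_genes = outdir / "raid_genes.tsv"
    formats.write_gene_table(raid_genes, f_genes)
    record(
        "simulate",
        {"allele_counts": f_counts, "raid_fasta": f_fasta, "raid_genes": f_genes},
        {"sites": len(acm.sites), "samples": len(acm.samples), "raid_genes": len(raid_genes)},
    )

    # ---- screen ---------------------------------------------------------
    systems = genome_screen.detect_raid_systems(
        raid_genes, fasta,
        genome_screen.filter_homology_hits(rec_hits, config.min_identity, config.min_coverage),
        gc_max=config.gc_max, min_members=config.min_members, genome_id="synthetic",
    )
    f_sys = outdir / "raid_systems.tsv"
    pd.DataFrame(
        [
            {
                "recombinase": s.recombinase.locus_tag,
                "n_members": len(s.member_genes),
                "members": ",".join(s.member_locus_tags),
                "member_gc": ",".join(f"{g:.4f}" for g in s.member_gc),
            }
            for s in systems
        ]
    ).to_csv(f_sys, sep="\t", index=False)
    record("screen", {"systems": f_sys}, {"systems": len(systems)})

    # ---- markers --------------------------------------------------------
    orth_by_gene = {
        g: [
            marker_snps.MarkerOrtholog(gid, g, seqs[g])
            for gid, seqs in sorted(iso.orthologs.items())
        ]
        for g in sorted(iso.ref_genes)
    }
    variants = marker_snps.call_genome_variants(orth_by_gene, reference=iso.ref_genes)
    marker_sets = marker_snps.identify_strain_markers(
        variants, iso.strain_labels, config.min_presence, config.max_presence_elsewhere
    )
    f_markers = outdir / "strain_markers.tsv"
    pd.DataFrame(
        [
            {"strain": ms.strain_label, "gene": g, "pos": p, "ref": r, "alt": a,
             "frac_in": fi, "frac_out": fo}
            for ms in marker_sets
            for (g, p, r, a), fi, fo in zip(
                ms.snps, ms.presence_fraction_in_strain, ms.presence_fraction_elsewhere
            )
        ]
    ).to_csv(f_markers, sep="\t", index=False, float_format="%.6g")
    record("markers", {"markers": f_markers}, {"markers": sum(len(m.snps) for m in marker_sets)})

    # ---- variants -------------------------------------------------------
    sites = metagenome_quant.detect_metagenome_variants(
        acm, config.min_site_coverage, config.min_minor, config.min_sample_fraction
    )
    f_var = outdir / "metagenome_variants.tsv"
    pd.DataFrame(
        [
            {"gene": s.gene_id, "pos": s.position, "ref": s.ref_base, "alt": s.alt_base,
             "n_covered": int(np.sum(~np.isnan(s.alt_freq))),
             "mean_alt_freq": float(np.nanmean(s.alt_freq))}
            for s in sites
        ]
    ).to_csv(f_var, sep="\t", index=False, float_format="%.6g")
    record("variants", {"variants": f_var}, {"variant_sites": len(sites)})

    # ---- trajectories ---------------------------------------------------
    traj_rows = []
    trajectories: dict[str, np.ndarray] = {}
    for ms in marker_sets:
        traj, n_contrib = metagenome_quant.strain_marker_trajectory(ms, sites)
        trajectories[ms.strain_label] = traj
        for j, sample in enumerate(acm.samples):
            traj_rows.append(
                {"strain": ms.strain_label, "sample": sample, "day": days[j],
                 "abundance": traj[j], "n_markers": int(n_contrib[j])}
            )
    f_traj = outdir / "strain_trajectories.tsv"
    pd.DataFrame(traj_rows).to_csv(f_traj, sep="\t", index=False, float_format="%.6g")
    record("trajectories", {"trajectories": f_traj}, {"rows": len(traj_rows)})

    # ---- dnds -----------------------------------------------------------
    classified = [
        selection.classify_snp_effect(cds, s.position, s.alt_base, gene_id="orf_sel")
        for s in planted
    ]
    windows = selection.sliding_window_dnds(
        classified, len(cds), config.window, config.step, config.pseudo, config.flag_threshold
    )
    f_dnds = outdir / "dnds_windows.tsv"
    pd.DataFrame(
        [
            {"gene": w.gene_id, "start": w.window_start, "end": w.window_end,
             "n_nonsyn": w.n_nonsyn, "n_syn": w.n_syn, "ratio": w.ratio, "flagged": w.flagged}
            for w in windows
        ]
    ).to_csv(f_dnds, sep="\t", index=False, float_format="%.6g")
    record("dnds", {"windows": f_dnds},
           {"windows": len(windows), "flagged": sum(w.flagged for w in windows)})

    # ---- trends ---------------------------------------------------------
    trends = [
        selection.temporal_trend(days, traj, target_id=strain)
        for strain, traj in sorted(trajectories.items())
    ]
    selection.adjust_trends(trends)
    f_trends = outdir / "trends.tsv"
    pd.DataFrame(
        [
            {"target": t.target_id, "slope": t.slope, "p": t.p_value,
             "adjusted_p": t.adjusted_p, "n": t.n_samples}
            for t in trends
        ]
    ).to_csv(f_trends, sep="\t", index=False, float_format="%.6g")
    record("trends", {"trends": f_trends}, {"targets": len(trends)})

    # ---- strains --------------------------------------------------------
    strains_ss = _stage_seed(config.seed, "strains")
    facs = build_factorization_family(
        G, true_props, ks=(1, 2, 3, 4), seed=_child_int(strains_ss)
    )
    targets = {
        "cognate_gene": true_props[0] + 0.01 * np.sin(days / 30.0),
        "orphan_gene": true_props[1] + 0.01 * np.cos(days / 30.0),
    }
    rep_t = strain_dynamics.select_K_by_target_correlation(facs, targets, config.r_min)
    rep_n = strain_dynamics.select_K_by_non_redundancy(facs, targets)
    f_sel = outdir / "strain_selection.tsv"
    pd.DataFrame(
        [
            {"K": k,
             "max_pairwise_corr": rep_n.max_pairwise_corr[k],
             **{f"r_{t}": rep_t.target_corr[k][t] for t in sorted(targets)},
             "chosen_by_target_corr": k == rep_t.chosen_K,
             "chosen_by_non_redundancy": k == rep_n.chosen_K}
            for k in rep_t.candidate_Ks
        ]
    ).to_csv(f_sel, sep="\t", index=False, float_format="%.6g")
    record("strains", {"selection": f_sel},
           {"chosen_K_target": rep_t.chosen_K or -1, "chosen_K_nonred": rep_n.chosen_K or -1})

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def build_factorization_family(
    genotypes: np.ndarray,
    true_props: np.ndarray,
    ks=(1, 2, 3, 4),
    seed: int = 0,
    split_jitter: float = 0.05,
) -> dict[int, formats.StrainFactorization]:
    """Candidate factorizations around a true K*-strain mixture.

    K below the truth merges strains (abundance summed, genotypes averaged);
    K above the truth splits the first strain into correlated halves whose
    split fraction jitters by ``split_jitter`` per sample — the redundant-
    strain pattern the non-redundancy criterion is designed to reject.
    """
    rng = np.random.default_rng(seed)
    k_true = true_props.shape[0]
    out: dict[int, formats.StrainFactorization] = {}
    for k in ks:
        if k <= k_true:
            # merge the last strains together until k rows remain
            props = np.vstack([true_props[: k - 1], true_props[k - 1 :].sum(axis=0)]) if k > 1 else true_props.sum(axis=0, keepdims=True)
            geno = np.vstack([genotypes[: k - 1], genotypes[k - 1 :].max(axis=0, keepdims=True)]) if k > 1 else genotypes.max(axis=0, keepdims=True)
        else:
            props = true_props.copy()
            geno = genotypes.copy()
            while props.shape[0] < k:
                u = np.clip(0.5 + rng.uniform(-split_jitter, split_jitter, size=props.shape[1]), 0.0, 1.0)
                first = props[0]
                props = np.vstack([first * u, first * (1 - u), props[1:]])
                geno = np.vstack([geno[0], geno[0], geno[1:]])
        out[k] = formats.StrainFactorization(genotype_prob=geno, strain_abundance=props)
    return out
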