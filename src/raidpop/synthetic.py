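"""Ground-truthed synthetic data: genomes, communities, pileup counts, SNPs.

Every generator is a pure function of (spec, seed): identical seeds give
byte-identical outputs, and ground-truth objects are emitted alongside the
data so every downstream stage has a recovery target.  The generators
emulate, at desk scale, the structures the analysis assumes:

* two-strain communities with planted strain-diagnostic SNPs and
  time-varying mixture proportions (including a late logistic "bloom");
* multinomial per-site nucleotide counts at configurable Poisson depth and
  uniform substitution error (no indels — the SNP analysis is
  substitution-only);
* coding genes with a planted cluster of non-synonymous SNPs plus
  background synonymous SNPs, every effect class re-verified by codon
  translation before emission;
* genomes carrying rAID-like gene clusters (recombinase + co-oriented
  low-GC array) and decoys that each violate exactly one detection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import BASES, AlleleCountMatrix, GeneModel, HomologyHit, StrainFactorization, ValidationError
from .marker_snps import Snp
from .selection import classify_snp_effect

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class StrainGenotypeSpec:
    """Marker-gene catalog and planted strain-diagnostic SNPs."""

    n_marker_genes: int = 5
    gene_length: int = 900  # nt, multiple of 3
    n_diagnostic_snps: int = 20  # per strain
    within_strain_noise_rate: float = 0.0
    n_strains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_length % 3 != 0:
            raise ValidationError("gene_length must be a multiple of 3")
        if not 0.0 <= self.within_strain_noise_rate < 0.5:
            raise ValidationError("within_strain_noise_rate must be in [0, 0.5)")
        avail = self.n_marker_genes * self.gene_length
        if self.n_strains * self.n_diagnostic_snps > avail:
            raise ValidationError(
                f"{self.n_strains * self.n_diagnostic_snps} diagnostic SNPs exceed "
                f"{avail} available positions"
            )


@dataclass
class CommunitySpec:
    """Strain trajectory shapes over longitudinal sampling days.

    ``trajectories`` holds one (kind, params) per strain; kinds are
    ``constant`` (level), ``oscillating`` (base, amplitude, period) and
    ``logistic_bloom`` (baseline, bloom_day, growth_rate).  Per-sample true
    proportions are the normalized trajectory weights.
    """

    sampling_days: list[float] = field(default_factory=lambda: list(np.linspace(0, 540, 30)))
    trajectories: list[tuple[str, dict]] = field(
        default_factory=lambda: [
            ("constant", {"level": 1.0}),
            ("logistic_bloom", {"baseline": 1e-3, "bloom_day": 270.0, "growth_rate": 0.05}),
        ]
    )
    noise_sd: float = 0.0  # lognormal sd on weights; 0 keeps curves deterministic
    seed: int = 0

    @property
    def n_strains(self) -> int:
        return len(self.trajectories)

    def __post_init__(self) -> None:
        days = np.asarray(self.sampling_days, dtype=float)
        if len(days) < 2 or not (np.diff(days) > 0).all():
            raise ValidationError("sampling_days must be strictly increasing")


# ---------------------------------------------------------------------------
# Marker genomes with diagnostic SNPs
# ---------------------------------------------------------------------------


@dataclass
class SimulatedIsolates:
    """Output bundle of :func:`simulate_marker_genomes`."""

    ref_genes: dict[str, str]  # gene_id -> reference sequence
    orthologs: dict[str, dict[str, str]]  # genome_id -> gene_id -> sequence
    strain_labels: dict[str, str]  # genome_id -> strain label
    diagnostic_snps: dict[str, set[Snp]]  # strain label -> planted SNP set


def _random_cds(rng: np.random.Generator, length: int) -> str:
    codons = rng.choice(_SENSE_CODONS, size=length // 3)
    return "".join(codons)


def simulate_marker_genomes(
    spec: StrainGenotypeSpec, n_isolates_per_strain: dict[str, int] | None = None
) -> SimulatedIsolates:
    """Simulate isolate genomes of K strains over a marker-gene catalog.

    Each strain S gets ``n_diagnostic_snps`` planted diagnostic SNPs at
    globally unique positions.  An isolate of S carries each SNP of S
    independently with probability 1 - within_strain_noise_rate, and each
    other strain's SNP with probability within_strain_noise_rate.
    """
    rng = np.random.default_rng(spec.seed)
    strains = (
        sorted(n_isolates_per_strain)
        if n_isolates_per_strain
        else [f"S{k + 1}" for k in range(spec.n_strains)]
    )
    if n_isolates_per_strain is None:
        n_isolates_per_strain = {s: 5 for s in strains}

    genes = {f"marker_{i:03d}": _random_cds(rng, spec.gene_length) for i in range(spec.n_marker_genes)}
    gene_ids = sorted(genes)

    # globally unique (gene, pos) pairs so marker sets are disjoint by design
    all_positions = [(g, p) for g in gene_ids for p in range(1, spec.gene_length + 1)]
    n_total = len(strains) * spec.n_diagnostic_snps
    chosen = rng.choice(len(all_positions), size=n_total, replace=False)
    diagnostic: dict[str, set[Snp]] = {}
    snp_list: list[tuple[str, Snp]] = []  # (strain, snp)
    for k, s in enumerate(strains):
        snps = set()
        for idx in chosen[k * spec.n_diagnostic_snps : (k + 1) * spec.n_diagnostic_snps]:
            gene, pos = all_positions[idx]
            ref = genes[gene][pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            snp = (gene, pos, ref, alt)
            snps.add(snp)
            snp_list.append((s, snp))
        diagnostic[s] = snps

    orthologs: dict[str, dict[str, str]] = {}
    labels: dict[str, str] = {}
    eps = spec.within_strain_noise_rate
    for s in strains:
        for i in range(n_isolates_per_strain[s]):
            gid = f"{s}_iso{i + 1:02d}"
            labels[gid] = s
            seqs = {g: list(genes[g]) for g in gene_ids}
            for owner, (gene, pos, _ref, alt) in snp_list:
                p_carry = 1.0 - eps if owner == s else eps
                if rng.random() < p_carry:
                    seqs[gene][pos - 1] = alt
            orthologs[gid] = {g: "".join(seqs[g]) for g in gene_ids}
    return SimulatedIsolates(
        ref_genes=genes, orthologs=orthologs, strain_labels=labels, diagnostic_snps=diagnostic
    )


# ---------------------------------------------------------------------------
# Community trajectories
# ---------------------------------------------------------------------------


def _trajectory_weight(kind: str, params: dict, days: np.ndarray) -> np.ndarray:
    if kind == "constant":
        return np.full(len(days), float(params.get("level", 1.0)))
    if kind == "oscillating":
        base = float(params.get("base", 1.0))
        amp = float(params.get("amplitude", 0.3))
        period = float(params.get("period", 180.0))
        if amp >= base:
            raise ValidationError("oscillation amplitude must stay below the base level")
        return base + amp * np.sin(2 * np.pi * days / period)
    if kind == "logistic_bloom":
        baseline = float(params.get("baseline", 1e-3))
        bloom_day = float(params.get("bloom_day", 270.0))
        rate = float(params.get("growth_rate", 0.05))
        # center the rise after bloom_day so the pre-bloom weight stays tiny
        center = bloom_day + np.log(99.0) / rate
        return baseline + 1.0 / (1.0 + np.exp(-rate * (days - center)))
    raise ValidationError(f"unknown trajectory kind {kind!r}")


def simulate_community(spec: CommunitySpec) -> np.ndarray:
    """True strain proportions (K x n_samples), normalized to sum 1 per sample.

    A ``logistic_bloom`` strain stays at low proportion before its
    ``bloom_day`` and rises monotonically afterwards (with noise_sd = 0).
    """
    days = np.asarray(spec.sampling_days, dtype=float)
    weights = np.vstack(
        [_trajectory_weight(kind, params, days) for kind, params in spec.trajectories]
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        weights = weights * rng.lognormal(0.0, spec.noise_sd, size=weights.shape)
    if (weights <= 0).any():
        raise ValidationError("trajectory weights must stay positive")
    return weights / weights.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Pileup counts
# ---------------------------------------------------------------------------


def genotype_matrix_from_diagnostics(
    diagnostic: dict[str, set[Snp]], strains: list[str] | None = None
) -> tuple[np.ndarray, list[Snp]]:
    """Binary K x n_sites genotype matrix over the union of diagnostic SNPs.

    Row k is 1 at the sites strain k carries (its own diagnostics).  Sites
    are sorted by (gene, position).  Returned alongside their
    (gene, pos, ref, alt) metadata.
    """
    strains = strains or sorted(diagnostic)
    sites = sorted(set().union(*diagnostic.values()), key=lambda s: (s[0], s[1]))
    G = np.zeros((len(strains), len(sites)), dtype=float)
    for k, s in enumerate(strains):
        for j, site in enumerate(sites):
            if site in diagnostic[s]:
                G[k, j] = 1.0
    return G, sites


def simulate_pileup(
    genotypes: np.ndarray,
    sites: list[Snp],
    strain_abundance: np.ndarray,
    depth_mean: float,
    error_rate: float,
    seed: int,
    sample_ids: list[str] | None = None,
    collection_days: np.ndarray | None = None,
) -> AlleleCountMatrix:
    """Simulate per-site nucleotide counts for a strain mixture.

    ``genotypes`` is a binary K x n_sites matrix of alternate-allele
    carriage; ``strain_abundance`` is K x n_samples with columns summing to
    1.  Per (site, sample): coverage ~ Poisson(depth_mean), independent
    across sites (no mapping bias), and base counts ~ Multinomial over the
    mixture allele frequency pushed through a uniform per-base substitution
    error (each read shows its true base w.p. 1 - error_rate, each other
    base w.p. error_rate / 3).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    strain_abundance = np.asarray(strain_abundance, dtype=float)
    if not np.isin(genotypes, (0.0, 1.0)).all():
        raise ValidationError("genotypes must be 0/1 truth values")
    if not 0.0 <= error_rate < 0.75:
        raise ValidationError("error_rate must be in [0, 0.75): base distribution degenerate")
    if genotypes.shape != (strain_abundance.shape[0], len(sites)):
        raise ValidationError("genotype/abundance/site dimensions disagree")
    rng = np.random.default_rng(seed)
    n_sites, n_samples = len(sites), strain_abundance.shape[1]
    alt_freq = genotypes.T @ strain_abundance  # (n_sites, n_samples)
    counts = np.zeros((n_sites, n_samples, 4), dtype=np.int64)
    for i, (gene, pos, ref, alt) in enumerate(sites):
        ri, ai = BASES.index(ref), BASES.index(alt)
        for j in range(n_samples):
            f = alt_freq[i, j]
            probs = np.full(4, error_rate / 3.0)
            probs[ai] = f * (1.0 - error_rate) + (1.0 - f) * error_rate / 3.0
            probs[ri] = (1.0 - f) * (1.0 - error_rate) + f * error_rate / 3.0
            cov = rng.poisson(depth_mean)
            counts[i, j] = rng.multinomial(cov, probs)
    samples = sample_ids or [f"s{j + 1:02d}" for j in range(n_samples)]
    return AlleleCountMatrix(
        sites=[(g, p) for g, p, _r, _a in sites],
        samples=samples,
        counts=counts,
        collection_days=collection_days,
    )


# ---------------------------------------------------------------------------
# Selection-scan gene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSnp:
    position: int  # 1-based in CDS
    ref_base: str
    alt_base: str
    effect: str  # verified by translation before emission


def simulate_selection_gene(
    length: int = 900,
    n_cluster_nonsyn: int = 8,
    cluster_span: int = 150,
    n_background_syn: int = 3,
    seed: int = 0,
    cluster_margin: int = 200,
    max_retries: int = 2000,
) -> tuple[str, list[PlantedSnp], tuple[int, int]]:
    """A coding gene with a planted cluster of non-synonymous SNPs.

    Non-synonymous SNPs are placed inside one ``cluster_span``-nt region;
    synonymous background SNPs are placed uniformly outside the cluster
    plus a ``cluster_margin``-nt guard on each side, keeping the planted
    selective contrast clear of the cluster's neighbourhood.  Every planted
    SNP's effect class is re-verified against codon translation before
    emission.  Returns (CDS, planted SNPs, cluster interval 1-based
    inclusive).
    """
    if length % 3 != 0:
        raise ValidationError("length must be a multiple of 3")
    if cluster_span > length:
        raise ValidationError("cluster_span exceeds gene length")
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, length)

    lo = 1 + cluster_margin if length - cluster_span + 1 - cluster_margin >= 1 + cluster_margin else 1
    hi = max(lo, length - cluster_span + 1 - cluster_margin)
    c_start = int(rng.integers(lo, hi + 1))
    c_end = c_start + cluster_span - 1

    outside = [
        p
        for p in range(1, length + 1)
        if p < c_start - cluster_margin or p > c_end + cluster_margin
    ]
    if n_background_syn and len(outside) < n_background_syn:
        raise ValidationError("no room for background synonymous SNPs outside the cluster margin")

    snps: list[PlantedSnp] = []
    used: set[int] = set()

    def plant(candidates: list[int], want_effect: str, n: int) -> None:
        tries = 0
        while n > 0:
            tries += 1
            if tries > max_retries:
                raise ValidationError(
                    f"could not place a {want_effect} SNP after {max_retries} retries"
                )
            pos = int(rng.choice(candidates))
            if pos in used:
                continue
            ref = cds[pos - 1]
            alts = [b for b in BASES if b != ref]
            rng.shuffle(alts)
            placed = False
            for alt in alts:
                eff = classify_snp_effect(cds, pos, alt).effect
                if eff == want_effect:
                    snps.append(PlantedSnp(pos, ref, alt, eff))
                    used.add(pos)
                    placed = True
                    break
            if placed:
                n -= 1

    plant(list(range(c_start, c_end + 1)), "non-synonymous", n_cluster_nonsyn)
    if n_background_syn:
        plant(outside, "synonymous", n_background_syn)
    snps.sort(key=lambda s: s.position)
    return cds, snps, (c_start, c_end)


# ---------------------------------------------------------------------------
# rAID genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaidTruth:
    """Ground truth for one planted unit (true system or decoy)."""

    unit_id: str
    is_system: bool
    violation: str  # "" | "orientation" | "count" | "gc"
    recombinase_locus: str
    member_loci: tuple[str, ...]  # expected members for true systems, () for decoys


def _seq_with_gc(rng: np.random.Generator, length: int, gc: float) -> str:
    """Sequence of given length with an exact (G+C) base count."""
    n_gc = int(round(gc * length))
    bases = np.concatenate(
        [
            rng.choice(["G", "C"], size=n_gc),
            rng.choice(["A", "T"], size=length - n_gc),
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def simulate_raid_genomes(
    n_true_systems: int = 3,
    n_decoys: int = 3,
    gc_low: float = 0.30,
    gc_high: float = 0.55,
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneModel], list[HomologyHit], list[RaidTruth]]:
    """One synthetic contig carrying true rAID systems and single-rule decoys.

    A true unit is a recombinase-labeled gene followed (in its
    transcriptional direction) by 2-4 co-oriented genes whose GC content
    sits near ``gc_low`` (always below 41% by construction).  Each decoy
    violates exactly one condition — ``orientation`` (the second downstream
    gene is inverted), ``count`` (only one qualifying gene) or ``gc``
    (downstream genes at ``gc_high``) — recorded in the truth labels.
    Units are separated by high-GC spacer genes so walks cannot cross unit
    boundaries.  Returns (FASTA dict, gene table, recombinase hits passing
    the homology filter, truth labels).
    """
    if not gc_low < 0.41 < gc_high:
        raise ValidationError("need gc_low < 0.41 < gc_high")
    rng = np.random.default_rng(seed)
    contig = "syncontig_1"
    seq_parts: list[str] = []
    genes: list[GeneModel] = []
    rec_hits: list[HomologyHit] = []
    truths: list[RaidTruth] = []
    cursor = 0
    tag_counter = [0]

    def add_gene(length: int, strand: str, gc: float, product: str) -> GeneModel:
        nonlocal cursor
        gap = int(rng.integers(20, 101))
        seq_parts.append(_seq_with_gc(rng, gap, 0.50))
        cursor += gap
        tag_counter[0] += 1
        tag = f"SYN_{tag_counter[0]:04d}"
        gseq = _seq_with_gc(rng, length, gc)
        g = GeneModel(contig, cursor, cursor + length, strand, tag, product)
        seq_parts.append(gseq)
        cursor += length
        genes.append(g)
        return g

    def add_spacer() -> None:
        add_gene(int(rng.integers(300, 601)), str(rng.choice(["+", "-"])), gc_high, "spacer")

    def member_gc() -> float:
        # near gc_low, clamped strictly below the 41% rule
        return float(min(0.40, max(0.05, gc_low + rng.uniform(-0.03, 0.03))))

    kinds = ["system"] * n_true_systems + ["orientation", "count", "gc"] * (
        n_decoys // 3 + 1
    )
    kinds = kinds[: n_true_systems + n_decoys]
    rng.shuffle(kinds)

    add_spacer()
    for u, kind in enumerate(kinds):
        strand = str(rng.choice(["+", "-"]))
        flip = "-" if strand == "+" else "+"
        unit_id = f"unit_{u + 1:02d}"
        if kind == "system":
            n_members = int(rng.integers(2, 5))
            lengths = [int(rng.integers(300, 601)) for _ in range(n_members)]
            if strand == "+":
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
                members = [add_gene(l, strand, member_gc(), "orphan immunity") for l in lengths]
            else:
                # downstream of a '-' recombinase = lower coordinates: lay the
                # array left of the recombinase, innermost member first
                members = [add_gene(l, strand, member_gc(), "orphan immunity") for l in lengths[::-1]][::-1]
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
            truths.append(RaidTruth(unit_id, True, "", rec.locus_tag, tuple(m.locus_tag for m in members)))
        elif kind == "orientation":
            if strand == "+":
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
                add_gene(int(rng.integers(300, 601)), strand, member_gc(), "orphan immunity")
                add_gene(int(rng.integers(300, 601)), flip, member_gc(), "inverted gene")
            else:
                add_gene(int(rng.integers(300, 601)), flip, member_gc(), "inverted gene")
                add_gene(int(rng.integers(300, 601)), strand, member_gc(), "orphan immunity")
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
            truths.append(RaidTruth(unit_id, False, "orientation", rec.locus_tag, ()))
        elif kind == "count":
            if strand == "+":
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
                add_gene(int(rng.integers(300, 601)), strand, member_gc(), "orphan immunity")
            else:
                add_gene(int(rng.integers(300, 601)), strand, member_gc(), "orphan immunity")
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
            truths.append(RaidTruth(unit_id, False, "count", rec.locus_tag, ()))
        else:  # gc
            n_members = int(rng.integers(2, 4))
            if strand == "+":
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
                for _ in range(n_members):
                    add_gene(int(rng.integers(300, 601)), strand, gc_high, "high-GC gene")
            else:
                for _ in range(n_members):
                    add_gene(int(rng.integers(300, 601)), strand, gc_high, "high-GC gene")
                rec = add_gene(int(rng.integers(900, 1201)), strand, 0.45, "tyrosine recombinase")
            truths.append(RaidTruth(unit_id, False, "gc", rec.locus_tag, ()))
        rec_hits.append(
            HomologyHit(
                query_id="recombinase_ref",
                subject_id=rec.locus_tag,
                pct_identity=95.0,
                aln_length=360,
                query_length=380,
                evalue=1e-120,
                bitscore=700.0,
            )
        )
        add_spacer()
    seq_parts.append(_seq_with_gc(rng, int(rng.integers(50, 150)), 0.50))
    return {contig: "".join(seq_parts)}, genes, rec_hits, truths
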