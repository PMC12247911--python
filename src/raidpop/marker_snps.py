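"""Strain-diagnostic SNP identification from per-genome marker-gene orthologs.

Workflow: isolate genomes contribute one ortholog per species marker gene
(alignment construction is external, e.g. MAFFT); variants are called per
genome against a reference — by default the majority consensus of the
alignment, optionally an explicit marker-gene reference sequence.  Genomes
are assigned to strains from a phylogeny, and a SNP is designated a strain
marker when it is present in >= 90% of that strain's genomes (and, by
default, in <= 10% of all other genomes: "strain-diagnostic" requires
discrimination; set ``max_presence_elsewhere=1.0`` to apply the
presence-only rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy

from .formats import HomologyHit, ValidationError
from .genome_screen import filter_homology_hits

logger = logging.getLogger(__name__)

Snp = tuple[str, int, str, str]  # (gene_id, 1-based position, ref_base, alt_base)


@dataclass(frozen=True)
class MarkerOrtholog:
    """One genome's copy of one marker gene, in a shared alignment frame."""

    genome_id: str
    gene_id: str
    aligned_seq: str


@dataclass
class StrainMarkerSet:
    """The diagnostic SNPs of one strain, with the presence fractions that
    justified each designation."""

    strain_label: str
    snps: list[Snp]
    presence_fraction_in_strain: list[float]
    presence_fraction_elsewhere: list[float]


def accept_marker_genomes(
    hits_by_genome: dict[str, list[HomologyHit]],
    n_markers_total: int,
    min_identity: float = 90.0,
    min_coverage: float = 0.90,
    min_marker_fraction: float = 0.80,
) -> set[str]:
    """Accept a genome iff it carries passing orthologs of at least
    ``min_marker_fraction`` of the species' marker genes.

    A marker counts once per genome however many hits it has; the
    identity/coverage filter is the standard >=90%/90% ortholog criterion.
    """
    if n_markers_total < 1:
        raise ValidationError("n_markers_total must be >= 1")
    accepted = set()
    needed = min_marker_fraction * n_markers_total
    for genome, hits in hits_by_genome.items():
        passing = filter_homology_hits(hits, min_identity, min_coverage)
        n_markers = len({h.query_id for h in passing})
        if n_markers >= needed:
            accepted.add(genome)
    logger.info("accepted %d of %d genomes", len(accepted), len(hits_by_genome))
    return accepted


def _consensus_base(column: list[str]) -> str | None:
    """Majority base of an alignment column; ties break to the
    lexicographically smallest base; None when gaps dominate (> 50%)."""
    n = len(column)
    gaps = sum(1 for b in column if b == "-")
    if gaps * 2 > n:
        return None
    counts: dict[str, int] = {}
    for b in column:
        if b != "-":
            counts[b] = counts.get(b, 0) + 1
    best = max(counts.values())
    return min(b for b, c in counts.items() if c == best)


def call_genome_variants(
    orthologs_by_gene: dict[str, list[MarkerOrtholog]],
    reference: dict[str, str] | None = None,
) -> dict[str, set[Snp]]:
    """Call per-genome SNP sets against a per-gene reference.

    With ``reference=None`` the reference is the majority consensus of each
    gene's alignment (per-column majority across genomes; ties to the
    lexicographically smallest base, logged; columns with > 50% gaps are
    excluded entirely).  Passing explicit (ungapped or alignment-frame)
    reference sequences instead anchors calls to the marker-gene catalog
    sequence, which is stable when strains are balanced.

    A genome's SNP is any included column where its base differs from the
    reference and is not a gap.  Positions are 1-based in ungapped
    reference coordinates.
    """
    variants: dict[str, set[Snp]] = {}
    for gene, orths in orthologs_by_gene.items():
        if len(orths) < 2:
            raise ValidationError(f"gene {gene}: need >= 2 genomes to call variants")
        lengths = {len(o.aligned_seq) for o in orths}
        if len(lengths) != 1:
            raise ValidationError(f"gene {gene}: unequal aligned lengths {sorted(lengths)}")
        (aln_len,) = lengths
        if aln_len == 0:
            raise ValidationError(f"gene {gene}: zero-length alignment")
        for o in orths:
            variants.setdefault(o.genome_id, set())

        ref_seq = None
        if reference is not None:
            if gene not in reference:
                raise ValidationError(f"gene {gene}: no reference sequence provided")
            ref_seq = reference[gene].upper()
            if len(ref_seq) not in (aln_len,):
                raise ValidationError(
                    f"gene {gene}: reference length {len(ref_seq)} != alignment "
                    f"length {aln_len} (provide the reference in alignment frame)"
                )

        ref_pos = 0
        for col in range(aln_len):
            column = [o.aligned_seq[col].upper() for o in orths]
            if ref_seq is not None:
                ref_base = ref_seq[col]
                if ref_base == "-":
                    continue
            else:
                ref_base = _consensus_base(column)
                if ref_base is None:
                    continue  # gap-dominated column excluded
            ref_pos += 1
            for o, base in zip(orths, column):
                if base != "-" and base != ref_base:
                    variants[o.genome_id].add((gene, ref_pos, ref_base, base))
    return variants


def assign_strains_from_tree(
    tree: dendropy.Tree, clade_anchors: dict[str, list[str]]
) -> dict[str, str]:
    """Assign genomes to strains as the smallest clades containing anchors.

    Each strain is defined by the leaves under the MRCA of its anchor
    leaves.  Genomes in no anchored clade are left out of the returned map
    (unassigned).  Overlapping clades or missing anchors are errors.
    """
    tree.is_rooted = True  # MRCA queries treat the seed node as root
    taxa = {l.taxon.label: l for l in tree.leaf_node_iter() if l.taxon is not None}
    assignment: dict[str, str] = {}
    for strain, anchors in clade_anchors.items():
        missing = [a for a in anchors if a not in taxa]
        if missing:
            raise ValidationError(f"strain {strain}: anchors not in tree: {missing}")
        if len(anchors) == 1:
            members = {anchors[0]}
        else:
            mrca = tree.mrca(taxa=[taxa[a].taxon for a in anchors])
            members = {
                l.taxon.label for l in mrca.leaf_iter() if l.taxon is not None
            }
        overlap = {g for g in members if g in assignment and assignment[g] != strain}
        if overlap:
            raise ValidationError(
                f"strain clades overlap at genomes {sorted(overlap)} "
                f"({strain} vs {assignment[sorted(overlap)[0]]})"
            )
        for g in members:
            assignment[g] = strain
    return assignment


def identify_strain_markers(
    variants: dict[str, set[Snp]],
    strain_map: dict[str, str],
    min_presence: float = 0.90,
    max_presence_elsewhere: float = 0.10,
) -> list[StrainMarkerSet]:
    """Designate strain-diagnostic SNPs.

    A SNP is a marker for strain S iff the fraction of S genomes carrying
    it is >= ``min_presence`` AND the fraction of all other genomes
    (including unassigned ones) carrying it is <= ``max_presence_elsewhere``.
    Both fractions are recorded per retained SNP.  Set
    ``max_presence_elsewhere=1.0`` to disable the exclusivity condition and
    recover the presence-only >=90% rule.
    """
    strains = sorted(set(strain_map.values()))
    genomes = sorted(variants)
    members = {s: [g for g in genomes if strain_map.get(g) == s] for s in strains}
    empty = [s for s in strains if not members[s]]
    if empty:
        raise ValidationError(f"strains with no genomes in variant table: {empty}")

    universe = sorted(set().union(*variants.values()) if variants else set())
    out: list[StrainMarkerSet] = []
    for s in strains:
        ins, outs = members[s], [g for g in genomes if strain_map.get(g) != s]
        snps, f_in, f_out = [], [], []
        for snp in universe:
            fi = sum(snp in variants[g] for g in ins) / len(ins)
            fo = sum(snp in variants[g] for g in outs) / len(outs) if outs else 0.0
            if fi >= min_presence and fo <= max_presence_elsewhere:
                snps.append(snp)
                f_in.append(fi)
                f_out.append(fo)
        out.append(
            StrainMarkerSet(
                strain_label=s,
                snps=snps,
                presence_fraction_in_strain=f_in,
                presence_fraction_elsewhere=f_out,
            )
        )
        logger.info("strain %s: %d marker SNPs", s, len(snps))
    return out
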