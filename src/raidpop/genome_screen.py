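"""Detection of effector/immunity homologs and rAID systems in annotated genomes.

A rAID (recombinase-associated acquired interbacterial defense) system is
called when a tyrosine-recombinase homolog lies upstream of an array of at
least ``min_members`` consecutive, co-directionally oriented genes whose GC
content is below ``gc_max`` (default 41%).  Homology hits are pre-filtered
to >= 90% identity over >= 90% of the query length.  The homology search
itself (BLAST) is external; this module consumes its tabular output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from .formats import GeneModel, HomologyHit, ValidationError

logger = logging.getLogger(__name__)


def filter_homology_hits(
    hits: list[HomologyHit],
    min_identity: float = 90.0,
    min_coverage: float = 0.90,
) -> list[HomologyHit]:
    """Keep hits with identity >= ``min_identity`` (percent) and
    alignment-length/query-length >= ``min_coverage``.  Both boundaries are
    inclusive."""
    kept = []
    for h in hits:
        if h.query_length <= 0:
            raise ValidationError(f"query_length must be positive for {h.query_id}")
        if h.pct_identity >= min_identity and h.query_coverage >= min_coverage:
            kept.append(h)
    logger.info("homology filter: kept %d of %d hits", len(kept), len(hits))
    return kept


def gc_fraction(seq: str) -> float:
    """(G + C) / (A + C + G + T); N bases are excluded from the denominator."""
    if not seq:
        raise ValidationError("empty sequence has no GC content")
    acgt = sum(seq.upper().count(b) for b in "ACGT")
    if acgt == 0:
        raise ValidationError("sequence contains no unambiguous bases")
    return _bio_gc_fraction(seq, ambiguous="remove")


def extract_effector_ctd(cds: str, ctd_nt: int = 399) -> str:
    """Return the final ``ctd_nt`` bases of a coding sequence.

    Effector genes share long N-terminal homology (Rhs regions), so only the
    C-terminal domain is informative for homology searches.
    """
    if len(cds) < ctd_nt:
        raise ValidationError(
            f"CDS length {len(cds)} shorter than requested CTD {ctd_nt} nt"
        )
    return cds[len(cds) - ctd_nt :]


@dataclass
class RaidSystem:
    """A detected rAID gene cluster on one genome."""

    genome_id: str
    recombinase: GeneModel
    member_genes: list[GeneModel]
    member_gc: list[float]
    orphan_immunity_hits: list[tuple[GeneModel, HomologyHit]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.member_genes) < 2:
            raise ValidationError("a rAID system needs at least two member genes")
        strands = {g.strand for g in self.member_genes}
        if len(strands) != 1:
            raise ValidationError("member genes must be co-oriented")

    @property
    def member_locus_tags(self) -> list[str]:
        return [g.locus_tag for g in self.member_genes]


def detect_raid_systems(
    genes: list[GeneModel],
    genome_seq: dict[str, str],
    recombinase_hits: list[HomologyHit],
    gc_max: float = 0.41,
    min_members: int = 2,
    require_recombinase_strand: bool = False,
    genome_id: str = "",
) -> list[RaidSystem]:
    """Detect rAID systems downstream of recombinase homologs.

    For each recombinase gene (resolved from ``recombinase_hits`` subject
    ids, which must already have passed :func:`filter_homology_hits`), walk
    gene-by-gene downstream in the recombinase's transcriptional direction,
    collecting consecutive genes that share one strand and have
    ``gc_fraction < gc_max`` (strict).  The walk stops at the first gene
    violating either condition, or at the contig end.  A system is emitted
    iff at least ``min_members`` genes were collected.

    By default the array members must be co-oriented with each other but not
    necessarily with the recombinase; ``require_recombinase_strand=True``
    additionally anchors the array to the recombinase strand.  Intergenic
    distance is unconstrained.
    """
    by_tag = {g.locus_tag: g for g in genes}
    rec_tags: list[str] = []
    missing = []
    for h in recombinase_hits:
        if h.subject_id not in by_tag:
            missing.append(h.subject_id)
        elif h.subject_id not in rec_tags:
            rec_tags.append(h.subject_id)
    if missing:
        raise ValidationError(
            "recombinase loci absent from gene table: " + ", ".join(sorted(set(missing)))
        )

    by_contig: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.locus_tag)):
        by_contig.setdefault(g.contig_id, []).append(g)

    systems: list[RaidSystem] = []
    for tag in sorted(rec_tags, key=lambda t: (by_tag[t].contig_id, by_tag[t].start)):
        rec = by_tag[tag]
        neighbours = by_contig[rec.contig_id]
        idx = neighbours.index(rec)
        step = 1 if rec.strand == "+" else -1
        members: list[GeneModel] = []
        gcs: list[float] = []
        array_strand = rec.strand if require_recombinase_strand else None
        i = idx + step
        while 0 <= i < len(neighbours):
            g = neighbours[i]
            if array_strand is None:
                array_strand = g.strand
            if g.strand != array_strand:
                break
            gc = gc_fraction(g.sequence(genome_seq[g.contig_id]))
            if gc >= gc_max:
                break
            members.append(g)
            gcs.append(gc)
            i += step
        if len(members) >= min_members:
            systems.append(
                RaidSystem(
                    genome_id=genome_id,
                    recombinase=rec,
                    member_genes=members,
                    member_gc=gcs,
                )
            )
            logger.info(
                "rAID system at %s: %d members downstream of %s",
                rec.contig_id, len(members), rec.locus_tag,
            )
    return systems


def annotate_orphan_immunity(
    systems: list[RaidSystem], immunity_hits: list[HomologyHit]
) -> list[RaidSystem]:
    """Attach filtered immunity-gene hits to the system members they land in.

    Hits to genes outside any system are ignored.  Systems are returned
    with ``orphan_immunity_hits`` populated and are otherwise unchanged.
    """
    by_subject: dict[str, list[HomologyHit]] = {}
    for h in immunity_hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    for sys_ in systems:
        sys_.orphan_immunity_hits = [
            (g, h)
            for g in sys_.member_genes
            for h in by_subject.get(g.locus_tag, [])
        ]
    return systems
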