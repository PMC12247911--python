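"""Domain types and readers/writers for every external format the pipeline touches.

Coordinate conventions, fixed here and nowhere else:

* Contig (genomic) coordinates are 1-based inclusive at the file boundary
  (GFF3/BLAST convention) and 0-based half-open in memory.  The conversion
  happens exactly once, in this module.
* Gene-relative SNP positions are 1-based on the coding strand of the gene,
  both in files and in memory, because all downstream codon arithmetic
  (``codon_index = ceil(pos / 3)``) assumes coding orientation.
* Allele counts use the fixed base order A, C, G, T.
* A missing (site, sample) row in a count table means observed zero
  coverage, not missing data: pileup emission is sparse.

All tabular files are UTF-8, tab-delimited, with a header row.  Every
reader/writer pair round-trips bit-identically on its own output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's location on a contig.

    ``start``/``end`` are 0-based half-open (in-memory convention).  Use
    :meth:`from_1based` / :meth:`to_1based` at file boundaries.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"strand must be '+' or '-', got {self.strand!r} for {self.locus_tag}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"need 0 <= start < end, got [{self.start}, {self.end}) "
                f"for {self.locus_tag}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based(cls, contig_id, start1, end1, strand, locus_tag, product=""):
        if start1 > end1:
            raise ValidationError(
                f"start > end ({start1} > {end1}) for {locus_tag}"
            )
        return cls(contig_id, start1 - 1, end1, strand, locus_tag, product)

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    def sequence(self, contig_seq: str) -> str:
        """Coding-strand sequence of this gene ('-' genes reverse-complemented)."""
        seg = contig_seq[self.start : self.end]
        if self.strand == "-":
            seg = reverse_complement(seg)
        return seg


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_gene_table(path) -> list[GeneModel]:
    """Read gene models from GFF3 (CDS features) or a 6-column TSV.

    The TSV dialect is ``contig  start  end  strand  locus_tag  product``
    with 1-based inclusive coordinates and a header row.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    first = next((l for l in text.splitlines() if l.strip()), "")
    if first.startswith("##gff") or len(first.split("\t")) == 9:
        return _parse_gff3(text, path)
    return _parse_gene_tsv(text, path)


def _parse_gff3(text: str, path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith(">"):  # trailing FASTA section
            break
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
        contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
        if ftype != "CDS":
            continue
        try:
            start1, end1 = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        attr = dict(
            kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
        )
        tag = attr.get("locus_tag") or attr.get("ID")
        if tag is None:
            raise ParseError(f"{path}:{lineno}: CDS without locus_tag/ID attribute")
        if tag in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
        seen.add(tag)
        try:
            genes.append(
                GeneModel.from_1based(
                    contig, start1, end1, strand, tag, attr.get("product", "")
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_gene_tsv(text: str, path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    lines = [l for l in text.splitlines() if l.strip()]
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and line.split("\t")[0].lower() in ("contig", "contig_id"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        contig, start, end, strand, tag, product = fields
        try:
            start1, end1 = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if tag in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
        seen.add(tag)
        try:
            genes.append(GeneModel.from_1based(contig, start1, end1, strand, tag, product))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    """Write the 6-column TSV gene-table dialect (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("contig\tstart\tend\tstrand\tlocus_tag\tproduct\n")
        for g in genes:
            s1, e1 = g.to_1based()
            fh.write(f"{g.contig_id}\t{s1}\t{e1}\t{g.strand}\t{g.locus_tag}\t{g.product}\n")


# ---------------------------------------------------------------------------
# Homology hits (BLAST tabular)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST outfmt-6 alignment, joined with the query's length."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_length: int
    evalue: float
    bitscore: float
    subject_genome: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValidationError(f"aln_length must be >= 1, got {self.aln_length}")

    @property
    def query_coverage(self) -> float:
        if self.query_length <= 0:
            raise ValidationError(f"query_length must be positive for {self.query_id}")
        return self.aln_length / self.query_length


def read_blast_tab(path, query_lengths: dict[str, int], subject_genome_map=None) -> list[HomologyHit]:
    """Read standard 12-column BLAST ``-outfmt 6`` output.

    ``query_lengths`` maps every query id to its length (residues for
    protein searches, bases for nucleotide).  ``subject_genome_map``
    optionally maps subject ids to genome ids.
    """
    hits: list[HomologyHit] = []
    missing: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            if qid not in query_lengths:
                missing.add(qid)
                continue
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    query_length=int(query_lengths[qid]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_genome=(subject_genome_map or {}).get(sid, ""),
                )
            )
    if missing:
        raise ValidationError(
            "query ids absent from query_lengths: " + ", ".join(sorted(missing))
        )
    return hits


# ---------------------------------------------------------------------------
# Allele count matrices
# ---------------------------------------------------------------------------


@dataclass
class AlleleCountMatrix:
    """Per-site x per-sample counts of the four nucleotides.

    ``sites`` are ``(gene_id, position)`` with 1-based coding-strand
    positions; ``counts`` has shape (n_sites, n_samples, 4) in base order
    A, C, G, T.  ``collection_days`` may be NaN when unknown.
    """

    sites: list[tuple[str, int]]
    samples: list[str]
    counts: np.ndarray
    collection_days: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sites), len(self.samples), 4):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sites)}, {len(self.samples)}, 4)"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative allele count")
        if self.collection_days is None:
            self.collection_days = np.full(len(self.samples), np.nan)
        self.collection_days = np.asarray(self.collection_days, dtype=float)
        if self.collection_days.shape != (len(self.samples),):
            raise ValidationError("one collection day per sample required")

    @property
    def site_index(self) -> dict[tuple[str, int], int]:
        return {s: i for i, s in enumerate(self.sites)}

    def totals(self) -> np.ndarray:
        """Total coverage per (site, sample)."""
        return self.counts.sum(axis=2)


def read_allele_counts(path, sample_days: dict[str, float] | None = None) -> AlleleCountMatrix:
    """Read a sparse TSV with columns gene, pos, sample, A, C, G, T.

    Absent (site, sample) pairs are zero counts.  Duplicate rows for the
    same (gene, pos, sample) are ambiguous and rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
    expected = ["gene", "pos", "sample", "A", "C", "G", "T"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if (df[list(BASES)].to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative allele count")
    key = df[["gene", "pos", "sample"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(
            f"{path}: duplicate rows for (gene={dup['gene']}, pos={dup['pos']}, "
            f"sample={dup['sample']})"
        )
    sites = sorted(set(zip(df["gene"], df["pos"].astype(int))))
    samples = sorted(set(df["sample"]))
    si = {s: i for i, s in enumerate(sites)}
    sj = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(sites), len(samples), 4), dtype=np.int64)
    for row in df.itertuples(index=False):
        counts[si[(row.gene, int(row.pos))], sj[row.sample]] = (row.A, row.C, row.G, row.T)
    days = None
    if sample_days is not None:
        days = np.array([sample_days.get(s, np.nan) for s in samples], dtype=float)
    return AlleleCountMatrix(sites=sites, samples=samples, counts=counts, collection_days=days)


def write_allele_counts(acm: AlleleCountMatrix, path, sparse: bool = True) -> None:
    """Write the gene/pos/sample/A/C/G/T TSV; zero-coverage cells are omitted."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tpos\tsample\tA\tC\tG\tT\n")
        totals = acm.totals()
        for i, (gene, pos) in enumerate(acm.sites):
            for j, sample in enumerate(acm.samples):
                if sparse and totals[i, j] == 0:
                    continue
                a, c, g, t = acm.counts[i, j]
                fh.write(f"{gene}\t{pos}\t{sample}\t{a}\t{c}\t{g}\t{t}\n")


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Gene or species abundances across longitudinal samples.

    ``values`` is a DataFrame (rows = gene/species ids, columns = sample
    ids); ``library_sizes`` are total mapped reads per sample.
    """

    values: pd.DataFrame
    collection_days: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.collection_days = np.asarray(self.collection_days, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes)
        n = self.values.shape[1]
        if self.collection_days.shape != (n,):
            raise ValidationError("one collection day per sample required")
        if self.library_sizes.shape != (n,):
            raise ValidationError("one library size per sample required")
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("abundances must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_abundance_table(path) -> AbundanceTable:
    """Read the abundance TSV written by :func:`write_abundance_table`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    days = df.loc["__collection_day__"].to_numpy(dtype=float)
    libs = df.loc["__library_size__"].to_numpy(dtype=np.int64)
    values = df.drop(index=["__collection_day__", "__library_size__"])
    return AbundanceTable(values=values, collection_days=days, library_sizes=libs)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.values.copy()
    df.loc["__collection_day__"] = table.collection_days
    df.loc["__library_size__"] = table.library_sizes
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Strain factorizations
# ---------------------------------------------------------------------------


@dataclass
class StrainFactorization:
    """K strains x sites alternate-allele probabilities plus K x samples abundances.

    The factorization inference itself (e.g. StrainFacts) is external;
    this container holds its output for post-processing.
    """

    genotype_prob: np.ndarray  # (K, n_sites) in [0, 1]
    strain_abundance: np.ndarray  # (K, n_samples), per-sample sums <= 1
    site_ids: list[tuple[str, int]] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotype_prob = np.asarray(self.genotype_prob, dtype=float)
        self.strain_abundance = np.asarray(self.strain_abundance, dtype=float)
        if self.genotype_prob.ndim != 2 or self.strain_abundance.ndim != 2:
            raise ValidationError("genotype_prob and strain_abundance must be 2-D")
        if self.genotype_prob.shape[0] != self.strain_abundance.shape[0]:
            raise ValidationError("strain dimension mismatch between matrices")
        if ((self.genotype_prob < 0) | (self.genotype_prob > 1)).any():
            raise ValidationError("genotype probabilities must lie in [0, 1]")
        if (self.strain_abundance < 0).any():
            raise ValidationError("strain abundances must be non-negative")
        if (self.strain_abundance.sum(axis=0) > 1 + 1e-9).any():
            raise ValidationError("per-sample strain abundances must sum to <= 1")

    @property
    def K(self) -> int:
        return self.genotype_prob.shape[0]


def read_strain_factorization(genotype_path, abundance_path) -> StrainFactorization:
    """Read a factorization from two TSVs: strain x site probabilities and
    strain x sample abundances (rows = strains)."""
    g = pd.read_csv(genotype_path, sep="\t", index_col=0)
    a = pd.read_csv(abundance_path, sep="\t", index_col=0)
    site_ids = []
    for col in g.columns:
        gene, _, pos = col.rpartition(":")
        site_ids.append((gene, int(pos)))
    return StrainFactorization(
        genotype_prob=g.to_numpy(dtype=float),
        strain_abundance=a.to_numpy(dtype=float),
        site_ids=site_ids,
        sample_ids=list(a.columns),
    )


def write_strain_factorization(fac: StrainFactorization, genotype_path, abundance_path) -> None:
    strains = [f"strain_{k}" for k in range(fac.K)]
    sites = fac.site_ids or [("site", i + 1) for i in range(fac.genotype_prob.shape[1])]
    pd.DataFrame(
        fac.genotype_prob, index=strains, columns=[f"{g}:{p}" for g, p in sites]
    ).to_csv(genotype_path, sep="\t", float_format="%.10g")
    samples = fac.sample_ids or [f"s{j}" for j in range(fac.strain_abundance.shape[1])]
    pd.DataFrame(fac.strain_abundance, index=strains, columns=samples).to_csv(
        abundance_path, sep="\t", float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# FASTA and Newick
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(path) -> dendropy.Tree:
    """Read a single Newick tree; leaf names are genome ids."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"{path}: duplicate leaf names: {exc}") from exc
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{path}: could not parse Newick tree: {exc}") from exc
    names = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate leaf names: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_leaf_names(tree: dendropy.Tree) -> set[str]:
    return {l.taxon.label for l in tree.leaf_node_iter() if l.taxon is not None}
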