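"""Positive-selection scanning of coding genes from metagenomic SNPs.

Two signals are computed: (i) a sliding-window dN/dS along each gene —
here the ratio of non-synonymous to synonymous SNP *counts* in 200 bp
windows stepped by 25 bp, with a +1 pseudo-count on both counts (a
Beta(1,1)-style prior that prevents division by zero); windows whose ratio
strictly exceeds 3 are flagged as candidate regions of positive selection —
and (ii) a temporal trend in SNP (or genotype-block) frequency, tested by
ordinary least-squares regression of frequency on collection day.

This is deliberately not a per-site-normalized dN/dS (no Nei-Gojobori site
counting, no phylogenetic codon model); a site-normalized variant is
available behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifiedSnp:
    """A coding SNP with its translated effect under the bacterial code."""

    gene_id: str
    position: int  # 1-based in the CDS, coding strand
    ref_base: str
    alt_base: str
    codon_index: int  # 1-based
    effect: str  # "synonymous" | "non-synonymous"
    amino_acid_change: str  # e.g. "Y223F"; "" for synonymous


@dataclass
class WindowDnDs:
    """One sliding window's SNP counts and pseudo-counted dN/dS ratio."""

    gene_id: str
    window_start: int  # 1-based inclusive
    window_end: int  # 1-based inclusive
    n_nonsyn: int
    n_syn: int
    ratio: float
    flagged: bool


@dataclass
class GenotypeBlock:
    """Adjacent SNPs co-detected in the same genomes, treated as one genotype."""

    block_id: str
    member_snps: list[ClassifiedSnp]
    carrier_genomes: frozenset
    frequency: np.ndarray | None = None  # per-sample mean of member alt freqs


@dataclass
class TrendResult:
    """OLS trend of a SNP/block frequency series over collection days."""

    target_id: str
    slope: float  # frequency per day
    p_value: float
    n_samples: int
    adjusted_p: float | None = None
    note: str = ""


def _translate_codon(codon: str, codon_table_id: int) -> str:
    table = CodonTable.unambiguous_dna_by_id[codon_table_id]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_snp_effect(
    cds: str,
    position: int,
    alt_base: str,
    gene_id: str = "",
    ref_base: str | None = None,
    codon_table_id: int = 11,
) -> ClassifiedSnp:
    """Classify a single-base substitution as synonymous or non-synonymous.

    The alternate base is substituted into its codon and both codons are
    translated under the bacterial/archaeal code (table 11 by default).
    Stop gain/loss counts as non-synonymous.  Multiple SNPs in one codon
    are classified independently against the reference codon: short-read
    metagenomic data cannot phase linked mutations.
    """
    cds = cds.upper()
    alt_base = alt_base.upper()
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} is not a multiple of 3")
    if not 1 <= position <= len(cds):
        raise ValidationError(f"position {position} outside CDS of length {len(cds)}")
    ref = cds[position - 1]
    if ref_base is not None and ref_base.upper() != ref:
        raise ValidationError(
            f"reference base mismatch at {position}: CDS has {ref}, SNP says {ref_base}"
        )
    if alt_base == ref:
        raise ValidationError(f"alt base equals reference base {ref} at {position}")
    codon_index = (position - 1) // 3 + 1
    cstart = (codon_index - 1) * 3
    ref_codon = cds[cstart : cstart + 3]
    offset = (position - 1) % 3
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    aa_ref = _translate_codon(ref_codon, codon_table_id)
    aa_alt = _translate_codon(alt_codon, codon_table_id)
    if aa_ref == aa_alt:
        effect, change = "synonymous", ""
    else:
        effect, change = "non-synonymous", f"{aa_ref}{codon_index}{aa_alt}"
    return ClassifiedSnp(
        gene_id=gene_id,
        position=position,
        ref_base=ref,
        alt_base=alt_base,
        codon_index=codon_index,
        effect=effect,
        amino_acid_change=change,
    )


def sliding_window_dnds(
    snps: list[ClassifiedSnp],
    gene_length: int,
    window: int = 200,
    step: int = 25,
    pseudo: float = 1.0,
    flag_threshold: float = 3.0,
    site_normalized: bool = False,
    cds: str | None = None,
) -> list[WindowDnDs]:
    """Scan a gene with sliding windows and compute the pseudo-counted dN/dS.

    Windows start at 1, 1+step, 1+2*step, ... while start + window - 1
    <= gene_length; every SNP is counted in every window containing its
    position.  ratio = (n_nonsyn + pseudo) / (n_syn + pseudo); a window is
    flagged iff ratio > flag_threshold (strict).  Genes shorter than the
    window get a single whole-gene window (logged).

    With ``site_normalized=True`` (requires ``cds``) counts are divided by
    the number of non-synonymous/synonymous sites in the window (each codon
    position contributes its fraction of mutations that change the amino
    acid); off by default.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > gene_length:
        logger.warning(
            "gene %s (%d nt) shorter than window (%d); using one whole-gene window",
            snps[0].gene_id if snps else "?", gene_length, window,
        )
        starts = [1]
        window = gene_length
    else:
        starts = list(range(1, gene_length - window + 2, step))
    gene_id = snps[0].gene_id if snps else ""
    positions = np.array([s.position for s in snps], dtype=int)
    nonsyn = np.array([s.effect == "non-synonymous" for s in snps], dtype=bool)

    ns_weight = syn_weight = None
    if site_normalized:
        if cds is None:
            raise ValidationError("site_normalized=True requires the CDS sequence")
        ns_weight, syn_weight = _site_counts(cds)

    out: list[WindowDnDs] = []
    for start in starts:
        end = start + window - 1
        in_win = (positions >= start) & (positions <= end)
        n_ns = int((in_win & nonsyn).sum())
        n_s = int((in_win & ~nonsyn).sum())
        num, den = n_ns + pseudo, n_s + pseudo
        if site_normalized:
            num = n_ns / max(ns_weight[start - 1 : end].sum(), 1e-9) + pseudo
            den = n_s / max(syn_weight[start - 1 : end].sum(), 1e-9) + pseudo
        ratio = num / den
        out.append(
            WindowDnDs(
                gene_id=gene_id,
                window_start=start,
                window_end=end,
                n_nonsyn=n_ns,
                n_syn=n_s,
                ratio=float(ratio),
                flagged=bool(ratio > flag_threshold),
            )
        )
    return out


def _site_counts(cds: str, codon_table_id: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Per-position fraction of possible mutations that are non-synonymous
    (and synonymous), for the optional site-normalized ratio."""
    cds = cds.upper()
    ns = np.zeros(len(cds))
    syn = np.zeros(len(cds))
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        for off in range(3):
            n_changed = 0
            for b in "ACGT":
                if b == codon[off]:
                    continue
                mut = codon[:off] + b + codon[off + 1 :]
                if _translate_codon(mut, codon_table_id) != _translate_codon(codon, codon_table_id):
                    n_changed += 1
            ns[i + off] = n_changed / 3.0
            syn[i + off] = 1.0 - n_changed / 3.0
    return ns, syn


def build_genotype_blocks(
    snps: list[ClassifiedSnp],
    carriers: dict[tuple[str, int], frozenset],
    snp_freqs: dict[tuple[str, int], np.ndarray] | None = None,
) -> list[GenotypeBlock]:
    """Group adjacent SNPs co-detected in the same genomes into blocks.

    SNPs are scanned in positional order within each gene; the current
    block extends while the next SNP's carrier-genome set equals the
    block's.  Block frequency (if per-SNP frequencies are supplied) is the
    per-sample mean of member alternate-allele frequencies.
    """
    blocks: list[GenotypeBlock] = []
    by_gene: dict[str, list[ClassifiedSnp]] = {}
    for s in snps:
        by_gene.setdefault(s.gene_id, []).append(s)
    for gene in sorted(by_gene):
        ordered = sorted(by_gene[gene], key=lambda s: s.position)
        current: list[ClassifiedSnp] = []
        current_set: frozenset | None = None
        for s in ordered:
            cset = frozenset(carriers[(s.gene_id, s.position)])
            if current and cset == current_set:
                current.append(s)
            else:
                if current:
                    blocks.append(_finish_block(gene, len(blocks), current, current_set, snp_freqs))
                current, current_set = [s], cset
        if current:
            blocks.append(_finish_block(gene, len(blocks), current, current_set, snp_freqs))
    return blocks


def _finish_block(gene, idx, members, cset, snp_freqs) -> GenotypeBlock:
    freq = None
    if snp_freqs is not None:
        rows = [snp_freqs[(s.gene_id, s.position)] for s in members]
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(np.vstack(rows), axis=0)
    return GenotypeBlock(
        block_id=f"{gene}_block{idx}",
        member_snps=members,
        carrier_genomes=cset,
        frequency=freq,
    )


def temporal_trend(
    days: np.ndarray,
    freqs: np.ndarray,
    target_id: str = "",
    min_points: int = 3,
) -> TrendResult:
    """OLS regression of frequency on collection day; two-sided p for slope = 0.

    Missing frequencies are dropped pairwise.  Fewer than ``min_points``
    usable points yields a missing result carrying the reason.  The
    regression is unweighted.
    """
    days = np.asarray(days, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    mask = ~np.isnan(days) & ~np.isnan(freqs)
    x, y = days[mask], freqs[mask]
    n = len(x)
    if n < min_points:
        return TrendResult(
            target_id=target_id, slope=float("nan"), p_value=float("nan"),
            n_samples=n, note=f"only {n} usable points (< {min_points})",
        )
    if np.ptp(x) == 0:
        raise ValidationError("collection days are all identical; slope undefined")
    if np.ptp(y) == 0:
        # flat series: slope exactly 0, no evidence of trend
        return TrendResult(target_id=target_id, slope=0.0, p_value=1.0, n_samples=n)
    res = stats.linregress(x, y)
    return TrendResult(
        target_id=target_id, slope=float(res.slope), p_value=float(res.pvalue), n_samples=n
    )


def adjust_trends(results: list[TrendResult]) -> list[TrendResult]:
    """Benjamini-Hochberg adjustment across targets (in place; returns input).

    Results with missing p-values are left unadjusted.
    """
    idx = [i for i, r in enumerate(results) if not np.isnan(r.p_value)]
    if idx:
        pvals = [results[i].p_value for i in idx]
        adj = multipletests(pvals, method="fdr_bh")[1]
        for i, a in zip(idx, adj):
            results[i].adjusted_p = float(a)
    return results
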