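"""Metagenomic quantification: gene abundances, per-site allele frequencies,
variant detection, strain-marker trajectories, and cohort comparisons.

Read mapping (Bowtie2) and species profiling (MetaPhlAn) are external;
their count tables are this module's inputs.  Nucleotide counts arrive
pre-extracted from pileups; the first and last 10 bases of each gene are
trimmed because alignment quality there is typically poor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .formats import (
    BASES,
    AbundanceTable,
    AlleleCountMatrix,
    ValidationError,
)
from .marker_snps import StrainMarkerSet

logger = logging.getLogger(__name__)


@dataclass
class SnpSite:
    """A metagenomic variant site with per-sample alternate-allele abundances.

    ``alt_freq`` is alt count / total count per sample, NaN where coverage
    is below the detection threshold (missing, not zero).
    """

    gene_id: str
    position: int  # 1-based within gene, coding strand
    ref_base: str
    alt_base: str
    coverage: np.ndarray  # (n_samples,) int
    alt_freq: np.ndarray  # (n_samples,) float with NaN for missing

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValidationError("alt_base must differ from ref_base")


def normalize_gene_abundance(
    raw_counts: pd.DataFrame,
    gene_lengths: dict[str, int],
    library_sizes: dict[str, int],
    collection_days: dict[str, float] | None = None,
) -> AbundanceTable:
    """Normalize read counts against gene length and library depth (RPKM).

    value = count / (gene length in kb x library size in millions).  Any
    positive rescaling is equivalent for the rank tests and correlations
    used downstream.
    """
    genes, samples = list(raw_counts.index), list(raw_counts.columns)
    lens = np.array([gene_lengths[g] for g in genes], dtype=float)
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    if (lens <= 0).any():
        raise ValidationError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValidationError("library sizes must be positive")
    values = raw_counts.to_numpy(dtype=float) / (lens[:, None] / 1e3) / (libs[None, :] / 1e6)
    days = np.array(
        [collection_days.get(s, np.nan) if collection_days else np.nan for s in samples]
    )
    return AbundanceTable(
        values=pd.DataFrame(values, index=genes, columns=samples),
        collection_days=days,
        library_sizes=libs.astype(np.int64),
    )


def detect_gene(abundance: AbundanceTable, min_value: float = 0.0) -> pd.DataFrame:
    """Boolean genes x samples detection calls: detected iff value > min_value."""
    return abundance.values > min_value


def site_allele_frequencies(
    counts: AlleleCountMatrix,
    gene_lengths: dict[str, int],
    end_trim: int = 10,
    min_total: int = 1,
) -> list[dict]:
    """Per-site base frequencies after end trimming.

    Sites within ``end_trim`` bases of either gene end are dropped; genes
    too short to retain any site are dropped with a warning.  Per remaining
    site and sample, the frequency of each base is count / total; samples
    with total < ``min_total`` are reported missing (NaN), not zero.
    """
    if end_trim < 0:
        raise ValidationError("end_trim must be >= 0")
    out = []
    dropped_genes = set()
    totals = counts.totals().astype(float)
    for i, (gene, pos) in enumerate(counts.sites):
        length = gene_lengths[gene]
        if 2 * end_trim >= length:
            if gene not in dropped_genes:
                logger.warning("gene %s (%d nt) shorter than twice end_trim; dropped", gene, length)
                dropped_genes.add(gene)
            continue
        if pos <= end_trim or pos > length - end_trim:
            continue
        tot = totals[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = counts.counts[i].astype(float) / tot[:, None]
        freqs[tot < min_total] = np.nan
        out.append({"gene": gene, "pos": pos, "freqs": freqs, "total": tot})
    return out


def detect_metagenome_variants(
    counts: AlleleCountMatrix,
    min_coverage: int = 5,
    min_minor: int = 2,
    min_sample_fraction: float = 0.10,
) -> list[SnpSite]:
    """Detect variant sites with the coverage / minor-allele / prevalence filters.

    A site qualifies in a sample iff total coverage >= ``min_coverage`` AND
    the second-most-frequent base there has count >= ``min_minor``; the
    site is emitted iff the fraction of qualifying samples is
    >= ``min_sample_fraction``.  The reference base is the globally most
    frequent base across all samples, the alternate the second most
    frequent (ties to the lexicographically smaller base).
    """
    sites: list[SnpSite] = []
    n_samples = len(counts.samples)
    totals = counts.totals()
    for i, (gene, pos) in enumerate(counts.sites):
        c = counts.counts[i]  # (n_samples, 4)
        tot = totals[i]
        minor = np.sort(c, axis=1)[:, -2]  # second-largest count per sample
        qualifying = (tot >= min_coverage) & (minor >= min_minor)
        if n_samples == 0 or qualifying.sum() / n_samples < min_sample_fraction:
            continue
        global_counts = c.sum(axis=0)
        order = np.lexsort((np.arange(4), -global_counts))  # ties -> smaller base
        ref, alt = BASES[order[0]], BASES[order[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = c[:, BASES.index(alt)].astype(float) / tot
        alt_freq[tot < min_coverage] = np.nan
        sites.append(
            SnpSite(
                gene_id=gene,
                position=pos,
                ref_base=ref,
                alt_base=alt,
                coverage=tot.copy(),
                alt_freq=alt_freq,
            )
        )
    logger.info(
        "variant detection: %d of %d sites pass (cov>=%d, minor>=%d, >=%.0f%% samples)",
        len(sites), len(counts.sites), min_coverage, min_minor, 100 * min_sample_fraction,
    )
    return sites


def strain_marker_trajectory(
    markers: StrainMarkerSet, sites: list[SnpSite]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample strain relative abundance: the mean alternate-allele
    frequency over the strain's marker SNPs.

    Marker (gene, pos, ref, alt) tuples are matched against detected sites;
    a site whose ref/alt orientation is swapped relative to the marker
    contributes ``1 - freq``.  Missing sites are skipped per sample; the
    per-sample count of contributing markers is returned alongside.
    """
    by_key = {(s.gene_id, s.position): s for s in sites}
    series_rows = []
    for gene, pos, ref, alt in markers.snps:
        site = by_key.get((gene, pos))
        if site is None:
            continue
        if site.alt_base == alt:
            series_rows.append(site.alt_freq)
        elif site.ref_base == alt:
            series_rows.append(1.0 - site.alt_freq)
        # a third allele at this site carries no information about the marker
    if not series_rows:
        raise ValidationError(
            f"no marker SNPs of strain {markers.strain_label} overlap detected sites"
        )
    mat = np.vstack(series_rows)
    n_contrib = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        traj = np.nanmean(mat, axis=0)
    return traj, n_contrib


def flag_outlier_marker_genes(
    sites: list[SnpSite], excess_snp_z: float = 2.0
) -> list[str]:
    """Exclude marker genes whose variant load and temporal pattern disagree
    with the rest of the marker set.

    A gene is excluded iff its SNP count exceeds the mean + ``excess_snp_z``
    standard deviations of the other genes' counts AND the correlation of
    its mean variant-frequency profile with the median profile of the other
    genes is negative.  This guards against paralogous genes attracting
    erroneous alignments.
    """
    genes = sorted({s.gene_id for s in sites})
    if len(genes) < 3:
        raise ValidationError("need variant profiles for >= 3 marker genes")
    n_snps = {g: 0 for g in genes}
    profiles: dict[str, list[np.ndarray]] = {g: [] for g in genes}
    for s in sites:
        n_snps[s.gene_id] += 1
        profiles[s.gene_id].append(s.alt_freq)
    mean_profile = {g: np.nanmean(np.vstack(profiles[g]), axis=0) for g in genes}

    excluded = []
    for g in genes:
        others = [h for h in genes if h != g]
        other_counts = np.array([n_snps[h] for h in others], dtype=float)
        mu, sd = other_counts.mean(), other_counts.std(ddof=1)
        if not n_snps[g] > mu + excess_snp_z * sd:
            continue
        med = np.nanmedian(np.vstack([mean_profile[h] for h in others]), axis=0)
        mask = ~np.isnan(mean_profile[g]) & ~np.isnan(med)
        if mask.sum() < 3:
            continue
        r = _pearson_or_nan(mean_profile[g][mask], med[mask])
        if np.isnan(r) or r >= 0:
            continue
        excluded.append(g)
        logger.warning(
            "marker gene %s excluded: %d SNPs (others mean %.1f, sd %.1f), "
            "profile correlation %.2f", g, n_snps[g], mu, sd, r,
        )
    return excluded


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def cooccurrence_rank_test(
    orphan_abundance: np.ndarray, e2_detected: np.ndarray
) -> tuple[float, float, int, int]:
    """Compare orphan-gene abundance between samples with and without the
    cognate effector: two-sided Wilcoxon rank-sum (Mann-Whitney U, normal
    approximation with tie correction).

    Returns (U statistic of the detected group, two-sided p, n_detected,
    n_not_detected).
    """
    orphan_abundance = np.asarray(orphan_abundance, dtype=float)
    e2_detected = np.asarray(e2_detected, dtype=bool)
    x = orphan_abundance[e2_detected]
    y = orphan_abundance[~e2_detected]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both detection groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), len(x), len(y)


def bin_days_into_groups(days: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Bin continuous collection days into ``n_bins`` equal-size ordered
    groups (default terciles) for categorical tests like PERMANOVA."""
    days = np.asarray(days, dtype=float)
    order = np.argsort(days, kind="stable")
    labels = np.empty(len(days), dtype=object)
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        labels[idx] = f"T{b + 1}"
    return labels


def _permanova_F(d2: np.ndarray, groups: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from a squared distance matrix."""
    n = d2.shape[0]
    labels = np.unique(groups)
    a = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def braycurtis_permanova(
    species_abundance: AbundanceTable,
    groups: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA on Bray-Curtis dissimilarities of relative abundances.

    Samples are the observations; abundances are converted to per-sample
    relative abundances first.  p = (1 + #{F* >= F}) / (1 + n_perm) over
    seeded label permutations (the add-one convention avoids p = 0).
    """
    groups = np.asarray(groups)
    labels, counts_per = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    if (counts_per < 2).any():
        small = labels[counts_per < 2]
        raise ValidationError(f"groups with < 2 samples: {list(small)}")
    X = species_abundance.values.to_numpy(dtype=float).T  # samples x taxa
    totals = X.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValidationError("every sample needs positive total abundance")
    X = X / totals
    d2 = squareform(pdist(X, metric="braycurtis")) ** 2
    f_obs = _permanova_F(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _permanova_F(d2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(p)


def correlate_gene_species(
    gene_series: np.ndarray, species_series: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation between a gene's and a species' abundance series.

    Pairs with a missing value in either series are dropped (pairwise
    deletion); returns (r, p, n).  Zero variance in either series makes the
    correlation undefined: (nan, nan, n).
    """
    x = np.asarray(gene_series, dtype=float)
    y = np.asarray(species_series, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValidationError("need >= 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), n
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n
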