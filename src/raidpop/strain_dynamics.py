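"""Post-processing of strain factorizations (genotype x abundance matrices).

The factorization inference itself (e.g. StrainFacts) is external; given
its output at several candidate strain numbers K, this module (i)
reconstructs per-strain sequences by thresholding genotype probabilities,
(ii) relates strain abundance trajectories to gene trajectories, and (iii)
selects K by either of two criteria: the smallest K whose strains reach a
reasonable correlation (> 0.3) to every target gene, or the K minimizing
the maximum pairwise strain-strain abundance correlation (redundant strains
add nothing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .formats import StrainFactorization, ValidationError


def _effectively_constant(x: np.ndarray) -> bool:
    """True when a series has no usable variance (scipy would warn)."""
    return np.ptp(x) < 1e-10 * max(1.0, float(np.abs(x).max()))

logger = logging.getLogger(__name__)


@dataclass
class StrainSelectionReport:
    """Diagnostics and outcome of strain-number selection."""

    candidate_Ks: list[int]
    max_pairwise_corr: dict[int, float]  # per K; nan where < 2 strains
    target_corr: dict[int, dict[str, float]]  # per K, best |strain| corr per target
    chosen_K: int | None
    criterion: str  # "target_correlation" | "non_redundancy"


def reconstruct_strain_sequence(
    genotype_prob: dict[int, float],
    ref_seq: str,
    alt_bases: dict[int, str],
    low: float = 0.25,
    high: float = 0.75,
) -> str:
    """Reconstruct one strain's gene sequence from genotype probabilities.

    At each variant position (1-based), the alternate base is inserted when
    its probability is strictly > ``high``, the reference base when it is
    strictly < ``low``, and the unknown base ``N`` otherwise (probabilities
    exactly at either boundary are ambiguous).  Non-variant positions copy
    the reference.
    """
    if low >= high:
        raise ValidationError(f"need low < high, got {low} >= {high}")
    seq = list(ref_seq.upper())
    for pos, p in genotype_prob.items():
        if not 1 <= pos <= len(seq):
            raise ValidationError(f"variant position {pos} outside reference of length {len(seq)}")
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"genotype probability {p} outside [0, 1]")
        if p > high:
            seq[pos - 1] = alt_bases[pos].upper()
        elif p < low:
            pass  # keep reference
        else:
            seq[pos - 1] = "N"
    return "".join(seq)


def strain_gene_correlation(
    strain_abundance: np.ndarray, gene_abundance: np.ndarray
) -> float:
    """Pearson r between a strain's and a gene's per-sample series
    (pairwise deletion of missing values; NaN when variance is zero)."""
    x = np.asarray(strain_abundance, dtype=float)
    y = np.asarray(gene_abundance, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValidationError("need >= 3 paired samples")
    if _effectively_constant(x) or _effectively_constant(y):
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _max_pairwise_corr(fac: StrainFactorization) -> float:
    if fac.K < 2:
        return float("nan")
    best = -np.inf
    for i, j in combinations(range(fac.K), 2):
        a, b = fac.strain_abundance[i], fac.strain_abundance[j]
        if _effectively_constant(a) or _effectively_constant(b):
            continue
        best = max(best, float(stats.pearsonr(a, b).statistic))
    return best if np.isfinite(best) else float("nan")


def _target_correlations(
    fac: StrainFactorization, targets: dict[str, np.ndarray]
) -> dict[str, float]:
    out = {}
    for name, series in targets.items():
        rs = []
        for k in range(fac.K):
            try:
                r = strain_gene_correlation(fac.strain_abundance[k], series)
            except ValidationError:
                r = float("nan")
            if not np.isnan(r):
                rs.append(r)
        out[name] = max(rs) if rs else float("nan")
    return out


def select_K_by_target_correlation(
    factorizations: dict[int, StrainFactorization],
    targets: dict[str, np.ndarray],
    r_min: float = 0.3,
) -> StrainSelectionReport:
    """Choose the minimum number of strains required to achieve a reasonable
    correlation (> ``r_min``) to every target gene.

    For each candidate K (ascending), every target must have some strain
    whose abundance series correlates with it at r > r_min.  If no K
    qualifies, ``chosen_K`` is None and the per-K diagnostics are returned.
    """
    if not factorizations:
        raise ValidationError("empty factorization map")
    if not targets:
        raise ValidationError("need at least one target gene series")
    ks = sorted(factorizations)
    target_corr = {k: _target_correlations(factorizations[k], targets) for k in ks}
    max_pair = {k: _max_pairwise_corr(factorizations[k]) for k in ks}
    chosen = None
    for k in ks:
        rs = target_corr[k].values()
        if all(not np.isnan(r) and r > r_min for r in rs):
            chosen = k
            break
    if chosen is None:
        logger.info("no K reaches r > %.2f for all targets", r_min)
    return StrainSelectionReport(
        candidate_Ks=ks,
        max_pairwise_corr=max_pair,
        target_corr=target_corr,
        chosen_K=chosen,
        criterion="target_correlation",
    )


def select_K_by_non_redundancy(
    factorizations: dict[int, StrainFactorization],
    targets: dict[str, np.ndarray] | None = None,
) -> StrainSelectionReport:
    """Choose the K minimizing the maximum pairwise strain-abundance
    correlation: highly correlated strains are redundant.

    Candidates with fewer than 2 strains carry no pairwise correlation and
    are excluded (logged).  Ties break to the smallest K.
    """
    if not factorizations:
        raise ValidationError("empty factorization map")
    ks = sorted(factorizations)
    max_pair = {k: _max_pairwise_corr(factorizations[k]) for k in ks}
    eligible = [k for k in ks if factorizations[k].K >= 2 and not np.isnan(max_pair[k])]
    excluded = [k for k in ks if k not in eligible]
    if excluded:
        logger.info("K candidates without pairwise correlations excluded: %s", excluded)
    if len(eligible) < 2:
        raise ValidationError(
            "need >= 2 candidate factorizations with >= 2 strains each"
        )
    best = min(max_pair[k] for k in eligible)
    chosen = min(k for k in eligible if max_pair[k] == best)
    target_corr = {}
    if targets:
        target_corr = {k: _target_correlations(factorizations[k], targets) for k in ks}
    return StrainSelectionReport(
        candidate_Ks=ks,
        max_pairwise_corr=max_pair,
        target_corr=target_corr,
        chosen_K=chosen,
        criterion="non_redundancy",
    )
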