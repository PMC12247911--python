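"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result by the most direct enumeration possible
and is kept free of any code path it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import nnls

BASES = "ACGT"


def brute_force_window_counts(snps, gene_length, window, step):
    """Recount (n_nonsyn, n_syn) per window by direct per-SNP scanning."""
    out = []
    start = 1
    while start + window - 1 <= gene_length:
        end = start + window - 1
        n_ns = n_s = 0
        for s in snps:
            if start <= s.position <= end:
                if s.effect == "non-synonymous":
                    n_ns += 1
                else:
                    n_s += 1
        out.append((start, end, n_ns, n_s))
        start += step
    return out


def brute_force_variant_sites(counts, sites, min_coverage, min_minor, min_sample_fraction):
    """Direct evaluation of the three-filter variant predicate.

    ``counts`` is (n_sites, n_samples, 4).  Returns the indices of emitted
    sites together with their (ref, alt) base calls.
    """
    emitted = []
    n_samples = counts.shape[1]
    for i in range(len(sites)):
        qualifying = 0
        for j in range(n_samples):
            c = sorted(counts[i, j], reverse=True)
            if sum(c) >= min_coverage and c[1] >= min_minor:
                qualifying += 1
        if qualifying / n_samples >= min_sample_fraction:
            glob = counts[i].sum(axis=0)
            ranked = sorted(range(4), key=lambda b: (-glob[b], b))
            emitted.append((i, BASES[ranked[0]], BASES[ranked[1]]))
    return emitted


def exhaustive_deconvolve(alt_freq, k, max_sites=12):
    """Tiny exhaustive strain deconvolver: enumerate all binary K x S
    genotype matrices and fit per-sample abundances by non-negative least
    squares; return the (genotypes, abundances) minimizing squared error.

    Only feasible for k <= 3 and a handful of sites; serves as an
    independent oracle for factorization fixtures.
    """
    n_sites, n_samples = alt_freq.shape
    assert k <= 3 and n_sites <= max_sites
    best = None
    for bits in product([0.0, 1.0], repeat=k * n_sites):
        G = np.array(bits).reshape(k, n_sites)
        # skip duplicated strains (unidentifiable)
        if len({tuple(row) for row in G}) < k:
            continue
        A = np.zeros((k, n_samples))
        sse = 0.0
        for j in range(n_samples):
            # alt_freq[:, j] ~ G.T @ a, a >= 0, sum(a) <= 1
            coeffs, resid = nnls(G.T, alt_freq[:, j])
            total = coeffs.sum()
            if total > 1.0:
                coeffs = coeffs / total
                resid = np.linalg.norm(G.T @ coeffs - alt_freq[:, j])
            A[:, j] = coeffs
            sse += resid**2
        if best is None or sse < best[0]:
            best = (sse, G, A)
    return best[1], best[2], best[0]
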