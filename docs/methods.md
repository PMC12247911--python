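# Methods

This note records the models and procedures implemented in `raidpop`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Coordinate and data conventions

Contig coordinates are 1-based inclusive in files (GFF3/BLAST
convention) and 0-based half-open in memory; `formats` is the single
conversion point. Gene-relative SNP positions are 1-based on the coding
strand everywhere (genes on the "−" strand are reverse-complemented at
read time), because codon arithmetic (`codon_index = ceil(pos/3)`)
assumes coding orientation. Allele counts use the fixed base order
A, C, G, T; a missing (site, sample) row in a count table means observed
zero coverage, not missing data, since pileup emission is sparse.
Missing *frequencies* (coverage below threshold) are NaN, never zero.

## Genome screening

Homology hits (BLAST tabular, computed externally) are kept when
`pct_identity ≥ 90` and `aln_length / query_length ≥ 0.90`, both
inclusive. Effector queries use only the final 399 nt (the C-terminal
domain), since effectors share long N-terminal Rhs homology.

The rAID rule: from each recombinase gene, walk gene-by-gene downstream
in its transcriptional direction, collecting consecutive genes that
share one strand and have GC fraction strictly below 0.41 (N excluded
from the denominator); stop at the first violation or contig end; emit a
system iff ≥ 2 genes were collected. Open choices resolved here:
"upstream" is read as the recombinase lying 5′ of the array in the
walk's direction; the array must be consecutive in gene order
(intergenic distance unconstrained — no distance cutoff is defined for
these systems); members must be co-oriented with each other but not
necessarily with the recombinase (a strict flag adds that requirement).
Detection is invariant to gene-table row order and to
reverse-complementing the contig, both covered by tests.

## Strain-diagnostic SNPs

Isolate orthologs of species marker genes (alignment construction is
external) are compared column-by-column against a reference. By default
the reference is the majority consensus (ties broken to the
lexicographically smallest base and logged; columns with > 50% gaps
excluded; a gapped genome carries no call at that column). An explicit
reference sequence can be supplied instead; the bundled pipeline passes
the generator's reference genes. This option exists because majority
consensus is ill-posed exactly at strain-diagnostic sites when two
strains are balanced: the site sits near 50% carriage, so the consensus
base itself — and with it every downstream call — flips with the
sampling noise. Anchoring to the marker-gene catalog sequence is what a
reference-based variant caller does and keeps the calls stable.

A SNP is designated a marker of strain S when carried by ≥ 90% of S's
genomes and ≤ 10% of all other genomes. The exclusivity half is this
package's addition: without it, species-fixed SNPs would be "markers"
of every strain. It is configurable (`max_presence_elsewhere=1.0`
recovers the presence-only rule). Strains come either from an explicit
label map or from a phylogeny, each strain being the smallest clade
containing its anchor leaves; overlapping clades are an error, leaves
in no clade stay unassigned.

## Metagenomic quantification

Gene abundance is RPKM — reads / (gene kb × library millions); any
positive rescaling is equivalent for the rank tests and correlations
used downstream. Gene "detection" defaults to strictly positive
normalized abundance (no published cutoff exists; configurable).

Per-site nucleotide counts arrive pre-extracted from pileups (mpileup
flags such as `--excl-flags UNMAP,QCFAIL,DUP -A -q0 -C0 -B` concern that
external step and are documented, not reproduced). The first and last
10 nt of each gene are trimmed (poor alignment quality). A site is a
variant when, in ≥ 10% of samples, it has coverage ≥ 5 and a
second-most-frequent base count ≥ 2; the reference/alternate bases are
the globally most/second-most frequent (ties to the smaller base).

A strain's trajectory is the per-sample mean of its marker SNPs'
alternate-allele frequencies (sites whose ref/alt orientation is
swapped contribute `1 − f`; missing sites are skipped and the
contributing-marker count reported). Marker genes whose SNP load
exceeds the other genes' mean by 2 SD *and* whose mean frequency
profile anti-correlates with the others' median profile are excluded —
the signature of paralogs attracting erroneous alignments.

Co-occurrence comparisons use the two-sided Wilcoxon rank-sum test
(normal approximation, tie-corrected). Community shifts use one-way
PERMANOVA on Bray–Curtis dissimilarities of relative abundances with
seeded label permutations and the add-one p-value convention
(p = (1 + #{F* ≥ F})/(1 + n_perm)), implemented in-package because a
seeded permutation stream is required for reproducibility; the
pseudo-F is cross-checked against scikit-bio's in tests. Continuous
collection time is binned into equal-size ordered groups (default
terciles) when a categorical factor is needed.

## Selection analysis

SNP effects are classified by substituting the alternate base into its
codon and translating both codons under the bacterial/archaeal code
(table 11); stop gain/loss counts as non-synonymous. Multiple SNPs in
one codon are classified independently against the reference codon:
short metagenomic reads cannot phase linked mutations.

The windowed dN/dS is deliberately a ratio of SNP *counts*, not
per-site-normalized rates: windows of 200 nt step by 25 nt, and each
window's ratio is `(N + 1)/(S + 1)` — the +1 pseudo-counts act like a
Beta(1,1) prior and keep the ratio finite (an empty window scores
exactly 1). Windows are flagged when the ratio strictly exceeds 3. A
Nei–Gojobori-style site-normalized variant exists behind
`site_normalized=True` for comparison, off by default. Windows that
would overrun the gene are not emitted; genes shorter than one window
get a single whole-gene window (logged).

Adjacent SNPs co-detected in exactly the same genomes form one genotype
block (strictly consecutive variant sites; the block's frequency is the
mean of its members'). Temporal change is tested by unweighted OLS of
frequency on collection day (two-sided p for zero slope; a
coverage-weighted option exists but plain regression is the default);
Benjamini–Hochberg adjustment across targets is optional since no
correction is prescribed for this test.

## Strain factorizations

Strain deconvolution itself (e.g. StrainFacts) is external; `raidpop`
post-processes its genotype-probability × abundance output. Sequences
are reconstructed by inserting the alternate base where the
alternate-allele probability is > 0.75, the reference where it is
< 0.25, and N otherwise — both boundaries fall in the N band (strict
inequalities). Two strain-number criteria are implemented and always
reported together, since either can reasonably govern: (i) the smallest
K for which every target gene (cognate effector, orphan) has a strain
correlating at r > 0.3, and (ii) the K minimizing the maximum pairwise
strain-abundance Pearson correlation, redundant strains adding nothing.
Ties break to the smallest K; K = 1 carries no pairwise correlation and
is excluded from (ii). Pearson correlation is used throughout.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed) — identical seeds give
byte-identical output — and always emit ground truth beside the data.

* **Isolate genomes**: K strains over a marker-gene catalog; each
  isolate of strain S carries each of S's diagnostic SNPs with
  probability 1 − ε and other strains' SNPs with probability ε
  (default ε = 0, i.e. clonal strains). Planted positions are globally
  unique, so marker sets are disjoint by construction.
* **Communities**: deterministic trajectory shapes — constant,
  oscillating, and a logistic bloom that stays below 5% before its
  bloom day and rises monotonically after — normalized to proportions,
  with optional lognormal sample noise (off by default). These are
  qualitative analogues of observed within-host dynamics, not fits.
* **Pileups**: coverage ~ Poisson(depth) independently per site (no
  mapping bias), base counts ~ Multinomial over the mixture allele
  frequency pushed through a uniform substitution error (each read
  shows its true base with probability 1 − e, each other base e/3).
  No indels and no read-level simulation: the analysis is
  substitution-only and consumes counts, not alignments. Error rates
  ≥ 0.75 are rejected (degenerate base distribution).
* **Selection genes**: reference CDS drawn from sense codons (no
  internal stops); 8 non-synonymous SNPs planted in one 150 nt span and
  synonymous background SNPs placed uniformly outside the cluster plus
  a 200 nt guard margin, so the planted selective contrast is not
  diluted by background variants landing in cluster-overlapping
  windows. Every planted effect is re-verified by translation before
  emission; impossible placements (e.g. a synonymous change at a codon
  with none) are resampled with bounded retries.
* **rAID genomes**: true systems are a recombinase followed by 2–4
  co-oriented genes with exact low-GC composition (clamped strictly
  below 0.41); each decoy violates exactly one rule (orientation,
  member count, or GC), recorded in the truth labels; high-GC spacer
  genes separate units so detection walks cannot cross them. By
  construction, sensitivity and specificity are both 1 for a correct
  detector — the fixtures test the rule logic, not robustness to
  annotation noise.

Passing tests on these fixtures therefore demonstrates correctness of
the implemented rules and estimators under the stated statistical
models; they do not demonstrate robustness to real-data pathologies
such as mapping bias, chimeric assemblies, indels, or uneven coverage.

## Numerical choices and problem sizes

Consensus ties and K-selection ties break deterministically (smallest
base / smallest K) and are logged. Permutation p-values use the add-one
convention. Zero-variance series yield NaN correlations (reported
missing) rather than errors; series constant to within 1e-10 relative
range are treated as zero-variance. The pipeline derives one substream
per stage from the run seed via `numpy.random.SeedSequence.spawn`, so
stage outputs are independent yet the whole run is reproducible
byte-for-byte.

The bundled synthetic study uses 2 strains × 10 isolates, 4 marker
genes of 900 nt, 20 diagnostic SNPs per strain, 30 samples over 540
days at 1000× depth with 0.5% error, and 3 true rAID systems plus 3
decoys; null calibrations use 1000 trend simulations and 200 PERMANOVA
simulations at 199 permutations. These sizes give sub-percent
trajectory error and tight type-I intervals while keeping any laptop
run in seconds.

## Known limitations

No phylogenetic codon models (PAML-style dN/dS), no ancestral
reconstruction, no haplotype-aware joint translation of linked SNPs, no
BAM/pileup parsing (counts arrive pre-extracted), no re-implementation
of read mapping, species profiling, alignment, tree inference, or
variational strain deconvolution — those tools' tabular outputs are
this package's inputs. The exhaustive deconvolver in the test suite
(≤ 3 strains, ≤ 12 sites) is an oracle for fixtures, not an analysis
tool.
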