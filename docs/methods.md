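# Methods

## Data model

Genotypes are biallelic, diploid, and stored as the within-individual
frequency of the reference allele: 1 (hom. reference), 0.5
(heterozygous), 0 (hom. alternate), NaN (missing).  This coding makes
each accession a vector of per-locus allele frequencies, which is the
form every distance and diversity formula below consumes directly.
Heterozygote phase is ignored.  Polyploid calls, phased haplotypes and
multi-allelic markers are out of scope; multi-allelic VCF records are
skipped with a logged count.

## Synthetic populations

`generate_structured_population` draws panels under the Balding–Nichols
model.  Per marker, an ancestral frequency `p ~ U(0.1, 0.9)`; per
collection `c`, a frequency
`p_c ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, whose mean is `p` and whose
between-collection differentiation equals `F` (at `F = 0` the Beta
degenerates to a point mass at `p`).  Genotype classes are then sampled
per accession with heterozygote probability `2 p_c (1−p_c) (1−F_IS)`;
the inbreeding coefficient `F_IS` defaults to 0.9 because the intended
application is a selfing cereal whose panels show per-marker
heterozygosity well below the 12.5 % QC cap.  Missing calls are
injected completely at random (no informative-missingness mechanism is
modeled).  All draws flow from one seeded generator in a fixed order
(ancestral frequencies → collection frequencies → genotypes →
missingness), so a config plus seed is bit-reproducible.

Defaults mirror the motivating wheat panel: five collections of sizes
92/284/40/220/254 (890 accessions); 1,000 markers by default in tests.
A Weir–Cockerham variance-components estimator implemented
independently in the test suite recovers the configured `F` (e.g.
`F = 0.10 ± 0.02` at 5 × 100 accessions × 2,000 markers).

What the generator does *not* emulate: linkage maps and LD decay along
chromosomes, realistic allele-frequency spectra, collection-specific
missingness or heterozygosity patterns.  Passing tests therefore
demonstrate algorithmic correctness and the qualitative behavior of
selection methods under divergence-driven structure, not numerical
agreement with any particular real panel.

`generate_placement_fixture` builds a random reference chromosome with
markers embedded at known coordinates and emits the matching pseudo
mate-pair alignments, deliberately planting the failure modes the
consistency filter must catch (missing mate, 2-nt inner gap, `N` at
the SNP site, sub-threshold MAPQ, duplicated position, spurious
secondary alignment) together with a ground-truth table.

## Probe placement

A marker's context sequence is split at the bracket site; the left
flank becomes mate 1 and the reverse complement of the right flank
becomes mate 2, so a correctly mapped pair is convergent with an inner
gap of exactly one reference base — the SNP itself.  Alignment is
external (any SAM/BED-producing mapper); the module consumes parsed
records.  The cascade:

1. drop unmapped reads, secondary alignments, MAPQ < 20 (inclusive
   threshold: 20 is kept);
2. per marker, require exactly one surviving alignment per mate.
   Alignments whose CIGAR is not a single full-length match are
   ineligible (a gapped flank alignment shifts the SNP coordinate
   unpredictably); a mate left with several equal-quality alignments
   makes the marker `ambiguous` — only uniquely placed markers count;
3. require same chromosome, convergent orientation, inner gap exactly
   1; the gap base must not be `N`;
4. collapse markers at the same (chromosome, position), keeping the
   first in manifest order.

A marker whose mate 1 maps to the minus strand is a valid minus-strand
placement; its alleles are complemented and the strand recorded.  Every
rejected marker carries exactly one primary reason
(`mate`/`cigar`/`ambiguous`/`orientation`/`gap`/`N-site`/`lookup`/`duplicate`);
the reasons partition the rejected set.  Coordinates are 1-based
inclusive internally; BED output is 0-based half-open.

## Marker QC

Fixed cascade order with the boundary semantics used on the array data
this mirrors: missing fraction ≥ 0.30 removes; monomorphic markers
(all observed calls identical and homozygous — a heterozygote-only
marker still shows both alleles) remove; duplicate call vectors
(including the missing pattern) keep the first; then imputation; then
MAF ≥ 0.05 keeps and heterozygous-call fraction ≤ 0.125 keeps.  MAF is
`min(q, 1−q)` with `q` the mean dosage.  The post-imputation filter is
idempotent.

Imputation is a deliberately simple stand-in: each missing call is
drawn, with a fixed seed, from the marker's observed genotype-class
frequencies.  It preserves per-marker allele frequencies in
expectation but ignores haplotype information entirely; externally
imputed matrices (e.g. from a haplotype-aware tool) can be read through
the normal IO layer instead, and a `--no-impute` path computes the
post filters and distances on pairwise-complete observed calls.

`collapse_perfect_ld` treats two markers as one haplotype block when
their call vectors are identical or exactly complementary (`d ↔ 1−d`
at every accession): the same signal up to allele coding.  One or two
representatives per block are retained (first in input order).  The
operation is invariant to flipping any marker's allele coding.

## Distances and PCoA

With per-individual allele frequencies `p_ila` (reference) and
`1 − p_ila` (alternate):

- `MRD(i,j) = sqrt( (1/2m) Σ_l Σ_a (p_ila − p_jla)² )`.  For biallelic
  loci the allele sum is `2 (Δdosage)²`, so MRD is the Euclidean
  distance between dosage vectors divided by `sqrt(m)` — this identity
  is the cross-check oracle in the tests.
- `CSE(i,j) = sqrt( (1/m) Σ_l (1 − Σ_a sqrt(p_ila p_jla)) )`.

Both are normalized to [0, 1]; opposite homozygotes at every locus give
exactly 1.  Default mode requires complete (post-imputation) data;
pairwise-complete mode restricts each pair to loci observed in both
accessions and errors if a pair shares none.

PCoA is classical Torgerson scaling: double-center `−½ J D² J`,
eigendecompose, scale eigenvectors by `sqrt(λ)`.  Negative eigenvalues
(non-Euclidean input) are excluded from both the coordinates and the
variance-explained denominator; no additive (Cailliez) correction is
applied because MRD is Euclidean by construction and CSE is close to
it, and a correction would distort the percent-explained figures.
Numerical tolerance for "positive" is `1e-9 · max λ`.

## Core selection

**PAM k-medoids.**  Greedy BUILD (start from the accession minimizing
total distance, add the accession with the largest cost reduction) then
best-improving SWAP until no (medoid, non-medoid) exchange lowers the
total nearest-medoid cost.  One SWAP sweep scores all exchanges at once
via the FastPAM decomposition (candidate-only gain plus a per-cluster
correction assembled with a matrix product), which is algebraically
identical to the textbook sweep.  Ties break toward the lowest index,
making the procedure deterministic; the test suite confirms bit-equal
objective values against the R reference implementation
(`cluster::pam`) from the BUILD start.  PAM is a local optimizer: on
tiny random instances it occasionally ends a few percent above the
exhaustive-search optimum — a property shared with the reference
implementation, not an artifact of this port.  Run-to-run stability is
probed by passing fresh random initial medoids per replicate (BUILD is
deterministic and would hide all variability).

**Objective-driven local search.**  The five evaluation statistics are
also selection objectives: maximize average entry-to-nearest-entry
(E-NE), Shannon diversity, expected heterozygosity, or allele coverage;
minimize average accession-to-nearest-entry (A-NE).  The optimizer is
seeded random descent over k-subsets: uniform random start, uniform
single-swap proposals, accept strictly improving moves, stop at an
evaluation budget or after a patience window, optionally restart.  This
stands in for annealing-style engines in dedicated core-selection
software; the comparisons here concern objective values and run-to-run
variability, which any well-mixing stochastic improver reproduces, and
no exact equivalence to a particular engine is claimed.  Proposals are
evaluated incrementally in compiled kernels — nearest/second-nearest
entry bookkeeping for E-NE/A-NE (O(k) and O(N) per proposal), pooled
allele-count updates for the allele statistics (O(m)) — so the
replicated grids run in minutes.

Budgets: the package default is 50,000 evaluations with patience 5,000
(generous convergence on panels of a few hundred accessions; on 8-point
instances the search recovers the exhaustive-subset optimum for every
objective in ≥ 95 % of seeded runs with 3,000 evaluations × 3
restarts).  The replicated comparison defaults to 6,000 evaluations
with patience 1,000 per run, the point where the pooled-statistic
objectives (Shannon, expected heterozygosity) are essentially converged
— mirroring run-to-threshold use of such optimizers — while a
1,000-run grid on a 200-accession panel stays around a minute per
method.

**Evaluation statistics.**  E-NE: mean over entries of the distance to
the closest other entry (undefined for k < 2).  A-NE: mean over *all*
accessions of the distance to the closest entry (entries contribute 0);
non-increasing as the core grows.  Shannon diversity pools allele
counts over all loci jointly (grand total `2km`), `H = −Σ f ln f`,
maximal at `ln(2m)` for a uniform pool.  Expected heterozygosity is the
per-locus gene diversity `1 − Σ_a p_a²` averaged over loci (max 0.5
for biallelic data).  Allele coverage is the fraction of the full
collection's observed alleles present among the entries; heterozygotes
contribute one copy of each allele.  Nearest-entry ties are broken by
value only.

## Replicated comparison

Each method is run R times (default 1,000) with consecutive derived
seeds; for k-medoids each run gets fresh random initial medoids.  The
per-accession selection frequency `f_i` over the R runs conserves
`Σ f_i = k`.  Stability is summarized two ways: the full ecdf
`F(x) = #{i : f_i ≤ x}/N` (for plotting: a stable method hugs the
horizontal, an unstable one the vertical) and the scalar index
`S = 1 − mean(4 f (1−f))`, which is 1 exactly when every accession is
always or never selected and 0 when all frequencies sit at 0.5.  The
index is this package's quantification of the "never-or-always"
stability notion; the ecdf data is still emitted.  Every produced core
is scored by average A-NE and average E-NE under one common metric
(default MRD, since MRD- and CSE-driven selections turn out nearly
interchangeable), and the summary ranks methods by S, mean A-NE and
mean E-NE.  Seeds, method labels and run indices are recorded per core
so any report is replayable.

On structured synthetic panels (200 accessions, 500 markers, F = 0.1,
k ∈ {40, 72}, R = 100, aggregated over 10 seeds — sizes chosen so the
whole grid runs in a few minutes on one CPU) the comparison reproduces
the expected qualitative picture: random and allele-coverage selections
are indistinguishably unstable; the distance-based objectives and
k-medoids are intermediate; Shannon and expected-heterozygosity
selections are the most stable; k-medoids or the A-NE objective achieve
the lowest mean average-A-NE; the E-NE objective achieves the highest
mean average-E-NE; MRD vs CSE changes the quality means by well under
10 %.

## Known limitations

- The naive imputer ignores LD; downstream distances on heavily missing
  data are noisier than a haplotype-aware imputer would give.
- PAM and the local search are local optimizers; global optimality is
  only guaranteed where the tests brute-force tiny instances.
- The synthetic generator's independence across loci means
  perfect-LD blocks essentially never arise by chance; the LD-collapse
  operation is exercised through constructed cases.
- Real-data figures (marker counts on a specific reference genome,
  variance-explained percentages of a particular panel) depend on
  external aligners, imputers and deposited data and are not reproduced
  by the synthetic pipeline.
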