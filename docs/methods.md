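# Methods

## Problem setting and model

`cclone` infers clonal structure from the SNVs visible in scRNA-seq reads.
The data are doubly unreliable: (i) most called variants are non-somatic
(germline SNPs, RNA edits, artefacts), and (ii) any given variant is only
observable in cells actively expressing its locus, so most cell x variant
entries carry no information at all. The model therefore never treats a
variant call as certain. Each entry is reduced to a three-level VAF
estimate M ∈ {0, 0.5, 1} plus a confidence W ∈ {0, 0.5, 1}: both alleles
seen → confident het (W = 1); one allele seen → the other may simply have
dropped out (W = 0.5); nothing seen → no information (W = 0). An allele is
"seen" with ≥ 1 read/UMI and within-cell frequency ≥ 0.05; the frequency
floor removes lone stray reads at well-covered sites (1 alt read in 31 is
an error, not a genotype). The 0.05 rule is applied to both alleles
symmetrically — that is the only reading under which "only REF observed"
is defined at all. Note dp ≥ 1 always observes at least one allele (the
two frequencies sum to 1), so the four (M, W) cases are exhaustive.

The clonal assumption is that somatic variants co-occur: cells of a clone
share its variant set. This makes M approximately low-rank, M ≈ C·V with
non-negative cell factors C (n_cells x K) and variant factors V
(K x n_vars), and the weighted cost

    E = Σ_ij W_ij (M_ij − (CV)_ij)²

ignores unobserved entries instead of imputing them. Structureless noise
variants inflate E but not the factors; correlated confounders (cell-type
specific RNA edits) would mislead the factorization, which is why they are
filtered by annotation upstream.

## Filtering grid

Fixed filters: RepeatMasker repeat regions (any positional overlap with a
BED interval, 0-based half-open converted to the VCF's 1-based positions),
REDIdb RNA edits, and low coverage (DP ≥ 2 in < 10% of cells; exactly 10%
passes, and the comparison uses integer covered-cell counts with an
epsilon guard so the boundary is not lost to floating-point rounding).

Six candidate subsets: {germline included, excluded} x {MAF > 2%, 5%, 10%}.
MAF here is the fraction of *covered* cells (DP ≥ 2, mirroring the coverage
filter's threshold) in which the variant's minor allele is observed under
the allele-observed rule; the comparison is strict (>). Germline SNPs stay
in half the grid on purpose: hets lost (VAF→0) or fixated (VAF→1) in the
cancer clone are deletion/LOH markers. Empty subsets are retained (they
simply lose model selection); subsets with fewer than 10 variants or fewer
than K are skipped and logged by the pipeline.

## wNMF fitting

Alternating exact minimization: with C fixed, E separates per variant
column into an independent weighted non-negative least-squares problem
with design C and weights W_:,j; with V fixed, symmetrically per cell row.
Each small (K-dimensional) weighted NNLS is solved exactly in Gram form by
enumerating all 2^K − 1 candidate active sets, batched over all columns at
once — exact for the K ≤ 6 used here, and fast enough to make the
bootstrap grid desk-scale. The previous iterate is always kept as a
candidate, so each half-step can only lower the cost and the recorded
per-iteration cost trace is non-increasing by construction. The public
`solve_weighted_nnls` solves the same problem by √w row scaling plus an
exact active-set NNLS routine; tests assert the two routes agree.

Numerical choices:

* Initialization: C ~ i.i.d. uniform(0, 1) from a user seed; fits are
  bit-reproducible given the seed.
* Stopping: at most `n_iter` = 100 EM iterations, early stop when the
  relative cost decrease over 5 iterations falls below 1e−6 (an
  optimization that cannot raise the cost).
* Cells/variants whose weights are entirely zero are dropped before
  fitting and reinserted as zero rows/columns after.
* A factor column of C collapsing to zero is re-randomized once; if the
  cost has not improved by the end of the next iteration the previous
  state is restored and the model is flagged `degenerate` (plain
  re-randomization would break the monotone-cost contract).
* No normalization during fitting; the scale gauge is fixed only where
  factors are compared (below).

## Bootstrap, alignment, selection

Robustness is measured by refitting on 50 (default) random 90% variant
subsamples. Because C·diag(a), diag(1/a)·V is cost-equivalent for any
a > 0, each replicate is first brought to a canonical gauge — C columns
scaled to unit L2 norm, magnitudes absorbed into V — otherwise entrywise
means and variances across replicates are meaningless. Replicates are then
aligned to the first replicate's factors by maximizing the summed cosine
similarity over column permutations (optimal bipartite matching; equal to
brute force for K ≤ 6). Mean/variance of C are over all replicates; each V
column uses only the replicates that drew that variant (variants drawn in
fewer than 5 replicates are flagged low-confidence, never-drawn ones are
zeroed and flagged).

Candidates (subset, K) are ranked by the orthogonality score of mean C,
s = −mean pairwise cosine over unordered column pairs (an ordered-pair
reading only doubles sum and normalizer, ranking identically). s ∈ [−1, 0]
for non-negative C; zero-norm columns contribute 0 to their pairs.
Largest s wins; ties break by smaller K, then fewer variants (stricter
filtering) — parsimony. Default K grid {2, 3, 4}: healthy + cancer plus
room for one subclone, while keeping the grid desk-scale. Candidates with
a collapsed mean factor are excluded; if all are, selection raises rather
than returning a meaningless winner. The weighted error E itself is never
compared across subsets (different variant counts and MAF profiles make it
incommensurable).

## Annotation

Cell assignment normalizes each row of mean C to sum 1 (NMF scale
ambiguity again) and assigns the argmax factor unless the top-two margin
is < 0.3 → "undetermined"; all-zero rows are undetermined. Factor
labelling: a factor "contains" known-healthy cells if > 1% of its assigned
cells carry a known-healthy type (tolerance 0, configurable, reproduces
the literal any-single-cell rule; 1% absorbs isolated mislabelled cells).
Factors containing none are cancer, the rest healthy. With fewer than 20
known-healthy cells dataset-wide (a declared default; the switch point is
a judgment call) the rule runs inverted on known-cancer types. Success
requires both labels to occur. Samples with < 3% known-healthy cells are
flagged as below the inclusion threshold.

Clone-associated variants: V columns normalized to sum 1 across factors
(mirroring the cell-side convention), selected iff max−min normalized
weight > 0.3 and ≥ 20% of each non-empty clone's cells cover the variant
(W > 0, the weakest coverage notion consistent with the weights). The
exported table adds per-clone coverage and per-clone mean discretized VAF
over covered cells for heatmap-style inspection.

## Synthetic data

The generator emulates a 10X-like tumour sample at the variant-call level.
Defaults: 500 cells, clones 60% healthy / 40% cancer, 30 somatic SNVs
(het, cancer-private), 50 germline hets, 10 LOH events (half allele loss,
half fixation in the cancer clone; flagged dbSNP-common, as real LOH
markers are germline SNPs), 200 noise variants; site expression
probability p_expr = 0.3, depth 1 + Poisson(3) at expressed sites, 20%
per-allele dropout at het sites (both alleles dropping leaves the site
unobserved), 1% per-read error flips, and a 0.05 per-covered-cell spurious
ALT rate at noise variants. Cell types: 30% of healthy cells are named
T_cell, 30% of cancer cells blast, the rest HSC — enough prior cells for
factor labelling while leaving most cells unlabelled, as in real samples.

What it does not emulate: transcriptome structure (expression is i.i.d.
per site, no gene-level or cell-type-specific coverage bias), correlated
artefacts such as cell-type-specific RNA edits, subclonal hierarchies,
doublets, or UMI duplication structure. Passing recovery tests on these
data therefore shows the pipeline is correct under its own model — clean
co-occurrence plus independent sparsity/noise — not that it will succeed
on any given real tumour, where correlated confounders and lower signal
are the main hazards.

`subsample_counts` thins ALT and REF counts independently and binomially
and recomputes DP as their sum (AD ≤ DP by construction), emulating lower
sequencing depth; recovery degrades monotonically with the retained
fraction on the default sample, reproducing the expected coverage
dependence qualitatively.

## Problem sizes and test scale

Integration tests run a reduced sample (150 cells, 84 variants, K = 2, 3
bootstraps) for speed; the recovery check runs the full default sample with
the complete 6-subset x K∈{2,3,4} grid at 10 bootstrap replicates, and the
subsampling-trend check uses K∈{2,3} at 10 replicates over 3 seeds. These
sizes are the package's own test-scale choices; the method's defaults (50
bootstraps, K {2,3,4}) are unchanged for real use.

## Known limitations

* Factors are flat: no subclone hierarchy or phylogeny is reconstructed.
* Selection by orthogonality can prefer any strong binary partition; if a
  correlated non-somatic signal (e.g. unfiltered RNA edits) dominates, the
  clones returned will track it.
* Very small clones are fundamentally hard: their cost contribution
  approaches noise, and populations under ~10% frequency are unlikely to
  be captured.
* The undetermined threshold (0.3), variant-difference threshold (0.3) and
  coverage threshold (20%) are fixed conventions, not fitted quantities;
  they are configurable in `RunConfig`.
* Multi-allelic sites are treated as independent (ref, alt) pairs.
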