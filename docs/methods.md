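# Methods

## Scope and data model

The package starts downstream of alignment and peak calling: its inputs are
aligned barcoded long reads (BED12 blocks plus a barcode/UMI sidecar or
delimited read names), a cell-barcode whitelist, a cell annotation table
(barcode, sample, cell_type, subtype, condition), a GTF gene annotation, a
10x-dialect fragments file, a peaks BED, and a target-gene list. All
coordinates are held 0-based half-open internally; GTF (1-based inclusive) is
converted at the reader and writer only. Chromosome-name dialects are never
translated silently.

## From reads to molecules

1. **Barcode calling** is exact-only by default: a read is kept iff its
   barcode candidate equals a whitelist entry. A one-mismatch rescue
   (accepted only when exactly one whitelist entry is within Hamming
   distance 1) exists behind `max_mismatch=1` but is off by default because
   conservative calling costs reads, not correctness.
2. **Gene assignment** gives a read to the gene whose body contains ≥ 80% of
   its aligned bases on the matching strand; if a runner-up gene is within 5
   overlap-percentage points, the read is ambiguous and dropped. Both numbers
   are package defaults exposed in the API; they are deliberately strict so
   that molecule counts per gene are conservative.
3. **UMI deduplication** treats "same molecule" as Levenshtein distance < 4
   between 10-mer UMI candidates of reads sharing one (barcode, gene). Only
   the pairwise rule is principled; how to extend it to sets is a design
   choice, and we use single-linkage (transitive closure), the simplest
   extension. The cluster representative UMI is the candidate supported by
   most reads (ties: lexicographically smallest); representative blocks come
   from the longest member read. Output is invariant to read input order. A
   Hamming-only distance mode exists for callers who want substitution-only
   matching. Distances are computed with edlib.

## Exon inclusion calls

A molecule is an **inclusion** for an exon when one of its *internal* aligned
blocks (spliced on both sides) matches the exon's start and end within ± `tol`
bp (default 0); an **exclusion** when an inter-block gap (intron) fully
contains the exon; otherwise **uninformative** — reads that end inside the
exon or its flanking introns, or overlap it partially, contribute nothing.
This is conservative by construction: every counted molecule carries
unambiguous splice evidence. Inclusion and exclusion are mutually exclusive,
and the call ignores strand given identical blocks.

## Differential exon inclusion

Per exon with ≥ `min_reads` (default 10) informative molecules in both
groups: ΔΨ = Ψ_A − Ψ_B and a two-sided Fisher exact test on
[[inc_A, exc_A], [inc_B, exc_B]] (conventional definition: sum of table
probabilities ≤ the observed one; verified against exact integer
hypergeometric enumeration to 1e-10 over all margins ≤ 30). The per-exon
p-values of one comparison form one family and are adjusted with
Benjamini–Yekutieli, whose penalty c(m) = Σ 1/i keeps FDR control under the
arbitrary dependence created by shared molecules and genes. Significance
requires p_adj < α (0.05) and |ΔΨ| ≥ 0.1; at most 5 significant exons are
kept per gene (smallest p_adj, ties by larger |ΔΨ|, then leftmost
coordinate). The direction bias of a significant set (fraction of exons
shifted toward one condition) is tested against 0.5 with an exact two-sided
binomial test.

The molecule-level association of two exons ("coordinated splicing") is a 2×2
table over molecules informative for both, with a two-sided Fisher p and the
phi coefficient; phi = +1 means the exons are always included or excluded
together on the same molecules.

## Differential chromatin accessibility

Accessibility is binarized: peak j is detected in cell i when ≥ 1 fragment of
that barcode overlaps it by ≥ 1 bp (a fragment overlapping k peaks counts for
all k, weighted by its duplicate count). Peaks detected in < 2% of the
comparison's cells are dropped. The default test (`fisher_binary`) is a
two-sided Fisher exact test on detection counts — transparent and exactly
testable against the same enumeration oracle. `lr_depth` offers a logistic
likelihood-ratio test of detection on group with log total fragments per cell
as covariate, approximating depth-adjusted practice; on separation or
non-convergence it falls back to the exact test. Peak p-values are adjusted
with Benjamini–Hochberg by default (BY by flag). The effect size is
log2((frac_A + ε)/(frac_B + ε)) with ε = 1e-3 to avoid log 0.

Peak context is assigned by midpoint with precedence UTR > exon > intron
(inside a gene body, no exon) > intergenic. The nearest gene is by gene-body
distance (0 if overlapping; ties by TSS distance, then gene id), and a peak is
"in target" when its nearest gene belongs to the target panel and lies within
`max_dist` (default 50 kb — a package default; "vicinity" has no canonical
radius). Peak-set similarity is the Jaccard index over merged interval sets,
basepair mode (intersection bp / union bp; invariant to splitting intervals
into adjacent pieces) or a symmetric overlap-count mode.

## Power-equalizing downsampling

Groups differ in cells, reads, and testable units, so raw %-significant
numbers confound effect prevalence with power. Per iteration the framework:

- **splicing** — restricts to exons with ≥ `reads_per_exon` (default 20)
  informative molecules per group, samples ≤ `exons_per_gene` (1) eligible
  exons per gene then `exons_per_iter` (100) exons without replacement,
  subsamples exactly `reads_per_exon` molecules per exon and group (a
  hypergeometric draw of inclusions), retests, BY-adjusts within the
  iteration, applies the |ΔΨ| ≥ 0.1 filter (switchable off), and records
  100 · #significant / #tested. Default 100 iterations.
- **chromatin** — samples `cells_per_group` (1,000) cells per group without
  replacement, re-applies the 2% detection filter on the sampled cells (the
  desk-scale surrogate for re-calling peaks per sample), restricts to
  target-vicinity peaks, samples `peaks_per_iter` (10,000) peaks — or
  `peaks_per_category` (5,000) per UTR/exon/intron/intergenic category when
  stratified — retests and records the passing percentage. Default 20
  iterations.

"20 reads per exon" is interpreted per group (balanced 20 × 20 tables);
`balanced_reads=False` marks the alternative reading. Sampling is without
replacement at every level; with-replacement is refused because it changes
null behavior. When fewer eligible units exist than the budget, all are used
and the shortfall is recorded per iteration rather than silently changing
denominators. All sampling derives from one `numpy` Generator seeded from the
config, so identical config + seed gives bit-identical distributions.

Distributions are compared with a two-sided Wilcoxon rank-sum test (exact
when both samples have ≤ 25 values and no ties, otherwise the normal
approximation with tie correction) or a paired signed-rank test for matched
iterations. Target genes can be stratified into disease-only / synaptic-only
/ both (D+S− / D−S+ / D+S+) by exact set algebra for stratified runs.

The FDR family is each iteration's sampled test set: the family the analyst
actually sees per iteration, and it keeps iterations exchangeable.

## Synthetic multiome generator

`simulate` plants ground truth and emits exactly the formats the readers
consume. Genes are non-overlapping on one synthetic chromosome
(`exons_per_gene` constitutive exons of 100 bp, 300 bp introns, first exon
annotated as UTR) with alternative internal exons centered in their own
introns; each such gene gets one transcript including and one skipping them.
Molecules pick a uniform gene per read, include each alternative exon with
the cell group's Ψ (independently, unless a coordination coefficient couples
all alternative exons of a molecule to one Bernoulli draw — coefficient 1
reproduces perfectly coordinated splicing). PCR duplicates follow
1 + Geometric(duplication rate) reads per molecule; duplicate UMI copies
carry exactly one substitution while molecule UMIs within a (cell, gene) are
kept at pairwise distance ≥ 6, so duplicates provably collapse under the
distance-4 rule and can never chain two molecules into one single-linkage
cluster. Fragments are drawn per cell from per-peak Bernoulli accessibility;
accessible peaks receive 1 + Poisson fragments with the rate set from the
target fragments-per-cell (function default 7,500, matching the
7,000–8,000 high-quality fragments per cell of the motivating experiments),
and a noise fraction lands uniformly outside peaks. A detection-level
shortcut (`simulate_peak_matrix`) draws the binarized cell × peak matrix
directly for power studies. A count-level shortcut
(`simulate_inclusion_counts`) does the same for exon tables.

What the generator does *not* model — sequencing errors on genomic bases,
realistic read-length and fragment-size distributions, barcode errors,
doublets, batch and donor effects, correlated accessibility between nearby
peaks — bounds what passing tests show: they validate the statistical
machinery and its calibration on clean planted truth, not robustness to
upstream artifacts of real libraries.

## Problem sizes used in the validation suite

The motivating experiments are far beyond desk scale (tens of millions of
reads; 10⁵ peaks per cell type), so the test suite and the acceptance script
run the identical code paths at reduced scale, chosen so every assertion has
adequate Monte-Carlo resolution: null calibration on 550 simulated genes with
300 cells (splicing) and 2,000 peaks with 600 cells (chromatin); the
power-equalization harness on count-level tables of 3,000 exons (the scale of
a targeted splicing panel) at 4× depth ratio, 20 replicates; effect-ordering
harnesses with planted prevalences 0.3/0.1/0.0 over 20 runs per modality; the
acceptance script on 300 genes / 1,000 peaks with 300 cells per arm. Preset
datasets use 800 (ATAC presets) or 300 (multiome preset) fragments per cell —
depth only needs to support detection, which saturates far below study-scale
depth.

## Numerical and degenerate-input choices

- Fisher exact p-values come from `scipy.stats.fisher_exact` and are cached
  on the 2×2 counts; downsampling reuses the cache heavily since subsampled
  margins are fixed.
- Benjamini–Yekutieli / Benjamini–Hochberg use `statsmodels.multipletests`;
  inputs outside [0, 1] raise.
- Empty exon tables and empty peak sets return empty results, not errors;
  zero eligible exons in downsampling raises naming the binding constraint
  (reads per exon).
- Jaccard of two empty merged sets is undefined and returned as `None`.
- Identical distributions (all values tied) get rank-sum/signed-rank p = 1
  directly, where the asymptotic formulas would divide by zero.
- Ψ of a group with no informative molecules is NaN and the exon is not
  tested.
- Tie-breaks are deterministic everywhere (lexicographic UMIs and gene ids,
  leftmost coordinates), so every pipeline stage is byte-reproducible given a
  seed.

## Known limitations

- Exon inclusion calling requires boundary matches within ±tol (default
  exact); aligners with imprecise splice-site placement need a nonzero
  tolerance, at the cost of occasionally counting near-miss exons.
- The detection-based chromatin test ignores per-cell depth by default;
  `lr_depth` adjusts for it but is asymptotic, slower, and falls back to the
  exact test under separation.
- Downsampling iterations reuse one observed dataset, so per-iteration values
  are not independent samples; rank tests between two *such* distributions
  are well calibrated only when the eligible pool is much larger than the
  per-iteration budget (see the power-equalization harness, which uses a
  3,000-exon pool for 100-exon iterations).
- Cross-species or cross-batch peak correspondence must be resolved upstream;
  the package assumes peaks of one comparison live in one coordinate frame.
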