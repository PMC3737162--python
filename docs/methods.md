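# Methods

`linescape` re-implements, as a tested pipeline, the genomic and
transcriptomic characterization computations used to profile a heavily
aneuploid cultured cell line against a reference genome: integer
copy-number (CN) calling from binned read depth, loss-of-heterozygosity
(LOH) segmentation, trinucleotide mutational spectra, structural-variant
(SV) filtering, construction of a personalized reference with coordinate
translation, allele-specific dosage-compensation analysis, and
expression-outlier detection against a tissue panel.  Every stage is
exercised end-to-end on synthetic data with known ground truth; the real
data such a pipeline targets (deep WGS and RNA-seq of a cell line) are
controlled-access and far beyond desk scale.

## Copy number from binned read depth

Per-base depth is averaged in fixed windows (default 10 kb).  Each bin is
divided by its *mappable fraction* — the fraction of read-start positions
whose 101-nt k-mer occurs exactly once over both strands of the genome —
and bins with fewer than half their positions mappable are set to NA and
never resurrected by any later stage.

**GC adjustment.** Coverage depends smoothly and unimodally on bin GC
fraction.  The curve f(gc) is estimated by a local quadratic regression
with tricube weights (LOESS-style k-nearest-neighbor bandwidth, span 0.3
of the points) with bisquare robustifying iterations, and the adjusted
value is `value / (f(gc) / target)` with a default target of 60.
Two design points matter here and were found the hard way:

* the fit is computed on coverage *divided by a per-chromosome running
  median* (15 bins).  The running median carries the local CN level, so
  the remaining ratio depends on GC alone.  Fitting raw coverage on GC
  instead confounds the curve with whichever CN states happen to occupy a
  GC window and can shift whole segments by a full copy;
* the robustifying iterations make the curve follow the dominant local
  behavior rather than the mean of a CN mixture.

**Calibration.** The log2 ratio is taken against `x0`, the median
adjusted coverage of a user-supplied calibration region of known CN
(canonically a curated CN-2 region; a region of any known CN is accepted
and rescaled by `2/region_cn`).  The whole chain is invariant to a global
rescaling of the coverage track — `x0` absorbs it — which is tested.

**Segmentation.** Changepoints are found per chromosome by recursive
*arc* (circular binary) segmentation: each candidate segment is scanned
for the pair (i, j) maximizing the t statistic between the arc and its
complement, with significance calibrated by permuting bins within the
segment (alpha 0.01, up to 1000 permutations, early-stopped once the
decision is determined, seeded).  An arc touching an edge is a single
split; an interior arc captures a dip or bump whose effect a single-split
scan systematically halves.  A final *sd-undo* pass merges adjacent
segments whose mean difference is below `undo_sd` (default 2) noise-SD
units on the standard error `sd * sqrt(1/n1 + 1/n2)` of the difference;
the noise SD comes from the median absolute first difference, which is
blind to the level shifts the segmentation looks for.  Scaling the undo
threshold by the standard error rather than by the raw SD keeps genuine
CN steps (which are ~1 SD of per-bin noise apart on the log2 scale at
realistic noise) while still undoing splits far below the noise floor.
Known resolution limit: levels of ~3 bins at a chromosome edge, or dips
separated by only a few bins, can fall below the permutation test's
detection limit and merge with a neighbor.

**Integer assignment.** Segment means `s` become CN estimates
`2^(s+1)`, to which a mixture of m = 8 normal components with means fixed
at 1..m (weights and SDs free) is fitted by EM (deterministic
initialization: uniform weights, common SD equal to the data SD;
convergence at log-likelihood change < 1e-8 or 500 iterations; the
log-likelihood is asserted non-decreasing at every step).  Segments are
weighted by bin count, so the fit follows genome fraction; a flag
restores unweighted fitting.  Component SDs are floored at 0.01 CN units:
segment estimates carry at least that much fit wobble, and letting an SD
collapse to ~0 makes the Bayes classifier assign near-integer estimates
to a leftover broad component rather than the obvious nearest one.
Each segment then gets the component with maximum posterior (mixture
weights as priors), requiring posterior >= 0.95, else NA; segments with
estimate below 0.5 — half the expectation of a single copy — are called
CN 0 before mixture classification, since the fixed-mean mixture has no
zero component.

## Zygosity and LOH

The proportion of homozygous SNV calls is computed in 100-kb bins
(zygosity from the VCF genotype: `1/1`-type is homozygous; without a
genotype, allele fraction >= 0.9).  Bins without calls are NA and are
excluded from segmentation rather than imputed — SNV deserts carry no
zygosity evidence and imputing them manufactures LOH.  The binned
proportions are segmented with the same changepoint machinery, and a
segment is homozygous iff its mean proportion is strictly above 0.5.
Both the segmented blocks and the direct per-bin classifier fraction are
reported, since either can be the basis of a genome-wide homozygosity
figure.  Copy-number-1 territory is genuinely homozygous (hemizygous), so
interpreting homozygous blocks as *copy-neutral* LOH requires CN >= 2,
which is the joint analysis left to the caller.

## Mutational spectrum

SNVs are classified by substitution type and flanking bases into a
4 x 4 x 6 matrix (preceding base x following base x the six
pyrimidine-based types C>A, C>G, C>T, T>A, T>C, T>G).  Purine-reference
calls are mapped to the pyrimidine strand by reverse complement, which
swaps and complements the flanks.  Counts are divided by the genomic
frequency of each source triplet (computed from the supplied reference
with the same pyrimidine-centering, so ACA pools with its image TGT) and
rescaled to sum to 100.  Because of that final rescaling the cells are
shares, not rates: comparisons across genomes of different composition
are exact only for rate *ratios*, which is what the invariance test
checks.  The local-coverage filter keeps calls with coverage in [10, 60],
bounds inclusive (a flag changes this); at ~10x per copy this window
corresponds to CN 1..6.  Chromosome-edge calls and ambiguous-base
contexts are skipped and counted; reference-base mismatches are collected
per record, never silently tallied.

## SV filtering

Externally produced calls pass a rule cascade with one primary reason
code per drop: population-panel frequency above 0.5% (coordinate overlap
defines call equivalence; the boundary is inclusive — at most 0.5%
survives) or presence in designated germline samples; paired-end support
< 2; missing split-read support; split-read identity < 90% (90.0 is
kept); deletions overlapping SINE/LINE repeats (an input annotation, not
computed); inversions without support on both sides.  Last, among
surviving same-type intrachromosomal calls, any pair with >= 10%
reciprocal overlap (both ratios >= 0.10) is removed — both members by
default, the lower-support member with `keep_best`.  Kept deletions are
homozygous iff the median per-bin coverage over their interval is
strictly below 1.

## Personalized reference and coordinate translation

Only homozygous, non-overlapping simple edits are integrable: SNVs,
deletions, insertions, in the VCF anchor-base convention internally
converted to 0-based end-exclusive edits.  Overlapping edits — including
an insertion at an edited position — are rejected with the conflicting
pair, and every ref allele is verified against the sequence before
anything is applied.  Applying a plan yields the modified sequences
(chromosome names and count unchanged), a per-class report, and a
block-wise coordinate map: equal-length aligned blocks plus deletion
(source-only) and insertion (destination-only) gap records.  Positions in
matched blocks lift by offset in either direction; positions in gaps
return an explicit unmapped result carrying the nearest mapped
coordinates on both sides — lossless and unambiguous, rather than a
silent nearest-base projection.  Round-trip identity over mappable
positions and exact length accounting are tested properties.

## Expression analyses

Counts are normalized with median-of-ratios size factors (reference =
per-gene geometric mean over samples; the factor is the median ratio over
genes expressed everywhere, with an optional positive-entry fallback for
sparse matrices).  Expression per gene is normalized counts per kilobase;
log10 of that value is the working scale, undefined (NA) at zero.

**CN dependence.** Genes are grouped by the CN of their locus; expressed
genes' log10 values are compared between adjacent CN groups with the
two-sided Wilcoxon rank-sum test (exact for group sizes under 20 without
ties, normal approximation with continuity and tie correction otherwise),
and per-group ECDFs are returned.  "Expressed" reuses the non-expression
rule below as its complement.

**Allelic dosage compensation.** At heterozygous sites in CN-3 regions
with total RNA depth >= 10, the higher-allele fraction
higher/(higher+lower) is summarized by its median with a seeded
10,000-resample bootstrap 95% CI, plus the distances of the median to 2/3
(both copies of the duplicated allele transcribed — no compensation) and
to 1/2 (allele-specific silencing of the extra copy).  Note the
max/min folding biases single-site fractions above the underlying
binomial p, which is why the statistic is the median at adequate depth.

**Outlier detection.** Panel values are variance-stabilized as
log2(normalized count + 1) — a documented proxy with the consequence that
z values are comparable only within a run; a fitted mean-variance
transform is out of scope.  Per gene, the panel (16 samples) yields mean
and SD (n-1 denominator); x is the mean of the stabilized cell-line
replicate values, and z = (x - mean)/SD.  A gene is *overexpressed* if
z > 3, *non-expressed* if the replicates' mean normalized counts per
kilobase fall below 1, *indeterminate* where the panel SD is 0 (no
epsilon floor — that would silently inflate z), otherwise within range.
Overexpression takes precedence over the low-expression label.

## Virus integration

Read pairs with exactly one mate on a host contig and one on a viral
contig are chimeric candidates; both-host and both-virus pairs are
discarded with counts, unknown contigs are an error.  Host-side intervals
are clustered by single linkage, merging intervals that overlap or lie
within `max_gap` (default 1000 bp; 0 restores strict overlap, but
paired-end host footprints rarely literally overlap).  Members of a
cluster must share the viral contig, or — at family level — the virus
family, which recovers sites whose support is split across similar viral
references.  Clusters below `min_support` (default 2: a lone chimeric
pair is indistinguishable from a mapping artifact) are set aside but
remain inspectable.  Family-level clusters are a coarsening of
virus-level clusters, which is tested.

## Synthetic data generator

The generator is first-class, tested code and defines the study
conditions:

* **Genome**: 2 chromosomes x 5 Mb by default, sequence drawn with
  per-10-kb-window GC targets ~ Normal(0.45, 0.07) clipped to [0.2, 0.8],
  so GC bias has compositional structure to act on.  CN truth is
  piecewise constant (geometric segment lengths, mean 60 bins, minimum
  8), drawn from a hypotriploid prior with mode 3 at 0.55; adjacent
  equal draws merge, keeping the marginal equal to the prior.  LOH blocks
  are placed deterministically (default 0.5/1/2 Mb, separated by 1.5-Mb
  heterozygous stretches — LOH blocks in real tumors are separated by
  megabases, and changepoint detection legitimately degrades when
  designed gaps shrink to a couple of bins).
* **Mappability** is an exact both-strand k-mer census (positions whose
  101-mer occurs once are mappable), implemented as a vectorized
  polynomial hash with byte-level verification of hash-duplicate groups,
  so collisions cannot corrupt the result.
* **Coverage**: expected value = CN x per-copy coverage (default 10x,
  putting CN 1..6 at 10-60x) x quadratic GC bias (peak 0.45, curvature
  8) x mappable fraction.  Noise is negative binomial with dispersion
  0.05 at the fragment-site level: a bin is the mean of
  bin_size/read_length (~99) iid NB draws, landing the per-bin
  coefficient of variation at the few percent real 10-kb binned coverage
  shows at this depth.  A single NB draw per bin would instead give ~26%
  CV — noisier than any real binned coverage — under which integer CN
  recovery at these scales is information-theoretically out of reach.
  Dispersion None/0 returns the expectation exactly.
* **SNVs**: emitted at het 1e-3 / hom 6e-4 per base; inside LOH blocks
  every call is homozygous, CN-1 territory emits only homozygous calls,
  CN-0 territory emits nothing.  Het alt fractions are Binomial(depth,
  k/CN) with k uniform in 1..CN-1; local coverage is the bin's simulated
  coverage.
* **Expression**: gene lengths log-uniform 0.5-10 kb tiled with 2-kb
  gaps; per-gene baseline rates log-normal; panel samples add log-normal
  tissue noise (sd 0.3) and NB counting noise; cell-line replicates scale
  linearly with the locus CN.  Outlier genes are injected at a target
  true z in [5, 12] on the stabilized scale computed from the realized
  panel; silenced genes get zero counts.  RNA allele counts at CN-3 het
  sites are Binomial(Poisson(50) depth, 2/3) with the duplicated allele
  chosen at random; the silencing scenario mixes 1:1 (70%) and 2:0 (30%).
* **SV call set**: 200 calls on disjoint coordinate slots, each either
  satisfying all filter rules or violating exactly one, with boundary
  calls sitting exactly on the documented thresholds and a coverage track
  that makes designated deletions homozygous.
* **Chimeric pairs**: each planted insertion emits 5 supporting pairs
  with the host mate within ~400 bp of the site; 100 background host-host
  pairs are added.  Insertion sites are drawn >= 50 kb apart.

Everything is deterministic given the seed: each stage derives an
independent generator stream from (seed, stage salt), so outputs are
byte-identical across runs and insensitive to call order.

What the generator does *not* emulate: raw reads or aligner behavior,
autocorrelated GC along the genome (windows are independent), mapping
artifacts and repeat structure (mappability of random sequence is ~1),
caller-specific genotyping error, subclonal mixtures, and chromothripsis
breakpoint mechanics.  Passing tests therefore demonstrate that the
algorithms recover truth under a clean, statistically honest forward
model — not that they are robust to every artifact of real sequencing
data.

## Problem sizes and numerical choices

End-to-end studies run on 2 x 5 Mb genomes at 10-kb bins (1,000 bins),
10-Mb chromosomes for the LOH study (100-kb bins), 50,000 SNVs for
spectrum conservation, 200 SV calls, ~10,000 genes for the z-score
operating characteristics, and 1,000 sites for the allelic-ratio
statistic — sizes at which every recovery property stabilizes while a
full run of the acceptance script stays under a minute.  Permutation
segmentation uses up to 1000 permutations at alpha 0.01 with decision
early-stopping; the bootstrap uses 10,000 resamples; EM runs to 1e-8
log-likelihood tolerance.  Ties and degenerate inputs are resolved as
documented above (strict inequalities at every threshold boundary:
hom proportion > 0.5, z > 3, counts/kb < 1, median coverage < 1,
estimate < 0.5; inclusive at panel frequency <= 0.5%, identity >= 90%,
overlap >= 10%, coverage in [10, 60]).
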