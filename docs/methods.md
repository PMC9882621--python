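# Methods

This note documents the models and procedures `mitokit` implements, the
defaults that matter, the design choices made where the design was open,
and what the synthetic fixtures do and do not emulate.

## Coordinate model

All internal coordinates are 1-based inclusive, matching VCF and SAM; BED
I/O converts from 0-based half-open at the boundary. The mtDNA is modeled
as a circular contig: position arithmetic is modular in the contig length
L, and an interval with start > end wraps through the linearization origin
(the L|1 junction). The control region wraps the origin by construction
(default 16024–576 at rCRS scale).

## Region catalog

The non-coding-region landmarks ship as a packaged default (control region
16024–576; CSBII 299–315; CSBIII 346–363; LSP 392–445; heavy-strand origin
zone 110–191; 7s-DNA span 16106–191), derived from standard rCRS
annotations; every coordinate is overridable through a plain-text config.
Three regions are derived rather than configured: the **DNA-primer** region
(between the heavy-strand origin and CSBII — the transient replication
flap), the **RNA-primer** region (between CSBIII and the LSP), and the
**first third of the 7s DNA**. The "first third" is counted (floor of a
third of the span, by base count) from the boundary nearer the wrap origin,
walking into the span — the replication-proximal end. The three derived
regions are checked to be pairwise disjoint at catalog construction. On toy
genomes shorter than the mtDNA, defaults that do not fit are dropped and
the fixture supplies scaled-down coordinates.

## Per-sample self-reference and liftover

The consensus genome is the reference with the sample's homoplasmic calls
applied as edits. The homoplasmy threshold for consensus inclusion is
**0.95** (the same operational homoplasmy definition used throughout), and
nuclear homozygous-alternate calls are accepted by the same rule on their
contigs. Overlapping candidate edits keep the higher fraction, then the
leftmost.

The coordinate map aligns the first `min(len(ref), len(alt))` bases of each
edit positionally; surplus reference bases are deletions (anchored to the
left flanking consensus base), surplus alternate bases insertions (anchored
to the left flanking reference base). Mapping is monotone and exactly
invertible outside edit footprints; interior positions return anchored
results with `inside_insertion` / `inside_deletion` flags. The map
serializes as a chain-style text of match/insert/delete block lengths.

Lifting a consensus-space call that overlaps an edit reconstructs the
asserted local haplotype (consensus flank + call alternate + consensus
flank) and re-expresses it against the reference slice covering both the
call and the edit, then parsimony-trims and left-aligns. Each consensus
edit is additionally re-emitted as a reference-coordinate call with
heteroplasmy `1 − Σ(fractions of lifted calls at that site asserting a
different allele)`, floored at 0 — the reads that did not contradict the
consensus support the edit allele. Calls that compose back to the reference
allele are dropped from output but still compete in that subtraction.

Coverage liftover copies depths at unedited/substituted positions, lets
deleted reference positions inherit the left flanking consensus depth, and
drops depths at inserted consensus bases (the documented alternative —
mean of flanks — is a one-line change). An exact bookkeeping identity
(total out = total in − inserted depths + duplicated flank depths) is
asserted in tests.

Indel normalization follows VCF convention: shared suffix then prefix
trimmed, pure indels left-aligned through homopolymer context, so poly-C
events at chrM:302 anchor identically across samples.

## Read placement, pileup, and the dual pass

Read placement against the mtDNA consensus plus NUMT decoys is exact
k-mer seeding (k = 21) with ungapped extension; each read goes to the
target with the fewest mismatches and **ties go to the decoy** — a
deliberate bias against manufacturing false heteroplasmy from NUMT reads.
In the pipeline, placement decides only the winning target; the read's
original alignment (position and CIGAR, which may carry indels) is kept
for pileup, with positions mapped through the coordinate map for the
consensus pass. This is exact when consensus edits are substitutions and
approximate for reads overlapping indel edits; gapped realignment is out
of scope.

Pileup uses modular coordinates, so reads spanning the circular origin are
counted correctly. Depth excludes duplicate, secondary, and unmapped reads
and bases below quality 20 (configurable; the threshold of a production
somatic caller is not published, 20 is a conventional floor). A call is
emitted whenever an alternate is supported by >= 2 reads — deliberately
permissive, because all fraction thresholds belong to post-calling QC.

Real aligners cannot wrap, which depresses coverage at the linearization
breakpoints; the pipeline therefore emulates linear alignment (reads
crossing a breakpoint are lost) and calls the control region in a second
pass against a molecule rotated by `floor(L/2)` — the rotation that
maximally separates the two breakpoints (the rotation amount used by
production pipelines is not published; any value far from 0 works and it
is configurable). Merged output takes control-region calls exclusively
from the shifted pass and everything else exclusively from the primary
pass, with membership evaluated on the lifted reference position.

## Copy number

`mean nuclear coverage = (total mapped − singletons − discordant-mate reads
− duplicates) × read length / genome length`, clamped at zero with a
warning for inconsistent inputs; the flagstat category definitions are
documented inputs since tools differ at the margins. `mtCN = 2 × (mean or
median mtDNA coverage) / mean nuclear coverage`, mean-based by default.

## Post-calling QC

Variant level, per sample-site cell: fraction < 0.01 → reference with
stored fraction 0; [0.01, 0.05) → missing (the NUMT-enriched band);
caller-flagged → missing; no call with depth >= 100 → reference; no call
with depth < 100 → missing; fraction >= 0.95 → homoplasmic. Surviving
heteroplasmic fractions therefore always lie in [0.05, 0.95). The rules
are idempotent on their own output, and depth is read-level, so calls
removed by QC still contribute to site depth.

Sample level: drop on mtCN < 50 (strict), contamination > 0.02 (strict),
homoplasmic-variant overlap, or a configurable processing-year exclusion
set (cohort-specific batch effects; empty by default). All applicable
reasons are recorded. "Homoplasmic variant overlap" lacks a published
main-text definition; it is implemented as any site where two distinct
non-reference alleles each reach fraction >= 0.5 — impossible for a clean
sample — and is configurable.

"Common low heteroplasmy" flags variants with >= 0.1% of passing samples
at a fraction strictly between 0 and 0.5 (strict bounds chosen where prose
is ambiguous); common heteroplasmies additionally require >= 500
heteroplasmic carriers. The AD-alt sensitivity filter masks calls whose
alternate depth is strictly below the sample's mean nuclear coverage.

## CSBII length variants

The forward-strand CSBII reference motif is `AA CCCCCCC T CCCCC GC`; in
opposite-strand nomenclature G<sub>m</sub>AG<sub>n</sub>, the reference is
G<sub>m</sub>AG<sub>7</sub> and the common insertions chrM:302:A,AC /
A,ACC / A,ACCC extend the 302-adjacent run to 8 / 9 / 10. The variable
("n") tract is the **first** C-run in forward orientation — the insertion
alleles extend the run anchored at position 302, which is the first run on
the forward strand and the last G-run read on the opposite strand.

Reads are classified by `AA(CCC+[CT]CC+)GC` applied to the forward strand
(reverse alignments are reverse-complemented first); non-matching reads
are NA. When the spacer base is C, the whole tract is a single
homopolymer and the split into two runs is not identifiable from the read;
the greedy regex semantics then produce the canonical decomposition
(longest first run, second run of 2), which preserves total tract length.
Tests assert exact recovery for T spacers and the canonical
structure-preserving form for C spacers.

Single-cell profiles drop reads with non-whitelisted barcodes, require
>= 20 locus-spanning reads per cell, and report fractions over the three
globally most common (run<sub>m</sub>, run<sub>302</sub>) variants with
everything else — including NA reads — aggregated into "other" (keeping NA
in the denominator treats classification failure as an observed outcome;
the alternative would bias pure-cell fractions upward). Pseudobulk sums
allele counts over retained cells and renormalizes. Per-sample composition
from variant calls assigns reference `1 − Σ(fractions)`, floors at 0 with
renormalization, imputes missing named alleles as 0, pools unnamed alleles
into "other", and excludes samples with locus depth < 100.

## Phenotypes and covariate correction

Case-only vectors give carriers their fraction and code reference,
no-call, and homoplasmic samples missing; case-control codes any
detectable heteroplasmy as 1 and only confidently-inferred reference
(depth >= 100, QC-pass) as 0. Every case-only non-missing sample is a
case-control case by construction.

The covariate design expands draw time in a natural cubic spline with 5
df; assessment date in a natural spline with fixed quarterly knots over a
configurable span (default 2007-07-01 through 2010-07-01, 13 knots; knots
outside the observed data range are dropped, as spline bases require
interior knots within the data); center, month, and fasting hours as
indicators (fasting recoded > 18 → 18 and 0 → 1); and 14 blood indices as
continuous columns with |Z| > 4 entries masked (complete-case rows for
fitting). Month indicators plus the seasonal spline are near-collinear by
construction; aliased columns are dropped deterministically last-in and
reported.

Residualization is gated by an F-test of the covariate model against
intercept-only at α = 0.05/40 (Bonferroni over the 40-phenotype battery),
applied per covariate block with a joint option. Gated-out phenotypes pass
through unchanged. Otherwise residuals (of log values for log-scale
traits such as mtCN) get the pre-correction mean added back and are
exponentiated where applicable, keeping corrected values on an absolute
scale. Inverse-rank normalization uses the Blom offset: rank r (ties
averaged) maps to Φ⁻¹((r − 3/8)/(n + 1/4)).

Coverage-discrepancy traits are residuals of
`dna_primer ~ x * haplogroup` with x the RNA-primer or 7s-DNA median
coverage, per-sample medians over the derived regions, restricted to
haplogroups with >= 30 members. Transmission tables pair relative
fractions per variant (>= 5 heteroplasmic carriers required), with
reference contributing 0 and missing/homoplasmic excluded pairwise.
Age-accrual summaries include zero-count individuals — excluding them
would bias means upward. Carrier contrasts run Welch t-tests for variant ×
phenotype pairs with > 10 defined carrier values against pan-negative
controls, with Benjamini–Hochberg q-values over all performed tests.

## Summary-statistics layer

The association scan is covariate-projected least squares
(Frisch–Waugh–Lovell), valid for the unrelated samples the simulator
produces; a cohort-scale analysis would use a mixed model, which is out of
scope. Variants need MAC strictly greater than 20. Meta-analysis is
fixed-effect IVW (weights 1/se²; pooled se (Σw)^(−1/2)) with Cochran's Q
against χ²(k−1). Clumping is greedy: smallest-p unassigned variant seeds
an index and absorbs unassigned variants within 500 kb at r² > 0.1; equal-p
index candidates tie-break to the lower genomic position (the external
tool's tie behavior is unspecified); missing LD is treated as r² = 0 with
a warning. Leads chain into loci at a 2-Mb merge window; prior loci count
as replicated at p < 5×10⁻⁵ or 5×10⁻⁸ within 2 Mb of their top variant.

Effect-size IVW regression weights each point by (1/se_x²)(1/se_y²).
Binary-genotype PCA filters columns at MAF >= 0.001, centers and scales on
training rows, takes the top-k SVD (k = 50 by default, capped by rank),
and projects held-out rows through the training transform. McFadden's
pseudo-R² is `1 − ll_model/ll_null` (the conventional direction; the
multinomial fit backing it is maximum likelihood and only log-likelihoods
enter the formula). Disease odds ratios come from a logistic fit with
OR = exp(β) and CI exp(β ± 1.96 se); complete separation is flagged, not
estimated. CLPP is the product of GWAS and eQTL PIPs. Enrichment is the
relative risk P(annotation | PIP > 0.1)/P(annotation | PIP <= 0.01) with a
percentile bootstrap (5,000 replicates) within strata. Gene assignment
implements the rule ladder: retain CS variants that are minimal-PIP,
coding, or PIP > 0.7; coding variants at PIP > 0.9 assign their gene;
otherwise genes within 3 kb, else the nearest gene (inside a gene body
counts as nearest); with multiple credible sets and any variant at
PIP > 0.1, only PIP > 0.1 assignments survive; a locus without a credible
set assigns the gene nearest its top variant.

## Synthetic fixtures

Every generator is a pure function of (params, seed). The toy genome
plants the CSBII motif (default at 297, locus 300–318, matching rCRS-scale
coordinates) in a random circular sequence with accidental poly-C tracts
scrubbed, and copies mtDNA segments into linear NUMT decoys at a
configurable per-base divergence (default 2%, a typical NUMT divergence
scale). Reads have constant length (100 bp), uniform substitution error
(default 0.3%), optional duplicate flagging, optional barcodes, optional
start-position weighting (control-region dip), and wrap the origin; per
read, each variant is included independently with probability equal to its
fraction.

Cohorts default to the study conditions the package is built around: a
−2%/decade age slope on log mtCN centered at baseline 100 copies, three
blood indices with real effects (−0.08, 0.05, 0.03 per SD on log mtCN),
center effects (SD 0.05) and residual noise (SD 0.15); maternal
transmission of indel heteroplasmies as additive truncated-normal noise on
the fraction scale (σ = 0.03 — small against the carrier Beta(2,5)
spread, consistent with tight parent–offspring correlation); somatic SNV
counts Poisson with a piecewise-constant rate stepping from 0.3 to 1.2 per
person at age 70; nuclear QTLs (MAF 0.3, betas 0.04 and −0.03 on the
fraction scale) shifting the first indel variant. A third of samples form
mother–offspring pairs. Summary statistics use one causal variant per LD
block, within-block r² fixed at the block parameter, and the
single-variant OLS standard-error approximation.

What the fixtures do **not** emulate: indel sequencing errors and quality
ramps, mapping-quality structure, relatedness beyond mother–offspring
pairs, haplogroup phylogenetic structure, linkage between mtDNA sites,
and realistic LD decay. Passing tests therefore demonstrate algorithmic
correctness under a clean generative model, not robustness to platform
artifacts in real data.

## Problem sizes and numerical choices

The test suite runs the full per-sample pipeline on 1.2-kb toy genomes at
depth 200 (20 samples in the recovery suite), consensus round trips on
200 random edit sets at the full 16,569-base scale, calibration checks on
2,000 null variants / 2,000 heterogeneity replicates, and parameter
recovery on a simulated cohort of n = 2,000 — sizes chosen so each suite
completes in seconds while leaving the statistical checks well-powered.
The age-slope recovery test adjusts its post-hoc regression for the blood
covariates that carry planted effects, since they are structured residual
variance with respect to age. Recovery assertions use 2-SE (parameter
recovery) or 4-sigma binomial (fraction recovery) bands at fixed seeds.

Degenerate inputs are errors, not silent results: zero nuclear coverage,
empty PIP strata, all-identical values into the rank transform, fewer than
3 points into effect-size regression, fraction sums above 1 at the 302
locus. Ties: overlap resolution prefers higher fraction then leftmost;
clumping prefers lower position; aliased design columns drop last-in.

## Known limitations

- The caller is a counting model with no error-aware genotype likelihoods;
  its floor of 2 alternate reads means very deep data will emit abundant
  sub-1% calls for QC to remove (by design, but memory-relevant at extreme
  depth).
- Competitive placement is ungapped; NUMT decoys diverged mainly by indels
  would be handled poorly.
- Consensus re-calling keeps original CIGARs, so reads overlapping indel
  edits are piled up approximately.
- The OLS scan ignores relatedness; transmission analyses assume the
  pedigree is correct.
- Single-cell composition assumes barcodes are demultiplexed upstream.
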