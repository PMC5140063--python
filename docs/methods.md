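# Methods

## Scope and model

`adipoepi` re-implements, as composable library functions plus an
orchestrating pipeline, a comparative analysis of brown (BA) and white (WA)
adipocyte differentiation over five ordered stages per lineage (BA: d-3, d0,
6h, d2, d7; WA: d-4, d0, 6h, d2, d7). Inputs are expression tables (FPKM for
coding genes and lncRNAs, array signal for miRNAs), per-stage ChIP peak sets
(BED), read-position intervals (BED) or precomputed region × stage count
matrices, and refFlat gene models. Alignment, peak calling, motif discovery
and GO enrichment are upstream/downstream of this package and out of scope.

## Conventions

All coordinates are 0-based half-open (BED). Overlap means ≥ 1 shared base.
"Not overlapping" in the enhancer definition is region-level: a candidate
H3K27ac region touching an H3K4me3 region or a TSS ± 2.5 kb window anywhere
is removed whole, because enhancers are treated as discrete regions rather
than base sets. TSS is txStart on +, txEnd on −; the TSS exclusion applies
per transcript model.

## Stage specificity

H = −Σ R_i log2 R_i with R_i = E_i/ΣE, 0·log 0 ≡ 0, and features with
ΣE = 0 excluded (NaN sentinel) rather than scored. Log base 2 makes the
maximum exactly log2(N). All threshold inequalities are strict as stated
("H < 2", "FPKM > 5", "more than two-fold"): a gene at exactly the cutoff is
not selected. Features may be assigned to several stages; the breadth rule
(high expression in ≤ 3 additional stages) is evaluated per assigned stage.
The miRNA fold rule uses max / max(min, floor) with a detection floor
(default 1.0 array units) so silent probes cannot produce unbounded folds;
ties at the maximum go to the earliest stage and are flagged.

The transient-induction selector (BMP7-style) is parameterized because no
exact thresholds exist for it: a gene qualifies when E(d0) ≥ up_fold ×
E(d-3), E(d0) ≥ down_fold × max(E(6h), E(d2)) and E(d0) > expr_min, with
up_fold = down_fold = 2 and expr_min = 5 (the coding expression cutoff) as
package defaults. Planted d0-stage-specific genes satisfy the same
predicate by construction, so on synthetic data the selector's precision
against the "transient" label alone is deliberately not a validation target;
recall is.

## Lineage classification

"At least 3-fold higher" is inclusive (≥); "FPKM < 10" strict. Zero
denominators pass when the numerator is positive (no pseudocount) — the
rules also bound the low side absolutely, so this cannot promote noise. If
both the BA rule and the mirrored WA rule hold simultaneously (possible only
when both d7 values are ≈ 0), the gene is called shared, preserving mutual
exclusivity. External tissue/primary-cell folds (≥ 2.5 in the concordant
direction, both required) downgrade a call to unclassified when failed and
pass through flagged-unchecked when absent; replicate folds are expected as
means.

## ChIP signal

Reads are extended to 300 bp from their 5′ end in strand direction (clipped
at 0); unstranded reads are rejected rather than defaulted. A read counts
toward a region on ≥ 1-base overlap of the extended interval. RPKM =
count / (region kb × library size in millions); library size defaults to
the read count of the supplied set. Z-scores use the population standard
deviation (immaterial at genomic region counts, exact in small worked
examples); constant slices map to z = 0 so downstream thresholds stay
finite. The standardization axis is a config field; the default is per
stage across regions, which cancels per-stage depth and batch scale.
Whether the original analysis standardized per stage or per region is not
determinable from its description; both are implemented.

## Super-enhancers

Stitching merges enhancers with z > 0 at the focal stage whose gaps are
≤ 12.5 kb; "larger than 12.5 kb" is strict and measured on the merged
genomic span including gaps. Per-stage RPKM is recomputed over the merged
span. The slope cut is defined on the unit-square rank-vs-signal curve
(both axes min-max rescaled): scanning from the low-signal end, the cut is
the first point whose forward discrete slope exceeds the threshold (0.5)
while the mean slope of the remaining curve also exceeds it — the second
condition keeps a local wiggle among weak candidates from triggering the
cut. Everything strictly above the cut point is an SE, so the SE set is
always a suffix of the ranked list. The geometry (what is rescaled, where
the crossing is read) is a documented package choice isolated in
`rank_and_cut`; alternative geometries can be swapped behind that function.
With < 2 candidates or a flat curve nothing is called (warning).

Target assignment: candidate genes are expressed (any-stage FPKM > 1) with
TSS within 100 kb of the SE span (inside = 0); all genes with Pearson
r > 0.75 over the shared stage grid are assigned, else the single best gene
with r > 0.5. Correlation uses the merged-span activity profile (not summed
constituents — a documented choice). Constant profiles have undefined r and
are never assigned. miRNAs in the window are assigned unconditionally when
genomic miRNA models are provided. With five stage points the null
distribution of r is wide: P(r > 0.75 | independent profiles) ≈ 0.07,
which sets the floor for decoy assignments and is why the synthetic decoy
rate hovers near 0.07 across seeds.

## TF peaks

Peaks are classified by midpoint with priority promoter (TSS ± 2.5 kb) >
exon > intron > TTS-proximal (± 2.5 kb) > intergenic; midpoint rules are
the common convention for element pie charts and neither the midpoint nor
the priority is externally fixed. Group regulatory neighborhoods are
H3K27ac peaks within ± 100 kb of a group member's TSS (reusing the SE
target window; configurable). Enrichment is the count and summed RPKM of TF
peaks overlapping those neighborhoods; nearest-peak distances are measured
TSS-to-nearest-edge, 0 inside.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
real genomes. Expression is multiplicative-lognormal: background genes are
stage-independent lognormal FPKM (log2 mean 4, sd 1), planted features get
baseline × 20 in their stage(s) and uniform [0, 1) FPKM elsewhere
([0, 0.25) for lncRNAs so the 0.5 cutoff engages cleanly), and every value
carries lognormal noise of sd 0.2 on the log2 scale. These sizes — 2,000
genes, 40 stage-specific genes per stage, 30 genes per lineage class, 20
transients, 20 SE loci, 80 stage-specific enhancers per stage — are the
package's default study conditions and are what the recovery tests certify.

The genome layout is deterministic: two 12.2 Mb chromosomes open with SE
blocks (200 kb: target gene, five 1 kb constituents spaced 2.5 kb apart
giving a 15 kb span, and three flat-profile decoy genes inside the 100 kb
window), then weak-cluster blocks (100 kb; four constituents spanning 13 kb
with a low d7 weight) that anchor the low-signal end of the ranked curve,
then 10 kb gene slots (6 kb bodies, three exons, one strand per chromosome)
whose intergenic zones hold planted distal enhancers clear of every TSS ±
2.5 kb window. Lineage-group genes sit on a ≥ 210 kb grid so their
regulatory neighborhoods stay disjoint. Reads are multinomial over weighted
source regions (planted enhancers 20× on-stage weight; SE constituents
weighted by the target's expression profile; promoters active/inactive)
plus 20% uniform background, 150,000 reads per stage per mark per lineage —
enough that Poisson noise is small against the z thresholds while the full
demo stays under half a minute on one CPU. H3K4me1 reads are co-placed with
H3K27ac by independent sampling, so concordance is planted. The
promoter-state fixture is generated as count matrices per promoter window
(H3K4me1 elevated at BA-specific promoters in BA only; H3K27me3 high early
and lost at d7 in both lineages equally).

What the generator does not emulate — mappability, GC bias, fragment-length
variation, replicate structure, isoform complexity, overlapping genes,
realistic inter-gene distance distributions — bounds what passing tests
show: they certify the selection logic, the interval algebra and the
normalization chain under the planted model, not performance on real
libraries.

## Numerical and degenerate-input choices

Quantile normalization replaces the value at rank r with the mean of the
rank-r order statistics across columns; ties receive the mean over their
spanned ranks. Welch's (unequal-variance) t-test is used wherever a t-test
is called for; groups with < 2 members yield summaries without a test,
flagged. Identical constant distributions are reported as t = 0, p = 1.
Nearest-gene ties are all reported with a tie flag. Empty TF peak sets are
an error for distance computation; empty groups yield flagged zero rows.
Distance from a point to an interval is 0 inside, else bases to the nearest
covered base.

## Determinism and problem sizes

All randomness flows from one integer seed through per-component child
streams; fixture files, pipeline outputs and manifests are byte-identical
across reruns (floats serialized at fixed precision). Default test and demo
problem sizes (2,000 genes, ~730 enhancer-universe regions, 150k reads per
stage) were chosen so the full end-to-end demo completes in well under a
minute on one CPU while keeping every planted margin several noise standard
deviations wide; the acceptance script runs the identical conditions.

## Known limitations

The slope-cut geometry is one of several defensible readings of a ranked
"slope > 0.5" rule; results near the cut depend on it. The enhancer
breadth rule (≤ 3 additional active stages) is weak for five-stage designs
(it only excludes regions active everywhere). Stage labels are matched
across lineages by name, so the first stages (d-3 vs d-4) never pair in
between-lineage promoter tests; comparisons run on the shared labels (d0,
6h, d2, d7). Chains of independently planted active enhancers can
occasionally stitch into spans > 12.5 kb and enter the SE candidate list;
they rank low and do not displace planted loci, but they can add SEs beyond
the planted count.
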