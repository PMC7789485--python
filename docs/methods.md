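# Methods

`dielmeth` analyses diel (day–night) DNA methylation dynamics and their
coupling to gene expression in a two-tissue plant leaf system
(photosynthetic "green" tip vs non-photosynthetic "white" base, sampled
at 4 am, 10 am, 4 pm and 10 pm with two biological replicates). The
pipeline starts from per-cytosine bisulfite counts and per-gene RNA
counts; read trimming, alignment and transcript assembly are upstream
of this package and out of scope.

## Weighted methylation and windows

Every methylation level in the package is a *weighted* level:

    m(region, context) = Σ methylated reads / Σ total reads

over the covered cytosines of that context in the region — a
coverage-weighted quantity, never a mean of per-site ratios. Regions
with a zero denominator are *undefined* and propagate as missing
(treating them as 0 would bias toward hypomethylation).

Cytosine contexts are CG, CHG and CHH (H = A, T or C), classified from
the genome sequence per strand; a cytosine whose downstream context is
truncated by the contig end is classified CHH by convention unless the
CG dinucleotide is still decidable (the count involved is negligible,
but the rule must be deterministic). CG sites are *not* merged across
strands by default — each strand's cytosine is an independent record,
matching per-strand methylation-ratio outputs; `pool_calls` can combine
arbitrary call sets when a merged view is wanted.

Window tables tile each contig with fixed-width windows (default
100 bp; chromosome-scale tracks use 500-kb windows sliding by 100 kb).
The trailing partial window is retained (and identifiable by its
width) rather than silently dropped.

QC follows standard WGBS practice: the bisulfite conversion rate is
one minus the weighted methylation of an unmethylated control contig
(the chloroplast stand-in); replicate concordance is the Pearson
correlation of per-window levels on non-overlapping 100-bp windows,
with windows undefined in either replicate dropped pairwise; a
coverage filter keeps cytosines with ≥ 4 reads.

## DMR calling

A 100-bp window is a differentially methylated region (DMR) between
two sample groups when, with replicate counts pooled within groups:

1. both groups have coverage and ≥ `min_cytosines` (default 4) covered
   cytosines of the context in the window;
2. a two-sided Fisher exact test on the pooled 2×2 table
   [[meth_A, unmeth_A], [meth_B, unmeth_B]] is significant after
   Benjamini–Hochberg control at q ≤ 0.05 (within context); and
3. |m_A − m_B| ≥ the per-context threshold: 0.4 (CG), 0.2 (CHG),
   0.1 (CHH).

The Δm thresholds are fixed study parameters; the choice of test and
significance level is this package's design (documented in output
metadata): Fisher exact on pooled counts is the simplest exact test at
the window level, and BH within context controls the expected false
discovery proportion among windows. Direction ("hyper"/"hypo") is
always relative to the first-named group, and every output carries the
comparison tuple to avoid sign ambiguity.

The two-sided Fisher p sums hypergeometric probabilities not exceeding
that of the observed table at fixed margins, including ties within a
1 + 1e−7 relative factor (the convention shared by mainstream
implementations). The scalar `fisher_exact` evaluates this in exact
integer arithmetic; the vectorized path used by `call_dmrs` uses a
cached log-factorial table and matches the scalar to ~1e−12.

Adjacent significant windows are *not* merged by default, so DMR
counts are window-level counts; `merge_dmrs(gap=N)` merges runs and
re-pools their counts for users who want region-level records.
Windows missing in either group are "not assessable" and excluded from
testing entirely.

DMRs are assigned one genomic feature class by maximal overlap with
precedence promoter > exon > intron > downstream > intergenic, where
the promoter is the 2 kb upstream of the TSS (strand-aware) and
downstream is 2 kb past the 3′ end. State dynamics across the diel
chain (10 am→4 pm→10 pm→4 am→10 am) are summarised as transition
matrices over the union of windows that are a DMR in at least one
comparison (states hyper / hypo / unchanged).

## Profiles

Metaplots use the upstream / body / downstream layout: 20 fixed 100-bp
bins per 2-kb flank and 20 proportional bins over the body, oriented
5′→3′ (minus-strand features reversed before binning). A cytosine at
offset `o` in a body of length `L` falls in bin `⌊20·o/L⌋` clamped to
19, which is deterministic and handles bodies shorter than 20 bp. Bin
levels pool raw counts across features (weighted-methylation
semantics, robust at low coverage); a mean-of-features mode exists for
sensitivity analysis. The 2-kb flank mirrors the DMR-association
envelope and is configurable.

## Expression

FPKM = count · 10⁹ / (gene length · library size), with exonic length
and per-sample total counts as defaults. Genes with FPKM > 0.5 are
"expressed". Expressed genes are stratified either into quintiles by a
ranking sample's (or group-mean) FPKM — ties broken by stable gene-id
order so strata reproduce exactly — or into three classes:
unexpressed, then terciles of the expressed genes with the middle
tercile set aside ("low"/"high"); cut-offs for low/high are a design
choice of this package.

The differential-expression stage is a deliberately minimal
negative-binomial Wald test (`method='nb-wald-mor'`): median-of-ratios
size factors; a pooled method-of-moments dispersion estimated from
within-group variances across genes (floor 0.01) — with two replicates
per group, per-gene dispersions are too noisy, and a pooled estimate
matches the generator's common-dispersion counts; and a normal Wald
statistic on log2 fold change with BH control. It is *not* DESeq2 (no
shrinkage, no Cox–Reid dispersion, no independent filtering) and is
never presented as such; it is calibrated (null type-I error ≈ 0.05 at
n = 2, verified by simulation in the test suite) and sufficient to
exercise the integration logic. All-zero genes are flagged and not
tested.

Rank comparisons between strata use the Mann–Whitney test: exact
enumeration for tie-free samples with both n ≤ 20, tie-corrected
normal approximation otherwise, and p = 1 for fully degenerate input.

## Integration

A gene is DMR-associated when a DMR interval intersects the gene body
extended by exactly 2000 bp on each side; the zone is strand-aware
(upstream / body / downstream), and a DMR straddling body and flank is
zoned "body" (the stronger claim, and it prevents double-zoning the
headline count). The headline DMR-associated DEG fraction counts each
DEG once regardless of how many DMRs it carries; the stratified
breakdown counts links per zone × context × DE direction. DEGs are
the union over the four per-time-point green-vs-white tests, with
per-time tables also available.

GO enrichment is the upper-tail hypergeometric test
p = P(X ≥ k), X ~ Hypergeom(N, K, n), reported at raw p < 0.01 with
no multiple-testing correction of the selection (a BH column is
emitted alongside for users). The population is the annotated genes
with ≥ 1 GO term.

## The synthetic study generator

The generator emulates the study's structure with planted,
parameterized effects so every downstream stage has known ground
truth. Defaults (the reference study): two 1-Mb chromosomes plus a
20-kb unmethylated control contig; 200 non-overlapping genes (1–3 kb,
1–4 exons) on the chromosome arms, spaced so their 2-kb association
envelopes stay disjoint; 150 TEs (0.5–3 kb), 70 % placed in the
central 30 % of each chromosome (pericentromere); 20× mean coverage
(Poisson per cytosine), two replicates.

True methylation per cytosine is assembled additively and clipped to
[0, 1]:

* context baselines 0.60 / 0.35 / 0.10 (CG/CHG/CHH) — plant-like
  ordering;
* +0.25 inside TEs (hypermethylated, pericentromere-enriched);
* shared regional variation: a per-1-kb-tile Gaussian (sd 0.15 / 0.18
  / 0.03 by context), identical in every sample. Real methylomes are
  strongly heterogeneous between windows; without this term, 100-bp
  replicate correlations at 20× are dominated by binomial noise and
  could never reach the r > 0.95 concordance real replicates show.
  Because the term is shared, it creates no differential signal;
* tissue contrast: CHH reduced by 0.03 genome-wide in "white";
* diel oscillation in "green" only, within TE intervals (the
  RdDM-targeted compartment, where plant CHH dynamics concentrate):
  +amplitude at 4 pm/10 pm, −amplitude at 4 am/10 am, amplitude 0.06
  for CHH and CHG, 0 for CG. With a common amplitude the per-context
  DMR thresholds alone reproduce the observed count ordering
  n(CHH) ≫ n(CHG) > n(CG): 0.1 catches the oscillation nearly
  everywhere it acts, 0.2 only in its upper noise tail, 0.4 never;
* silenced genes (30 % of genes): methylation +0.15 over the gene
  ±2 kb in every sample, and expression suppressed to near zero —
  the methylation–repression coupling behind the
  expression-stratification analyses;
* planted DMRs, two kinds, recorded in the ground truth:
  *recovery* regions — per context, 40 grid-aligned 500-bp regions
  (5 windows), intergenic and clear of TEs, with effect sizes equal to
  the calling thresholds, planted on one side of the white-4am vs
  white-10am comparison (a pair with no other systematic signal); and
  *DEG-linked* regions — one 300-bp promoter or body region for 85 %
  of the DE genes, planted on the green-vs-white contrast at all
  times, context cycling CG/CHG/CHH. Planted regions keep a clean
  context baseline (no regional/tissue/diel terms) and the effect is
  always *added* to one side of the comparison, so the realized |Δm|
  equals the configured effect exactly, without clipping.

A planted region whose true effect equals the calling threshold is
recovered by any given overlapping window with probability ≈ 0.5
(symmetric noise around the threshold), which is why planted DMRs are
multi-window regions: recovery of ≥ 1 of 5 windows succeeds with
probability ≈ 0.95, and the pipeline's measured sensitivity is
region-level. Window-level empirical FDR is measured against the
planted intervals.

Observed counts model bisulfite chemistry: non-conversion turns a
truly unmethylated cytosine into an apparent methylated call, so the
binomial success probability is p + (1 − p) · conversion_error, and
the control contig (true p = 0) reads out the conversion error
directly. The default error 0.012 keeps the estimated conversion rate
(≈ 98.8 %) above the usual 98.7 % QC bar with margin. Sequencing
miscalls are not modelled.

RNA counts are negative binomial (dispersion 0.05) with mean
proportional to gene length and a per-sample library factor
(uniform 0.7–1.3). 120 of 200 genes are differentially expressed
green vs white (log2FC = 2, split symmetrically across tissues, half
up and half down); planted DE genes get a detectable baseline (mean
≥ 50 per kb). The DE fraction is deliberately large (the study this
emulates reported roughly half the genome differentially expressed
between tissues): with only a handful of expressed null genes, the
few BH false-positive DEGs that accumulate over the four time-point
unions cannot dilute the DMR-associated DEG fraction away from its
planted value. The GO map gives every gene a root term, background
terms at random, and one planted term covering 90 % of DE genes but
only 10 % of the rest.

Determinism: all randomness flows from `SimConfig.seed` through
per-stage `numpy` generators (`[seed, k]` streams), so a fixed seed
reproduces every file byte-for-byte.

### What the generator does *not* emulate

Realistic sequence composition (uniform ACGT only — context
frequencies, not motif biology), read-level artifacts (mapping bias,
duplicates, M-bias), beta-binomial overdispersion of methylation
counts beyond the shared regional term, chromatin domains, isoform
structure, and any batch or positional covariates. Passing tests on
this generator therefore demonstrate correctness of the quantification
and inference machinery under a controlled noise model — not
performance on real WGBS libraries, where dispersion modelling and
mapping artifacts matter.

## Numerical and design notes

* Fisher tie convention 1 + 1e−7 (above); BH with monotonicity
  enforcement via statsmodels.
* Undefined levels are NaN end-to-end; writers omit undefined windows
  from bedGraph output.
* Coverage filtering is per sample, with pooling available (the
  "≥ 4 reads" rule is ambiguous between per-replicate and pooled
  readings; per-sample is the conservative default).
* Quintile/tercile boundaries distribute remainders to the lowest
  groups deterministically; ties break by gene id.
* The DMR caller raises on mismatched window grids rather than
  aligning silently.
* Problem sizes in the test-suite and acceptance runs (2-Mb reference
  genome, 200 genes, 2 000-gene calibration simulations) are the
  package's reference study scale: large enough that every planted
  effect is measurable with comfortable statistical margin, small
  enough to iterate on quickly.

## Known limitations

No smoothing/HMM segmentation of DMRs and no beta-binomial dispersion
(listed extensions); the NB Wald test is intentionally minimal; GO
enrichment does no DAG propagation; linking uses a fixed 2-kb envelope
rather than expression-aware assignment.
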