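# Methods

## Scope and data model

The package starts from aligned data: spliced single-end alignments
(text SAM) with a GTF annotation on the expression side, and per-cytosine
methylation call reports (Bismark coverage2cytosine layout) with BED
region sets on the methylation side. Upstream read QC, trimming and
alignment are out of scope. Internally all coordinates are 1-based and
inclusive; BED input/output is converted at the parse/write boundary, so
there is exactly one conversion point.

## Canonical splice-junction counting

Junctions are read off the alignment by walking the CIGAR string: the
reference cursor advances through `M`, `D`, `=`, `X` and `N`; each `N`
of length L at cursor c contributes the junction (c, c+L−1), i.e. the
skipped intron. The intron catalog is derived from the annotation as
(previous exon end + 1, next exon start − 1) for every consecutive exon
pair of every transcript; identical coordinates from different
transcripts or genes merge into one entry with the union of gene ids.

Classification is exact-match: a read with no junctions is *unspliced*
(tallied, not counted — junction-crossing reads are the counting unit);
a read with any junction absent from the catalog is *non-canonical* and
excluded (a single novel junction dominates, even alongside annotated
ones); if all junctions are annotated, the read is assigned iff the
intersection of the junctions' gene sets has exactly one element,
otherwise it is *ambiguous* and excluded so the count matrix never
double-counts. Matching ignores strand by default (unstranded library
assumption); a flag enables strand-aware catalogs. Duplicate-flagged
(0x400) and supplementary (0x800) records are skipped alongside unmapped
and secondary ones, making the counter safe on un-deduplicated input.
The five classification tallies plus the skipped count must equal the
total record count; this conservation identity is asserted on every run.

The ~4% non-canonical read fraction seen in real GV-oocyte libraries is
treated as data-dependent, not a constant; it is the generator's default
but never assumed by the counter.

## Differential expression

A deliberately simple negative-binomial Wald stack, calibrated by
simulation rather than validated against any external tool's numerics:

- **Size factors** — median-of-ratios over genes with all-positive
  counts. A matrix with no such gene is an error that suggests a
  pseudo-reference fallback rather than silently changing the estimator.
- **Dispersion** — method of moments on normalized counts with variance
  pooled within groups (each group centered on its own mean), floored at
  1e−8. At a handful of replicates per genotype the per-gene estimate is
  noisy, so it is squeezed toward the across-gene median in log space
  with `prior_df = 6` pseudo-degrees of freedom; the Wald statistic is
  then referred to a t distribution with residual + prior degrees of
  freedom. Without these two choices the plug-in normal test is
  anti-conservative at n = 5 vs 5 (empirical null rate ≈ 0.09 at nominal
  0.05); with them the measured null rate is ≈ 0.05 and power for a
  planted log2FC = 2 at mean 200 exceeds 0.95.
- **Fold change** — log2((μ̄_test + ½)/(μ̄_ref + ½)) on mean normalized
  counts, pseudo-count ½ for stability at zero-mean groups. WT is always
  the reference, so positive values read "more abundant in the mutant".
  Note the pseudo-count makes log2FC exactly scale-invariant only at
  pc = 0; with the default ½ the invariance is approximate because the
  median-of-ratios reference shifts under single-sample rescaling.
- **Calling** — two-sided p, Benjamini–Hochberg adjustment, DEG iff
  adjusted p < 0.05 and |log2FC| > 1 (both configurable).

There is no dispersion-trend fitting, LFC shrinkage, independent
filtering or outlier refitting. All-zero genes are dropped and reported.

## Methylome quantitation

All region statistics are *weighted* methylation — summed methylated
counts over summed total counts across the region's CpGs, × 100 — not
means of per-CpG ratios; this is the standard bisulfite feature
statistic and is robust at low per-CpG depth. A per-CpG coverage floor
(default 3×) is applied before any feature quantitation. Undefined
values (no covered CpG) are `None`/NaN, never coerced to 0. Pooling by
genotype sums counts position-wise, so a pool's weighted value is
exactly the coverage-weighted combination of its members.

Tilings: 100-CpG tiles are runs of exactly 100 consecutive CpGs per
chromosome (trailing remainder dropped, tiles span first to last member
CpG); 10-kb tiles are adjacent fixed-width windows with the final
partial window kept. A tile enters the differential-testing universe
("informative") iff every sample has ≥ 3 CpGs at ≥ 3× inside it — the
per-tile reading of "3× coverage in all samples" is a documented choice
and both knobs are configurable.

Sample QC uses the mean over X-chromosome CGIs of their weighted
methylation (one vote per CGI so a single deep CGI cannot dominate) with
a strict < 13.5% cutoff, plus a strict > 5,000,000 mapped-read floor.
Promoters default to the 1,000 bp upstream of the TSS, strand-aware and
configurable. The bimodality summary reports the tile fractions at the
≤ 25% and ≥ 75% poles and flags a methylome bimodal when the poles
jointly hold ≥ 0.7 of tiles.

## Differential methylation and domains

Each region contributes a 2×2 table of pooled (methylated, unmethylated)
counts per genotype. The default test is Pearson chi-square without
continuity correction, replaced by Fisher's exact test whenever any
expected cell is < 5 (the chi-square approximation is invalid there).
The per-sample logistic-regression-with-overdispersion style of testing
is deliberately not implemented. Multiple testing uses
Benjamini–Hochberg q-values as a stand-in for sliding-linear-model
q-value estimators whose parameters are not reproducible here; the
substitution is noted in output headers and the q-threshold semantics
are unchanged. Delta is computed on the same pooled weighted methylation
the test uses, so swapping ref and test exactly negates delta and
preserves p.

DMRs are regions with q below the threshold AND |Δ| at or above the
minimum (10-kb default: q < 0.01, Δ ≥ 20; CGI default: q < 0.05,
Δ ≥ 10). Promoter-level differential calls reuse the CGI rule. Context
annotation is any-overlap with precedence promoter > exon > intron >
intergenic. DMR intersection between comparisons matches region ids from
a shared tiling and reports direction concordance without requiring it.

Domains are classified per genotype from pooled weighted methylation:
a HyperD is maintained iff ≥ 75% (boundary inclusive), a HypoD iff
≤ 25%; uncovered domains are uninformative and excluded from loss
tallies rather than counted as lost.

## Synthetic data generator

Methylation is simulated at the cytosine-call level, not the read level:
the pipeline starts at call reports, so read-level bisulfite simulation
would add cost without covering any additional operation. A region plan
paints a mean methylation level onto every CpG (HyperD 0.85, HypoD 0.05,
maternal gDMR 0.95, paternal gDMR 0.02, methylated oocyte CGI 0.90,
X-CGI 0.02); one Beta level per CpG (concentration 20 for domains, 50
for the near-binary gDMRs/CGIs) is drawn once and shared by all
genotypes, so genotype differences arise only from planted shifts —
this keeps null chi-square tests calibrated, since pools differ only by
binomial noise. Coverage is Poisson per CpG and sample, methylated
counts binomial. The default plan sizes HyperDs at 43.75% of CpGs
(17.5 kb / 22.5 kb alternation), which lands global CpG methylation at
≈ 40%, the level of a fully grown GV oocyte; non-CpG calls are emitted
at ~5% methylation. Contamination mixes a granulosa-like somatic profile
(flat 0.70, X-CGIs 0.70, gDMRs 0.50, autosomal CGIs 0.10) into the true
level at a per-sample fraction, so a 0.25-contaminated pool shows X-CGI
methylation ≈ 0.75·2% + 0.25·70% ≈ 19% and fails QC.

Spliced-read simulation draws exact multinomial class counts
(default unspliced 0.40 / canonical 0.52 / non-canonical 0.04 /
ambiguous 0.04): canonical reads span one intron unique to their gene
with exact boundaries; non-canonical reads use junctions offset ≥ 1 bp
from every annotated intron; ambiguous reads span a planted intron
shared by two overlapping genes. Count matrices are Gamma–Poisson
(NB) draws with log-uniform size factors on [0.5, 2] and planted log2
fold changes. Every generator is a pure function of its parameters and
seed, and serializes a truth object sufficient to score recovery without
re-reading the generated data.

The generator emulates the *statistical* structure of the assays, not
their full biology: no mean-dependent dispersion trend, no bisulfite
conversion failure or M-bias, no fragment-level coverage correlation
along the genome, no batch or superovulation effects, uniform CpG
spacing. Passing tests therefore demonstrate correctness and calibration
of the algorithms under the stated models, not performance on real
libraries.

## Pipeline, configuration and problem sizes

Every numeric threshold lives in `AnalysisConfig` (a flat key-value YAML
maps onto it); no threshold is hard-coded at a call site, which a
lint-style test enforces for the QC cutoffs. The pipeline runs QC →
splice counting → DE + Venn → methylome quantitation → tile/CGI DMRs →
domain classification → integration, logs thresholds, seeds, per-stage
row counts and excluded samples with reasons, and is byte-identical
under a fixed seed and config. QC-failed samples are removed from both
arms of the downstream analysis.

Default validation problem sizes are chosen to exercise every code path
at desk scale: a 2.5-Mb three-chromosome genome at 1 CpG/50 bp for the
oocyte plan; a 50.5-Mb single-chromosome plan at 1 CpG/kb (5,050 10-kb
tiles, 30× pooled coverage) for DMR calibration; 5,000 genes at n = 5
vs 5 for DE calibration; 1,000–20,000 reads per sample for the splice
counter, whose correctness is exact rather than statistical.

## Known limitations

- The NB test is a calibrated stand-in, not a numerical re-implementation
  of any published tool; on real data with strong mean-dispersion trends
  its median squeeze target is cruder than a fitted trend.
- Chi-square on pooled counts ignores biological replicate variance; with
  few pools per genotype this is the classic pooled-test trade-off, and
  planted-truth calibration holds only under the generator's
  shared-level null.
- DMR calls are per-tile; no merging or smoothing across adjacent tiles.
- The ambiguity rule (gene-set intersection must be a singleton) is one
  reasonable resolution of multi-gene introns; counting a read once per
  matching gene would be an alternative with different double-counting
  behavior.
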