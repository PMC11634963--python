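# Methods

## Scope and model

`ctdnakit` implements the *downstream* decision logic of a targeted cfDNA
assay: it consumes per-caller variant and structural-variant call sets,
per-target mean read depths, and per-sample aneuploidy-fraction estimates
(produced upstream by a genome-wide estimator such as ichorCNA), and emits
gene-level copy-ratio calls, filtered pathogenic mutations, *AR* structural
rearrangement classifications, a three-group ctDNA positivity call, and
survival summaries. Read mapping, duplicate handling, the variant callers
themselves, and the aneuploidy estimator are out of scope; their outputs are
inputs here and are emulated by the synthetic generator.

## Coordinates and conventions

All intervals are 0-based half-open internally. BED I/O is native; VCF
positions are converted at the boundary. The *AR* model records the 0-based
position of the first base of the stop codon; intervals described as running
"through the stop codon" end at `stop_codon + 1`. The breakpoint window used
by the truncation rules, "between the end of exon 3 and the stop codon", is
inclusive at both ends: a breakend at the first base after exon 3 or at the
stop codon itself is inside the window.

## Copy ratios

Within-sample normalization divides a target's mean depth by the median of
the five control-region depths placed on the target chromosome's copy scale
(C2, on chrX, is doubled for chrX targets; the other four are halved for
autosomal targets — the male genome carries one chrX copy). The chrX and
autosomal scales differ by a factor of 4 as written (a chrX-neutral gene
normalizes to 0.5, an autosomal one to 2.0); this asymmetry cancels exactly
in the ratio against the panel of normals, so it is implemented verbatim.
The panel of normals is the per-target mean normalized depth over samples
with aneuploidy fraction ≤ 0.05, built once per cohort and reused; the query
sample is not excluded, matching a fixed-reference design. Median of five is
the middle order statistic; for an (unexpected) even count the mean of the
middle two is used.

Gain is `log2(ratio) > 0.3`, loss is `log2(ratio) < −0.3` *and* the sample is
ctDNA-positive; both inequalities are strict, so the boundary value 0.3 is
neutral. Loss suppression in negative samples reflects the poor
signal-to-noise of shallow deletions at low tumor content. Because the
positivity call depends only on gains, mutations, and rearrangements, group
assignment runs first and loss states are finalized afterwards; there is no
circularity.

## Variant filtering

Both callers' records are normalized before intersection: equal-length
multi-base substitutions split into per-base SNVs (only differing bases are
emitted; VAF and alt-read count are inherited, not recomputed), shared
suffix/prefix bases are trimmed, and indels are left-aligned by the standard
rotation against a ±20 bp reference context carried in the record (no genome
access required). Records with fewer than 6 alternate-allele reads are
dropped; per-caller internal thresholds are treated as upstream behavior and
are emulated by the generator rather than re-implemented. Consensus requires
an identical normalized key in both sets, ignoring genotype; the consensus
record carries the first caller's VAF and alt-read count.

The pathogenicity filter keeps curated variants labeled Oncogenic or Likely
Oncogenic, and uncurated variants with such a label provided they carry no
splice-site/splice-region consequence (the label for uncurated variants is a
second annotation field, since the curated source by definition does not
supply it). A per-gene removal ledger drops eight recurrent germline/artifact
protein changes; the symbol "KMTC2" is normalized to KMT2C via a configurable
synonym table. FOXA1 bypasses the oncogenicity rules entirely: all FOXA1
variants are kept except synonymous ones and three listed substitutions.
Every dropped candidate carries exactly one machine-readable reason.

Origin: likely germline iff the gene is HSD3B1 (regardless of VAF), or any
gene outside {AR, TP53, PTEN, ERF, PIK3CA, CDK12} with VAF in the inclusive
band [0.45, 0.55] or strictly above 0.95; otherwise likely somatic. The
exempt genes are those whose somatic mutations in this tumor type can reach
clonal VAFs inside the heterozygous band.

## Structural variants and *AR*-GSR rules

A breakend stores which flank of its position the rearranged molecule keeps.
For a same-chromosome pair ordered p1 < p2: (left, right) is a deletion,
(right, left) a tandem duplication, equal sides an inversion; cross-chromosome
pairs are translocations. Cross-caller matching compares chromosome pairs and
both positions within a 1000 bp tolerance after canonical ordering; SV type
is deliberately not compared, since callers label the same adjacency
differently. Merging is single-linkage (pairwise comparison is how
breakend-level intersection tools operate); chaining is bounded by the small
tolerance and the cluster size is recorded. The cluster representative is the
member from the lexicographically smallest caller ID; read support is the
per-field maximum over members (aggregation across callers is a design
choice; per-record thresholds were the plausible alternative).

An *AR*-GSR is a consensus SV with ≥ 1 breakend inside the *AR* gene body (no
flank), ≥ 2 of 4 supporting callers, ≥ 3 split reads and ≥ 3 discordant
pairs, after removing SVs with either breakend in a blacklist interval.

The four LBD-truncation rules are evaluated in order and the first match is
recorded (the truncation flag itself is rule-agnostic):

1. DEL/INV/BND overlapping exon 4, 5, 6, 7 and/or the exon-8-start-to-stop
   interval, with no overlap of the exon 1–3 span;
2. DUP/INV/BND fully covering the exon 1–3 span with a breakpoint in the
   window (end of exon 3 through the stop codon);
3. DUP with both breakpoints inside the gene body whose span fully contains
   at least one of exons 3–7 ("flanking" read as full containment);
4. TRA whose *AR*-side breakend lies in the window and retains the
   centromeric side: *AR* is plus-strand on chrX with exons 1–3 at lower,
   centromere-proximal coordinates, so `retains_left` keeps the
   exon 1–3 segment.

"Breakpoint" means either breakend position; same-chromosome spans are
`[min(pos), max(pos))`; cross-chromosome events contribute only their
*AR*-side breakend. A sample with ≥ 2 *AR*-GSRs and *AR* body
`log2 > 0.3` is flagged as likely carrying *AR* ecDNA.

## Classification and reporting

The aneuploidy threshold is `mean + 3·SD` of the healthy-donor control
fractions, with the sample (n−1) standard deviation — for a small control
series this is the standard choice, and with the reference control summary
(mean 0.0698, SD 0.0241, n = 8) either convention reproduces 0.1421. Group 1
requires the fraction to *strictly* exceed the threshold; a sample exactly at
threshold is eligible only for Group 2. The Group-2 mutation trigger requires
a variant that is both pathogenic (it survived the filter) and likely
somatic. Reported percentages round half away from zero to whole percents.

Kaplan-Meier estimation and the log-rank test are delegated to `lifelines`
(the test suite cross-checks the estimator against an independent brute-force
product over risk sets); the median is the smallest observed time with
S(t) ≤ 0.5, undefined if never reached; ties between events and censorings
resolve events first. Benjamini-Hochberg adjustment is applied whenever the
report performs more than one pairwise comparison. Median confidence
intervals are available through `lifelines` but are not part of the standard
report.

## Synthetic cohort generator

The generator encodes the diploid-admixture assumptions the analysis relies
on. For a planted tumor copy number `CN_t` at fraction `f`, the expected
observed ratio is `1 + f·(CN_t/2 − 1)` on autosomes and `1 + f·(CN_t − 1)` on
chrX. Depths are drawn around a per-sample baseline (default 400×, matching
the assay's mean unique coverage) with multiplicative lognormal noise;
control regions share the baseline, so within-sample normalization cancels it
by construction. Somatic VAFs follow the admixture (one mutated copy:
`f·m / (f·CN_t + (1−f)·ploidy)`, ≈ `f/2` for a neutral autosomal site) with
beta dispersion; germline VAFs sit near 0.5. Each pseudo-caller detects a
planted variant or SV independently with a configurable sensitivity and adds
private false positives; SV breakends are jittered by at most half the
matching tolerance, so a planted event's own copies always cluster. Survival
times are exponential (`median = ln 2 / λ`) with independent exponential
censoring tuned to the configured censoring rate. cfDNA yield increases with
fraction under lognormal noise, mirroring the observed positive association;
it is reported but does not enter classification.

Defaults are the study conditions: control fractions mean 0.0698 / SD 0.0241
(n = 8); a group mix proportional to 200/256/320; per-group fraction ranges
U(0.15, 0.70), U(0.055, 0.135), U(0.004, 0.13); planted gain copy numbers 8
(*AR*, enhancer) and 16 (*MYC*, *MYCN*); per-group survival medians 23/29/47
months with 20% censoring. The Group-2 floor of 0.055 keeps altered samples
out of the ≤ 0.05 panel of normals — mirroring a fixed low-fraction reference
— and guarantees the planted gains clear the 0.3 log2 threshold after
dilution. Planted group labels are defined relative to the threshold derived
from the bundle's own control draws, so truth and pipeline share one regime
split. Problem sizes used in validation (500-sample titration series,
1000-sample closed-loop cohort) were chosen to make Monte-Carlo error small
relative to the tested tolerances.

What the generator does *not* emulate: read-level data (no FASTQ/BAM), GC and
mappability bias, fragment-size structure, clonal hematopoiesis, subclonal
copy-number heterogeneity, and caller-specific error modes beyond uniform
sensitivity/false-positive rates. Passing closed-loop tests therefore
demonstrates the correctness of the decision logic under the stated admixture
model, not the end-to-end accuracy of the assay on real plasma.

## Numerical choices and degenerate inputs

Strict inequalities at ±0.3 and at the aneuploidy threshold (figure-style
"≥ 0.3" phrasing exists in the field; the strict form of the written rule was
chosen and the boundary value is classified neutral/negative). Control depths
≤ 0, a missing control region, fewer than two panel-of-normals members or
control assays, an empty cohort, and mismatched sample IDs between
classification and survival inputs are all named, fatal errors rather than
silent defaults. Within-caller SV deduplication is exact-key on
`(chrom1, pos1, chrom2, pos2, svtype)`. The consensus merge output is
independent of input ordering.

## Known limitations

* The *AR*-GSR membership test uses the gene body alone, without flanking
  capture targets; assays that tile flanking probes may call more events.
* Cross-caller SV matching ignores SV type; two nearby events of different
  types within tolerance merge into one consensus call.
* The GRCh37 *AR* model shipped under `data/` is externally sourced
  configuration for running against real call sets; all validation uses the
  round-number toy model, so the real coordinates are not themselves tested.
* Cox modeling, hazard-ratio estimation with covariates, and
  clinical risk-model integration are out of scope.
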