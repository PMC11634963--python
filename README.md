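# ctdnakit

Detection and classification of circulating tumor DNA (ctDNA) from targeted
cell-free DNA (cfDNA) sequencing panels, built for metastatic
castration-resistant prostate cancer (mCRPC) liquid biopsies where the
androgen receptor gene (*AR*) is the most informative target.

## The problem

Plasma cfDNA from cancer patients contains a tumor-derived fraction (ctDNA)
whose presence predicts poor outcomes, but low plasma volumes make it hard to
detect. Genome-wide aneuploidy estimators flag samples with high tumor
content; samples below that detection limit can still carry tumor-specific
signal in the form of high-amplitude focal events — *AR* gene-body and
upstream-enhancer amplification, *AR* gene structural rearrangements
(*AR*-GSRs), *MYC*/*MYCN* gains, and pathogenic somatic point mutations.
`ctdnakit` implements the decision logic that combines these signals into a
three-group call per sample:

* **Group 1** (aneuploidy-high): aneuploidy fraction `f > mean + 3·SD` of
  healthy-donor controls (the assay threshold; with control mean 0.0698 and
  SD 0.0241, the threshold is 0.1421).
* **Group 2** (aneuploidy-low, ctDNA-positive): `f` at or below the threshold
  but with at least one of — a pathogenic likely-somatic SNV, *AR* gene-body
  gain, *AR* enhancer gain, an *AR*-GSR, *MYC* gain, or *MYCN* gain
  (gain = `log2(copy ratio) > 0.3`).
* **Group 3** (ctDNA-negative): everything else.

## What is implemented

* **`panel`** — the genomic coordinate model: gene targets, the five
  depth-normalization control regions C1–C5 (C2 on chrX), an 8-exon *AR*
  model with stop codon and upstream enhancer, and an artifact blacklist.
  Internally 0-based half-open; BED/VCF conversion at the boundary.
* **`cnv`** — within-sample normalized depths
  (`depth / median(C1, 2·C2, C3, C4, C5)` for chrX targets,
  `depth / median(C1/2, C2, C3/2, C4/2, C5/2)` for autosomes), copy ratios
  against a panel of normals built from samples with aneuploidy fraction
  ≤ 0.05, and gain/neutral/loss states (`log2 > 0.3` gain; `log2 < −0.3`
  loss, called only in ctDNA-positive samples).
* **`variants`** — two-caller SNV/indel consensus: MNP decomposition,
  allele trimming and indel left-alignment, a ≥ 6 alt-read prefilter,
  intersection on the normalized `(chrom, pos, ref, alt)` key, an
  oncogenicity filter with a per-gene removal ledger and a FOXA1 override,
  and a likely-somatic vs likely-germline call from the VAF
  (germline: HSD3B1, or any non-exempt gene with VAF in [0.45, 0.55] or
  > 0.95).
* **`sv`** — breakend algebra: symbolic-to-breakend decomposition, SV type
  inference from breakend orientation, four-caller single-linkage consensus
  with a 1000 bp tolerance, blacklist filtering, *AR*-GSR detection
  (≥ 1 breakend in the *AR* gene body, ≥ 2 callers, ≥ 3 split and ≥ 3
  discordant reads), the four ligand-binding-domain (LBD) truncation rules,
  and the ecDNA signature (≥ 2 *AR*-GSRs plus *AR* body gain).
* **`classify`** — threshold derivation, per-sample feature aggregation,
  Group 1/2/3 assignment, and cohort summaries.
* **`survival`** — Kaplan-Meier estimates, log-rank tests, and
  Benjamini-Hochberg adjustment (via `lifelines`/`scipy`), with a cohort
  report renderer.
* **`simulate`** — a synthetic cohort generator that emits every input the
  pipeline consumes, with admixture-consistent copy-ratio dilution
  (`ratio = 1 + f·(CN_t/2 − 1)` on autosomes, `1 + f·(CN_t − 1)` on chrX),
  fraction-scaled VAFs, per-caller jitter and sensitivity, and per-group
  exponential survival.
* **`pipeline`** — the end-to-end orchestration, plus a small `ctdnakit` CLI.

## Worked example

```sh
ctdnakit simulate --seed 11 --n 120 --out demo/
ctdnakit run --bundle demo/ --out demo_report.json
```

prints

```
Samples: 120   ctDNA-positive: 74 (62%)
  Group1: n=38  KM median=27.7 mo
  Group2: n=36  KM median=29.1 mo
  Group3: n=46  KM median=43.7 mo
Log-rank (2 df): chi2=3.41, p=0.182
AR-altered among positives: 54 (73%)
```

Reading: 74 of 120 synthetic samples are called ctDNA-positive (38 above the
aneuploidy threshold, 36 rescued by focal *AR*/*MYC*/mutation signal), the
ctDNA-negative group survives markedly longer (43.7 vs ~28 months median),
and 73% of positives carry at least one *AR* alteration — the co-amplified
gene body/enhancer pattern dominating, as expected for mCRPC. At n = 120 the
three-way log-rank is underpowered (p = 0.18); at cohort scale (n = 1000)
the same generator settings yield p < 1e-14.

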