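# Externally sourced configuration: AR gene model on GRCh37/hg19.
#
# Coordinates are taken from public genome annotation (Ensembl GRCh37 release
# series) for the canonical AR transcript on chrX (plus strand), rounded to the
# annotated exon boundaries. This file is configuration for running the
# structural-rearrangement rules against real GRCh37 call sets; it is NOT used
# by the test suite or the acceptance computations, which rely exclusively on
# the round-number toy model so that boundary conventions are exercised
# explicitly. The enhancer interval is the recurrently amplified upstream
# regulatory region ~650 kb 5' of the gene body; its exact bounds are a
# configuration choice, not a measured quantity.
#
# Coordinates below are 0-based half-open (BED convention).
assembly: GRCh37
ar:
  gene_body: [chrX, 66763873, 66950461]
  exons:
    - [chrX, 66763873, 66766604]   # exon 1
    - [chrX, 66863097, 66863249]   # exon 2
    - [chrX, 66905851, 66905968]   # exon 3
    - [chrX, 66931243, 66931531]   # exon 4
    - [chrX, 66937319, 66937464]   # exon 5
    - [chrX, 66941674, 66941805]   # exon 6
    - [chrX, 66942668, 66942826]   # exon 7
    - [chrX, 66943527, 66950461]   # exon 8
  stop_codon: 66943680             # first base of the stop codon, exon 8
  enhancer: [chrX, 66113000, 66127000]
controls:
  # Depth-normalization control regions (0-based half-open).
  C1: [chr9, 98258994, 98264381]
  C2: [chrX, 16153016, 16159789]
  C3: [chr14, 105249979, 105255049]
  C4: [chr15, 40514991, 40520036]
  C5: [chr15, 67390101, 67395049]
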