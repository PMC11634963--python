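"""SNV/indel consensus filtering and somatic/germline classification.

Two callers' call sets are normalized (multi-nucleotide substitutions split
into per-base SNVs, shared allele bases trimmed, indels left-aligned against a
supplied reference context), pre-filtered to calls with at least 6 reads
supporting the alternate allele, and intersected on the (chrom, pos, ref, alt)
key. Retained variants must carry a pathogenic annotation:

* curated variants must be labeled Oncogenic or Likely Oncogenic;
* uncurated variants must be labeled Oncogenic/Likely Oncogenic AND must not
  carry a splice-site or splice-region consequence;
* a small per-gene removal ledger drops recurrent germline/artifact calls;
* FOXA1 bypasses the oncogenicity rules entirely: all FOXA1 variants are kept
  except synonymous ones and three listed substitutions.

Finally each kept variant is called likely germline if it affects HSD3B1, or
any gene other than AR/TP53/PTEN/ERF/PIK3CA/CDK12 with VAF in [0.45, 0.55] or
VAF > 0.95 (heterozygous/homozygous germline bands); otherwise likely somatic.

Positions are 1-based at I/O (VCF convention) and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RawVariantCall",
    "VariantAnnotation",
    "FilteredVariant",
    "VariantKey",
    "decompose_and_prefilter",
    "intersect_callers",
    "apply_pathogenicity_filter",
    "classify_origin",
    "run_variant_filter",
    "MIN_ALT_READS",
    "GERMLINE_EXEMPT_GENES",
    "GENE_SPECIFIC_REMOVALS",
    "GENE_SYNONYMS",
]

MIN_ALT_READS = 6
DNA = set("ACGT")

#: Genes exempt from the VAF-band germline call (recurrently somatically mutated
#: in this tumor type, where clonal VAFs can reach the heterozygous band).
GERMLINE_EXEMPT_GENES = frozenset({"AR", "TP53", "PTEN", "ERF", "PIK3CA", "CDK12"})

#: Known germline / non-pathogenic protein changes removed per gene.
GENE_SPECIFIC_REMOVALS: Mapping[str, frozenset[str]] = {
    "PMS2": frozenset({"p.Arg20Gln"}),
    "MET": frozenset({"p.Glu168Asp"}),
    "KMT2C": frozenset({"p.Tyr816Ter"}),
    "ATM": frozenset({"p.His1380Tyr"}),
    "FANCA": frozenset({"p.Ser1088Phe", "p.Ser858Arg"}),
    "NCOR1": frozenset({"p.Arg190Ter"}),
    "AURKA": frozenset({"p.Phe31Ile"}),
}

#: Symbol normalization applied before ledger lookup.
GENE_SYNONYMS: Mapping[str, str] = {"KMTC2": "KMT2C"}

FOXA1_REMOVALS = frozenset({"p.Ala83Thr", "p.Ser448Asn", "p.Leu148Val"})
ONCOGENIC_LABELS = frozenset({"Oncogenic", "Likely Oncogenic"})
SPLICE_CLASSES = frozenset({"splice-site", "splice-region"})

VariantKey = tuple[str, int, str, str]  # chrom, pos0, ref, alt


@dataclass(frozen=True)
class RawVariantCall:
    """One caller's record. ``pos`` is 0-based internally.

    ``context``/``context_start`` optionally give the reference sequence around
    the site (needed only to left-align indels without genome access).
    """

    sample_id: str
    caller: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    alt_reads: int
    context: str = ""
    context_start: int = -1

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if not self.ref or not self.alt or (set(self.ref) | set(self.alt)) - DNA:
            raise ValueError(f"alleles must be non-empty over ACGT: {self.ref}>{self.alt}")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.alt_reads < 0:
            raise ValueError("alt_reads < 0")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation keyed by variant.

    ``oncogenicity`` is the pathogenicity label consulted by the filter; for
    uncurated variants it comes from the annotation source rather than the
    curated knowledge base, hence the separate ``oncokb_curated`` flag.
    """

    gene: str
    protein_change: str = ""
    consequence_classes: frozenset[str] = field(default_factory=frozenset)
    oncokb_curated: bool = False
    oncogenicity: str | None = None  # "Oncogenic" | "Likely Oncogenic" | "Other" | None

    def __post_init__(self) -> None:
        if self.oncokb_curated and self.oncogenicity is None:
            raise ValueError("curated annotation must carry an oncogenicity label")

    @property
    def norm_gene(self) -> str:
        return GENE_SYNONYMS.get(self.gene, self.gene)


@dataclass(frozen=True)
class FilteredVariant:
    """Consensus variant that survived all filters (hence pathogenic)."""

    sample_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    gene: str
    protein_change: str
    vaf: float
    alt_reads: int
    origin: str  # "likely_somatic" | "likely_germline"
    pathogenic: bool = True

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix then prefix bases, keeping at least one base each."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _left_align(pos: int, ref: str, alt: str, context: str, context_start: int) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent representation.

    Standard rotation: while ref and alt end in the same base, drop it and
    prepend the reference base preceding ``pos`` (taken from ``context``).
    No-op when no context is supplied or the variant is not an indel.
    """
    if len(ref) == len(alt) or not context or context_start < 0:
        return pos, ref, alt
    while (
        ref and alt and ref[-1] == alt[-1]
        and context_start <= pos - 1 < context_start + len(context)
    ):
        prev = context[pos - 1 - context_start]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return pos, ref, alt


def normalize_call(call: RawVariantCall) -> list[RawVariantCall]:
    """Decompose one record into normalized atomic records.

    Equal-length multi-base substitutions become one SNV per differing base
    (inheriting vaf and alt_reads); indels are trimmed and left-aligned.
    """
    pos, ref, alt = _trim_alleles(call.pos, call.ref, call.alt)
    if len(ref) == len(alt):
        if len(ref) == 1:
            return [replace(call, pos=pos, ref=ref, alt=alt)]
        return [
            replace(call, pos=pos + i, ref=r, alt=a)
            for i, (r, a) in enumerate(zip(ref, alt))
            if r != a
        ]
    pos, ref, alt = _left_align(pos, ref, alt, call.context, call.context_start)
    return [replace(call, pos=pos, ref=ref, alt=alt)]


def decompose_and_prefilter(
    calls: Iterable[RawVariantCall], min_alt_reads: int = MIN_ALT_READS
) -> list[RawVariantCall]:
    """Normalize every record and drop those with < ``min_alt_reads`` alt reads."""
    out: list[RawVariantCall] = []
    for call in calls:
        if call.alt_reads < min_alt_reads:
            continue
        out.extend(normalize_call(call))
    return out


def intersect_callers(
    set_a: Sequence[RawVariantCall], set_b: Sequence[RawVariantCall]
) -> list[RawVariantCall]:
    """Consensus = identical normalized keys in both sets (genotype ignored).

    The consensus record carries caller A's vaf and alt_reads. Order follows
    set A; duplicate keys within A collapse to the first occurrence.
    """
    keys_b = {c.key for c in set_b}
    seen: set[VariantKey] = set()
    out = []
    for c in set_a:
        if c.key in keys_b and c.key not in seen:
            seen.add(c.key)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Pathogenicity filter and origin classification
# ---------------------------------------------------------------------------

def apply_pathogenicity_filter(annotation: VariantAnnotation) -> tuple[bool, str | None]:
    """Keep/drop with a machine-readable drop reason (None when kept)."""
    gene = annotation.norm_gene
    pchange = annotation.protein_change
    synonymous = "synonymous" in annotation.consequence_classes

    if gene == "FOXA1":
        if synonymous:
            return False, "foxa1_synonymous"
        if pchange in FOXA1_REMOVALS:
            return False, "foxa1_listed_removal"
        return True, None

    if pchange and pchange in GENE_SPECIFIC_REMOVALS.get(gene, frozenset()):
        return False, "gene_specific_ledger"
    if annotation.oncogenicity not in ONCOGENIC_LABELS:
        return False, "not_oncogenic"
    if not annotation.oncokb_curated and annotation.consequence_classes & SPLICE_CLASSES:
        return False, "uncurated_splice"
    return True, None


def classify_origin(gene: str, vaf: float) -> str:
    """Likely germline iff HSD3B1, or a non-exempt gene in a germline VAF band."""
    gene = GENE_SYNONYMS.get(gene, gene)
    if gene == "HSD3B1":
        return "likely_germline"
    if gene not in GERMLINE_EXEMPT_GENES and (0.45 <= vaf <= 0.55 or vaf > 0.95):
        return "likely_germline"
    return "likely_somatic"


def run_variant_filter(
    calls_a: Sequence[RawVariantCall],
    calls_b: Sequence[RawVariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    min_alt_reads: int = MIN_ALT_READS,
) -> tuple[list[FilteredVariant], list[dict]]:
    """Full per-sample filter pipeline.

    Returns the retained variants and an audit log: one entry per dropped
    consensus candidate or per non-consensus key, with exactly one drop reason.
    """
    audit: list[dict] = []

    norm_a = decompose_and_prefilter(calls_a, min_alt_reads)
    norm_b = decompose_and_prefilter(calls_b, min_alt_reads)
    consensus = intersect_callers(norm_a, norm_b)

    consensus_keys = {c.key for c in consensus}
    for c in norm_a:
        if c.key not in consensus_keys:
            audit.append({"key": c.key, "caller": c.caller, "reason": "not_in_both_callers"})

    kept: list[FilteredVariant] = []
    for c in consensus:
        ann = annotations.get(c.key)
        if ann is None:
            audit.append({"key": c.key, "caller": c.caller, "reason": "unannotated"})
            continue
        keep, reason = apply_pathogenicity_filter(ann)
        if not keep:
            audit.append({"key": c.key, "caller": c.caller, "reason": reason})
            continue
        origin = classify_origin(ann.norm_gene, c.vaf)
        kept.append(
            FilteredVariant(
                sample_id=c.sample_id,
                chrom=c.chrom,
                pos=c.pos,
                ref=c.ref,
                alt=c.alt,
                gene=ann.norm_gene,
                protein_change=ann.protein_change,
                vaf=c.vaf,
                alt_reads=c.alt_reads,
                origin=origin,
            )
        )
    return kept, audit
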