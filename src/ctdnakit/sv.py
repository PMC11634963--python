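"""Breakend algebra, multi-caller SV consensus, and AR rearrangement rules.

A structural variant is a pair of breakends. Each breakend records which flank
of its position the rearranged molecule keeps (``retains_left`` keeps sequence
up to and including the position; ``retains_right`` keeps the position and
everything after it). For a same-chromosome pair ordered p1 < p2 the
orientation combination determines the SV type:

* (retains_left, retains_right)  -> DEL  (interior segment lost)
* (retains_right, retains_left)  -> DUP  (tandem duplication adjacency)
* equal sides                    -> INV  (one of the two inversion adjacencies)

Breakends on different chromosomes are translocations (TRA). Calls from four
callers are merged by single-linkage clustering under a positional tolerance
(default 1000 bp on both breakends); clusters supported by >= 2 callers with
>= 3 split and >= 3 discordant reads and at least one breakend inside the AR
gene body are AR gene structural rearrangements (AR-GSRs). Four interval rules
then identify AR-GSRs predicted to encode a ligand-binding-domain-truncated AR
protein, and samples with >= 2 AR-GSRs plus AR gene-body copy gain are flagged
as likely carrying AR ecDNA.

Positions are 0-based internally, 1-based at VCF I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .panel import ARModel, GenomicInterval

RETAINS_LEFT = "retains_left"
RETAINS_RIGHT = "retains_right"
SV_MATCH_TOLERANCE = 1000
MIN_SUPPORTING_CALLERS = 2
MIN_SPLIT_READS = 3
MIN_DISCORDANT_READS = 3
ECDNA_MIN_GSRS = 2
ECDNA_MIN_AR_LOG2 = 0.3

__all__ = [
    "Breakend",
    "StructuralVariant",
    "ConsensusSV",
    "ARGSRCall",
    "SvError",
    "infer_svtype",
    "decompose_to_breakends",
    "match_sv",
    "consensus_merge",
    "filter_blacklist",
    "detect_ar_gsrs",
    "classify_lbd_truncating",
    "flag_ecdna",
    "dedup_within_caller",
]


class SvError(ValueError):
    """Malformed breakend/SV record."""


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 0-based
    side: str  # retains_left | retains_right

    def __post_init__(self) -> None:
        if self.side not in (RETAINS_LEFT, RETAINS_RIGHT):
            raise SvError(f"malformed breakend orientation: {self.side!r}")
        if self.pos < 0:
            raise SvError("breakend position < 0")


@dataclass(frozen=True)
class StructuralVariant:
    """A breakend pair with caller provenance and read support."""

    bnd1: Breakend
    bnd2: Breakend
    svtype: str  # DEL | DUP | INV | BND | TRA
    split_reads: int = 0
    discordant_reads: int = 0
    caller: str = ""

    @property
    def length(self) -> int:
        """Base-pair difference between breakends; -1 for translocations."""
        if self.bnd1.chrom != self.bnd2.chrom:
            return -1
        return abs(self.bnd2.pos - self.bnd1.pos)

    def canonical_pair(self) -> tuple[Breakend, Breakend]:
        """Breakends sorted by (chrom, pos) so comparisons are orientation-stable."""
        a, b = self.bnd1, self.bnd2
        return (a, b) if (a.chrom, a.pos) <= (b.chrom, b.pos) else (b, a)

    @property
    def dedup_key(self) -> tuple:
        a, b = self.canonical_pair()
        return (a.chrom, a.pos, b.chrom, b.pos, self.svtype)

    def ar_side_breakend(self, ar: ARModel) -> Breakend | None:
        """The breakend inside the AR gene body, if any (first of the pair wins)."""
        for bnd in self.canonical_pair():
            if ar.gene_body.contains_point(bnd.chrom, bnd.pos):
                return bnd
        return None


@dataclass(frozen=True)
class ConsensusSV:
    """Cluster of matching calls across callers, with per-field max read support."""

    representative: StructuralVariant
    supporting_callers: frozenset[str]
    best_split_reads: int
    best_discordant_reads: int
    cluster_size: int = 1

    @property
    def svtype(self) -> str:
        return self.representative.svtype


@dataclass(frozen=True)
class ARGSRCall:
    sv: ConsensusSV
    in_ar_region: bool
    lbd_truncating: bool
    matched_rule: int | None  # 1..4 or None


# ---------------------------------------------------------------------------
# Breakend algebra
# ---------------------------------------------------------------------------

def infer_svtype(bnd1: Breakend, bnd2: Breakend) -> str:
    """SV type from breakend orientation and mate chromosome."""
    if bnd1.chrom != bnd2.chrom:
        return "TRA"
    a, b = (bnd1, bnd2) if bnd1.pos <= bnd2.pos else (bnd2, bnd1)
    if a.side == b.side:
        return "INV"
    if a.side == RETAINS_LEFT:  # and b retains_right
        return "DEL"
    return "DUP"


def decompose_to_breakends(
    svtype: str, chrom: str, pos: int, end: int | None, inv_layout: str = RETAINS_LEFT
) -> tuple[Breakend, Breakend]:
    """Symbolic DEL/DUP/INV -> the breakend pair that round-trips its type.

    ``inv_layout`` selects which of the two inversion adjacencies to emit.
    """
    if end is None:
        raise SvError(f"symbolic {svtype} record missing END coordinate")
    if svtype == "DEL":
        return Breakend(chrom, pos, RETAINS_LEFT), Breakend(chrom, end, RETAINS_RIGHT)
    if svtype == "DUP":
        return Breakend(chrom, pos, RETAINS_RIGHT), Breakend(chrom, end, RETAINS_LEFT)
    if svtype == "INV":
        return Breakend(chrom, pos, inv_layout), Breakend(chrom, end, inv_layout)
    raise SvError(f"cannot decompose symbolic type {svtype!r}")


def match_sv(a: StructuralVariant, b: StructuralVariant, tolerance: int = SV_MATCH_TOLERANCE) -> bool:
    """True iff chromosome pairs agree and both breakends are within tolerance.

    Symmetric; svtype is deliberately not compared (cross-caller type labels
    disagree for the same adjacency).
    """
    a1, a2 = a.canonical_pair()
    b1, b2 = b.canonical_pair()
    return (
        a1.chrom == b1.chrom
        and a2.chrom == b2.chrom
        and abs(a1.pos - b1.pos) <= tolerance
        and abs(a2.pos - b2.pos) <= tolerance
    )


def dedup_within_caller(svs: Iterable[StructuralVariant]) -> list[StructuralVariant]:
    """Exact-key dedup on (chrom1, pos1, chrom2, pos2, svtype)."""
    seen: set[tuple] = set()
    out = []
    for sv in svs:
        if sv.dedup_key not in seen:
            seen.add(sv.dedup_key)
            out.append(sv)
    return out


def consensus_merge(
    per_caller_sets: Mapping[str, Sequence[StructuralVariant]],
    tolerance: int = SV_MATCH_TOLERANCE,
) -> list[ConsensusSV]:
    """Single-linkage clustering of all callers' calls under :func:`match_sv`.

    Each cluster becomes one consensus SV: supporting callers are the union,
    read-support fields are per-field maxima, and the representative is the
    member from the lexicographically smallest caller ID (position as
    tie-break), making the output independent of input order.
    """
    members: list[StructuralVariant] = []
    for caller in sorted(per_caller_sets):
        members.extend(dedup_within_caller(per_caller_sets[caller]))

    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if match_sv(members[i], members[j], tolerance):
                union(i, j)

    clusters: dict[int, list[StructuralVariant]] = {}
    for i, sv in enumerate(members):
        clusters.setdefault(find(i), []).append(sv)

    out = []
    for group in clusters.values():
        rep = min(group, key=lambda s: (s.caller, s.dedup_key))
        out.append(
            ConsensusSV(
                representative=rep,
                supporting_callers=frozenset(s.caller for s in group),
                best_split_reads=max(s.split_reads for s in group),
                best_discordant_reads=max(s.discordant_reads for s in group),
                cluster_size=len(group),
            )
        )
    out.sort(key=lambda c: c.representative.dedup_key)
    return out


def filter_blacklist(
    svs: Sequence[ConsensusSV], blacklist: Sequence[GenomicInterval]
) -> list[ConsensusSV]:
    """Drop consensus SVs with either breakend inside a blacklist interval."""
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def hit(bnd: Breakend) -> bool:
        tree = trees.get(bnd.chrom)
        return bool(tree is not None and tree[bnd.pos])

    return [sv for sv in svs if not (hit(sv.representative.bnd1) or hit(sv.representative.bnd2))]


# ---------------------------------------------------------------------------
# AR-GSR detection and LBD-truncation rules
# ---------------------------------------------------------------------------

def detect_ar_gsrs(consensus: Sequence[ConsensusSV], ar: ARModel) -> list[ARGSRCall]:
    """AR-GSRs: >=1 breakend in the AR gene body, >=2 callers, >=3 SR and >=3 PE."""
    out = []
    for sv in consensus:
        if sv.representative.ar_side_breakend(ar) is None:
            continue
        if len(sv.supporting_callers) < MIN_SUPPORTING_CALLERS:
            continue
        if sv.best_split_reads < MIN_SPLIT_READS or sv.best_discordant_reads < MIN_DISCORDANT_READS:
            continue
        rule = classify_lbd_truncating(sv, ar)
        out.append(ARGSRCall(sv, in_ar_region=True, lbd_truncating=rule is not None, matched_rule=rule))
    return out


def _span(sv: StructuralVariant) -> tuple[int, int] | None:
    """Same-chromosome span [min(pos), max(pos)); None for cross-chromosome events."""
    if sv.bnd1.chrom != sv.bnd2.chrom:
        return None
    lo, hi = sorted((sv.bnd1.pos, sv.bnd2.pos))
    return lo, hi


def _overlaps(lo: int, hi: int, iv: GenomicInterval) -> bool:
    return lo < iv.end and iv.start < hi


def classify_lbd_truncating(sv: ConsensusSV, ar: ARModel) -> int | None:
    """Lowest-numbered satisfied LBD-truncation rule, or None.

    The rules predict whether the rearranged AR allele can still express the
    exon 1-3 reading frame (N-terminal domain and DNA-binding domain) while
    losing or disrupting the ligand-binding domain encoded by exons 4-8:

    1. DEL/INV/BND overlapping exon 4, 5, 6, 7 and/or the exon 8 start-to-stop
       interval, without touching the exon 1-3 span.
    2. DUP/INV/BND fully covering the exon 1-3 span with a breakpoint between
       the end of exon 3 and the stop codon.
    3. DUP with both breakpoints inside the gene body, fully containing at
       least one of exons 3-7.
    4. TRA whose AR-side breakend lies between the end of exon 3 and the stop
       codon and retains the centromeric (lower-coordinate, exon 1-3) side.

    "Breakpoint" means either breakend position; membership of the breakpoint
    window [exon3.end, stop_codon] is inclusive at both ends.
    """
    rep = sv.representative
    svtype = rep.svtype
    span = _span(rep)
    window = ar.breakpoint_window  # [exon3.end, stop_codon + 1)
    lbd_intervals = [ar.exons[3], ar.exons[4], ar.exons[5], ar.exons[6], ar.lbd_tail]

    def breakpoint_in_window(bnd: Breakend) -> bool:
        return window.contains_point(bnd.chrom, bnd.pos)

    # Rule 1 — loses LBD exons while sparing the exon 1-3 span.
    if svtype in ("DEL", "INV", "BND") and span is not None:
        lo, hi = span
        if any(_overlaps(lo, hi, iv) for iv in lbd_intervals) and not _overlaps(lo, hi, ar.head):
            return 1
    # Rule 2 — duplicates/rearranges the intact exon 1-3 unit with an LBD break.
    if svtype in ("DUP", "INV", "BND") and span is not None:
        lo, hi = span
        if lo <= ar.head.start and hi >= ar.head.end and (
            breakpoint_in_window(rep.bnd1) or breakpoint_in_window(rep.bnd2)
        ):
            return 2
    # Rule 3 — internal tandem duplication flanking one or more of exons 3-7.
    if svtype == "DUP" and span is not None:
        lo, hi = span
        in_gene = ar.gene_body.contains_point(rep.bnd1.chrom, rep.bnd1.pos) and \
            ar.gene_body.contains_point(rep.bnd2.chrom, rep.bnd2.pos)
        if in_gene and any(
            lo <= ex.start and ex.end <= hi for ex in ar.exons[2:7]
        ):
            return 3
    # Rule 4 — translocation keeping the centromeric exon 1-3 side.
    if svtype == "TRA":
        ar_bnd = rep.ar_side_breakend(ar)
        if ar_bnd is not None and breakpoint_in_window(ar_bnd) and ar_bnd.side == RETAINS_LEFT:
            return 4
    return None


def flag_ecdna(sample_ar_gsr_count: int, ar_body_log2: float) -> bool:
    """Likely AR ecDNA: >=2 AR-GSRs and AR gene-body log2 ratio > 0.3 (strict)."""
    return sample_ar_gsr_count >= ECDNA_MIN_GSRS and ar_body_log2 > ECDNA_MIN_AR_LOG2
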