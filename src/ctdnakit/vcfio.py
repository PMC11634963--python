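"""VCF 4.2 I/O for per-caller SNV/indel and SV call sets.

Readers use pysam and convert to the package's 0-based internal coordinates;
writers emit plain-text VCF 4.2. SNV records carry VAF, alt-read count, and an
optional reference-context string (for indel left-alignment) in INFO fields
whose names are declared in a small schema. SV records are written as breakend
(BND) pairs in bracket notation; symbolic DEL/DUP/INV records with an END key
are also accepted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pysam

from .sv import (
    RETAINS_LEFT,
    RETAINS_RIGHT,
    Breakend,
    StructuralVariant,
    SvError,
    decompose_to_breakends,
    infer_svtype,
)
from .variants import RawVariantCall

CONTIGS = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"])


@dataclass(frozen=True)
class SnvSchema:
    """INFO field names carrying the numeric annotations of an SNV record."""

    vaf: str = "VAF"
    alt_reads: str = "AO"
    context: str = "CTX"
    context_start: str = "CTXS"  # 1-based start of the context string


@dataclass(frozen=True)
class SvSchema:
    """INFO field names carrying read support for an SV caller."""

    split_reads: str = "SR"
    discordant_reads: str = "PE"


def _vcf_header(extra_info: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in CONTIGS]
    lines += list(extra_info)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SNV/indel
# ---------------------------------------------------------------------------

def write_snv_vcf(calls: Sequence[RawVariantCall], path: str | Path, schema: SnvSchema = SnvSchema()) -> None:
    info_defs = [
        f'##INFO=<ID={schema.vaf},Number=1,Type=Float,Description="Variant allele fraction">',
        f'##INFO=<ID={schema.alt_reads},Number=1,Type=Integer,Description="Alternate allele read count">',
        f'##INFO=<ID={schema.context},Number=1,Type=String,Description="Reference context sequence">',
        f'##INFO=<ID={schema.context_start},Number=1,Type=Integer,Description="1-based start of context">',
    ]
    with open(path, "w") as fh:
        fh.write(_vcf_header(info_defs))
        for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info = f"{schema.vaf}={c.vaf:.6g};{schema.alt_reads}={c.alt_reads}"
            if c.context:
                info += f";{schema.context}={c.context};{schema.context_start}={c.context_start + 1}"
            fh.write(f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_snv_vcf(
    path: str | Path, sample_id: str, caller: str, schema: SnvSchema = SnvSchema()
) -> list[RawVariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            info = rec.info
            ctx = info.get(schema.context, "") or ""
            ctx_start = int(info.get(schema.context_start, 0)) - 1
            out.append(
                RawVariantCall(
                    sample_id=sample_id,
                    caller=caller,
                    chrom=rec.chrom,
                    pos=rec.start,  # pysam start is 0-based
                    ref=rec.ref,
                    alt=rec.alts[0],
                    vaf=float(info[schema.vaf]),
                    alt_reads=int(info[schema.alt_reads]),
                    context=ctx,
                    context_start=ctx_start if ctx else -1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def _bracket_alt(this: Breakend, mate: Breakend, ref_base: str = "N") -> str:
    """VCF 4.2 bracket notation for one end of an adjacency.

    The placed base precedes the bracket when this breakend retains its left
    flank, and follows it otherwise; the bracket direction encodes which flank
    the mate retains ('[' -> right, ']' -> left).
    """
    bracket = "[" if mate.side == RETAINS_RIGHT else "]"
    mate_loc = f"{mate.chrom}:{mate.pos + 1}"
    if this.side == RETAINS_LEFT:
        return f"{ref_base}{bracket}{mate_loc}{bracket}"
    return f"{bracket}{mate_loc}{bracket}{ref_base}"


def parse_bracket_alt(alt: str) -> tuple[str, str, int, str]:
    """Parse a bracket ALT -> (this_side, mate_chrom, mate_pos0, mate_side)."""
    for bracket, mate_side in (("[", RETAINS_RIGHT), ("]", RETAINS_LEFT)):
        if bracket in alt:
            first = alt.index(bracket)
            last = alt.rindex(bracket)
            if first == last:
                raise SvError(f"malformed breakend ALT {alt!r}")
            loc = alt[first + 1:last]
            chrom, _, pos_s = loc.rpartition(":")
            this_side = RETAINS_LEFT if first > 0 else RETAINS_RIGHT
            return this_side, chrom, int(pos_s) - 1, mate_side
    raise SvError(f"not a breakend ALT: {alt!r}")


def write_sv_vcf(svs: Sequence[StructuralVariant], path: str | Path, schema: SvSchema = SvSchema()) -> None:
    """Write each SV as a pair of BND records linked by MATEID."""
    info_defs = [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
        f'##INFO=<ID={schema.split_reads},Number=1,Type=Integer,Description="Split read support">',
        f'##INFO=<ID={schema.discordant_reads},Number=1,Type=Integer,Description="Discordant pair support">',
    ]
    with open(path, "w") as fh:
        fh.write(_vcf_header(info_defs))
        rows = []
        for i, sv in enumerate(sorted(svs, key=lambda s: s.dedup_key)):
            ids = (f"bnd_{i}_1", f"bnd_{i}_2")
            for k, (this, mate) in enumerate(((sv.bnd1, sv.bnd2), (sv.bnd2, sv.bnd1))):
                info = (
                    f"SVTYPE=BND;MATEID={ids[1 - k]};"
                    f"{schema.split_reads}={sv.split_reads};{schema.discordant_reads}={sv.discordant_reads}"
                )
                rows.append((this.chrom, this.pos + 1, ids[k], "N",
                             _bracket_alt(this, mate), info))
        for chrom, pos, rid, ref, alt, info in sorted(rows):
            fh.write(f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def read_sv_vcf(path: str | Path, caller: str, schema: SvSchema = SvSchema()) -> list[StructuralVariant]:
    """Read breakend and symbolic records into StructuralVariant pairs.

    Records flagged IMPRECISE are dropped. Cross-chromosome events are labeled
    TRA; same-chromosome breakend pairs take the record's SVTYPE when it names
    a concrete type, otherwise the type inferred from orientation.
    """
    out: list[StructuralVariant] = []
    seen: set[tuple] = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if "IMPRECISE" in rec.info:
                continue
            alt = rec.alts[0] if rec.alts else ""
            info = rec.info
            sr = int(info.get(schema.split_reads, 0))
            pe = int(info.get(schema.discordant_reads, 0))
            svtype_info = info.get("SVTYPE", "")
            if alt.startswith("<"):
                end = info.get("END") or rec.stop
                b1, b2 = decompose_to_breakends(svtype_info, rec.chrom, rec.start, int(end))
                svtype = svtype_info
            else:
                this_side, mate_chrom, mate_pos, mate_side = parse_bracket_alt(alt)
                b1 = Breakend(rec.chrom, rec.start, this_side)
                b2 = Breakend(mate_chrom, mate_pos, mate_side)
                if b1.chrom != b2.chrom:
                    svtype = "TRA"
                elif svtype_info in ("DEL", "DUP", "INV", "TRA"):
                    svtype = svtype_info
                else:
                    svtype = infer_svtype(b1, b2)
            sv = StructuralVariant(b1, b2, svtype, sr, pe, caller)
            if sv.dedup_key not in seen:
                seen.add(sv.dedup_key)
                out.append(sv)
    return out
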