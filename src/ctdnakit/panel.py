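"""Genomic coordinate model for a targeted cfDNA panel.

All coordinates are held internally as 0-based half-open intervals. BED I/O is
native (BED is already 0-based half-open); VCF-style positions are converted at
the boundary (1-based, inclusive). The panel consists of gene targets (exons),
five control regions C1..C5 used for within-sample depth normalization (exactly
one, C2, on chrX), a detailed AR gene model (8 exons, stop codon, upstream
enhancer) used by the structural-rearrangement rules, and a blacklist of
artifact-prone mapping regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

CONTROL_LABELS = ("C1", "C2", "C3", "C4", "C5")

__all__ = [
    "GenomicInterval",
    "ControlRegionSet",
    "GeneTarget",
    "ARModel",
    "PanelModel",
    "PanelError",
    "load_panel",
    "validate_panel",
    "toy_panel",
    "panel_to_json",
    "panel_from_json",
    "CONTROL_LABELS",
]


class PanelError(ValueError):
    """Fatal panel construction/validation error."""


def is_chrx(chrom: str) -> bool:
    return chrom.removeprefix("chr").upper() == "X"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PanelError(
                f"invalid interval {self.label or ''} {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based position, half-open convention."""
        return chrom == self.chrom and self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class ControlRegionSet:
    """The five depth-normalization control regions C1..C5 (C2 on chrX)."""

    regions: Mapping[str, GenomicInterval]

    def violations(self) -> list[str]:
        # Reports rather than raising so validate_panel can collect everything.
        out: list[str] = []
        extra = set(self.regions) - set(CONTROL_LABELS)
        if extra:
            out.append(f"ControlRegionSet: unexpected labels {sorted(extra)}")
        if len([lab for lab in CONTROL_LABELS if lab in self.regions]) != 5:
            out.append("ControlRegionSet requires 5 regions C1..C5")
        on_x = [lab for lab, iv in self.regions.items() if is_chrx(iv.chrom)]
        if on_x != ["C2"]:
            out.append(f"ControlRegionSet: exactly C2 must lie on chrX (found {on_x})")
        labs = list(self.regions)
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                if self.regions[a].overlaps(self.regions[b]):
                    out.append(f"ControlRegionSet: {a} overlaps {b}")
        return out

    def __getitem__(self, label: str) -> GenomicInterval:
        return self.regions[label]


@dataclass(frozen=True)
class GeneTarget:
    """A panel gene: ordered, non-overlapping exon intervals on one chromosome."""

    symbol: str
    chrom: str
    exons: tuple[GenomicInterval, ...]
    strand: str = "+"

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.strand not in ("+", "-"):
            out.append(f"{self.symbol}: strand must be + or -")
        if not self.exons:
            out.append(f"{self.symbol}: no exons")
            return out
        for ex in self.exons:
            if ex.chrom != self.chrom:
                out.append(f"{self.symbol}: exon on {ex.chrom}, gene on {self.chrom}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                out.append(f"{self.symbol}: exons overlap or are unsorted")
                break
        return out

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.symbol)


@dataclass(frozen=True)
class ARModel:
    """AR gene model: gene body, 8 exons, stop codon position, upstream enhancer.

    AR is plus-strand on chrX, so exon 1 is the centromere-proximal (lowest
    coordinate) exon. ``stop_codon`` is the 0-based position of the first base
    of the stop codon inside exon 8; intervals described as running "through
    the stop codon" end at ``stop_codon + 1``.
    """

    gene_body: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    stop_codon: int
    enhancer: GenomicInterval

    def violations(self) -> list[str]:
        out: list[str] = []
        if not is_chrx(self.gene_body.chrom):
            out.append("ARModel: gene_body must lie on chrX")
        if len(self.exons) != 8:
            out.append(f"ARModel: requires exactly 8 exons (got {len(self.exons)})")
            return out
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                out.append("ARModel: exons must be ordered by increasing coordinate")
                break
        for ex in self.exons:
            if not self.gene_body.contains_interval(ex):
                out.append(f"ARModel: exon outside gene body ({ex.start}-{ex.end})")
        e8 = self.exons[7]
        if not (e8.start <= self.stop_codon < e8.end):
            out.append("ARModel: stop_codon must lie inside exon 8")
        if self.enhancer.overlaps(self.gene_body):
            out.append("ARModel: enhancer overlaps gene_body")
        if self.enhancer.chrom != self.gene_body.chrom or self.enhancer.end > self.gene_body.start:
            out.append("ARModel: enhancer must lie upstream of gene_body on the same chromosome")
        return out

    # Derived intervals used by the LBD-truncation rules -------------------
    @property
    def head(self) -> GenomicInterval:
        """Start of exon 1 through the end of exon 3 (encodes the AR N-terminal domain/DBD)."""
        return GenomicInterval(self.gene_body.chrom, self.exons[0].start, self.exons[2].end, "AR_exon1_3")

    @property
    def lbd_tail(self) -> GenomicInterval:
        """Start of exon 8 through the stop codon."""
        return GenomicInterval(self.gene_body.chrom, self.exons[7].start, self.stop_codon + 1, "AR_exon8_to_stop")

    @property
    def breakpoint_window(self) -> GenomicInterval:
        """End of exon 3 through the stop codon in exon 8."""
        return GenomicInterval(self.gene_body.chrom, self.exons[2].end, self.stop_codon + 1, "AR_bkpt_window")


@dataclass(frozen=True)
class PanelModel:
    """Full panel: gene targets, control regions, AR model, blacklist."""

    assembly: str
    genes: tuple[GeneTarget, ...]
    controls: ControlRegionSet
    ar: ARModel
    blacklist: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def gene(self, symbol: str) -> GeneTarget:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def target_chrom(self, target_label: str) -> str:
        """Chromosome of a depth target; 'AR_enhancer' maps to the enhancer interval."""
        if target_label == "AR_enhancer":
            return self.ar.enhancer.chrom
        return self.gene(target_label).chrom

    @property
    def target_labels(self) -> tuple[str, ...]:
        """All copy-ratio targets: every gene plus the AR enhancer."""
        return tuple(g.symbol for g in self.genes) + ("AR_enhancer",)


def validate_panel(panel: PanelModel) -> list[str]:
    """Collect invariant violations; empty list iff the panel is valid.

    Reports, never throws.
    """
    out: list[str] = []
    out.extend(panel.controls.violations())
    seen: set[str] = set()
    for g in panel.genes:
        if g.symbol in seen:
            out.append(f"duplicate gene symbol {g.symbol}")
        seen.add(g.symbol)
        out.extend(g.violations())
    out.extend(panel.ar.violations())
    if "AR" not in seen:
        out.append("panel must include AR as a GeneTarget")
    else:
        ar_gene = panel.gene("AR")
        if ar_gene.span.chrom != panel.ar.gene_body.chrom or (
            ar_gene.span.start != panel.ar.gene_body.start or ar_gene.span.end != panel.ar.gene_body.end
        ):
            out.append("AR GeneTarget span must equal ARModel gene_body")
    return out


# ---------------------------------------------------------------------------
# Construction & I/O
# ---------------------------------------------------------------------------

def toy_panel() -> PanelModel:
    """Round-number panel used throughout the test fixtures.

    AR occupies chrX:1000-9000 with eight 600 bp exons every 1000 bp and the
    stop codon at 8900; the enhancer sits upstream at chrX:100-400. A handful
    of autosomal targets cover the genes the classifier consults. The blacklist
    holds one decoy interval far from every target.
    """
    def mk_exons(chrom: str, starts: Sequence[int], width: int) -> tuple[GenomicInterval, ...]:
        return tuple(GenomicInterval(chrom, s, s + width) for s in starts)

    ar_exons = tuple(GenomicInterval("chrX", 1000 + i * 1000, 1000 + i * 1000 + 600) for i in range(8))
    # exon 8 widened so the stop codon at 8900 lies inside it
    ar_exons = ar_exons[:7] + (GenomicInterval("chrX", 8000, 9000),)
    ar = ARModel(
        gene_body=GenomicInterval("chrX", 1000, 9000, "AR"),
        exons=ar_exons,
        stop_codon=8900,
        enhancer=GenomicInterval("chrX", 100, 400, "AR_enhancer"),
    )
    autosomal = {
        "TP53": ("chr17", (10000, 12000, 14000)),
        "PTEN": ("chr10", (20000, 22000)),
        "RB1": ("chr13", (30000, 32000)),
        "MYC": ("chr8", (40000, 42000)),
        "MYCN": ("chr2", (50000, 52000)),
        "BRCA2": ("chr13", (60000, 62000, 64000)),
        "HSD3B1": ("chr1", (70000, 72000)),
        "ERF": ("chr19", (80000,)),
        "PIK3CA": ("chr3", (90000, 92000)),
        "CDK12": ("chr17", (100000, 102000)),
        "FOXA1": ("chr14", (110000,)),
        "ATM": ("chr11", (120000, 122000)),
        "SPOP": ("chr17", (130000,)),
    }
    genes = [GeneTarget("AR", "chrX", ar_exons)]
    for sym, (chrom, starts) in autosomal.items():
        genes.append(GeneTarget(sym, chrom, mk_exons(chrom, starts, 800)))
    controls = ControlRegionSet({
        "C1": GenomicInterval("chr9", 1_000_000, 1_005_000, "C1"),
        "C2": GenomicInterval("chrX", 16_000_000, 16_005_000, "C2"),
        "C3": GenomicInterval("chr14", 1_000_000, 1_005_000, "C3"),
        "C4": GenomicInterval("chr15", 1_000_000, 1_005_000, "C4"),
        "C5": GenomicInterval("chr15", 2_000_000, 2_005_000, "C5"),
    })
    blacklist = (GenomicInterval("chrX", 5_000_000, 5_010_000, "decoy"),)
    panel = PanelModel("toy", tuple(genes), controls, ar, blacklist)
    problems = validate_panel(panel)
    assert not problems, problems
    return panel


def _read_bed(path: Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PanelError(f"{path}:{ln}: malformed BED line (need >=3 columns)")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise PanelError(f"{path}:{ln}: non-integer BED coordinates") from exc
        label = parts[3] if len(parts) > 3 else ""
        out.append(GenomicInterval(parts[0], start, end, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def _interval_from_cfg(value, label: str = "") -> GenomicInterval:
    chrom, start, end = value[0], int(value[1]), int(value[2])
    return GenomicInterval(chrom, start, end, label)


def load_panel(config_path: str | Path) -> PanelModel:
    """Load and validate a PanelModel from a YAML config plus BED files.

    The config names the assembly, the five control regions, the AR model
    (gene body, 8 exons, stop codon, enhancer), a genes BED (one row per exon,
    column 4 = gene symbol) and optionally a blacklist BED and a strand map.
    Raises :class:`PanelError` naming the offending field on any violation.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    base = config_path.parent

    if "ar" not in cfg:
        raise PanelError("panel config: AR model absent")
    arc = cfg["ar"]
    ar = ARModel(
        gene_body=_interval_from_cfg(arc["gene_body"], "AR"),
        exons=tuple(_interval_from_cfg(e) for e in arc["exons"]),
        stop_codon=int(arc["stop_codon"]),
        enhancer=_interval_from_cfg(arc["enhancer"], "AR_enhancer"),
    )

    controls_cfg = cfg.get("controls", {})
    missing = [lab for lab in CONTROL_LABELS if lab not in controls_cfg]
    if missing:
        raise PanelError(f"panel config: missing control region(s) {', '.join(missing)}")
    controls = ControlRegionSet({lab: _interval_from_cfg(v, lab) for lab, v in controls_cfg.items()})

    strands = cfg.get("strands", {})
    exon_rows = _read_bed(base / cfg["genes_bed"]) if "genes_bed" in cfg else []
    by_gene: dict[str, list[GenomicInterval]] = {}
    for iv in exon_rows:
        if not iv.label:
            raise PanelError("genes BED: exon row lacks a gene symbol in column 4")
        by_gene.setdefault(iv.label, []).append(iv)
    genes = tuple(
        GeneTarget(sym, ivs[0].chrom, tuple(sorted(ivs)), strands.get(sym, "+"))
        for sym, ivs in by_gene.items()
    )

    blacklist: tuple[GenomicInterval, ...] = ()
    if cfg.get("blacklist_bed"):
        blacklist = tuple(_read_bed(base / cfg["blacklist_bed"]))

    panel = PanelModel(cfg.get("assembly", "unknown"), genes, controls, ar, blacklist)
    problems = validate_panel(panel)
    if problems:
        raise PanelError("; ".join(problems))
    return panel


# ---------------------------------------------------------------------------
# JSON serialization (lossless round trip)
# ---------------------------------------------------------------------------

def _iv_to_obj(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "label": iv.label}


def _iv_from_obj(o: dict) -> GenomicInterval:
    return GenomicInterval(o["chrom"], o["start"], o["end"], o.get("label", ""))


def panel_to_json(panel: PanelModel) -> str:
    obj = {
        "assembly": panel.assembly,
        "genes": [
            {"symbol": g.symbol, "chrom": g.chrom, "strand": g.strand,
             "exons": [_iv_to_obj(e) for e in g.exons]}
            for g in panel.genes
        ],
        "controls": {lab: _iv_to_obj(iv) for lab, iv in panel.controls.regions.items()},
        "ar": {
            "gene_body": _iv_to_obj(panel.ar.gene_body),
            "exons": [_iv_to_obj(e) for e in panel.ar.exons],
            "stop_codon": panel.ar.stop_codon,
            "enhancer": _iv_to_obj(panel.ar.enhancer),
        },
        "blacklist": [_iv_to_obj(iv) for iv in panel.blacklist],
    }
    return json.dumps(obj, indent=2, sort_keys=True)


def panel_from_json(text: str) -> PanelModel:
    o = json.loads(text)
    genes = tuple(
        GeneTarget(g["symbol"], g["chrom"], tuple(_iv_from_obj(e) for e in g["exons"]), g["strand"])
        for g in o["genes"]
    )
    controls = ControlRegionSet({lab: _iv_from_obj(iv) for lab, iv in o["controls"].items()})
    ar = ARModel(
        gene_body=_iv_from_obj(o["ar"]["gene_body"]),
        exons=tuple(_iv_from_obj(e) for e in o["ar"]["exons"]),
        stop_codon=o["ar"]["stop_codon"],
        enhancer=_iv_from_obj(o["ar"]["enhancer"]),
    )
    blacklist = tuple(_iv_from_obj(iv) for iv in o.get("blacklist", []))
    panel = PanelModel(o["assembly"], genes, controls, ar, blacklist)
    problems = validate_panel(panel)
    if problems:
        raise PanelError("; ".join(problems))
    return panel
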