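"""Synthetic cohort generator for end-to-end exercise of the classification pipeline.

The generator emits everything the pipeline consumes — healthy-donor control
fractions, per-sample depth profiles, two pseudo-callers' SNV call sets with an
annotation table, four pseudo-callers' SV call sets, aneuploidy fractions,
cfDNA yields, and survival follow-up — together with a ground-truth record
that the pipeline never reads.

The statistical structure encodes the admixture model the analysis relies on:
a tumor at aneuploidy fraction ``f`` carrying ``CN_t`` copies of a target
dilutes into a diploid background, so the expected observed copy ratio is
``1 + f*(CN_t/2 - 1)`` on autosomes and ``1 + f*(CN_t - 1)`` on chrX (one
germline copy in a male genome). Somatic VAFs follow the same admixture
(~``f/2`` for a heterozygous autosomal mutation), germline VAFs sit near 0.5,
callers jitter SV breakends and miss calls independently, and survival times
are exponential with a per-group median.

Defaults mirror the study conditions: mean coverage 400X, control fractions
with mean 0.0698 and SD 0.0241 (n = 8), a three-group mix proportional to
200/256/320, and per-group survival medians of 23/29/47 months.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .classify import GROUP1, GROUP2, GROUP3, TRIGGER_FEATURES, derive_aneuploidy_threshold
from .cnv import DepthProfile, depth_profiles_to_frame
from .panel import PanelModel, is_chrx, toy_panel
from .sv import SV_MATCH_TOLERANCE, Breakend, StructuralVariant, decompose_to_breakends
from .survival import SurvivalRecord
from .variants import RawVariantCall, VariantAnnotation, VariantKey
from . import vcfio

SNV_CALLERS = ("snvA", "snvB")
SV_CALLERS = ("sv1", "sv2", "sv3", "sv4")

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "generate_controls",
    "generate_cohort",
    "write_fixture_bundle",
    "read_fixture_bundle",
    "generate_dilution_series",
    "expected_ratio",
    "SNV_CALLERS",
    "SV_CALLERS",
]


def expected_ratio(fraction: float, tumor_copies: float, chrx: bool) -> float:
    """Admixture-diluted copy ratio for a planted tumor copy number."""
    if chrx:
        return 1.0 + fraction * (tumor_copies - 1.0)
    return 1.0 + fraction * (tumor_copies / 2.0 - 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``group_probs`` follows the observed cohort mix (200/256/320 of 776).
    Group-2 fractions start above the panel-of-normals cutoff (0.05) so the
    depth reference is built purely from unaltered low-fraction samples, and
    their floor (0.055) guarantees that the planted gains (8 extra-copy scale)
    clear the log2 > 0.3 gain threshold after dilution.
    """

    n_samples: int = 200
    group_probs: tuple[float, float, float] = (200 / 776, 256 / 776, 320 / 776)
    # healthy-donor controls
    control_mean: float = 0.0698
    control_sd: float = 0.0241
    n_controls: int = 8
    # per-group aneuploidy fraction ranges (uniform)
    fraction_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            GROUP1: (0.15, 0.70),
            GROUP2: (0.055, 0.135),
            GROUP3: (0.004, 0.13),
        }
    )
    # depth model
    baseline_depth: float = 400.0
    baseline_log_sd: float = 0.2
    depth_log_sd: float = 0.05
    # planted copy numbers
    gain_copies: Mapping[str, float] = field(
        default_factory=lambda: {"AR": 8.0, "AR_enhancer": 8.0, "MYC": 16.0, "MYCN": 16.0}
    )
    loss_copies: Mapping[str, float] = field(
        default_factory=lambda: {"TP53": 1.0, "PTEN": 1.0, "RB1": 1.0}
    )
    p_alteration_group1: float = 0.8
    p_loss_group1: float = 0.5
    # SNV model
    vaf_concentration: float | None = 400.0  # beta concentration; None = exact mean
    germline_variant_rate: float = 0.3
    germline_vaf_sd: float = 0.015
    snv_sensitivity: float = 0.97
    snv_fp_rate: float = 0.5  # mean false-positive records per caller
    # SV model
    sv_sensitivity: float = 0.95
    sv_jitter: int = SV_MATCH_TOLERANCE // 2 - 200  # 300 bp
    sv_fp_rate: float = 0.3
    # survival
    survival_medians: Mapping[str, float] = field(
        default_factory=lambda: {GROUP1: 23.0, GROUP2: 29.0, GROUP3: 47.0}
    )
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1")
        if any(m <= 0 for m in self.survival_medians.values()):
            raise ValueError("survival medians must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @classmethod
    def noise_free(cls, **overrides) -> "SimulationConfig":
        """Deterministic-signal conditions: no depth/VAF noise, perfect callers."""
        base = dict(
            depth_log_sd=0.0,
            baseline_log_sd=0.0,
            vaf_concentration=None,
            germline_vaf_sd=0.0,
            snv_sensitivity=1.0,
            snv_fp_rate=0.0,
            sv_sensitivity=1.0,
            sv_fp_rate=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class CohortBundle:
    """In-memory synthetic cohort; the pipeline consumes everything but ``truth``."""

    seed: int
    config: SimulationConfig
    panel: PanelModel
    controls: list[float]
    profiles: list[DepthProfile]
    fractions: dict[str, float]
    snv_calls: dict[str, dict[str, list[RawVariantCall]]]
    annotations: dict[VariantKey, VariantAnnotation]
    sv_calls: dict[str, dict[str, list[StructuralVariant]]]
    survival: list[SurvivalRecord]
    sample_meta: dict[str, dict]  # cfdna_mass_ng, plasma_volume_ml
    truth: dict[str, dict]


def generate_controls(config: SimulationConfig, rng: np.random.Generator) -> list[float]:
    """Healthy-donor aneuploidy fractions: normal truncated to [0, 1]."""
    out: list[float] = []
    while len(out) < config.n_controls:
        draw = rng.normal(config.control_mean, config.control_sd)
        if config.control_sd == 0:
            draw = config.control_mean
        if 0.0 <= draw <= 1.0:
            out.append(float(draw))
    return out


# ---------------------------------------------------------------------------
# Per-sample generation helpers
# ---------------------------------------------------------------------------

def _lognorm(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def _depth_profile(
    sample_id: str,
    panel: PanelModel,
    fraction: float,
    tumor_copies: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> DepthProfile:
    baseline = config.baseline_depth * _lognorm(rng, config.baseline_log_sd)
    depths: dict[str, float] = {}
    for lab, iv in panel.controls.regions.items():
        rel = 0.5 if is_chrx(iv.chrom) else 1.0  # controls are copy-neutral
        depths[lab] = baseline * rel * _lognorm(rng, config.depth_log_sd)
    for target in panel.target_labels:
        chrom = panel.target_chrom(target)
        chrx = is_chrx(chrom)
        rel = 0.5 if chrx else 1.0
        germline = 1.0 if chrx else 2.0
        cn_t = tumor_copies.get(target, germline)
        ratio = expected_ratio(fraction, cn_t, chrx)
        depths[target] = baseline * rel * ratio * _lognorm(rng, config.depth_log_sd)
    return DepthProfile(sample_id, depths)


def _beta_vaf(mean: float, concentration: float | None, rng: np.random.Generator) -> float:
    mean = min(max(mean, 1e-4), 1.0 - 1e-4)
    if concentration is None:
        return mean
    a, b = mean * concentration, (1.0 - mean) * concentration
    return float(rng.beta(a, b))


def _somatic_vaf(fraction: float, chrx: bool, tumor_copies: float | None = None) -> float:
    """Admixture VAF of one mutated copy at the planted tumor copy number."""
    if chrx:
        cn = 1.0 if tumor_copies is None else tumor_copies
        return fraction / (fraction * cn + (1.0 - fraction))
    cn = 2.0 if tumor_copies is None else tumor_copies
    return fraction / (fraction * cn + (1.0 - fraction) * 2.0)


_PROTEIN_CHANGES = ("p.Arg175His", "p.Gly245Ser", "p.Arg273Cys", "p.Glu285Lys", "p.His875Tyr")


def _plant_snv(
    sample_id: str,
    gene: str,
    vaf: float,
    depth: float,
    panel: PanelModel,
    annotations: dict[VariantKey, VariantAnnotation],
    rng: np.random.Generator,
    oncogenic: bool = True,
) -> RawVariantCall | None:
    target = panel.gene(gene)
    exon = target.exons[int(rng.integers(len(target.exons)))]
    pos = int(rng.integers(exon.start, exon.end))
    ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
    alt_reads = int(round(vaf * depth))
    call = RawVariantCall(
        sample_id=sample_id, caller="", chrom=target.chrom, pos=pos,
        ref=ref, alt=alt, vaf=min(max(vaf, 0.0), 1.0), alt_reads=alt_reads,
    )
    annotations.setdefault(
        call.key,
        VariantAnnotation(
            gene=gene,
            protein_change=str(rng.choice(_PROTEIN_CHANGES)),
            consequence_classes=frozenset({"missense"}),
            oncokb_curated=oncogenic,
            oncogenicity="Oncogenic" if oncogenic else "Other",
        ),
    )
    return call


def _emit_to_snv_callers(
    call: RawVariantCall, config: SimulationConfig, rng: np.random.Generator,
    per_caller: dict[str, list[RawVariantCall]],
) -> None:
    for caller in SNV_CALLERS:
        if rng.random() <= config.snv_sensitivity:
            per_caller[caller].append(replace(call, caller=caller))


def _plant_ar_gsrs(
    count: int,
    panel: PanelModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    per_caller: dict[str, list[StructuralVariant]],
) -> int:
    """Plant AR rearrangements and scatter jittered copies across SV callers."""
    gb = panel.ar.gene_body
    margin = SV_MATCH_TOLERANCE + 100
    lo, hi = gb.start + margin, gb.end - margin
    planted = 0
    for _ in range(count):
        svtype = str(rng.choice(["DEL", "DUP", "INV", "TRA"], p=[0.35, 0.25, 0.2, 0.2]))
        sr = 3 + int(rng.poisson(4))
        pe = 3 + int(rng.poisson(4))
        if svtype == "TRA":
            pos = int(rng.integers(lo, hi))
            side = "retains_left" if rng.random() < 0.5 else "retains_right"
            b1 = Breakend(gb.chrom, pos, side)
            b2 = Breakend("chr7", int(rng.integers(1_000_000, 2_000_000)),
                          "retains_left" if rng.random() < 0.5 else "retains_right")
            base = StructuralVariant(b1, b2, "TRA", sr, pe)
        else:
            p1 = int(rng.integers(lo, hi - 500))
            p2 = int(rng.integers(p1 + 400, hi))
            b1, b2 = decompose_to_breakends(svtype, gb.chrom, p1, p2)
            base = StructuralVariant(b1, b2, svtype, sr, pe)
        planted += 1
        for caller in SV_CALLERS:
            if rng.random() > config.sv_sensitivity:
                continue
            j1 = int(rng.integers(-config.sv_jitter, config.sv_jitter + 1)) if config.sv_jitter else 0
            j2 = int(rng.integers(-config.sv_jitter, config.sv_jitter + 1)) if config.sv_jitter else 0
            jittered = StructuralVariant(
                Breakend(base.bnd1.chrom, base.bnd1.pos + j1, base.bnd1.side),
                Breakend(base.bnd2.chrom, base.bnd2.pos + j2, base.bnd2.side),
                base.svtype, sr, pe, caller,
            )
            per_caller[caller].append(jittered)
    return planted


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig, seed: int, panel: PanelModel | None = None
) -> CohortBundle:
    """Generate a full synthetic cohort bundle (deterministic in config+seed)."""
    rng = np.random.default_rng(seed)
    panel = panel or toy_panel()
    controls = generate_controls(config, rng)
    # Planted labels are defined relative to the threshold this bundle's own
    # control series yields, so truth and classification share one regime split.
    threshold = derive_aneuploidy_threshold(controls).threshold

    profiles: list[DepthProfile] = []
    fractions: dict[str, float] = {}
    snv_calls: dict[str, dict[str, list[RawVariantCall]]] = {}
    sv_calls: dict[str, dict[str, list[StructuralVariant]]] = {}
    annotations: dict[VariantKey, VariantAnnotation] = {}
    survival: list[SurvivalRecord] = []
    sample_meta: dict[str, dict] = {}
    truth: dict[str, dict] = {}

    group_names = (GROUP1, GROUP2, GROUP3)
    exempt_somatic_genes = ("TP53", "PTEN", "CDK12", "PIK3CA")

    for i in range(config.n_samples):
        sid = f"S{i:04d}"
        group = str(rng.choice(group_names, p=list(config.group_probs)))
        flo, fhi = config.fraction_ranges[group]
        fraction = float(rng.uniform(flo, fhi))
        if group == GROUP1:
            fraction = max(fraction, threshold + 1e-6)
        else:
            fraction = min(fraction, threshold - 1e-6)

        tumor_copies: dict[str, float] = {}
        triggers: list[str] = []
        if group == GROUP2:
            chosen = [t for t in TRIGGER_FEATURES if rng.random() < 0.35]
            if not chosen:
                chosen = [str(rng.choice(TRIGGER_FEATURES))]
            triggers = chosen
        elif group == GROUP1 and rng.random() < config.p_alteration_group1:
            triggers = [t for t in TRIGGER_FEATURES if rng.random() < 0.4]
            if rng.random() < config.p_loss_group1:
                for gene, cn in config.loss_copies.items():
                    if rng.random() < 0.5:
                        tumor_copies[gene] = cn

        for feat, target in (
            ("AR_gain", "AR"), ("AR_enhancer_gain", "AR_enhancer"),
            ("MYC_gain", "MYC"), ("MYCN_gain", "MYCN"),
        ):
            if feat in triggers:
                tumor_copies[target] = config.gain_copies[target]
        # the AR body and enhancer usually co-amplify on one amplicon
        if "AR" in tumor_copies and "AR_enhancer" not in tumor_copies and rng.random() < 0.8:
            tumor_copies["AR_enhancer"] = tumor_copies["AR"]

        profile = _depth_profile(sid, panel, fraction, tumor_copies, config, rng)
        profiles.append(profile)
        fractions[sid] = fraction

        per_snv: dict[str, list[RawVariantCall]] = {c: [] for c in SNV_CALLERS}
        planted_somatic = 0
        if "somatic_mutation" in triggers:
            gene = str(rng.choice(exempt_somatic_genes))
            vaf = _beta_vaf(_somatic_vaf(fraction, chrx=False), config.vaf_concentration, rng)
            call = _plant_snv(sid, gene, vaf, profile.depth(gene), panel, annotations, rng)
            _emit_to_snv_callers(call, config, rng, per_snv)
            planted_somatic += 1
        planted_germline = 0
        if rng.random() < config.germline_variant_rate:
            gene = str(rng.choice(["HSD3B1", "BRCA2", "ATM"]))
            gvaf = 0.5 + (rng.normal(0.0, config.germline_vaf_sd) if config.germline_vaf_sd else 0.0)
            gvaf = min(max(gvaf, 0.40), 0.60)
            call = _plant_snv(sid, gene, gvaf, profile.depth(gene), panel, annotations, rng)
            _emit_to_snv_callers(call, config, rng, per_snv)
            planted_germline += 1
        for caller in SNV_CALLERS:  # caller-private false positives
            for _ in range(int(rng.poisson(config.snv_fp_rate))):
                gene = str(rng.choice([g.symbol for g in panel.genes]))
                fp = _plant_snv(sid, gene, float(rng.uniform(0.02, 0.2)),
                                profile.depth(gene), panel, annotations, rng, oncogenic=False)
                per_snv[caller].append(replace(fp, caller=caller))
        snv_calls[sid] = per_snv

        per_sv: dict[str, list[StructuralVariant]] = {c: [] for c in SV_CALLERS}
        n_gsr = 0
        if "AR_GSR" in triggers:
            want = int(rng.integers(1, 4))
            if "AR" in tumor_copies and want < 2 and rng.random() < 0.5:
                want = 2  # amplified-and-rearranged samples trend to multiple events
            n_gsr = _plant_ar_gsrs(want, panel, config, rng, per_sv)
        for caller in SV_CALLERS:  # caller-private false positives away from AR
            for _ in range(int(rng.poisson(config.sv_fp_rate))):
                p1 = int(rng.integers(1_000_000, 5_000_000))
                b1, b2 = decompose_to_breakends("DEL", "chr5", p1, p1 + int(rng.integers(500, 5000)))
                per_sv[caller].append(StructuralVariant(b1, b2, "DEL", 1 + int(rng.poisson(2)),
                                                        1 + int(rng.poisson(2)), caller))
        sv_calls[sid] = per_sv

        # survival: exponential time with per-group median, independent censoring
        median = config.survival_medians[group]
        lam = np.log(2.0) / median
        t_event = float(rng.exponential(1.0 / lam))
        if config.censoring_rate > 0:
            lam_c = lam * config.censoring_rate / (1.0 - config.censoring_rate)
            t_cens = float(rng.exponential(1.0 / lam_c))
        else:
            t_cens = float("inf")
        time = max(min(t_event, t_cens), 1e-3)
        survival.append(SurvivalRecord(sid, time, t_event <= t_cens, group))

        volume = float(np.clip(rng.normal(2.12, 0.49), 1.0, 3.0))
        yield_per_ml = (5.0 + 40.0 * fraction) * _lognorm(rng, 0.3)
        sample_meta[sid] = {
            "cfdna_mass_ng": yield_per_ml * volume,
            "plasma_volume_ml": volume,
        }

        truth[sid] = {
            "group": group,
            "fraction": fraction,
            "tumor_copies": tumor_copies,
            "triggers": sorted(triggers),
            "n_somatic_snvs": planted_somatic,
            "n_germline_snvs": planted_germline,
            "n_ar_gsrs": n_gsr,
            "survival_median": median,
        }

    return CohortBundle(
        seed=seed, config=config, panel=panel, controls=controls, profiles=profiles,
        fractions=fractions, snv_calls=snv_calls, annotations=annotations,
        sv_calls=sv_calls, survival=survival, sample_meta=sample_meta, truth=truth,
    )


def generate_dilution_series(
    n: int,
    seed: int,
    tumor_copies: float = 8.0,
    target: str = "AR",
    fraction_range: tuple[float, float] = (0.05, 0.5),
    config: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, "PanelModel", list[DepthProfile], dict[str, float]]:
    """Titration series: every sample carries the same planted copy number at a
    varying fraction, plus enough neutral low-fraction samples for the depth
    reference. Returns (fractions, sample_ids ordered, panel, profiles, fraction map)."""
    rng = np.random.default_rng(seed)
    cfg = config or SimulationConfig()
    panel = toy_panel()
    chrx = is_chrx(panel.target_chrom(target))
    profiles: list[DepthProfile] = []
    fractions: dict[str, float] = {}
    for i in range(40):  # neutral reference samples
        sid = f"N{i:03d}"
        f = float(rng.uniform(0.004, 0.05))
        profiles.append(_depth_profile(sid, panel, f, {}, cfg, rng))
        fractions[sid] = f
    planted_f = np.sort(rng.uniform(*fraction_range, size=n))
    for i, f in enumerate(planted_f):
        sid = f"T{i:04d}"
        profiles.append(_depth_profile(sid, panel, float(f), {target: tumor_copies}, cfg, rng))
        fractions[sid] = float(f)
    ids = np.array([f"T{i:04d}" for i in range(n)])
    return planted_f, ids, panel, profiles, fractions


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict:
    """Write the bundle as plain-text files; returns a checksum manifest."""
    from .panel import panel_to_json

    out = Path(out_dir)
    (out / "snv").mkdir(parents=True, exist_ok=True)
    (out / "sv").mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    p = out / "panel.json"
    p.write_text(panel_to_json(bundle.panel))
    files.append(p)

    p = out / "controls.tsv"
    p.write_text("fraction\n" + "".join(f"{v:.10g}\n" for v in bundle.controls))
    files.append(p)

    p = out / "depths.tsv"
    depth_profiles_to_frame(bundle.profiles).to_csv(p, sep="\t", index=False, float_format="%.6f")
    files.append(p)

    p = out / "fractions.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tfraction\n")
        for sid in sorted(bundle.fractions):
            fh.write(f"{sid}\t{bundle.fractions[sid]:.8f}\n")
    files.append(p)

    p = out / "sample_meta.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tcfdna_mass_ng\tplasma_volume_ml\n")
        for sid in sorted(bundle.sample_meta):
            m = bundle.sample_meta[sid]
            fh.write(f"{sid}\t{m['cfdna_mass_ng']:.6f}\t{m['plasma_volume_ml']:.6f}\n")
    files.append(p)

    p = out / "survival.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\ttime_months\tevent\n")
        for r in bundle.survival:
            fh.write(f"{r.sample_id}\t{r.time:.6f}\t{int(r.event)}\n")
    files.append(p)

    p = out / "annotations.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tprotein_change\tconsequences\toncokb_curated\toncogenicity\n")
        for key in sorted(bundle.annotations):
            ann = bundle.annotations[key]
            chrom, pos, ref, alt = key
            fh.write(
                f"{chrom}\t{pos + 1}\t{ref}\t{alt}\t{ann.gene}\t{ann.protein_change}\t"
                f"{','.join(sorted(ann.consequence_classes))}\t{int(ann.oncokb_curated)}\t"
                f"{ann.oncogenicity or ''}\n"
            )
    files.append(p)

    for sid in sorted(bundle.snv_calls):
        for caller, calls in bundle.snv_calls[sid].items():
            p = out / "snv" / f"{sid}.{caller}.vcf"
            vcfio.write_snv_vcf(calls, p)
            files.append(p)
    for sid in sorted(bundle.sv_calls):
        for caller, svs in bundle.sv_calls[sid].items():
            p = out / "sv" / f"{sid}.{caller}.vcf"
            vcfio.write_sv_vcf(svs, p)
            files.append(p)

    p = out / "truth.json"
    p.write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    files.append(p)

    manifest = {
        "seed": bundle.seed,
        "n_samples": bundle.config.n_samples,
        "files": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_fixture_bundle(in_dir: str | Path) -> CohortBundle:
    """Re-read a written bundle into the in-memory form the pipeline consumes.

    ``truth`` is loaded for closed-loop comparison but is never an input to the
    classification stages.
    """
    import pandas as pd

    from .cnv import read_depth_table
    from .panel import panel_from_json
    from .survival import read_survival_table
    from .variants import VariantAnnotation

    d = Path(in_dir)
    panel = panel_from_json((d / "panel.json").read_text())
    controls = [float(x) for x in (d / "controls.tsv").read_text().splitlines()[1:]]
    profiles = read_depth_table(d / "depths.tsv")
    fractions = dict(
        pd.read_csv(d / "fractions.tsv", sep="\t")
        .set_index("sample_id")["fraction"].astype(float)
    )
    meta_df = pd.read_csv(d / "sample_meta.tsv", sep="\t").set_index("sample_id")
    sample_meta = {
        sid: {"cfdna_mass_ng": float(row["cfdna_mass_ng"]),
              "plasma_volume_ml": float(row["plasma_volume_ml"])}
        for sid, row in meta_df.iterrows()
    }
    survival = read_survival_table(d / "survival.tsv")

    ann_df = pd.read_csv(d / "annotations.tsv", sep="\t", keep_default_na=False)
    annotations: dict[VariantKey, VariantAnnotation] = {}
    for r in ann_df.itertuples():
        key = (r.chrom, int(r.pos) - 1, r.ref, r.alt)
        classes = frozenset(c for c in str(r.consequences).split(",") if c)
        annotations[key] = VariantAnnotation(
            gene=r.gene, protein_change=str(r.protein_change),
            consequence_classes=classes, oncokb_curated=bool(int(r.oncokb_curated)),
            oncogenicity=(str(r.oncogenicity) or None),
        )

    sample_ids = sorted(fractions)
    snv_calls = {
        sid: {c: vcfio.read_snv_vcf(d / "snv" / f"{sid}.{c}.vcf", sid, c) for c in SNV_CALLERS}
        for sid in sample_ids
    }
    sv_calls = {
        sid: {c: vcfio.read_sv_vcf(d / "sv" / f"{sid}.{c}.vcf", c) for c in SV_CALLERS}
        for sid in sample_ids
    }
    truth = json.loads((d / "truth.json").read_text()) if (d / "truth.json").exists() else {}
    return CohortBundle(
        seed=-1, config=SimulationConfig(n_samples=len(sample_ids)), panel=panel,
        controls=controls, profiles=profiles, fractions=fractions, snv_calls=snv_calls,
        annotations=annotations, sv_calls=sv_calls, survival=survival,
        sample_meta=sample_meta, truth=truth,
    )
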