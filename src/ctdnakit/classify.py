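"""ctDNA positivity classification into aneuploidy-high / feature-positive / negative groups.

The assay threshold is derived from healthy-donor control assays as
mean + 3*SD of their aneuploidy fraction estimates (sample SD, n-1
denominator). Samples with fraction strictly above the threshold form
aneuploidy-high Group 1. Samples at or below the threshold join Group 2 when
they display at least one high-signal tumor feature: a pathogenic likely
somatic SNV, AR gene-body gain, AR enhancer gain, an AR-GSR, MYC gain, or
MYCN gain (gain = log2 ratio > 0.3). Everything else is ctDNA-negative
Group 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cnv import GAIN_LOG2, CopyRatioCall
from .sv import ARGSRCall, flag_ecdna
from .variants import FilteredVariant

GROUP1 = "Group1"
GROUP2 = "Group2"
GROUP3 = "Group3"

#: The six Group-2 trigger features, in reporting order.
TRIGGER_FEATURES = (
    "somatic_mutation",
    "AR_gain",
    "AR_enhancer_gain",
    "AR_GSR",
    "MYC_gain",
    "MYCN_gain",
)

__all__ = [
    "AneuploidyControlStats",
    "SampleFeatures",
    "SampleClassification",
    "ClassifyError",
    "derive_aneuploidy_threshold",
    "build_sample_features",
    "assign_group",
    "summarize_cohort",
    "percent_whole",
    "TRIGGER_FEATURES",
    "GROUP1",
    "GROUP2",
    "GROUP3",
]


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class AneuploidyControlStats:
    """Healthy-donor control summary; threshold = mean + 3*SD."""

    n: int
    mean: float
    sd: float
    threshold: float

    @classmethod
    def from_summary(cls, mean: float, sd: float, n: int) -> "AneuploidyControlStats":
        if n < 2:
            raise ClassifyError("control stats require n >= 2")
        return cls(n=n, mean=mean, sd=sd, threshold=mean + 3.0 * sd)


def derive_aneuploidy_threshold(control_fractions: Sequence[float]) -> AneuploidyControlStats:
    """Mean and sample SD (n-1) of control fractions; threshold = mean + 3*SD."""
    vals = np.asarray(list(control_fractions), dtype=float)
    if vals.size < 2:
        raise ClassifyError(f"need >= 2 control fractions (got {vals.size})")
    if np.any((vals < 0) | (vals > 1)):
        raise ClassifyError("control fractions must lie in [0, 1]")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return AneuploidyControlStats(n=int(vals.size), mean=mean, sd=sd, threshold=mean + 3.0 * sd)


@dataclass(frozen=True)
class SampleFeatures:
    """Per-sample feature vector consumed by group assignment."""

    sample_id: str
    aneuploidy_fraction: float
    has_somatic_pathogenic_snv: bool = False
    ar_body_log2: float = 0.0
    ar_enhancer_log2: float = 0.0
    myc_log2: float = 0.0
    mycn_log2: float = 0.0
    ar_gsr_count: int = 0
    lbd_truncating_count: int = 0
    ecdna_flag: bool = False
    cfdna_yield: float | None = None  # ng per mL plasma
    ar_mutation_count: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.aneuploidy_fraction <= 1.0):
            raise ClassifyError(f"{self.sample_id}: aneuploidy fraction out of [0,1]")
        if self.ar_gsr_count < 0 or self.lbd_truncating_count < 0:
            raise ClassifyError(f"{self.sample_id}: negative event count")

    @property
    def ar_altered(self) -> bool:
        """Any AR alteration: body/enhancer gain, AR-GSR, or AR mutation."""
        return (
            self.ar_body_log2 > GAIN_LOG2
            or self.ar_enhancer_log2 > GAIN_LOG2
            or self.ar_gsr_count >= 1
            or self.ar_mutation_count >= 1
        )


@dataclass(frozen=True)
class SampleClassification:
    sample_id: str
    group: str
    triggering_features: frozenset[str] = field(default_factory=frozenset)


def build_sample_features(
    sample_id: str,
    copy_calls: Sequence[CopyRatioCall],
    variants: Sequence[FilteredVariant],
    gsr_calls: Sequence[ARGSRCall],
    aneuploidy_fraction: float,
    cfdna_mass_ng: float | None = None,
    plasma_volume_ml: float | None = None,
) -> SampleFeatures:
    """Aggregate per-stage outputs into the classifier's feature vector.

    cfDNA yield = eluted mass / input plasma volume (ng/mL), when both given.
    """
    log2_by_target = {c.target: c.log2_ratio for c in copy_calls}
    required = ("AR", "AR_enhancer", "MYC", "MYCN")
    missing = [t for t in required if t not in log2_by_target]
    if missing:
        raise ClassifyError(f"{sample_id}: missing copy-ratio call(s) for {missing}")

    yield_val: float | None = None
    if cfdna_mass_ng is not None and plasma_volume_ml is not None:
        if plasma_volume_ml <= 0:
            raise ClassifyError(f"{sample_id}: plasma volume must be > 0")
        yield_val = cfdna_mass_ng / plasma_volume_ml

    gsr_count = len(gsr_calls)
    ar_body_log2 = log2_by_target["AR"]
    return SampleFeatures(
        sample_id=sample_id,
        aneuploidy_fraction=aneuploidy_fraction,
        has_somatic_pathogenic_snv=any(v.origin == "likely_somatic" for v in variants),
        ar_body_log2=ar_body_log2,
        ar_enhancer_log2=log2_by_target["AR_enhancer"],
        myc_log2=log2_by_target["MYC"],
        mycn_log2=log2_by_target["MYCN"],
        ar_gsr_count=gsr_count,
        lbd_truncating_count=sum(1 for g in gsr_calls if g.lbd_truncating),
        ecdna_flag=flag_ecdna(gsr_count, ar_body_log2),
        cfdna_yield=yield_val,
        ar_mutation_count=sum(1 for v in variants if v.gene == "AR" and v.origin == "likely_somatic"),
    )


def assign_group(features: SampleFeatures, stats: AneuploidyControlStats) -> SampleClassification:
    """Group 1 iff fraction strictly exceeds the threshold; else Group 2 on any
    trigger feature; else Group 3. A fraction exactly at the threshold is
    'at or below' and eligible only for Group 2."""
    if features.aneuploidy_fraction > stats.threshold:
        return SampleClassification(features.sample_id, GROUP1, frozenset({"aneuploidy_high"}))
    triggers = set()
    if features.has_somatic_pathogenic_snv:
        triggers.add("somatic_mutation")
    if features.ar_body_log2 > GAIN_LOG2:
        triggers.add("AR_gain")
    if features.ar_enhancer_log2 > GAIN_LOG2:
        triggers.add("AR_enhancer_gain")
    if features.ar_gsr_count >= 1:
        triggers.add("AR_GSR")
    if features.myc_log2 > GAIN_LOG2:
        triggers.add("MYC_gain")
    if features.mycn_log2 > GAIN_LOG2:
        triggers.add("MYCN_gain")
    if triggers:
        return SampleClassification(features.sample_id, GROUP2, frozenset(triggers))
    return SampleClassification(features.sample_id, GROUP3)


def percent_whole(numerator: float, denominator: float) -> int:
    """Whole percent, rounding half away from zero (59% style reporting)."""
    if denominator == 0:
        raise ClassifyError("percent of empty denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_cohort(
    classifications: Sequence[SampleClassification],
    features: Mapping[str, SampleFeatures] | None = None,
) -> dict:
    """Cohort-level counts, positivity rate, and feature frequencies.

    Positives are Groups 1 and 2. When feature vectors are supplied, the
    summary adds the frequency of AR alterations and other features among
    positives, and the Group-2 split into mutation-positive vs.
    alteration-only subgroups.
    """
    if not classifications:
        raise ClassifyError("summarize_cohort: empty cohort")
    counts = {GROUP1: 0, GROUP2: 0, GROUP3: 0}
    for c in classifications:
        if c.group not in counts:
            raise ClassifyError(f"unknown group {c.group!r}")
        counts[c.group] += 1
    n = len(classifications)
    n_pos = counts[GROUP1] + counts[GROUP2]
    summary = {
        "n": n,
        "counts": counts,
        "n_positive": n_pos,
        "percent_positive": percent_whole(n_pos, n),
        "group2_with_mutation": sum(
            1 for c in classifications
            if c.group == GROUP2 and "somatic_mutation" in c.triggering_features
        ),
    }
    summary["group2_without_mutation"] = counts[GROUP2] - summary["group2_with_mutation"]

    if features is not None:
        pos = [c for c in classifications if c.group in (GROUP1, GROUP2)]
        missing = [c.sample_id for c in pos if c.sample_id not in features]
        if missing:
            raise ClassifyError(f"missing feature vectors for {missing[:5]}...")
        if pos:
            ar_altered = sum(1 for c in pos if features[c.sample_id].ar_altered)
            ecdna = sum(1 for c in pos if features[c.sample_id].ecdna_flag)
            summary["positives_ar_altered"] = ar_altered
            summary["percent_positives_ar_altered"] = percent_whole(ar_altered, len(pos))
            summary["positives_ecdna"] = ecdna
    return summary
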