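"""End-to-end cohort pipeline: depth tables and call sets in, classification out.

Stages, per the assay's decision logic:

1. derive the aneuploidy threshold from healthy-donor controls;
2. build the panel of normals from samples with fraction <= 0.05 and compute
   per-target copy ratios for every sample;
3. per sample, intersect and filter the two SNV callers' sets and classify
   variant origin;
4. per sample, merge the four SV callers' sets, drop blacklisted breakends,
   and call AR-GSRs with LBD-truncation flags;
5. aggregate features, assign Group 1/2/3, finalize gain/loss states (losses
   need the ctDNA-positive flag), and render the cohort report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import (
    GROUP1,
    GROUP2,
    AneuploidyControlStats,
    SampleClassification,
    SampleFeatures,
    assign_group,
    build_sample_features,
    derive_aneuploidy_threshold,
)
from .cnv import CopyRatioCall, build_panel_of_normals, call_copy_state, compute_copy_ratio
from .simulate import SNV_CALLERS, CohortBundle
from .survival import cohort_report
from .sv import ARGSRCall, consensus_merge, detect_ar_gsrs, filter_blacklist
from .variants import FilteredVariant, run_variant_filter

__all__ = ["SampleResult", "CohortResult", "run_cohort"]


@dataclass
class SampleResult:
    sample_id: str
    copy_calls: list[CopyRatioCall]
    variants: list[FilteredVariant]
    variant_audit: list[dict]
    gsr_calls: list[ARGSRCall]
    features: SampleFeatures
    classification: SampleClassification


@dataclass
class CohortResult:
    stats: AneuploidyControlStats
    samples: dict[str, SampleResult]
    report: dict

    @property
    def classifications(self) -> list[SampleClassification]:
        return [s.classification for s in self.samples.values()]


def run_cohort(bundle: CohortBundle) -> CohortResult:
    """Run the full classification pipeline over a cohort bundle.

    The bundle's ``truth`` field (when present) is never consulted.
    """
    stats = derive_aneuploidy_threshold(bundle.controls)
    pon = build_panel_of_normals(bundle.profiles, bundle.fractions, bundle.panel)

    samples: dict[str, SampleResult] = {}
    for profile in bundle.profiles:
        sid = profile.sample_id
        copy_calls = compute_copy_ratio(profile, pon, bundle.panel)

        per_caller = bundle.snv_calls.get(sid, {})
        calls_a = per_caller.get(SNV_CALLERS[0], [])
        calls_b = per_caller.get(SNV_CALLERS[1], [])
        variants, audit = run_variant_filter(calls_a, calls_b, bundle.annotations)

        consensus = consensus_merge(bundle.sv_calls.get(sid, {}))
        consensus = filter_blacklist(consensus, bundle.panel.blacklist)
        gsrs = detect_ar_gsrs(consensus, bundle.panel.ar)

        meta = bundle.sample_meta.get(sid, {})
        features = build_sample_features(
            sid, copy_calls, variants, gsrs,
            aneuploidy_fraction=bundle.fractions[sid],
            cfdna_mass_ng=meta.get("cfdna_mass_ng"),
            plasma_volume_ml=meta.get("plasma_volume_ml"),
        )
        classification = assign_group(features, stats)
        positive = classification.group in (GROUP1, GROUP2)
        copy_calls = [call_copy_state(c, positive) for c in copy_calls]

        samples[sid] = SampleResult(sid, copy_calls, variants, audit, gsrs, features, classification)

    classifications = [s.classification for s in samples.values()]
    features_by_id = {sid: s.features for sid, s in samples.items()}
    report = cohort_report(classifications, bundle.survival, features_by_id)
    report["aneuploidy_threshold"] = stats.threshold
    return CohortResult(stats=stats, samples=samples, report=report)
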