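"""Gene-level copy ratios from targeted mean read depths.

Each sample's per-target mean depth is normalized within-sample against the
five control regions. Because C2 lies on chrX (one copy in a male genome), the
control series is put on the target chromosome's scale before taking the
median:

* chrX target:     norm_depth = depth / median(C1, 2*C2, C3, C4, C5)
* autosome target: norm_depth = depth / median(C1/2, C2, C3/2, C4/2, C5/2)

Copy ratios divide a sample's norm_depth by the mean norm_depth of a panel of
normals (samples with aneuploidy fraction <= 0.05), so the chrX/autosome scale
factors cancel. A target is a gain when log2(ratio) > 0.3; a loss when
log2(ratio) < -0.3 *and* the sample is ctDNA-positive (loss calls are
suppressed in ctDNA-negative samples, where shallow negative ratios are noise).
Both thresholds are strict inequalities; the boundary value is neutral.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CONTROL_LABELS, PanelModel, is_chrx

GAIN_LOG2 = 0.3
LOSS_LOG2 = -0.3
PON_FRACTION_CUTOFF = 0.05

__all__ = [
    "DepthProfile",
    "PanelOfNormals",
    "CopyRatioCall",
    "CnvError",
    "control_scale",
    "normalize_gene_depth",
    "build_panel_of_normals",
    "compute_copy_ratio",
    "call_copy_state",
    "read_depth_table",
    "write_copy_ratio_table",
]


class CnvError(ValueError):
    """Copy-ratio computation error (missing target, undefined scale, ...)."""


@dataclass(frozen=True)
class DepthProfile:
    """Per-sample mean read depth by target label (genes, C1..C5, AR_enhancer)."""

    sample_id: str
    mean_depth_by_target: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, d in self.mean_depth_by_target.items():
            if not math.isfinite(d) or d < 0:
                raise CnvError(f"{self.sample_id}: depth for {label} must be finite and >= 0")
        missing = [c for c in CONTROL_LABELS if c not in self.mean_depth_by_target]
        if missing:
            raise CnvError(f"{self.sample_id}: missing control depth(s) {missing}")

    def depth(self, label: str) -> float:
        try:
            return self.mean_depth_by_target[label]
        except KeyError:
            raise CnvError(f"{self.sample_id}: no depth for target {label!r}") from None


@dataclass(frozen=True)
class PanelOfNormals:
    member_sample_ids: tuple[str, ...]
    mean_norm_depth_by_target: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.member_sample_ids) < 2:
            raise CnvError("panel of normals requires >= 2 members")
        for label, m in self.mean_norm_depth_by_target.items():
            if not (m > 0):
                raise CnvError(f"panel of normals: mean norm depth for {label} must be > 0")

    def to_json(self) -> str:
        return json.dumps({
            "members": list(self.member_sample_ids),
            "mean_norm_depth": dict(self.mean_norm_depth_by_target),
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PanelOfNormals":
        o = json.loads(text)
        return cls(tuple(o["members"]), o["mean_norm_depth"])


@dataclass(frozen=True)
class CopyRatioCall:
    target: str
    norm_depth: float
    ratio: float
    log2_ratio: float
    state: str | None = None  # "gain" | "neutral" | "loss"


def control_scale(profile: DepthProfile, target_chrom: str) -> float:
    """Within-sample normalization scale for a target on ``target_chrom``.

    Median of the five control depths after putting them on the target
    chromosome's copy scale (C2 doubled for chrX targets; the other four halved
    for autosomal targets).
    """
    c = [profile.depth(lab) for lab in CONTROL_LABELS]
    if any(d <= 0 for d in c):
        raise CnvError(f"{profile.sample_id}: control depth <= 0, normalization scale undefined")
    c1, c2, c3, c4, c5 = c
    if is_chrx(target_chrom):
        series = [c1, 2.0 * c2, c3, c4, c5]
    else:
        series = [c1 / 2.0, c2, c3 / 2.0, c4 / 2.0, c5 / 2.0]
    return float(np.median(series))


def normalize_gene_depth(profile: DepthProfile, target: str, panel: PanelModel) -> float:
    """Mean target depth divided by the control scale for its chromosome."""
    chrom = panel.target_chrom(target)
    return profile.depth(target) / control_scale(profile, chrom)


def build_panel_of_normals(
    profiles: Sequence[DepthProfile],
    fractions: Mapping[str, float],
    panel: PanelModel,
    cutoff: float = PON_FRACTION_CUTOFF,
) -> PanelOfNormals:
    """Mean normalized depth per target over samples with fraction <= cutoff."""
    members = [p for p in profiles if fractions.get(p.sample_id, math.inf) <= cutoff]
    if len(members) < 2:
        raise CnvError(
            f"panel of normals unbuildable: {len(members)} sample(s) with fraction <= {cutoff}"
        )
    means = {
        t: float(np.mean([normalize_gene_depth(p, t, panel) for p in members]))
        for t in panel.target_labels
    }
    return PanelOfNormals(tuple(p.sample_id for p in members), means)


def compute_copy_ratio(
    profile: DepthProfile, pon: PanelOfNormals, panel: PanelModel
) -> list[CopyRatioCall]:
    """One unstated-state call per panel target (including the AR enhancer)."""
    calls = []
    for target in panel.target_labels:
        ref = pon.mean_norm_depth_by_target.get(target)
        if ref is None or ref == 0:
            raise CnvError(f"panel of normals has no usable mean for target {target!r}")
        nd = normalize_gene_depth(profile, target, panel)
        ratio = nd / ref
        log2 = math.log2(ratio) if ratio > 0 else -math.inf
        calls.append(CopyRatioCall(target, nd, ratio, log2))
    return calls


def call_copy_state(call: CopyRatioCall, sample_is_ctdna_positive: bool) -> CopyRatioCall:
    """Assign gain/neutral/loss. Losses require the ctDNA-positive flag."""
    if call.log2_ratio > GAIN_LOG2:
        state = "gain"
    elif call.log2_ratio < LOSS_LOG2 and sample_is_ctdna_positive:
        state = "loss"
    else:
        state = "neutral"
    return replace(call, state=state)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path) -> list[DepthProfile]:
    """Long-format TSV (sample_id, target_label, mean_depth) -> profiles."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target_label", "mean_depth"}
    if not required.issubset(df.columns):
        raise CnvError(f"depth table must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(DepthProfile(str(sid), dict(zip(grp["target_label"], grp["mean_depth"].astype(float)))))
    return out


def depth_profiles_to_frame(profiles: Iterable[DepthProfile]) -> pd.DataFrame:
    rows = [
        {"sample_id": p.sample_id, "target_label": t, "mean_depth": d}
        for p in profiles
        for t, d in sorted(p.mean_depth_by_target.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "target_label", "mean_depth"])


def write_copy_ratio_table(
    calls_by_sample: Mapping[str, Sequence[CopyRatioCall]], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": sid,
            "target": c.target,
            "norm_depth": c.norm_depth,
            "ratio": c.ratio,
            "log2_ratio": c.log2_ratio,
            "state": c.state or "",
        }
        for sid, calls in calls_by_sample.items()
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
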