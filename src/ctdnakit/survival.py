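"""Kaplan-Meier estimation, log-rank comparison, and cohort reporting.

Product-limit estimation and the log-rank test are delegated to lifelines;
this module wraps them in the cohort's vocabulary (groups, medians, reports)
and adds Benjamini-Hochberg adjustment for multi-way pairwise comparisons.
Conventions: the median is the smallest observed time with S(t) <= 0.5
(undefined when S never reaches 0.5); at tied times events precede censorings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import false_discovery_control

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "SurvivalError",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "cohort_report",
    "read_survival_table",
]


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months
    event: bool  # True = event observed, False = censored
    group: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise SurvivalError(f"{self.sample_id}: time must be finite and > 0")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate: step function over event times."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    median: float | None  # None when S(t) never reaches 0.5

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    if not records:
        raise SurvivalError("km_estimate: no records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    # drop the implicit t=0 row; keep observed timeline
    tl = [float(t) for t in sf.index if t > 0]
    surv = [float(sf.loc[t].iloc[0]) for t in tl]
    at_risk = [int(kmf.event_table.loc[t, "at_risk"]) for t in tl]
    med = float(kmf.median_survival_time_)
    median = None if math.isinf(med) else med
    return KMEstimate(tuple(tl), tuple(surv), tuple(at_risk), median)


def logrank_test(groups: Mapping[str, Sequence[SurvivalRecord]]) -> tuple[float, float]:
    """Log-rank chi-square over pooled event times; df = k - 1.

    Returns (statistic, p_value). Raises on an empty group.
    """
    if len(groups) < 2:
        raise SurvivalError("logrank_test: need >= 2 groups")
    for name, recs in groups.items():
        if not recs:
            raise SurvivalError(f"logrank_test: group {name!r} has no records")
    times, events, labels = [], [], []
    for name, recs in groups.items():
        for r in recs:
            times.append(r.time)
            events.append(r.event)
            labels.append(name)
    res = multivariate_logrank_test(np.array(times), np.array(labels), np.array(events, dtype=bool))
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (applied to >1 pairwise comparison)."""
    if not p_values:
        return []
    return [float(q) for q in false_discovery_control(np.asarray(p_values, dtype=float), method="bh")]


def read_survival_table(path) -> list[SurvivalRecord]:
    """TSV with columns sample_id, time_months, event (1=event, 0=censored)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(str(r.sample_id), float(r.time_months), bool(int(r.event)))
        for r in df.itertuples()
    ]


def cohort_report(
    classifications: Sequence,
    survival: Sequence[SurvivalRecord],
    features: Mapping[str, object],
) -> dict:
    """Assemble the cohort's machine-readable report.

    Joins classifications, survival follow-up, and feature vectors by
    sample_id; any orphan on either side is a hard error. Renders group counts,
    percent positive, per-group KM medians, a 3-group log-rank test, pairwise
    log-rank p-values with BH adjustment, and feature frequencies.
    """
    from .classify import summarize_cohort  # local import avoids a cycle

    class_ids = {c.sample_id for c in classifications}
    surv_ids = {r.sample_id for r in survival}
    orphans = sorted(class_ids ^ surv_ids)
    if orphans:
        raise SurvivalError(f"sample_id mismatch between classifications and survival: {orphans[:10]}")

    group_of = {c.sample_id: c.group for c in classifications}
    by_group: dict[str, list[SurvivalRecord]] = {}
    for r in survival:
        g = group_of[r.sample_id]
        by_group.setdefault(g, []).append(SurvivalRecord(r.sample_id, r.time, r.event, g))

    summary = summarize_cohort(list(classifications), features)

    km = {g: km_estimate(recs) for g, recs in sorted(by_group.items())}
    report = {
        "cohort": summary,
        "km_median_months": {g: est.median for g, est in km.items()},
        "n_per_group": {g: len(recs) for g, recs in sorted(by_group.items())},
    }
    if len(by_group) >= 2:
        stat, p = logrank_test(by_group)
        report["logrank"] = {"statistic": stat, "p_value": p, "df": len(by_group) - 1}
        names = sorted(by_group)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        raw = [logrank_test({a: by_group[a], b: by_group[b]})[1] for a, b in pairs]
        adj = bh_adjust(raw)
        report["pairwise_logrank"] = [
            {"groups": [a, b], "p_value": p_raw, "p_adjusted": p_adj}
            for (a, b), p_raw, p_adj in zip(pairs, raw, adj)
        ]
    return report


def render_report_text(report: dict) -> str:
    """Human-readable rendering of :func:`cohort_report` output."""
    lines = []
    co = report["cohort"]
    lines.append(f"Samples: {co['n']}   ctDNA-positive: {co['n_positive']} ({co['percent_positive']}%)")
    for g, cnt in sorted(co["counts"].items()):
        med = report["km_median_months"].get(g)
        med_s = f"{med:.1f} mo" if med is not None else "not reached"
        lines.append(f"  {g}: n={cnt}  KM median={med_s}")
    if "logrank" in report:
        lr = report["logrank"]
        lines.append(f"Log-rank ({lr['df']} df): chi2={lr['statistic']:.2f}, p={lr['p_value']:.3g}")
    if "percent_positives_ar_altered" in co:
        lines.append(f"AR-altered among positives: {co['positives_ar_altered']} "
                     f"({co['percent_positives_ar_altered']}%)")
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
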