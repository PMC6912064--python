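"""Four-step germline/artifact filter cascade for serial cfDNA calls.

Steps, applied in order per patient:

1. common germline — population allele frequency at or above 0.1% in any
   public database removes the variant;
2. matched normal — more than two supporting reads in the patient's white
   blood cells removes it (covers both true germline and clonal
   hematopoiesis);
3. private germline — a variant whose VAF exceeds 20% at *every* time point
   of the patient is removed from all of the patient's samples (a germline
   call cannot be somatic at another draw); an undetected time point vetoes
   removal;
4. review flag — a maximum VAF change above 2% across the series flags the
   variant for manual review; nothing is removed at this step.

Each removed variant keeps the label of the first filter that failed it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pipeline_io import PatientSeries, VariantCall, VariantKey

log = logging.getLogger("ctdnatrack")


@dataclass
class SampleFilterCounts:
    patient_id: str
    day: int
    input: int
    removed_common_germline: int
    removed_matched_normal: int
    removed_private_germline: int
    flagged_for_review: int
    passing: int

    def conserved(self) -> bool:
        return self.input == (
            self.removed_common_germline
            + self.removed_matched_normal
            + self.removed_private_germline
            + self.passing
        )


@dataclass
class FilterReport:
    """Per-sample filter accounting; the review flag does not remove."""

    patient_id: str
    per_sample: list[SampleFilterCounts] = field(default_factory=list)

    def conserved(self) -> bool:
        return all(c.conserved() for c in self.per_sample)


def filter_common_germline(
    variants: Sequence[VariantCall],
    popdb: Mapping[VariantKey, float],
    af_threshold: float = 0.001,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition variants into (removed, kept) by population allele frequency.

    A variant present in the population database with AF >= ``af_threshold``
    (threshold inclusive) is labeled ``common_germline``; variants absent
    from the database are kept.
    """
    removed, kept = [], []
    for v in variants:
        af = popdb.get(v.key)
        if af is not None and af >= af_threshold:
            v.filter_status = "common_germline"
            removed.append(v)
        else:
            kept.append(v)
    return removed, kept


def filter_matched_normal(
    variants: Sequence[VariantCall],
    normal_evidence: Mapping[VariantKey, int],
    max_normal_reads: int = 2,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition by white-blood-cell support: more than ``max_normal_reads``
    alt reads in the matched normal removes the variant."""
    removed, kept = [], []
    for v in variants:
        if normal_evidence.get(v.key, 0) > max_normal_reads:
            v.filter_status = "matched_normal"
            removed.append(v)
        else:
            kept.append(v)
    return removed, kept


def private_germline_keys(
    series_variants: Sequence[Sequence[VariantCall]],
    vaf_threshold: float = 0.20,
) -> set[VariantKey]:
    """Keys removed patient-globally by the private-germline rule.

    A key qualifies iff it is detected (alt reads > 0) in every time point
    and its VAF is strictly above ``vaf_threshold`` at every time point.
    With a single time point the rule still applies to that one VAF.
    """
    if len(series_variants) == 1:
        log.warning("private-germline rule applied to a single-time-point series")
    by_key: dict[VariantKey, list[VariantCall]] = {}
    for sample in series_variants:
        for v in sample:
            by_key.setdefault(v.key, []).append(v)
    n_samples = len(series_variants)
    removed = set()
    for key, calls in by_key.items():
        if len(calls) == n_samples and all(
            c.alt_reads > 0 and c.vaf > vaf_threshold for c in calls
        ):
            removed.add(key)
    return removed


def filter_private_germline(
    series: PatientSeries,
    vaf_threshold: float = 0.20,
) -> tuple[list[list[VariantCall]], list[list[VariantCall]]]:
    """Apply the patient-global private-germline rule to a series.

    Returns (removed, kept) partitions aligned with the series' samples.
    """
    per_sample = [s.variants for s in series]
    keys = private_germline_keys(per_sample, vaf_threshold)
    removed, kept = [], []
    for sample in per_sample:
        rem, kee = [], []
        for v in sample:
            if v.key in keys:
                v.filter_status = "private_germline"
                rem.append(v)
            else:
                kee.append(v)
        removed.append(rem)
        kept.append(kee)
    return removed, kept


def flag_for_review(
    series: PatientSeries,
    delta_threshold: float = 0.02,
) -> set[VariantKey]:
    """Flag passing variants whose VAF range across the series exceeds
    ``delta_threshold``; a time point where the variant is undetected
    contributes VAF 0.  Nothing is removed."""
    keys = {v.key for s in series for v in s.passing()}
    vafs: dict[VariantKey, list[float]] = {k: [] for k in keys}
    for sample in series:
        present = {v.key: v.vaf for v in sample.passing()}
        for key in keys:
            vafs[key].append(present.get(key, 0.0))
    flagged = {k for k, vs in vafs.items() if max(vs) - min(vs) > delta_threshold}
    for sample in series:
        for v in sample.passing():
            if v.key in flagged:
                v.review_flag = True
    return flagged


def apply_filter_cascade(
    series: PatientSeries,
    popdb: Mapping[VariantKey, float],
    normal_evidence: Mapping[VariantKey, int],
    af_threshold: float = 0.001,
    max_normal_reads: int = 2,
    vaf_threshold: float = 0.20,
    delta_threshold: float = 0.02,
) -> tuple[PatientSeries, FilterReport]:
    """Run steps 1-4 in order on one patient's series.

    The returned series keeps every input variant (removed ones carry their
    first-failing label); the report satisfies the conservation invariant
    input == removed + passing per sample.
    """
    counts = []
    step12: list[dict] = []
    for sample in series:
        n_input = len(sample.variants)
        rem1, kept1 = filter_common_germline(sample.variants, popdb, af_threshold)
        rem2, kept2 = filter_matched_normal(kept1, normal_evidence, max_normal_reads)
        step12.append(
            {"input": n_input, "common": len(rem1), "normal": len(rem2), "kept": kept2}
        )
    # step 3 operates patient-globally on the survivors of steps 1-2
    keys3 = private_germline_keys([s["kept"] for s in step12], vaf_threshold)
    for sample, acc in zip(series, step12):
        n_priv = 0
        for v in acc["kept"]:
            if v.key in keys3:
                v.filter_status = "private_germline"
                n_priv += 1
        acc["private"] = n_priv
    flagged = flag_for_review(series, delta_threshold)
    for sample, acc in zip(series, step12):
        n_pass = sum(1 for v in sample.variants if v.filter_status == "PASS")
        n_flag = sum(
            1 for v in sample.variants if v.filter_status == "PASS" and v.review_flag
        )
        counts.append(
            SampleFilterCounts(
                patient_id=series.patient_id,
                day=sample.day,
                input=acc["input"],
                removed_common_germline=acc["common"],
                removed_matched_normal=acc["normal"],
                removed_private_germline=acc["private"],
                flagged_for_review=n_flag,
                passing=n_pass,
            )
        )
    report = FilterReport(patient_id=series.patient_id, per_sample=counts)
    assert report.conserved(), "filter partition lost or duplicated variants"
    return series, report


def write_filter_report(reports: Sequence[FilterReport], path: str | Path) -> Path:
    rows = [vars(c) for rep in reports for c in rep.per_sample]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
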