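"""Per-sample circulating-tumor burden statistics: MSAF and bTMB.

MSAF (maximum somatic allele frequency) is the maximum VAF among passing
somatic variants of a sample — reportable alterations, variants of unknown
significance and synonymous mutations all included — and serves as a proxy
for the circulating tumor fraction.  No per-sample 20% cap is applied: the
patient-combined 20% rule is already realized by the private-germline filter
step, which pools VAFs across all of the patient's samples.

bTMB (blood tumor mutational burden) is the count of passing somatic
variants per megabase of panel territory (default panel 637 kb).  Synonymous
variants are counted by default, mirroring the MSAF inclusion rule, since a
narrower numerator is a configuration choice; the baseline (day-0) bTMB is
the value used for survival splits.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .pipeline_io import PatientSeries, PipelineError, SampleRecord

DEFAULT_PANEL_BP = 637_000


def compute_msaf(
    sample: SampleRecord,
    include_classes: Iterable[str] | None = None,
) -> float:
    """Maximum VAF over the sample's passing variants; 0.0 for an empty set.

    ``include_classes`` restricts the effect classes considered (default:
    all classes, synonymous included).
    """
    classes = set(include_classes) if include_classes is not None else None
    vafs = [
        v.vaf
        for v in sample.passing()
        if classes is None or v.effect in classes
    ]
    return max(vafs) if vafs else 0.0


def compute_btmb(
    sample: SampleRecord,
    panel_bp: int = DEFAULT_PANEL_BP,
    nonsynonymous_only: bool = False,
) -> float:
    """Passing somatic variants per megabase of panel territory."""
    if panel_bp <= 0:
        raise PipelineError("panel_bp must be positive")
    variants = sample.passing()
    if nonsynonymous_only:
        variants = [v for v in variants if v.effect != "synonymous"]
    return len(variants) / (panel_bp / 1e6)


def mean_msaf(series: PatientSeries, min_day: int | None = None) -> float:
    """Arithmetic mean of per-sample MSAF over the patient's samples.

    ``min_day`` restricts to samples collected at or after that day (e.g.
    on-treatment samples only); by default all samples enter the mean.
    """
    samples = [s for s in series if min_day is None or s.day >= min_day]
    if not samples:
        raise PipelineError(f"patient {series.patient_id}: no samples in window")
    msafs = [compute_msaf(s) for s in samples]
    return sum(msafs) / len(msafs)


def annotate_series(series: PatientSeries, panel_bp: int = DEFAULT_PANEL_BP) -> PatientSeries:
    """Fill each sample's ``msaf`` and ``btmb`` fields in place."""
    for sample in series:
        sample.msaf = compute_msaf(sample)
        sample.btmb = compute_btmb(sample, panel_bp)
    return series


def cohort_metrics(
    cohort: Sequence[PatientSeries],
    panel_bp: int = DEFAULT_PANEL_BP,
) -> pd.DataFrame:
    """Tidy metrics table: patient_id, day, msaf, btmb, n_passing."""
    rows = []
    for series in cohort:
        annotate_series(series, panel_bp)
        for sample in series:
            rows.append(
                {
                    "patient_id": series.patient_id,
                    "day": sample.day,
                    "msaf": sample.msaf,
                    "btmb": sample.btmb,
                    "n_passing": len(sample.passing()),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "day", "msaf", "btmb", "n_passing"])
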