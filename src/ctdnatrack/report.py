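"""Per-patient and cohort-level report bundles.

Figures are out of scope; every figure-style surface (filter accounting,
burden trajectories, cluster prevalence trajectories, clone tree, emergence
calls, lesion-association signs) is emitted as JSON-serializable tables.
A patient with fewer serial draws than the clustering minimum gets a bundle
without cluster/tree sections and an explicit reason instead.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from .burden_metrics import compute_msaf, compute_btmb
from .evolution_tree import lesion_association
from .pipeline_io import ClinicalRecord, PatientSeries

SECTIONS = ("filter_report", "metrics", "clusters", "tree", "emergence", "lesion_association")


def patient_report(
    series: PatientSeries,
    clinical: ClinicalRecord | None = None,
    filter_report=None,
    cluster_result=None,
    tree=None,
    emergence_rows: Sequence[Mapping] | None = None,
    min_timepoints: int = 3,
    panel_bp: int = 637_000,
) -> dict:
    """Assemble one patient's bundle; missing stages leave explicit gaps."""
    bundle: dict = {"patient_id": series.patient_id, "gaps": {}}
    if filter_report is not None:
        bundle["filter_report"] = [dataclasses.asdict(c) for c in filter_report.per_sample]
    else:
        bundle["gaps"]["filter_report"] = "stage not run"
    bundle["metrics"] = [
        {
            "day": s.day,
            "msaf": s.msaf if s.msaf is not None else compute_msaf(s),
            "btmb": s.btmb if s.btmb is not None else compute_btmb(s, panel_bp),
            "n_passing": len(s.passing()),
        }
        for s in series
    ]
    if len(series) < min_timepoints:
        reason = (
            f"{len(series)} time point(s) < {min_timepoints}: "
            "patient ineligible for clonal deconvolution"
        )
        bundle["gaps"]["clusters"] = reason
        bundle["gaps"]["tree"] = reason
    else:
        if cluster_result is not None:
            bundle["clusters"] = cluster_result.to_dict()
        else:
            bundle["gaps"]["clusters"] = "stage not run"
        if tree is not None:
            bundle["tree"] = tree.to_dict()
        else:
            bundle["gaps"]["tree"] = "stage not run"
    if emergence_rows:
        bundle["emergence"] = [dict(r) for r in emergence_rows]
    else:
        bundle["gaps"]["emergence"] = "no emergence calls"
    if cluster_result is not None and clinical is not None and clinical.diameters_per_scan:
        scan_days = [d for d, _ in clinical.diameters_per_scan]
        diams = [x for _, x in clinical.diameters_per_scan]
        bundle["lesion_association"] = lesion_association(
            cluster_result.prevalence, cluster_result.days, scan_days, diams
        )
    else:
        bundle["gaps"]["lesion_association"] = "needs clusters and scan diameters"
    return bundle


def cohort_report(
    cohort: Sequence[PatientSeries],
    clinical: Sequence[ClinicalRecord],
    filter_reports: Mapping = {},
    cluster_results: Mapping = {},
    trees: Mapping = {},
    emergence_rows: Sequence[Mapping] = (),
    min_timepoints: int = 3,
) -> dict:
    """One bundle per patient, keyed by patient id."""
    clin_by_pid = {c.patient_id: c for c in clinical}
    bundles = {}
    for series in cohort:
        pid = series.patient_id
        rows = [r for r in emergence_rows if r.get("patient_id") == pid]
        bundles[pid] = patient_report(
            series,
            clinical=clin_by_pid.get(pid),
            filter_report=filter_reports.get(pid),
            cluster_result=cluster_results.get(pid),
            tree=trees.get(pid),
            emergence_rows=rows,
            min_timepoints=min_timepoints,
        )
    return bundles
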