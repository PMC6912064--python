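"""Domain types, file formats, and the pipeline driver.

Everything downstream of raw variant calling lives in this package: the
pipeline starts from per-sample VCFs (one per plasma draw), a sample sheet
linking patients to serial draws, matched white-blood-cell evidence, a
population allele-frequency table, and a clinical table.  This module owns
the parsing/writing of those formats plus the ``run_pipeline`` driver that
chains filtering, burden metrics, clonal deconvolution, tree reconstruction
and outcome statistics.

Coordinates are 1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger("ctdnatrack")

#: response labels, best to worst
RESPONSE_ORDER = ("PR", "SD", "PD")

EFFECT_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "intronic",
    "other",
)

FILTER_LABELS = ("PASS", "common_germline", "matched_normal", "private_germline")


class PipelineError(RuntimeError):
    """Raised for malformed inputs or failed pipeline stages."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

VariantKey = tuple[str, int, str, str]


@dataclass
class VariantCall:
    """One candidate variant in one sample.

    VAF is always derived from the read counts, never taken from an AF tag,
    so it stays consistent with the binomial model used downstream.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: int
    ref_reads: int
    gene: str = ""
    effect: str = "other"
    logr: float | None = None
    filter_status: str = "PASS"
    review_flag: bool = False

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.ref_reads < 0:
            raise PipelineError(
                f"negative read count at {self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )
        if self.alt_reads + self.ref_reads == 0:
            raise PipelineError(
                f"zero total depth at {self.chrom}:{self.pos} {self.ref}>{self.alt}; "
                "VAF undefined"
            )
        if self.effect not in EFFECT_CLASSES:
            raise PipelineError(f"unknown effect class {self.effect!r}")
        if self.filter_status not in FILTER_LABELS:
            raise PipelineError(f"unknown filter label {self.filter_status!r}")

    @property
    def total_reads(self) -> int:
        return self.alt_reads + self.ref_reads

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.total_reads

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleRecord:
    """All variant calls of one plasma draw, plus derived burden metrics."""

    patient_id: str
    day: int
    variants: list[VariantCall] = field(default_factory=list)
    msaf: float | None = None
    btmb: float | None = None

    def __post_init__(self) -> None:
        if self.day < 0:
            raise PipelineError(f"negative collection day for {self.patient_id}")

    def passing(self) -> list[VariantCall]:
        return [v for v in self.variants if v.filter_status == "PASS"]

    def get(self, key: VariantKey) -> VariantCall | None:
        for v in self.variants:
            if v.key == key:
                return v
        return None


@dataclass
class PatientSeries:
    """Serial samples of one patient, strictly ordered by collection day."""

    patient_id: str
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        days = [s.day for s in self.samples]
        if sorted(set(days)) != days:
            raise PipelineError(
                f"patient {self.patient_id}: sample days must be strictly increasing, got {days}"
            )

    @property
    def days(self) -> list[int]:
        return [s.day for s in self.samples]

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotations (response, lesions, survival)."""

    patient_id: str
    stage: str
    smoking_index: int
    diameter_sum_cm: float
    best_response: str
    response_per_scan: list[tuple[int, str]] = field(default_factory=list)
    diameters_per_scan: list[tuple[int, float]] = field(default_factory=list)
    pfs_days: int | None = None
    event: bool | None = None
    age: int | None = None
    gender: str | None = None
    histology: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("III", "IV"):
            raise PipelineError(f"unknown stage {self.stage!r}")
        if self.smoking_index < 0:
            raise PipelineError("smoking index must be non-negative")
        if self.best_response not in RESPONSE_ORDER:
            raise PipelineError(f"unknown response label {self.best_response!r}")
        for _, lab in self.response_per_scan:
            if lab not in RESPONSE_ORDER:
                raise PipelineError(f"unknown response label {lab!r}")
        if self.pfs_days is not None and self.pfs_days <= 0:
            raise PipelineError("pfs_days must be positive")

    @property
    def pd_day(self) -> int | None:
        """Day of the first scan labeled PD, or None."""
        for day, lab in self.response_per_scan:
            if lab == "PD":
                return day
        return None


def best_response_of(labels: Sequence[str]) -> str:
    """Best label attained under the ordering PR > SD > PD."""
    for lab in RESPONSE_ORDER:
        if lab in labels:
            return lab
    raise PipelineError("no response labels given")


# ---------------------------------------------------------------------------
# VCF in/out
# ---------------------------------------------------------------------------

@dataclass
class VcfReadResult:
    """Calls surviving the depth cut, plus how many records were dropped."""

    calls: list[VariantCall]
    n_dropped_low_depth: int

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def read_vcf(
    path: str | Path,
    min_total_depth: int = 100,
    logr_key: str = "LOGR",
) -> VcfReadResult:
    """Read a VCF v4.2 into :class:`VariantCall` objects.

    Requires a per-sample AD (allelic depths) field; multi-allelic records are
    split into one call per ALT with AD matched positionally.  Records whose
    per-allele depth (ref + alt reads) falls below ``min_total_depth`` are
    dropped and counted.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise PipelineError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # noqa: BLE001 - cyvcf2 raises bare exceptions
        raise PipelineError(f"malformed VCF {path}: {exc}") from exc

    calls: list[VariantCall] = []
    dropped = 0
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise PipelineError(
                f"{path}: record {rec.CHROM}:{rec.POS} has no AD field; "
                "allelic depths are required"
            )
        ad = ad[0]  # single-sample files
        ref_reads = int(ad[0])
        gene = rec.INFO.get("GENE") or ""
        effect = rec.INFO.get("EFFECT") or "other"
        logr = rec.INFO.get(logr_key)
        review = rec.INFO.get("REVIEW") is not None
        filt = rec.FILTER or "PASS"  # cyvcf2 reports PASS as None
        for i, alt in enumerate(rec.ALT):
            if i + 1 >= len(ad):
                raise PipelineError(
                    f"{path}: record {rec.CHROM}:{rec.POS} AD has fewer entries than ALTs"
                )
            alt_reads = int(ad[i + 1])
            if ref_reads + alt_reads < min_total_depth:
                dropped += 1
                continue
            calls.append(
                VariantCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    alt_reads=alt_reads,
                    ref_reads=ref_reads,
                    gene=gene,
                    effect=effect if effect in EFFECT_CLASSES else "other",
                    logr=float(logr) if logr is not None else None,
                    filter_status=filt if filt in FILTER_LABELS else "PASS",
                    review_flag=bool(review),
                )
            )
    if dropped:
        log.info("%s: dropped %d record(s) below depth %d", path.name, dropped, min_total_depth)
    return VcfReadResult(calls=calls, n_dropped_low_depth=dropped)


_CONTIG_LINES = "".join(
    f"##contig=<ID=chr{c}>\n" for c in list(range(1, 23)) + ["X", "Y"]
)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ctdnatrack
{contigs}\
##FILTER=<ID=common_germline,Description="Population allele frequency at or above threshold">
##FILTER=<ID=matched_normal,Description="Supported by more than the allowed reads in matched white blood cells">
##FILTER=<ID=private_germline,Description="VAF above 20% at every time point of the patient">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect class">
##INFO=<ID={logr_key},Number=1,Type=Float,Description="Copy-number log2 ratio">
##INFO=<ID=REVIEW,Number=0,Type=Flag,Description="Flagged for manual review (max VAF change above threshold)">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    sample_name: str = "SAMPLE",
    logr_key: str = "LOGR",
) -> Path:
    """Write calls as a single-sample uncompressed VCF v4.2.

    The FILTER column carries the removal label (or PASS) and the review flag
    is written as the REVIEW INFO flag, so a filtered VCF round-trips.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [_VCF_HEADER.format(sample=sample_name, logr_key=logr_key, contigs=_CONTIG_LINES)]
    for v in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
        info = []
        if v.gene:
            info.append(f"GENE={v.gene}")
        info.append(f"EFFECT={v.effect}")
        if v.logr is not None:
            info.append(f"{logr_key}={v.logr:.4f}")
        if v.review_flag:
            info.append("REVIEW")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t"
            f"{';'.join(info) or '.'}\tAD:DP\t{v.ref_reads},{v.alt_reads}:{v.total_reads}\n"
        )
    path.write_text("".join(lines))
    return path


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> dict[str, list[tuple[int, str]]]:
    """Read the TSV sample sheet (patient_id, day, vcf_path).

    Returns per-patient lists of (day, vcf_path) sorted by day; duplicate
    (patient, day) pairs are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "day", "vcf_path"}
    if not required.issubset(df.columns):
        raise PipelineError(f"sample sheet {path} must have columns {sorted(required)}")
    out: dict[str, list[tuple[int, str]]] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        days = grp["day"].astype(int).tolist()
        if len(set(days)) != len(days):
            raise PipelineError(f"duplicate sample day for patient {pid}")
        entries = sorted(zip(days, grp["vcf_path"].astype(str)))
        out[str(pid)] = [(int(d), p) for d, p in entries]
    return out


def read_clinical_table(
    path: str | Path,
    scans_path: str | Path | None = None,
) -> list[ClinicalRecord]:
    """Read the per-patient clinical TSV, optionally joined with per-scan rows.

    The scans table (patient_id, day, diameter_sum_cm, response) supplies
    ``response_per_scan``; when present, best_response is recomputed from the
    scan labels and cross-checked against the stated column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if df.empty:
        warnings.warn(f"clinical table {path} is empty", stacklevel=2)
        return []
    scans: dict[str, list[tuple[int, str, float]]] = {}
    if scans_path is not None:
        sdf = pd.read_csv(scans_path, sep="\t", dtype={"patient_id": str})
        for pid, grp in sdf.groupby("patient_id"):
            grp = grp.sort_values("day")
            scans[str(pid)] = [
                (int(r.day), str(r.response), float(r.diameter_sum_cm))
                for r in grp.itertuples()
            ]
    records = []
    for row in df.itertuples():
        pid = str(row.patient_id)
        per_scan = scans.get(pid, [])
        stated = str(row.best_response)
        if per_scan:
            labels = [lab for _, lab, _ in per_scan]
            best = best_response_of(labels)
            if stated and stated != "nan" and best != stated:
                raise PipelineError(
                    f"patient {pid}: best_response column {stated!r} contradicts "
                    f"scan labels (recomputed {best!r})"
                )
        else:
            best = stated
        records.append(
            ClinicalRecord(
                patient_id=pid,
                stage=str(row.stage),
                smoking_index=int(row.smoking_index),
                diameter_sum_cm=float(row.diameter_sum_cm),
                best_response=best,
                response_per_scan=[(d, lab) for d, lab, _ in per_scan],
                diameters_per_scan=[(d, diam) for d, _, diam in per_scan],
                pfs_days=int(row.pfs_days) if hasattr(row, "pfs_days") else None,
                event=bool(row.event) if hasattr(row, "event") else None,
                age=int(row.age) if hasattr(row, "age") else None,
                gender=str(row.gender) if hasattr(row, "gender") else None,
                histology=str(row.histology) if hasattr(row, "histology") else None,
            )
        )
    return records


def bundled_cohort_path() -> Path:
    """Path of the packaged 12-patient NSCLC anti-PD1 cohort table."""
    return Path(__file__).parent / "data" / "nsclc_anti_pd1_cohort.tsv"


def _read_keyed_table(path: str | Path, value_col: str) -> dict[VariantKey, float]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", value_col}
    if not required.issubset(df.columns):
        raise PipelineError(f"{path} must have columns {sorted(required)}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): float(getattr(r, value_col))
        for r in df.itertuples()
    }


def read_popdb(path: str | Path) -> dict[VariantKey, float]:
    """Population allele frequencies keyed by chrom:pos:ref:alt."""
    table = _read_keyed_table(path, "pop_af")
    for key, af in table.items():
        if not 0.0 <= af <= 1.0:
            raise PipelineError(f"pop_af out of [0,1] for {key}")
    return table


def read_normal_evidence(path: str | Path) -> dict[VariantKey, int]:
    """White-blood-cell alt read counts keyed by chrom:pos:ref:alt."""
    table = _read_keyed_table(path, "wbc_alt_reads")
    out = {}
    for key, n in table.items():
        if n < 0:
            raise PipelineError(f"negative wbc_alt_reads for {key}")
        out[key] = int(n)
    return out


def load_cohort(
    sample_sheet: Mapping[str, list[tuple[int, str]]],
    min_total_depth: int = 100,
    logr_key: str = "LOGR",
) -> list[PatientSeries]:
    """Load every patient's serial VCFs into :class:`PatientSeries`."""
    cohort = []
    for pid, entries in sample_sheet.items():
        samples = []
        for day, vcf_path in entries:
            result = read_vcf(vcf_path, min_total_depth=min_total_depth, logr_key=logr_key)
            samples.append(SampleRecord(patient_id=pid, day=day, variants=result.calls))
        cohort.append(PatientSeries(patient_id=pid, samples=samples))
    return cohort


# ---------------------------------------------------------------------------
# pipeline configuration and driver
# ---------------------------------------------------------------------------

ALL_STAGES = ("filter", "metrics", "cluster", "tree", "stats")


@dataclass
class PipelineConfig:
    """Everything ``run_pipeline`` needs, loadable from YAML/JSON."""

    sample_sheet: str
    clinical_table: str
    popdb: str
    normal_evidence: str
    outdir: str
    scans_table: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    min_total_depth: int = 100
    logr_key: str = "LOGR"
    pop_af_threshold: float = 0.001
    max_normal_reads: int = 2
    private_germline_vaf: float = 0.20
    review_delta: float = 0.02
    panel_bp: int = 637_000
    min_timepoints: int = 3
    dp_alpha: float = 1.0
    dp_iterations: int = 5000
    dp_burn_in: int = 1000
    dp_thin: int = 5
    tree_epsilon: float = 0.02
    detection_phi: float = 0.01

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the staged analysis: filter → metrics → cluster → tree → stats.

    Writes per-stage TSV/JSON outputs under ``config.outdir`` plus a run log
    (seed, per-stage variant counts).  Returns a dict of output paths and the
    in-memory report bundle.  Any stage failure aborts with the stage name.
    """
    from . import burden_metrics, clonal_inference, evolution_tree, outcome_stats, report
    from . import variant_filtering

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise PipelineError(f"unknown stage {stage!r}")

    sheet = read_sample_sheet(config.sample_sheet)
    clinical = read_clinical_table(config.clinical_table, config.scans_table)
    popdb = read_popdb(config.popdb)
    normal = read_normal_evidence(config.normal_evidence)
    cohort = load_cohort(sheet, config.min_total_depth, config.logr_key)
    run_log: dict = {"seed": config.seed, "stages": list(config.stages), "patients": {}}
    outputs: dict = {"outdir": str(outdir), "run_log": run_log}
    if not config.stages:
        log.info("validation-only run: all stages off")
        return outputs

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    filter_reports = {}
    if "filter" in config.stages:
        vcf_dir = outdir / "filtered_vcfs"
        for series in cohort:
            series_f, rep = _stage(
                "filter",
                variant_filtering.apply_filter_cascade,
                series,
                popdb,
                normal,
                af_threshold=config.pop_af_threshold,
                max_normal_reads=config.max_normal_reads,
                vaf_threshold=config.private_germline_vaf,
                delta_threshold=config.review_delta,
            )
            filter_reports[series.patient_id] = rep
            for sample in series_f:
                write_vcf(
                    sample.variants,
                    vcf_dir / f"{series.patient_id}_day{sample.day}.filtered.vcf",
                    sample_name=f"{series.patient_id}_d{sample.day}",
                    logr_key=config.logr_key,
                )
            run_log["patients"][series.patient_id] = {
                "filter": [dataclasses.asdict(c) for c in rep.per_sample]
            }
        variant_filtering.write_filter_report(
            list(filter_reports.values()), outdir / "filter_report.tsv"
        )
        outputs["filter_report"] = str(outdir / "filter_report.tsv")

    metrics_df = None
    if "metrics" in config.stages:
        metrics_df = _stage(
            "metrics", burden_metrics.cohort_metrics, cohort, panel_bp=config.panel_bp
        )
        metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        outputs["metrics"] = str(outdir / "metrics.tsv")

    cluster_results = {}
    if "cluster" in config.stages:
        dp_cfg = clonal_inference.DPConfig(
            alpha=config.dp_alpha,
            n_iterations=config.dp_iterations,
            burn_in=config.dp_burn_in,
            thin=config.dp_thin,
            min_timepoints=config.min_timepoints,
        )
        traj_frames = []
        cluster_json = {}
        for series in cohort:
            if len(series) < config.min_timepoints:
                log.info(
                    "patient %s: %d time point(s) < %d, skipping clonal deconvolution",
                    series.patient_id, len(series), config.min_timepoints,
                )
                continue
            res = _stage(
                "cluster", clonal_inference.dp_cluster, series, dp_cfg, seed=config.seed
            )
            cluster_results[series.patient_id] = res
            cluster_json[series.patient_id] = res.to_dict()
            traj_frames.append(clonal_inference.summarize_trajectories(res, series))
        (outdir / "clusters.json").write_text(json.dumps(cluster_json, indent=1))
        outputs["clusters"] = str(outdir / "clusters.json")
        if traj_frames:
            traj = pd.concat(traj_frames, ignore_index=True)
            traj.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
            outputs["trajectories"] = str(outdir / "trajectories.tsv")

    trees = {}
    emergence_rows = []
    if "tree" in config.stages:
        clin_by_pid = {c.patient_id: c for c in clinical}
        tree_json = {}
        for pid, res in cluster_results.items():
            trajs = {k: res.prevalence[k] for k in res.cluster_ids}
            tree = _stage(
                "tree",
                evolution_tree.build_tree,
                trajs,
                res.days,
                epsilon=config.tree_epsilon,
                detection_threshold=config.detection_phi,
            )
            trees[pid] = tree
            tree_json[pid] = tree.to_dict()
            pd_day = clin_by_pid[pid].pd_day if pid in clin_by_pid else None
            for cid in res.cluster_ids:
                em = evolution_tree.detect_emergence(
                    res.days, res.prevalence[cid], phi_min=config.detection_phi
                )
                lead = evolution_tree.compute_lead_time(em, pd_day)
                emergence_rows.append(
                    {"patient_id": pid, "cluster": cid, "emergence_day": em,
                     "pd_day": pd_day, "lead_time_days": lead}
                )
        (outdir / "trees.json").write_text(json.dumps(tree_json, indent=1))
        pd.DataFrame(emergence_rows).to_csv(outdir / "emergence.tsv", sep="\t", index=False)
        outputs["trees"] = str(outdir / "trees.json")
        outputs["emergence"] = str(outdir / "emergence.tsv")

    if "stats" in config.stages:
        if metrics_df is None:
            metrics_df = burden_metrics.cohort_metrics(cohort, panel_bp=config.panel_bp)
        stats = _stage(
            "stats", outcome_stats.cohort_statistics, metrics_df, clinical
        )
        (outdir / "stats.json").write_text(json.dumps(stats, indent=1))
        outputs["stats"] = str(outdir / "stats.json")

    bundles = report.cohort_report(
        cohort, clinical, filter_reports, cluster_results, trees, emergence_rows,
        min_timepoints=config.min_timepoints,
    )
    (outdir / "patient_reports.json").write_text(json.dumps(bundles, indent=1))
    outputs["patient_reports"] = str(outdir / "patient_reports.json")
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1, default=str))
    outputs["bundles"] = bundles
    return outputs
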