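import pytest

from ctdnatrack.pipeline_io import PatientSeries, SampleRecord, VariantCall
from ctdnatrack.synthetic_data import SimulationConfig, simulate_cohort


def make_call(chrom="chr1", pos=100, ref="A", alt="T", alt_reads=30, ref_reads=70, **kw):
    return VariantCall(chrom, pos, ref, alt, alt_reads, ref_reads, **kw)


def series_from_vafs(vafs_by_key, days, depth=1000, patient_id="PX"):
    """Build a PatientSeries from exact per-variant VAF trajectories."""
    samples = []
    for j, day in enumerate(days):
        calls = []
        for i, (key, vafs) in enumerate(sorted(vafs_by_key.items())):
            v = vafs[j]
            alt = int(round(v * depth))
            if alt == 0 and v == 0:
                continue  # undetected
            calls.append(
                VariantCall("chr1", 1000 + 10 * i, "A", "T", alt, depth - alt)
            )
        samples.append(SampleRecord(patient_id, day, calls))
    return PatientSeries(patient_id, samples)


def series_from_counts(alt, depth, days, patient_id="PX"):
    """Build a PatientSeries from (N, T) alt/depth count matrices."""
    n, t = alt.shape
    samples = []
    for j in range(t):
        calls = [
            VariantCall("chr1", 1000 + i, "A", "T", int(alt[i, j]), int(depth[i, j] - alt[i, j]))
            for i in range(n)
        ]
        samples.append(SampleRecord(patient_id, days[j], calls))
    return PatientSeries(patient_id, samples)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 12-patient / 44-sample cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def filtered_cohort():
    """Default cohort with the filter cascade applied (fresh copy)."""
    from ctdnatrack.variant_filtering import apply_filter_cascade

    cohort = simulate_cohort(SimulationConfig(seed=42))
    reports = {}
    for p in cohort.patients:
        _, reports[p.patient_id] = apply_filter_cascade(
            p.series, cohort.popdb, cohort.normal_evidence
        )
    return cohort, reports
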