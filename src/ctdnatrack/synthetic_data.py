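"""Synthetic serial-ctDNA cohort generator with ground truth.

Emulates the study design the pipeline targets: ~12 NSCLC patients on
anti-PD1 therapy, each with a baseline and serial plasma draws every 2-5
weeks, sequenced at ~3000x deduplicated depth over a 329-gene / 637-kb
panel.  For every patient the generator plants

* a random clonal tree whose prevalence trajectories follow a response
  archetype (responder, stable, progressor, or relapse-after-response with a
  resistance clone emerging 60-120 days before the planted progression day),
  satisfying the crossing and sum constraints exactly by construction;
* binomial read counts per mutation per draw (depth ~ Poisson(3000),
  alt ~ Binomial(depth, phi * m / c));
* germline heterozygous SNPs (VAF ~ 0.5, present in the population
  database), white-blood-cell-detectable CHIP variants, and private germline
  variants absent from both the database and the normal (the confounders the
  filter cascade must remove);
* lesion diameter sums positively coupled to the circulating tumor
  fraction, with iRECIST-like PR/SD/PD labels and PFS derived from them.

The default schedule fixes seven patients at 2 draws and five at 6 draws
(44 samples, 5 patients eligible for clonal deconvolution), the cohort shape
the downstream statistics consume.  Everything is driven by one seed; the
same config and seed produce byte-identical output files.

The bundled 329-gene panel list is a synthetic stand-in: ~30 recurrent lung
cancer genes plus synthetic filler names that only decorate outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline_io import (
    ClinicalRecord,
    PatientSeries,
    PipelineError,
    SampleRecord,
    VariantCall,
    VariantKey,
    write_vcf,
)

DRIVER_GENES = [
    "TP53", "CDKN2A", "NTRK3", "B2M", "BRAF", "ROS1", "PDGFRA", "PTCH1",
    "EGFR", "KRAS", "STK11", "KEAP1", "ALK", "MET", "ERBB2", "RET",
    "PIK3CA", "PTEN", "RB1", "NF1", "SMARCA4", "ARID1A", "FGFR1", "CCND1",
    "MYC", "MDM2", "CDK4", "ATM", "BRCA2", "NOTCH1",
]
#: synthetic 329-gene panel (driver names + filler); names only decorate outputs
PANEL_GENES = DRIVER_GENES + [f"PANEL{i:03d}" for i in range(1, 300)]

ARCHETYPES = ("responder", "stable", "progressor", "relapse")

_EFFECTS = ["nonsynonymous", "synonymous", "frameshift", "inframe_indel", "intronic", "other"]
_EFFECT_P = [0.55, 0.15, 0.08, 0.05, 0.07, 0.10]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.  ``seed`` is mandatory."""

    seed: int
    n_patients: int = 12
    samples_per_patient: tuple[int, ...] | None = None  # None -> 7x2 + 5x6 = 44
    interval_days: tuple[int, int] = (14, 35)
    depth_mean: float = 3000.0
    panel_bp: int = 637_000
    n_clones_range: tuple[int, int] = (2, 4)
    mutations_per_clone_range: tuple[int, int] = (4, 6)
    n_germline_snps: int = 5
    n_chip_variants: int = 2
    n_private_germline: int = 1
    founder_phi_range: tuple[float, float] = (0.10, 0.35)
    relapse_lead_range: tuple[int, int] = (60, 120)
    archetypes: tuple[str, ...] | None = None  # None -> default mix
    diameter_noise_frac: float = 0.10
    coupling_a: float = 0.4
    coupling_b: float = 2.0
    cn_event_rate: float = 0.0  # fraction of somatic loci with a planted logR shift
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.depth_mean <= 0 or self.panel_bp <= 0:
            raise PipelineError("counts and sizes must be positive")
        if self.archetypes is not None:
            for a in self.archetypes:
                if a not in ARCHETYPES:
                    raise PipelineError(f"unknown archetype {a!r}")


@dataclass
class SimMutation:
    key: VariantKey
    gene: str
    effect: str
    clone: int | None  # None for non-somatic variants
    origin: str  # somatic | common_germline | private_germline | chip
    logr: float = 0.0
    pop_af: float | None = None
    wbc_alt_reads: int = 0


@dataclass
class SimulatedPatient:
    patient_id: str
    archetype: str
    days: list[int]
    tree_parent: dict[int, int | None]  # clone -> parent clone (None for founder)
    phi: np.ndarray  # (n_clones, T) true prevalences
    mutations: list[SimMutation]
    series: PatientSeries  # raw calls as a caller would emit them
    clinical: ClinicalRecord
    resistance_clone: int | None = None
    true_emergence_day: float | None = None
    true_pd_day: int | None = None

    @property
    def n_clones(self) -> int:
        return self.phi.shape[0]

    def truth_origin(self) -> dict[VariantKey, str]:
        return {m.key: m.origin for m in self.mutations}

    def truth_clone(self) -> dict[VariantKey, int]:
        return {m.key: m.clone for m in self.mutations if m.clone is not None}


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    patients: list[SimulatedPatient]
    popdb: dict[VariantKey, float] = field(default_factory=dict)
    normal_evidence: dict[VariantKey, int] = field(default_factory=dict)

    def series(self) -> list[PatientSeries]:
        return [p.series for p in self.patients]

    def clinical(self) -> list[ClinicalRecord]:
        return [p.clinical for p in self.patients]


# ---------------------------------------------------------------------------
# clone trees and prevalence trajectories
# ---------------------------------------------------------------------------

def simulate_clone_tree(n_clones: int, seed_or_rng) -> dict[int, int | None]:
    """Random rooted clone tree: clone 0 is the founder, every later clone
    attaches to a uniformly chosen earlier clone."""
    if n_clones < 1:
        raise PipelineError("need at least one clone")
    rng = _as_rng(seed_or_rng)
    tree: dict[int, int | None] = {0: None}
    for c in range(1, n_clones):
        tree[c] = int(rng.integers(0, c))
    return tree


def _as_rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _sibling_shares(k: int, days: np.ndarray, rng) -> np.ndarray:
    """Time-varying prevalence shares for k sibling clones, (k, T), summing
    to <= 0.85 of the parent at every time point.

    Sibling shares oscillate with distinct phases, so sibling trajectories
    cross each other over the course — which both pins the planted topology
    (a sibling cannot pose as the other's ancestor without violating the
    crossing rule) and keeps sibling clusters separable by trajectory shape
    at panel depth.
    """
    total = rng.uniform(0.55, 0.85)
    if k == 1:
        # a single child tracks its parent exactly: it peaks with the parent,
        # so it cannot be mistaken for a child of the parent's siblings
        return np.full((1, len(days)), total)
    base = np.full(k, 0.5)
    phases = rng.uniform(0, 2 * np.pi) + np.arange(k) * (2 * np.pi / k)
    period = rng.uniform(70, 110)
    u = base[:, None] * (1 + 0.55 * np.sin(2 * np.pi * days[None, :] / period + phases[:, None]))
    u = np.clip(u, 0.05, None)
    return u * (total / u.sum(axis=0).max())


def simulate_trajectories(
    tree: dict[int, int | None],
    archetype: str,
    days: Sequence[int],
    seed_or_rng,
    founder_phi_range: tuple[float, float] = (0.10, 0.35),
    relapse_lead_range: tuple[int, int] = (60, 120),
    coupling_a: float = 0.4,
    coupling_b: float = 2.0,
    phi0: float | None = None,
    baseline_cm: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-clone prevalence matrix (n_clones, T) under a response archetype.

    Children's trajectories are oscillating shares of their parent's (the
    crossing and sum constraints hold exactly by construction; sibling
    shares cross over time, which pins the planted topology).  For the relapse archetype a
    non-founder resistance clone emerges ``relapse_lead_range`` days before
    the planted progression day (the last draw), growing exponentially from
    the detection floor to 1.35x the prevalence at which the lesion-diameter
    progression criterion (+20% from nadir and at least +0.5 cm) is met, so
    the noiseless diameter first crosses that criterion inside the final
    scan interval; the resistance prevalence is added to all of its
    ancestors.  Returns (phi, meta) with meta carrying the resistance clone
    id, the true emergence day and the planted PD day.
    """
    rng = _as_rng(seed_or_rng)
    days = np.asarray(days, dtype=float)
    t = len(days)
    n_clones = len(tree)
    if phi0 is None:
        phi0 = float(rng.uniform(*founder_phi_range))
    meta: dict = {"resistance_clone": None, "emergence_day": None, "pd_day": None}

    if archetype == "responder":
        base = phi0 * np.exp(-days / rng.uniform(40, 80))
    elif archetype == "stable":
        phase = rng.uniform(0, 2 * np.pi)
        base = phi0 * (1 + 0.08 * np.sin(2 * np.pi * days / 160 + phase))
    elif archetype == "progressor":
        base = np.minimum(0.8, phi0 * np.exp(days / rng.uniform(150, 300)))
    elif archetype == "relapse":
        base = phi0 * np.exp(-days / rng.uniform(40, 80))
    else:
        raise PipelineError(f"unknown archetype {archetype!r}")

    resistance = None
    res_phi = np.zeros(t)
    if archetype == "relapse":
        if n_clones < 2:
            raise PipelineError("relapse archetype needs at least 2 clones")
        resistance = int(rng.integers(1, n_clones))
        pd_day = float(days[-1])
        lead = float(rng.uniform(*relapse_lead_range))
        emergence = max(pd_day - lead, float(days[1]) if t > 1 else 0.0)
        # prevalence needed at PD: relative diameter a + b*tf must clear the
        # nadir by 20% and by 0.5 cm absolute (in baseline-scaled units).
        # The nadir is of the total fraction (decay + growing resistance),
        # which depends on the resistance level itself -> fixed point.
        if baseline_cm is None:
            baseline_cm = 2.0 + 30.0 * phi0
        # two-phase growth: the clone creeps at low, molecularly detectable
        # prevalence (1.5% -> 3%) after emergence, then accelerates over the
        # final ~45 days to 1.6x the radiological threshold.  The creep phase
        # keeps the lesion diameter quiet until shortly before the planted
        # progression day, so measurement noise rarely pulls the
        # radiological call earlier than planted.
        r0 = coupling_a + coupling_b * phi0
        creep_lo, creep_hi, accel_days = 0.013, 0.02, 35.0
        t_star = max(emergence, pd_day - accel_days)
        phi_end = 0.10
        for _ in range(8):
            if t_star > emergence:
                creep = creep_lo + (creep_hi - creep_lo) * (
                    (days - emergence) / (t_star - emergence)
                )
                growth = np.log(phi_end / creep_hi) / max(pd_day - t_star, 1.0)
                late = creep_hi * np.exp(growth * (days - t_star))
            else:
                creep = np.full_like(days, creep_lo)
                growth = np.log(phi_end / creep_lo) / max(pd_day - emergence, 1.0)
                late = creep_lo * np.exp(growth * (days - emergence))
            res_phi = np.where(days < emergence, 0.0, np.where(days <= t_star, creep, late))
            res_phi = np.minimum(res_phi, phi_end)
            r_nadir = coupling_a + coupling_b * float((base + res_phi).min())
            r_thr = r_nadir + max(0.2 * r_nadir, 0.5 * r0 / baseline_cm)
            phi_needed = (r_thr - coupling_a) / coupling_b - float(base[-1])
            phi_end = float(np.clip(1.6 * phi_needed, 0.10, 0.65))
        meta.update(
            resistance_clone=resistance, emergence_day=emergence, pd_day=int(pd_day)
        )

    # ancestors of the resistance clone carry its prevalence on top of their
    # own (a subclone's mutations ride inside its ancestors' cells)
    ancestors = set()
    node = resistance
    while node is not None and tree[node] is not None:
        ancestors.add(tree[node])
        node = tree[node]

    phi = np.zeros((n_clones, t))
    nonres = np.zeros((n_clones, t))  # prevalence excluding the resistance mass
    nonres[0] = base
    phi[0] = base + (res_phi if 0 in ancestors or resistance is not None else 0.0)
    children: dict[int, list[int]] = {}
    for c, p in tree.items():
        if p is not None:
            children.setdefault(p, []).append(c)
    for parent in sorted(children):
        kids = sorted(children[parent])
        shares = _sibling_shares(len(kids), days, rng)
        for kid, w in zip(kids, shares):
            if kid == resistance:
                nonres[kid] = 0.0
                phi[kid] = res_phi
            else:
                nonres[kid] = w * nonres[parent]
                phi[kid] = nonres[kid] + (res_phi if kid in ancestors else 0.0)
    # descendants of the resistance clone (late second hits) ride inside it
    if resistance is not None:
        for parent in sorted(children):
            if not _descends(tree, parent, resistance) and parent != resistance:
                continue
            kids = sorted(children[parent])
            shares = _sibling_shares(len(kids), days, rng)
            for kid, w in zip(kids, shares):
                delay = rng.uniform(0.3, 0.6)
                e2 = meta["emergence_day"] + delay * (
                    meta["pd_day"] - meta["emergence_day"]
                )
                ramp = np.clip((days - e2) / max(meta["pd_day"] - e2, 1.0), 0.0, 1.0)
                phi[kid] = w * phi[parent] * ramp
                nonres[kid] = 0.0
    return phi, meta


def _descends(tree, node, ancestor) -> bool:
    while node is not None:
        if node == ancestor:
            return True
        node = tree[node]
    return False


# ---------------------------------------------------------------------------
# read counts and variant tables
# ---------------------------------------------------------------------------

def simulate_read_counts(
    phi: np.ndarray,
    depth_mean: float,
    rate: np.ndarray,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth ~ Poisson(depth_mean); alt ~ Binomial(depth, clip(phi*rate, 0, 1)).

    ``phi`` and ``rate`` broadcast to the same shape.
    """
    p = np.clip(phi * rate, 0.0, 1.0)
    depth = rng.poisson(depth_mean, size=p.shape)
    alt = rng.binomial(depth, p)
    return depth, alt


def _random_locus(rng, used: set) -> tuple[str, int, str, str]:
    bases = "ACGT"
    while True:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1_000_000, 200_000_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        if alt == ref:
            alt = bases[(bases.index(ref) + 1) % 4]
        return chrom, pos, ref, alt


# ---------------------------------------------------------------------------
# clinical coupling
# ---------------------------------------------------------------------------

def simulate_clinical(
    patient_id: str,
    days: Sequence[int],
    tumor_fraction: np.ndarray,
    seed_or_rng,
    coupling_a: float = 0.4,
    coupling_b: float = 2.0,
    noise_frac: float = 0.10,
    baseline_cm: float | None = None,
) -> ClinicalRecord:
    """Lesion diameters coupled to tumor fraction, with iRECIST-like labels.

    diameter(t) = baseline_cm * (a + b*tf(t)) / (a + b*tf(0)), observed with
    proportional Gaussian noise.  PR: >=30% decrease from baseline.  PD
    follows the immune-modified convention: a >=20% increase from nadir
    (and >=0.5 cm absolute) is unconfirmed progression, which counts as PD
    only when the next scan also exceeds the threshold (or when there is no
    further scan); progression is dated at the scan that confirms it, the
    comparator being scan-confirmed relapse.  Without confirmation,
    independent measurement noise over many scans produces spurious early
    PD calls no reading workflow would make.  PFS is the PD day (event) or
    the last scan day (censored).
    Baseline size is itself positively coupled to the baseline tumor
    fraction, as in real cohorts where bulky disease sheds more ctDNA.
    """
    rng = _as_rng(seed_or_rng)
    days = list(days)
    tf = np.asarray(tumor_fraction, dtype=float)
    if baseline_cm is None:
        baseline_cm = float(2.0 + 30.0 * tf[0] * rng.lognormal(0.0, 1.0))
    rel = (coupling_a + coupling_b * tf) / (coupling_a + coupling_b * tf[0])
    true_diam = baseline_cm * rel
    obs = true_diam * (1.0 + rng.normal(0.0, noise_frac, size=len(days)))
    obs = np.maximum(obs, 0.1)
    baseline_obs = float(obs[0])
    on_treatment = [float(d) for d in obs[1:]]
    # pass 1: threshold exceedance vs the running nadir of earlier scans
    exceed = []
    nadir = baseline_obs
    for d in on_treatment:
        exceed.append(d >= nadir + max(0.2 * nadir, 0.5))
        nadir = min(nadir, d)
    # pass 2: first exceedance confirmed by the following scan (or terminal);
    # progression is dated at the confirming scan
    pd_idx = None
    for i, ex in enumerate(exceed):
        if ex and i == len(exceed) - 1:
            pd_idx = i
            break
        if ex and exceed[i + 1]:
            pd_idx = i + 1
            break
    scans: list[tuple[int, str]] = []
    diams: list[tuple[int, float]] = []
    pfs_day, event = days[-1], False
    for i, (day, d) in enumerate(zip(days[1:], on_treatment)):
        if pd_idx is not None and i >= pd_idx:
            label = "PD"
        elif d <= 0.7 * baseline_obs:
            label = "PR"
        else:
            label = "SD"
        scans.append((int(day), label))
        diams.append((int(day), round(d, 2)))
    if pd_idx is not None:
        pfs_day, event = days[1 + pd_idx], True
    labels = [lab for _, lab in scans] or ["SD"]
    from .pipeline_io import best_response_of

    return ClinicalRecord(
        patient_id=patient_id,
        stage="IV" if rng.uniform() < 11 / 12 else "III",
        smoking_index=int(rng.choice([0, 400, 450, 600, 800, 1500])),
        diameter_sum_cm=round(baseline_obs, 2),
        best_response=best_response_of(labels),
        response_per_scan=scans,
        diameters_per_scan=diams,
        pfs_days=int(pfs_day),
        event=event,
    )


# ---------------------------------------------------------------------------
# whole-cohort assembly
# ---------------------------------------------------------------------------

def _default_schedule(n_patients: int) -> list[int]:
    """Seven 2-draw patients plus five eligible patients (44 draws total).

    The three relapse courses get the longest follow-up (7 draws each, like
    the index relapse case such serial studies center on), the eligible
    responder 5 and the eligible progressor 4.
    """
    if n_patients == 12:
        return [5, 2, 2, 7, 2, 7, 2, 7, 2, 2, 4, 2]
    return [6 if i % 2 == 0 else 2 for i in range(n_patients)]


def _default_archetypes(n_samples: list[int]) -> list[str]:
    """Eligible (>=3 draws) patients: 1 responder, 3 relapse, 1 progressor,
    mirroring the 1-PR / 4-PD mix among clustering-eligible patients; the
    short-series rest cycle through responder/stable/progressor."""
    eligible_cycle = ["responder", "relapse", "relapse", "relapse", "progressor"]
    short_cycle = ["stable", "responder", "progressor", "stable"]
    out, ei, si = [], 0, 0
    for n in n_samples:
        if n >= 3:
            out.append(eligible_cycle[ei % len(eligible_cycle)])
            ei += 1
        else:
            out.append(short_cycle[si % len(short_cycle)])
            si += 1
    return out


def simulate_patient(
    patient_id: str,
    archetype: str,
    n_samples: int,
    config: SimulationConfig,
    rng,
    used_loci: set,
    popdb: dict,
    normal_evidence: dict,
) -> SimulatedPatient:
    # sampling schedule: baseline plus draws every 2-5 weeks; relapse courses
    # use the upper part of the interval range so the follow-up span always
    # covers the planted 60-120-day pre-progression window
    lo, hi = config.interval_days
    if archetype == "relapse":
        lo = max(lo, 21)
    intervals = rng.integers(lo, hi + 1, size=max(n_samples - 1, 0))
    days = [0] + list(np.cumsum(intervals).astype(int))
    n_clones = int(rng.integers(config.n_clones_range[0], config.n_clones_range[1] + 1))
    if archetype == "relapse":
        n_clones = max(n_clones, 2)
    tree = simulate_clone_tree(n_clones, rng)
    phi0 = float(rng.uniform(*config.founder_phi_range))
    baseline_cm = float(2.0 + 30.0 * phi0 * rng.lognormal(0.0, 1.0))
    phi, meta = simulate_trajectories(
        tree, archetype, days, rng,
        founder_phi_range=config.founder_phi_range,
        relapse_lead_range=config.relapse_lead_range,
        coupling_a=config.coupling_a,
        coupling_b=config.coupling_b,
        phi0=phi0,
        baseline_cm=baseline_cm,
    )

    mutations: list[SimMutation] = []
    # somatic mutations per clone (founder carries driver-like labels)
    for clone in range(n_clones):
        n_mut = int(rng.integers(config.mutations_per_clone_range[0],
                                 config.mutations_per_clone_range[1] + 1))
        for j in range(n_mut):
            key = _random_locus(rng, used_loci)
            if clone == 0 and j < 2:
                gene = DRIVER_GENES[j]  # TP53 / CDKN2A-style founder drivers
            else:
                gene = str(rng.choice(PANEL_GENES))
            logr = 0.0
            if rng.uniform() < config.cn_event_rate:
                logr = float(rng.choice([-0.5, 0.5]))
            mutations.append(
                SimMutation(key=key, gene=gene,
                            effect=str(rng.choice(_EFFECTS, p=_EFFECT_P)),
                            clone=clone, origin="somatic", logr=logr)
            )
    for _ in range(config.n_germline_snps):
        key = _random_locus(rng, used_loci)
        af = float(rng.uniform(0.001, 0.5))
        mutations.append(
            SimMutation(key=key, gene=str(rng.choice(PANEL_GENES)), effect="other",
                        clone=None, origin="common_germline", pop_af=af,
                        wbc_alt_reads=int(rng.poisson(50)))
        )
        popdb[key] = af
    for _ in range(config.n_chip_variants):
        key = _random_locus(rng, used_loci)
        wbc = 3 + int(rng.poisson(10))
        mutations.append(
            SimMutation(key=key, gene=str(rng.choice(PANEL_GENES)),
                        effect="nonsynonymous", clone=None, origin="chip",
                        wbc_alt_reads=wbc)
        )
        normal_evidence[key] = wbc
    for _ in range(config.n_private_germline):
        key = _random_locus(rng, used_loci)
        # a real germline allele the white-blood draw failed to evidence;
        # only the patient-global 20% rule can catch it
        mutations.append(
            SimMutation(key=key, gene=str(rng.choice(PANEL_GENES)), effect="other",
                        clone=None, origin="private_germline", wbc_alt_reads=0)
        )

    # per-draw read counts -> raw caller-style variant lists
    cn = np.array([1 if m.logr < -0.25 else 3 if m.logr > 0.25 else 2
                   for m in mutations])
    chip_vaf = rng.uniform(0.01, 0.05, size=len(mutations))
    samples = []
    for t_idx, day in enumerate(days):
        calls = []
        for i, m in enumerate(mutations):
            if m.origin == "somatic":
                p_true = phi[m.clone, t_idx] * config.multiplicity / cn[i]
            elif m.origin == "chip":
                p_true = chip_vaf[i]
            else:  # germline heterozygous
                p_true = 0.5
            depth = int(rng.poisson(config.depth_mean))
            alt = int(rng.binomial(depth, min(p_true, 1.0)))
            if alt == 0:
                continue  # a caller does not emit unsupported sites
            calls.append(
                VariantCall(
                    chrom=m.key[0], pos=m.key[1], ref=m.key[2], alt=m.key[3],
                    alt_reads=alt, ref_reads=depth - alt, gene=m.gene,
                    effect=m.effect, logr=m.logr if m.origin == "somatic" else 0.0,
                )
            )
        samples.append(SampleRecord(patient_id=patient_id, day=int(day), variants=calls))
    series = PatientSeries(patient_id=patient_id, samples=samples)

    tumor_fraction = phi.max(axis=0)  # the founder carries the whole tumor mass
    clinical = simulate_clinical(
        patient_id, days, tumor_fraction, rng,
        coupling_a=config.coupling_a, coupling_b=config.coupling_b,
        noise_frac=config.diameter_noise_frac, baseline_cm=baseline_cm,
    )
    return SimulatedPatient(
        patient_id=patient_id,
        archetype=archetype,
        days=list(map(int, days)),
        tree_parent=tree,
        phi=phi,
        mutations=mutations,
        series=series,
        clinical=clinical,
        resistance_clone=meta["resistance_clone"],
        true_emergence_day=meta["emergence_day"],
        true_pd_day=meta["pd_day"],
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort with ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    schedule = (
        list(config.samples_per_patient)
        if config.samples_per_patient is not None
        else _default_schedule(config.n_patients)
    )
    if len(schedule) != config.n_patients:
        raise PipelineError("samples_per_patient length must equal n_patients")
    archetypes = (
        list(config.archetypes)
        if config.archetypes is not None
        else _default_archetypes(schedule)
    )
    if len(archetypes) != config.n_patients:
        raise PipelineError("archetypes length must equal n_patients")
    used_loci: set = set()
    popdb: dict = {}
    normal: dict = {}
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        patients.append(
            simulate_patient(pid, archetypes[i], schedule[i], config, rng,
                             used_loci, popdb, normal)
        )
    return SimulatedCohort(config=config, patients=patients, popdb=popdb,
                           normal_evidence=normal)


# ---------------------------------------------------------------------------
# writers (the exact formats pipeline_io reads) and the truth file
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, str]:
    """Write VCFs, sample sheet, clinical + scans tables, population DB,
    normal evidence and the truth JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet_rows = []
    for p in cohort.patients:
        for sample in p.series:
            path = outdir / "vcf" / f"{p.patient_id}_day{sample.day}.vcf"
            write_vcf(sample.variants, path, sample_name=f"{p.patient_id}_d{sample.day}")
            sheet_rows.append(
                {"patient_id": p.patient_id, "day": sample.day, "vcf_path": str(path)}
            )
    pd.DataFrame(sheet_rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)

    clin_rows, scan_rows = [], []
    for p in cohort.patients:
        c = p.clinical
        clin_rows.append(
            {"patient_id": c.patient_id, "stage": c.stage,
             "smoking_index": c.smoking_index, "diameter_sum_cm": c.diameter_sum_cm,
             "best_response": c.best_response, "pfs_days": c.pfs_days,
             "event": int(bool(c.event))}
        )
        diams = dict(c.diameters_per_scan)
        for day, lab in c.response_per_scan:
            scan_rows.append(
                {"patient_id": c.patient_id, "day": day,
                 "diameter_sum_cm": diams[day], "response": lab}
            )
    pd.DataFrame(clin_rows).to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    pd.DataFrame(scan_rows).to_csv(outdir / "scans.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "pop_af": af}
         for k, af in sorted(cohort.popdb.items())]
    ).to_csv(outdir / "popdb.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "wbc_alt_reads": n}
         for k, n in sorted(cohort.normal_evidence.items())]
    ).to_csv(outdir / "normal_evidence.tsv", sep="\t", index=False)

    truth = {}
    for p in cohort.patients:
        truth[p.patient_id] = {
            "archetype": p.archetype,
            "days": p.days,
            "tree": {str(c): par for c, par in p.tree_parent.items()},
            "phi": p.phi.round(6).tolist(),
            "variants": {
                "{}:{}:{}:{}".format(*m.key): {"origin": m.origin, "clone": m.clone}
                for m in p.mutations
            },
            "resistance_clone": p.resistance_clone,
            "true_emergence_day": p.true_emergence_day,
            "true_pd_day": p.true_pd_day,
        }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    cfg = dataclasses.asdict(cohort.config)
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=1, default=list))
    return {
        "sample_sheet": str(outdir / "sample_sheet.tsv"),
        "clinical": str(outdir / "clinical.tsv"),
        "scans": str(outdir / "scans.tsv"),
        "popdb": str(outdir / "popdb.tsv"),
        "normal_evidence": str(outdir / "normal_evidence.tsv"),
        "truth": str(outdir / "truth.json"),
    }


# ---------------------------------------------------------------------------
# a fixed seven-mutation relapse scenario for trend/tree examples
# ---------------------------------------------------------------------------

def relapse_case_study() -> dict:
    """A deterministic relapse-after-response fixture with a founder cluster
    (TP53/CDKN2A), a descending branch (BRAF/ROS1/PDGFRA) and an ascending
    resistance lineage (NTRK3 -> B2M), mirroring a manually curated serial
    series: between days 106 and 149 four mutations ascend while three
    descend, and the late B2M-like cluster nests inside the NTRK3-like one.
    """
    days = [0, 36, 86, 106, 149, 191, 212]
    phi = {
        "founder": [0.60, 0.36, 0.16, 0.14, 0.26, 0.42, 0.56],
        "descending": [0.55, 0.30, 0.12, 0.08, 0.05, 0.02, 0.01],
        "ntrk3": [0.0, 0.0, 0.03, 0.06, 0.20, 0.36, 0.50],
        "b2m": [0.0, 0.0, 0.0, 0.02, 0.10, 0.22, 0.32],
    }
    members = {
        "founder": ["TP53", "CDKN2A"],
        "descending": ["BRAF", "ROS1", "PDGFRA"],
        "ntrk3": ["NTRK3"],
        "b2m": ["B2M"],
    }
    vaf = {}
    for cluster, genes in members.items():
        for g in genes:
            vaf[g] = [p / 2.0 for p in phi[cluster]]
    truth_edges = {
        ("founder", "descending"),
        ("founder", "ntrk3"),
        ("ntrk3", "b2m"),
    }
    return {
        "days": days,
        "cluster_phi": phi,
        "mutation_vaf": vaf,
        "members": members,
        "truth_edges": truth_edges,
        "ascending": ["TP53", "CDKN2A", "NTRK3", "B2M"],
        "descending": ["BRAF", "ROS1", "PDGFRA"],
        "window": (106, 149),
    }
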