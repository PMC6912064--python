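"""Clonal deconvolution of serial ctDNA samples.

Mutations are clustered into clones by a Dirichlet-process binomial mixture
fitted across all of a patient's time points jointly.  For mutation *i* in
cluster *k* at time *t* the alt-read count is modeled as

    alt_it ~ Binomial(depth_it, phi_kt * m_i / c_it)

where phi_kt is the cluster's cellular prevalence (Uniform(0,1) prior),
m_i the mutation multiplicity (fixed at 1) and c_it the total copy number,
discretized from the logR of the locus.  Cluster assignments follow a
Chinese-restaurant-process prior with concentration alpha; the posterior is
explored by Gibbs sampling, with the new-cluster move weighted by the exact
prior-predictive marginal (phi integrated numerically on a grid) and each
cluster's phi refreshed by griddy Gibbs.  The reported partition is the consensus cut
of the posterior co-clustering (similarity) matrix — average linkage, cut at
similarity 0.5 — and phi trajectories are posterior means under the fixed
consensus partition, which makes the report deterministic for a given seed.

For small instances an exact alternative, :func:`enumerate_map_partition`,
scores every set partition (Bell numbers stay tractable up to ~8 mutations)
under the same likelihood and CRP prior.

A variant that is undetected at a time point contributes alt_reads = 0 with
that sample's median depth as the trial count; it is never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .pipeline_io import PatientSeries, PipelineError, VariantKey

_EPS = 1e-12


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def discretize_copy_number(logr: float | None) -> int:
    """Total copy number from a copy-number log2 ratio.

    logR below −0.25 → 1, above 0.25 → 3, in between (boundaries included)
    → 2.  A missing logR means copy number 2.
    """
    if logr is None:
        return 2
    if not math.isfinite(logr):
        raise PipelineError(f"non-finite logR {logr!r}")
    if logr < -0.25:
        return 1
    if logr > 0.25:
        return 3
    return 2


def prevalence_of_vaf(vaf: float, cn_total: int, multiplicity: int = 1) -> float:
    """Point-estimate cellular prevalence from a VAF: min(1, vaf * c / m)."""
    if multiplicity < 1 or multiplicity > cn_total:
        raise PipelineError(
            f"multiplicity {multiplicity} outside 1..{cn_total}"
        )
    return min(1.0, vaf * cn_total / multiplicity)


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class DPConfig:
    """Sampler settings (defaults are the package's own, config-exposed)."""

    alpha: float = 1.0
    n_iterations: int = 5000
    burn_in: int = 1000
    thin: int = 5
    grid_size: int = 201  # phi grid resolution (step 0.005)
    min_timepoints: int = 3
    consensus_cut: float = 0.5


@dataclass
class ClusterResult:
    assignments: dict[VariantKey, int]
    prevalence: dict[int, list[float]]  # cluster id -> phi per day
    ci_lower: dict[int, list[float]]
    ci_upper: dict[int, list[float]]
    days: list[int]
    n_clusters: int
    mcmc_diagnostics: dict = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.prevalence)

    def partition(self) -> set[frozenset[VariantKey]]:
        """Label-free view of the clustering (for partition comparisons)."""
        groups: dict[int, set] = {}
        for key, cid in self.assignments.items():
            groups.setdefault(cid, set()).add(key)
        return {frozenset(g) for g in groups.values()}

    def to_dict(self) -> dict:
        return {
            "days": self.days,
            "n_clusters": self.n_clusters,
            "assignments": {
                f"{c}:{p}:{r}:{a}": cid for (c, p, r, a), cid in self.assignments.items()
            },
            "prevalence": {str(k): v for k, v in self.prevalence.items()},
            "ci_lower": {str(k): v for k, v in self.ci_lower.items()},
            "ci_upper": {str(k): v for k, v in self.ci_upper.items()},
            "mcmc_diagnostics": self.mcmc_diagnostics,
        }


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_counts(
    series: PatientSeries,
) -> tuple[list[VariantKey], np.ndarray, np.ndarray, np.ndarray]:
    """Build the (N, T) alt/depth/rate matrices from a filtered series.

    Rates are m/c per variant per time point.  Undetected variants get
    alt = 0 with the sample's median depth as trials.
    """
    keys = sorted({v.key for s in series for v in s.passing()})
    n, t = len(keys), len(series)
    alt = np.zeros((n, t), dtype=np.int64)
    depth = np.zeros((n, t), dtype=np.int64)
    rate = np.full((n, t), 0.5)
    key_idx = {k: i for i, k in enumerate(keys)}
    for j, sample in enumerate(series):
        depths = [v.total_reads for v in sample.variants]
        median_depth = int(np.median(depths)) if depths else 1000
        seen = np.zeros(n, dtype=bool)
        for v in sample.passing():
            i = key_idx[v.key]
            alt[i, j] = v.alt_reads
            depth[i, j] = v.total_reads
            rate[i, j] = 1.0 / discretize_copy_number(v.logr)
            seen[i] = True
        depth[~seen, j] = median_depth
    return keys, alt, depth, rate


# ---------------------------------------------------------------------------
# likelihood helpers (binomial kernel, coefficients dropped: they are
# constant per mutation and cancel in every comparison made here)
# ---------------------------------------------------------------------------

def _loglik_vs_phis(a_i, d_i, r_i, phis: np.ndarray) -> np.ndarray:
    """Log-likelihood of one mutation against each phi row. phis: (K, T)."""
    p = np.clip(phis * r_i, _EPS, 1.0 - _EPS)
    return (a_i * np.log(p) + (d_i - a_i) * np.log1p(-p)).sum(axis=1)


def _grid_logpost(a, d, r, grid: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior of phi on a grid for one cluster/time.

    a, d, r are member vectors at a single time point; returns (G,).
    """
    p = np.clip(grid[:, None] * r[None, :], _EPS, 1.0 - _EPS)
    return (a[None, :] * np.log(p) + (d - a)[None, :] * np.log1p(-p)).sum(axis=1)


def _grid_sample(rng, logpost: np.ndarray, grid: np.ndarray) -> float:
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return float(rng.choice(grid, p=w))


def _grid_moments(logpost: np.ndarray, grid: np.ndarray) -> tuple[float, float, float]:
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = float((grid * w).sum())
    cum = np.cumsum(w)
    lo = float(grid[int(np.searchsorted(cum, 0.025))])
    hi = float(grid[min(int(np.searchsorted(cum, 0.975)), len(grid) - 1)])
    return mean, lo, hi


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _gibbs(alt, depth, rate, config: DPConfig, rng) -> tuple[np.ndarray, int, dict]:
    """Run the CRP Gibbs sampler; returns (similarity matrix, n_kept, diag).

    Assignments use the conditional likelihood against each occupied
    cluster's current phi and the exact prior-predictive marginal (phi
    integrated out numerically on the grid) for opening a new cluster, which
    keeps split moves well-mixed; each cluster's phi is refreshed by griddy
    Gibbs after every sweep.  The chain starts from singleton clusters.
    """
    n, t = alt.shape
    grid = np.linspace(0.0, 1.0, config.grid_size)
    log_g = math.log(config.grid_size)
    # prior-predictive log marginal of each mutation alone, per time point
    log_marginal = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(t):
            lp = _grid_logpost(alt[i: i + 1, j], depth[i: i + 1, j], rate[i: i + 1, j], grid)
            m = lp.max()
            s += m + math.log(np.exp(lp - m).sum()) - log_g
        log_marginal[i] = s
    z = np.arange(n, dtype=np.int64)  # start from singletons
    next_id = n
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    phis: dict[int, np.ndarray] = {}
    for i in range(n):
        phi_i = np.empty(t)
        for j in range(t):
            lp = _grid_logpost(alt[i: i + 1, j], depth[i: i + 1, j], rate[i: i + 1, j], grid)
            phi_i[j] = _grid_sample(rng, lp, grid)
        phis[i] = phi_i
    sim = np.zeros((n, n))
    n_kept = 0
    k_trace = []
    log_alpha = math.log(config.alpha)
    for it in range(config.n_iterations):
        for i in range(n):
            cid = z[i]
            members[cid].remove(i)
            if not members[cid]:
                del members[cid]
                del phis[cid]
            ids = list(members)
            if ids:
                phi_mat = np.stack([phis[k] for k in ids])
                ll = _loglik_vs_phis(alt[i], depth[i], rate[i], phi_mat)
                sizes = np.log([len(members[k]) for k in ids])
                logw = np.concatenate([sizes + ll, [log_alpha + log_marginal[i]]])
            else:
                logw = np.array([log_alpha + log_marginal[i]])
            w = np.exp(logw - logw.max())
            w /= w.sum()
            choice = int(rng.choice(len(w), p=w))
            if choice < len(ids):
                new_cid = ids[choice]
            else:
                new_cid = next_id
                next_id += 1
                members[new_cid] = []
                phi_i = np.empty(t)
                for j in range(t):
                    lp = _grid_logpost(
                        alt[i: i + 1, j], depth[i: i + 1, j], rate[i: i + 1, j], grid
                    )
                    phi_i[j] = _grid_sample(rng, lp, grid)
                phis[new_cid] = phi_i
            members[new_cid].append(i)
            z[i] = new_cid
        # griddy-Gibbs update of each cluster's phi trajectory
        for k, idx in members.items():
            idx_arr = np.asarray(idx)
            for j in range(t):
                lp = _grid_logpost(alt[idx_arr, j], depth[idx_arr, j], rate[idx_arr, j], grid)
                phis[k][j] = _grid_sample(rng, lp, grid)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            sim += z[:, None] == z[None, :]
            n_kept += 1
            k_trace.append(len(members))
    diag = {
        "n_iterations": config.n_iterations,
        "n_kept": n_kept,
        "mean_n_clusters": float(np.mean(k_trace)) if k_trace else None,
        "max_n_clusters": int(np.max(k_trace)) if k_trace else None,
    }
    return sim / max(n_kept, 1), n_kept, diag


def _consensus(sim: np.ndarray, cut: float) -> np.ndarray:
    """Average-linkage consensus labels from a posterior similarity matrix."""
    n = sim.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    return fcluster(link, t=cut, criterion="distance") - 1


def dp_cluster(
    series: PatientSeries,
    config: DPConfig | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster a patient's passing mutations into clones across time points.

    Requires at least ``config.min_timepoints`` samples.  Deterministic for
    a fixed seed and inputs.
    """
    config = config or DPConfig()
    if len(series) < config.min_timepoints:
        raise PipelineError(
            f"patient {series.patient_id}: {len(series)} time point(s), "
            f"need at least {config.min_timepoints} for clonal deconvolution"
        )
    keys, alt, depth, rate = prepare_counts(series)
    if not keys:
        return ClusterResult(
            assignments={}, prevalence={}, ci_lower={}, ci_upper={},
            days=series.days, n_clusters=0,
        )
    rng = np.random.default_rng(seed)
    sim, n_kept, diag = _gibbs(alt, depth, rate, config, rng)
    labels = _consensus(sim, config.consensus_cut)
    # relabel consensus clusters by descending mean prevalence estimate
    grid = np.linspace(0.0, 1.0, config.grid_size)
    raw: dict[int, dict] = {}
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        phi, lo, hi = [], [], []
        for j in range(alt.shape[1]):
            lp = _grid_logpost(alt[idx, j], depth[idx, j], rate[idx, j], grid)
            m, l, h = _grid_moments(lp, grid)
            phi.append(m)
            lo.append(l)
            hi.append(h)
        raw[int(lab)] = {"idx": idx, "phi": phi, "lo": lo, "hi": hi}
    order = sorted(raw, key=lambda lab: -float(np.mean(raw[lab]["phi"])))
    assignments, prevalence, ci_lo, ci_hi = {}, {}, {}, {}
    for new_id, lab in enumerate(order):
        info = raw[lab]
        for i in info["idx"]:
            assignments[keys[i]] = new_id
        prevalence[new_id] = info["phi"]
        ci_lo[new_id] = info["lo"]
        ci_hi[new_id] = info["hi"]
    return ClusterResult(
        assignments=assignments,
        prevalence=prevalence,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        days=series.days,
        n_clusters=len(order),
        mcmc_diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# exact small-instance alternative
# ---------------------------------------------------------------------------

def _set_partitions(items: Sequence[int]):
    """Yield all set partitions of ``items`` (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_log_score(
    blocks: Sequence[Sequence[int]],
    alt: np.ndarray,
    depth: np.ndarray,
    rate: np.ndarray,
    alpha: float = 1.0,
    grid_size: int = 201,
) -> float:
    """CRP-prior × marginal-likelihood log score of one set partition.

    The per-cluster, per-time marginal integrates phi out numerically over
    the same uniform prior and grid used by the Gibbs sampler.
    """
    grid = np.linspace(0.0, 1.0, grid_size)
    score = 0.0
    for block in blocks:
        score += math.log(alpha) + math.lgamma(len(block))
        idx = np.asarray(block)
        for j in range(alt.shape[1]):
            lp = _grid_logpost(alt[idx, j], depth[idx, j], rate[idx, j], grid)
            m = lp.max()
            score += m + math.log(np.exp(lp - m).mean())
    return score


def enumerate_map_partition(
    alt: np.ndarray,
    depth: np.ndarray,
    rate: np.ndarray,
    alpha: float = 1.0,
    grid_size: int = 201,
) -> set[frozenset[int]]:
    """Exhaustive MAP partition over all set partitions (use only for N ≤ 8)."""
    n = alt.shape[0]
    if n > 10:
        raise PipelineError("exhaustive enumeration is limited to small instances")
    best, best_score = None, -math.inf
    for blocks in _set_partitions(list(range(n))):
        s = partition_log_score(blocks, alt, depth, rate, alpha, grid_size)
        if s > best_score:
            best, best_score = blocks, s
    return {frozenset(b) for b in best}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize_trajectories(result: ClusterResult, series: PatientSeries) -> pd.DataFrame:
    """Tidy (patient, cluster, day, phi, n_mutations) trajectory table."""
    counts: dict[int, int] = {}
    for cid in result.assignments.values():
        counts[cid] = counts.get(cid, 0) + 1
    rows = []
    for cid in result.cluster_ids:
        for day, phi in zip(result.days, result.prevalence[cid]):
            rows.append(
                {
                    "patient_id": series.patient_id,
                    "cluster": cid,
                    "day": day,
                    "phi": phi,
                    "n_mutations": counts.get(cid, 0),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "cluster", "day", "phi", "n_mutations"])
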