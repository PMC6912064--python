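"""Association statistics for ctDNA burden metrics and clinical outcome.

Implements the tests the monitoring analysis reports:

* Mann-Whitney U for burden-vs-response group comparisons — exact p by
  enumeration of the rank distribution (ties handled with midranks) for
  combined n <= 20, tie-corrected normal approximation beyond;
* Spearman rank correlation (burden vs tumor size);
* Kaplan-Meier product-limit curves and the two-group log-rank test for the
  median-split survival comparison (values at the median go to the low
  group).

The Mann-Whitney exact distribution is computed by convolution over the
tied-rank multiset, which is checked in the test suite against a brute-force
enumeration of rank arrangements; KM and log-rank are written out directly
from the product-limit / observed-minus-expected definitions and
cross-checked against an independent survival library.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline_io import ClinicalRecord, PipelineError

EXACT_MAX_N = 20


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_u_distribution(ranks2: np.ndarray, n_a: int) -> dict[int, int]:
    """Counts of rank-sum values (doubled to stay integral with midranks)
    over all ways of choosing n_a of the ranks.  dp[j][s] = #subsets of size
    j summing to s."""
    total = int(ranks2.sum())
    dp = np.zeros((n_a + 1, total + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in ranks2:
        r = int(r)
        for j in range(min(n_a, 1_000_000), 0, -1):
            dp[j, r:] += dp[j - 1, : total + 1 - r]
    return {s: int(c) for s, c in enumerate(dp[n_a]) if c}


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of group_a, p).

    Exact enumeration (with midranks for ties) when the combined sample size
    is at most 20; tie-corrected normal approximation with continuity
    correction otherwise.  ``alternative`` in {two-sided, less, greater}
    refers to group_a's tendency toward smaller/larger values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PipelineError("both groups must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise PipelineError(f"unknown alternative {alternative!r}")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    if n <= EXACT_MAX_N:
        ranks2 = np.round(ranks * 2).astype(np.int64)
        dist = _exact_u_distribution(ranks2, n_a)
        total = sum(dist.values())
        offset = n_a * (n_a + 1)  # doubled min rank sum
        obs2 = int(round(u_a * 2)) + offset
        p_le = sum(c for s, c in dist.items() if s <= obs2) / total
        p_ge = sum(c for s, c in dist.items() if s >= obs2) / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_a, float(p)
    # tie-corrected normal approximation with continuity correction
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma = np.sqrt(n_a * n_b / 12.0 * ((n + 1) - tie_term))
    if sigma == 0:
        return u_a, 1.0
    if alternative == "less":
        z = (u_a - mu + 0.5) / sigma
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        z = (u_a - mu - 0.5) / sigma
        p = sps.norm.sf(z)
    else:
        z = (abs(u_a - mu) - 0.5) / sigma
        p = 2.0 * sps.norm.sf(z)
    return u_a, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise PipelineError("need equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise PipelineError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: step function day -> survival probability."""

    times: list[float]  # distinct event times, ascending
    survival: list[float]  # S(t) just after each event time
    n_at_risk: list[int]

    def at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Censored observations (event False) leave the risk set without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise PipelineError("survival times must be positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    s = 1.0
    out_t, out_s, out_r = [], [], []
    i, n = 0, len(times)
    while i < n:
        t = times[i]
        at_risk = n - i
        d = 0
        while i < n and times[i] == t:
            d += int(events[i])
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(float(t))
            out_s.append(float(s))
            out_r.append(int(at_risk))
    return KMCurve(times=out_t, survival=out_s, n_at_risk=out_r)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p).

    Standard observed-minus-expected statistic over the pooled distinct
    event times, with the hypergeometric variance term.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & ea).sum())
        d2 = int(((tb == t) & eb).sum())
        n_tot = n1 + n2
        d_tot = d1 + d2
        if n_tot == 0 or d_tot == 0:
            continue
        e1 = d_tot * n1 / n_tot
        o_minus_e += d1 - e1
        if n_tot > 1:
            var += (
                d_tot * (n1 / n_tot) * (n2 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def median_split_logrank(
    survival: pd.DataFrame,
    biomarker_col: str = "biomarker",
    time_col: str = "pfs_days",
    event_col: str = "event",
    ties_to_low: bool = True,
) -> dict:
    """Split a cohort at the biomarker median and compare PFS by log-rank.

    Values equal to the median go to the low group (config-exposed).
    Returns group labels, the chi-square and p, and per-group KM curves.
    """
    values = survival[biomarker_col].to_numpy(dtype=float)
    median = float(np.median(values))
    if ties_to_low:
        high = values > median
    else:
        high = values >= median
    if high.all() or (~high).all():
        raise PipelineError("degenerate median split: one group is empty")
    if high.sum() < 2 or (~high).sum() < 2:
        raise PipelineError("need at least 2 patients per side of the split")
    t = survival[time_col].to_numpy(dtype=float)
    e = survival[event_col].to_numpy(dtype=bool)
    chi2, p = logrank_test(t[high], e[high], t[~high], e[~high])
    return {
        "median": median,
        "labels": ["high" if h else "low" for h in high],
        "chi2": chi2,
        "p": p,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "km_high": km_curve(t[high], e[high]),
        "km_low": km_curve(t[~high], e[~high]),
    }


# ---------------------------------------------------------------------------
# cohort-level assembly
# ---------------------------------------------------------------------------

def response_at_day(clinical: ClinicalRecord, day: int) -> str | None:
    """Response label of the scan interval containing ``day``: the first scan
    at or after the draw (the assessment that evaluates that interval)."""
    for scan_day, label in clinical.response_per_scan:
        if scan_day >= day:
            return label
    return None


def cohort_statistics(
    metrics: pd.DataFrame,
    clinical: Sequence[ClinicalRecord],
) -> dict:
    """The analysis' headline associations on one cohort.

    * sample-level MSAF: PR vs SD/PD on-treatment samples (Mann-Whitney);
    * patient-level mean MSAF by best response (Mann-Whitney);
    * Spearman correlation of MSAF with lesion diameter sum;
    * baseline bTMB median-split log-rank on PFS.
    """
    clin_by_pid = {c.patient_id: c for c in clinical}
    out: dict = {}

    # MSAF by response, sample level (on-treatment draws with a labeled scan)
    pr, sdpd = [], []
    for row in metrics.itertuples():
        if row.day == 0:
            continue
        clin = clin_by_pid.get(row.patient_id)
        if clin is None:
            continue
        label = response_at_day(clin, int(row.day))
        if label == "PR":
            pr.append(row.msaf)
        elif label in ("SD", "PD"):
            sdpd.append(row.msaf)
    if pr and sdpd:
        u, p = mann_whitney_u(pr, sdpd)
        out["msaf_response_sample_level"] = {
            "U": u, "p": p, "n_pr": len(pr), "n_sdpd": len(sdpd)
        }

    # patient-level mean MSAF by best response
    mmsaf = metrics.groupby("patient_id")["msaf"].mean()
    pr_m = [mmsaf[c.patient_id] for c in clinical
            if c.best_response == "PR" and c.patient_id in mmsaf]
    sdpd_m = [mmsaf[c.patient_id] for c in clinical
              if c.best_response in ("SD", "PD") and c.patient_id in mmsaf]
    if pr_m and sdpd_m:
        u, p = mann_whitney_u(pr_m, sdpd_m)
        out["mean_msaf_response_patient_level"] = {
            "U": u, "p": p, "n_pr": len(pr_m), "n_sdpd": len(sdpd_m)
        }

    # MSAF vs tumor burden (diameter sum at the matching scan day)
    xs, ys = [], []
    for row in metrics.itertuples():
        clin = clin_by_pid.get(row.patient_id)
        if clin is None:
            continue
        diams = dict(clin.diameters_per_scan)
        if int(row.day) in diams:
            xs.append(row.msaf)
            ys.append(diams[int(row.day)])
        elif row.day == 0 and clin.diameter_sum_cm is not None:
            xs.append(row.msaf)
            ys.append(clin.diameter_sum_cm)
    if len(xs) >= 3 and len(set(xs)) > 1 and len(set(ys)) > 1:
        rho, p = spearman_corr(xs, ys)
        out["msaf_tumor_burden_spearman"] = {"rho": rho, "p": p, "n": len(xs)}

    # baseline bTMB median split on PFS
    baseline = metrics[metrics["day"] == 0].set_index("patient_id")["btmb"]
    rows = []
    for c in clinical:
        if c.pfs_days is not None and c.patient_id in baseline:
            rows.append(
                {"biomarker": baseline[c.patient_id], "pfs_days": c.pfs_days,
                 "event": bool(c.event)}
            )
    if len(rows) >= 4:
        df = pd.DataFrame(rows)
        try:
            split = median_split_logrank(df)
            out["btmb_median_split_logrank"] = {
                "median": split["median"], "chi2": split["chi2"], "p": split["p"],
                "n_high": split["n_high"], "n_low": split["n_low"],
            }
        except PipelineError:
            pass
    return out
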