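"""Clone-tree reconstruction under the crossing rule, and emergence calls.

The crossing rule states that a descendant clone's cellular prevalence can
never exceed its ancestor's at any time point; its corollary, the sum-up
pattern, states that an ancestor's prevalence must cover the sum of its
children's at every time point.  The published analysis applied these rules
by manual inspection of VAF trends; here they are encoded as a deterministic
greedy algorithm so the reconstruction is reproducible:

* clusters are sorted by descending mean prevalence and attached one by one;
* each cluster attaches to the already-placed candidate parent with the
  smallest mean prevalence that satisfies both the crossing rule and the sum
  constraint (children's prevalences summing to at most the parent's, within
  tolerance epsilon);
* among otherwise-valid parents of equal mean prevalence, the parent whose
  own detection day precedes the child's is preferred (late appearance of a
  mutation is evidence it arose within an already-established clone);
* a cluster with no valid parent attaches to the implicit germline root.

Emergence of a clone is called at the earliest sampled day where its
prevalence exceeds a detection floor and a run of consecutive rising
intervals ends at or after that day; the lead time is the number of days by
which emergence precedes the first progressive-disease (PD) scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pipeline_io import PipelineError

log = logging.getLogger("ctdnatrack")

ROOT = "germline"


@dataclass
class CloneTree:
    """Rooted clone tree; every non-root node has exactly one parent."""

    nodes: list
    parent: dict  # node -> parent (ROOT for top-level clones)
    days: list[int]
    trajectories: dict  # node -> list of phi
    detection_day: dict  # node -> first day phi exceeds the detection floor
    edge_valid: dict = field(default_factory=dict)  # node -> bool

    @property
    def edges(self) -> list[tuple]:
        return [(p, c) for c, p in self.parent.items()]

    def children(self, node) -> list:
        return sorted(c for c, p in self.parent.items() if p == node)

    def to_dict(self) -> dict:
        return {
            "days": self.days,
            "nodes": [str(n) for n in self.nodes],
            "edges": [[str(p), str(c)] for p, c in sorted(self.edges, key=str)],
            "detection_day": {str(n): d for n, d in self.detection_day.items()},
            "edge_valid": {str(n): bool(v) for n, v in self.edge_valid.items()},
        }


# ---------------------------------------------------------------------------
# trend sub-clustering
# ---------------------------------------------------------------------------

def split_by_trend(
    trajectories: Mapping[tuple, Sequence[float]],
    days: Sequence[int],
    window: tuple[int, int],
    min_corr: float = 0.0,
) -> list[list[tuple]]:
    """Partition a cluster's mutations by VAF-trend agreement over a window.

    Mutations are first split by the sign of their VAF change across the
    window, then each sign group is split further into connected components
    of the graph whose edges join mutations with pairwise trajectory
    correlation >= ``min_corr``.  Deterministic: members are ordered by
    genomic coordinate (the mapping keys).
    """
    days = list(days)
    d0, d1 = window
    if d0 not in days or d1 not in days:
        raise PipelineError(f"window {window} outside sampled days {days}")
    i0, i1 = days.index(d0), days.index(d1)
    keys = sorted(trajectories)
    asc = [k for k in keys if trajectories[k][i1] - trajectories[k][i0] > 0]
    desc = [k for k in keys if k not in asc]
    groups = []
    for sign_group in (asc, desc):
        if not sign_group:
            continue
        groups.extend(_split_by_correlation(sign_group, trajectories, min_corr))
    return groups


def _split_by_correlation(keys, trajectories, min_corr):
    """Connected components under pairwise Pearson correlation >= min_corr."""
    remaining = list(keys)
    comps = []
    while remaining:
        comp = [remaining.pop(0)]
        frontier = list(comp)
        while frontier:
            cur = frontier.pop()
            still = []
            for other in remaining:
                if _corr(trajectories[cur], trajectories[other]) >= min_corr:
                    comp.append(other)
                    frontier.append(other)
                else:
                    still.append(other)
            remaining = still
        comps.append(sorted(comp))
    return comps


def _corr(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 1.0  # flat trajectories cannot disagree in trend
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# crossing rule and tree assembly
# ---------------------------------------------------------------------------

def check_crossing_rule(
    parent_traj: Sequence[float],
    child_traj: Sequence[float],
    epsilon: float = 0.02,
) -> bool:
    """True iff child phi <= parent phi + epsilon at every time point."""
    if len(parent_traj) != len(child_traj):
        raise PipelineError("trajectories are on different day grids")
    return all(c <= p + epsilon for p, c in zip(parent_traj, child_traj))


def _sum_ok(parent_traj, child_trajs, epsilon) -> bool:
    """Sum constraint: children's phi must sum to <= parent phi + epsilon."""
    total = np.sum(np.asarray(child_trajs, dtype=float), axis=0)
    return bool(np.all(total <= np.asarray(parent_traj) + epsilon))


def _first_detection(days, traj, threshold) -> int | None:
    for day, phi in zip(days, traj):
        if phi > threshold:
            return day
    return None


def build_tree(
    trajectories: Mapping[object, Sequence[float]],
    days: Sequence[int],
    epsilon: float = 0.02,
    detection_threshold: float = 0.01,
) -> CloneTree:
    """Assemble the clone tree greedily under crossing + sum constraints.

    ``trajectories`` maps cluster ids to prevalence trajectories on a common
    day grid.  The implicit germline root has prevalence 1 at every time
    point.  Construction is deterministic; a post-hoc validator marks each
    edge's constraint status (a cluster that fits nowhere falls back to the
    root with its edge marked invalid if the root's sum constraint breaks).
    """
    if not trajectories:
        raise PipelineError("no clusters to build a tree from")
    days = list(days)
    t = len(days)
    for cid, traj in trajectories.items():
        if len(traj) != t:
            raise PipelineError(f"cluster {cid}: trajectory not on the day grid")
    root_traj = [1.0] * t
    order = sorted(trajectories, key=lambda c: (-float(np.mean(trajectories[c])), str(c)))
    parent: dict = {}
    detection = {
        cid: _first_detection(days, trajectories[cid], detection_threshold)
        for cid in order
    }

    def traj_of(node):
        return root_traj if node == ROOT else list(trajectories[node])

    placed = [ROOT]
    for cid in order:
        candidates = []
        for cand in placed:
            if not check_crossing_rule(traj_of(cand), trajectories[cid], epsilon):
                continue
            sibling_trajs = [trajectories[c] for c, p in parent.items() if p == cand]
            if not _sum_ok(traj_of(cand), sibling_trajs + [trajectories[cid]], epsilon):
                continue
            candidates.append(cand)
        if candidates:
            det_c = detection[cid]

            def rank(cand):
                det_p = None if cand == ROOT else detection[cand]
                precedes = (
                    det_p is not None and det_c is not None and det_p < det_c
                ) or cand == ROOT
                return (
                    float(np.mean(traj_of(cand))),
                    0 if precedes else 1,
                    det_p if det_p is not None else -1,
                    str(cand),
                )

            best = min(candidates, key=rank)
            parent[cid] = best
        else:
            parent[cid] = ROOT  # fallback; validator will flag it
        placed.append(cid)

    tree = CloneTree(
        nodes=list(order),
        parent=parent,
        days=days,
        trajectories={cid: list(trajectories[cid]) for cid in order},
        detection_day=detection,
    )
    validate_tree(tree, epsilon)
    return tree


def validate_tree(tree: CloneTree, epsilon: float = 0.02) -> bool:
    """Check crossing rule on every edge and sum constraint at every node.

    Fills ``tree.edge_valid`` per child and returns the overall verdict.
    """
    ok = True
    root_traj = [1.0] * len(tree.days)

    def traj_of(node):
        return root_traj if node == ROOT else tree.trajectories[node]

    for child, par in tree.parent.items():
        valid = check_crossing_rule(traj_of(par), traj_of(child), epsilon)
        tree.edge_valid[child] = valid
        ok = ok and valid
    for node in [ROOT] + tree.nodes:
        kids = tree.children(node)
        if kids and not _sum_ok(traj_of(node), [traj_of(k) for k in kids], epsilon):
            for k in kids:
                tree.edge_valid[k] = False
            ok = False
    return ok


# ---------------------------------------------------------------------------
# emergence and lead time
# ---------------------------------------------------------------------------

def detect_emergence(
    days: Sequence[int],
    trajectory: Sequence[float],
    phi_min: float = 0.01,
    rise_points: int = 2,
) -> int | None:
    """Earliest sampled day where the clone is above the detection floor and
    a run of ``rise_points`` consecutive rising intervals ends at or after
    that day; None if the clone never emerges."""
    days = list(days)
    phi = list(trajectory)
    rising = [phi[i + 1] > phi[i] for i in range(len(phi) - 1)]
    run_end_days = [
        days[i + rise_points]
        for i in range(len(rising) - rise_points + 1)
        if all(rising[i: i + rise_points])
    ]
    if not run_end_days:
        return None
    for day, value in zip(days, phi):
        if value > phi_min and any(end >= day for end in run_end_days):
            return day
    return None


def compute_lead_time(emergence_day: int | None, pd_day: int | None) -> int | None:
    """Days by which molecular emergence precedes radiological progression.

    Negative when emergence follows the PD scan; None when either day is
    missing (e.g. no PD scan was recorded).
    """
    if emergence_day is None:
        return None
    if pd_day is None:
        log.info("no PD scan recorded; lead time undefined")
        return None
    return pd_day - emergence_day


# ---------------------------------------------------------------------------
# lesion association (sign agreement only; no causal claim)
# ---------------------------------------------------------------------------

def lesion_association(
    cluster_trajectories: Mapping[object, Sequence[float]],
    days: Sequence[int],
    scan_days: Sequence[int],
    diameters: Sequence[float],
) -> list[dict]:
    """Sign agreement between per-cluster prevalence changes and lesion
    diameter-sum changes over matched intervals.

    For each cluster, intervals between consecutive scans are matched to the
    nearest sampled days and the fraction of intervals where the prevalence
    change and the diameter change share a sign is reported.
    """
    days = list(days)
    rows = []
    for cid, traj in sorted(cluster_trajectories.items(), key=lambda kv: str(kv[0])):
        agree = total = 0
        for (s0, d0), (s1, d1) in zip(
            zip(scan_days, diameters), zip(scan_days[1:], diameters[1:])
        ):
            i0 = int(np.argmin([abs(d - s0) for d in days]))
            i1 = int(np.argmin([abs(d - s1) for d in days]))
            if i0 == i1:
                continue
            dphi = traj[i1] - traj[i0]
            ddiam = d1 - d0
            if dphi == 0 or ddiam == 0:
                continue
            total += 1
            agree += int((dphi > 0) == (ddiam > 0))
        rows.append(
            {
                "cluster": cid,
                "n_intervals": total,
                "sign_agreement": agree / total if total else None,
            }
        )
    return rows
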