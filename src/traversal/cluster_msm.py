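"""Partitioning Around Medoids over Hamming distances and Markov state models.

PAM is used (rather than k-means) so every cluster center is an actual
sampled conformation: averaging contact patterns or coordinates can
produce physically impossible structures.  The classic BUILD phase greedily
seeds medoids to minimize total cost, then the SWAP phase repeatedly
applies the best cost-reducing (medoid, non-medoid) exchange until no swap
improves - all tie-breaks are by lowest index, so results are
bit-reproducible.

Cluster assignments of time-ordered trajectory snapshots become state
sequences, and pooled consecutive-pair counts (never across run
boundaries) define the Markov state model used by the entropy measure.
Self-transitions are retained: confinement shows up as a
high-self-transition, low-weight row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .contactspace import ContactMap, DistanceMatrix, hamming
from .errors import DegenerateInputError, IncomparableStructuresError, ValidationError


@dataclass(frozen=True)
class Clustering:
    """PAM solution: medoid indices (sorted), per-point assignment, cost."""

    k: int
    medoids: tuple[int, ...]
    assignment: np.ndarray
    cost: float


@dataclass(frozen=True)
class StateSequence:
    """Ordered cluster ids of one run's snapshots, in move order."""

    run_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int64)
        states.setflags(write=False)
        object.__setattr__(self, "states", states)


@dataclass(frozen=True)
class MarkovStateModel:
    """Transition bookkeeping over k states.

    ``counts[i, j]`` pools observed i->j transitions over the supplied
    sequences; ``transition`` holds row-conditional probabilities (NaN rows
    where a state emits nothing); ``occupancy`` is the share of transition
    *sources* in each state.
    """

    k: int
    counts: np.ndarray
    transition: np.ndarray
    occupancy: np.ndarray


def _assign(D: np.ndarray, medoids: Sequence[int]) -> tuple[np.ndarray, float]:
    med = np.asarray(sorted(medoids), dtype=int)
    sub = D[:, med]
    assignment = np.argmin(sub, axis=1)  # first minimum -> lowest medoid index
    cost = float(sub[np.arange(D.shape[0]), assignment].sum())
    return assignment, cost


def pam(dm: DistanceMatrix | np.ndarray, k: int) -> Clustering:
    """Deterministic PAM (BUILD + best-improvement SWAP)."""
    D = dm.d.astype(float) if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}]")
    # BUILD: start from the point minimizing total distance, then greedily
    # add the candidate giving the largest cost reduction.
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        cand_cost = np.minimum(nearest[:, None], D).sum(axis=0)
        cand_cost[medoids] = np.inf
        j = int(np.argmin(cand_cost))
        medoids.append(j)
        nearest = np.minimum(nearest, D[:, j])
    # SWAP: accept the best strictly improving exchange until none exists.
    medoids = sorted(medoids)
    _, cost = _assign(D, medoids)
    while True:
        best = None  # (new_cost, medoid_out, candidate_in)
        med_set = set(medoids)
        for mi in medoids:
            rest = [m for m in medoids if m != mi]
            if rest:
                rest_min = D[:, rest].min(axis=1)
            else:
                rest_min = np.full(n, np.inf)
            cand_costs = np.minimum(rest_min[:, None], D).sum(axis=0)
            for h in range(n):
                if h in med_set:
                    continue
                c = cand_costs[h]
                if c < cost - 1e-12 and (best is None or c < best[0] - 1e-12):
                    best = (c, mi, h)
        if best is None:
            break
        _, mi, h = best
        medoids = sorted(m for m in medoids if m != mi) + [h]
        medoids.sort()
        _, cost = _assign(D, medoids)
    assignment, cost = _assign(D, medoids)
    return Clustering(k=k, medoids=tuple(medoids), assignment=assignment, cost=cost)


def choose_k(
    dm: DistanceMatrix | np.ndarray,
    k_min: int = 5,
    k_max: int = 25,
) -> tuple[int, pd.DataFrame]:
    """Pick k by maximal mean silhouette width over PAM solutions.

    Returns the chosen k and the full (k, silhouette, cost) table for
    inspection.  The search range is clipped to [2, n-1].
    """
    D = dm.d.astype(float) if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = D.shape[0]
    if not np.any(D > 0):
        raise DegenerateInputError("all-zero distance matrix")
    k_min = max(2, k_min)
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        raise ValidationError(f"empty k range [{k_min}, {k_max}] for n={n}")
    rows = []
    for k in range(k_min, k_max + 1):
        clustering = pam(D, k)
        if len(set(clustering.assignment.tolist())) < 2:
            sil = -1.0
        else:
            sil = float(
                silhouette_score(D, clustering.assignment, metric="precomputed")
            )
        rows.append({"k": k, "silhouette": sil, "cost": clustering.cost})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["silhouette"].idxmax(), "k"])
    return best_k, table


def assign_states(
    traj_maps: Sequence[ContactMap],
    clustering: Clustering,
    reference_maps: Sequence[ContactMap],
    run_id: str = "run",
) -> StateSequence:
    """Assign each trajectory snapshot to its nearest medoid's cluster.

    Ties go to the lowest medoid index.  The reference maps are the set the
    clustering was fit on; medoid indices point into it.
    """
    medoid_maps = [reference_maps[i] for i in clustering.medoids]
    states = np.empty(len(traj_maps), dtype=np.int64)
    for t, m in enumerate(traj_maps):
        dists = [hamming(m, mm) for mm in medoid_maps]
        states[t] = int(np.argmin(dists))
    return StateSequence(run_id=run_id, states=states)


def build_msm(seqs: Sequence[StateSequence | np.ndarray], k: int) -> MarkovStateModel:
    """Pool within-run consecutive-pair counts into a k-state MSM.

    No transitions are counted across run boundaries.  Rows without
    outgoing counts get NaN conditional probabilities and zero occupancy.
    """
    C = np.zeros((k, k), dtype=np.int64)
    for seq in seqs:
        states = seq.states if isinstance(seq, StateSequence) else np.asarray(seq)
        if states.size and states.max() >= k:
            raise ValidationError("state id >= k")
        if states.size >= 2:
            np.add.at(C, (states[:-1], states[1:]), 1)
    rowsums = C.sum(axis=1)
    total = rowsums.sum()
    P = np.full((k, k), np.nan)
    nz = rowsums > 0
    P[nz] = C[nz] / rowsums[nz, None]
    pi = rowsums / total if total > 0 else np.zeros(k)
    return MarkovStateModel(k=k, counts=C, transition=P, occupancy=pi)
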