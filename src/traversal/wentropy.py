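"""Structurally weighted Shannon entropy of a Markov state model.

Each transition's uncertainty contribution is weighted by the structural
difference it introduces - the Hamming distance between the medoid contact
maps of its source and destination clusters, rescaled so the largest pair
has weight 1 (self-transitions have weight 0).  The raw entropy

    H_raw = sum_i pi_i sum_j w_ij * (-P_ij ln P_ij)

is the occupancy-averaged, pairwise-weighted row entropy (a Guiasu-style
weighted entropy); it is normalized by the theoretical maximum H_max
attainable for the given number of clusters and set of weights, so
H_norm = H_raw / H_max always lies in [0, 1].  H_norm is 1 only for a
maximally uncertain walk over structurally distinct states and 0 for a
trajectory following deterministic paths ("going round in circles") or
confined to one region (high self-transition probability, zero-weight).

The maximizer of a weighted row entropy sum_j w_j (-p_j ln p_j) on the
probability simplex satisfies p_j = exp(-1 - lambda / w_j) on
positive-weight entries; surplus mass parks on zero-weight entries (where
it contributes nothing), and lambda is found by 1-D root finding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cluster_msm import Clustering, MarkovStateModel
from .contactspace import DistanceMatrix
from .errors import DegenerateInputError, ValidationError

#: probabilities below this are treated as exact zeros
_P_GUARD = 1e-12


@dataclass(frozen=True)
class EntropyResult:
    """Weighted entropy (nats), its theoretical maximum, and the [0, 1] score."""

    H_raw: float
    H_max: float
    H_norm: float


def medoid_weights(clustering: Clustering, dm: DistanceMatrix) -> np.ndarray:
    """Weight matrix from pairwise medoid Hamming distances, max-rescaled to 1.

    The diagonal is zero by the metric identity.  k = 1 or identical
    medoid structures give an all-zero (degenerate) weight set, which is
    an error.
    """
    med = np.asarray(clustering.medoids, dtype=int)
    W = dm.d[np.ix_(med, med)].astype(float)
    mx = W.max()
    if mx <= 0:
        raise DegenerateInputError(
            "degenerate weights: medoid contact maps are identical (or k = 1)"
        )
    return W / mx


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be finite and nonnegative")
    return w


def _row_max(wrow: np.ndarray) -> float:
    """Maximum of sum_j w_j (-p_j ln p_j) over the probability simplex.

    Zero-weight entries act as a parking slot for surplus mass.  With m
    equal weights w and no slack this is w * ln m; with a single positive
    weight and slack available the optimum parks 1 - 1/e and returns w/e.
    """
    wrow = np.asarray(wrow, dtype=float)
    pos = wrow[wrow > 0]
    if pos.size == 0:
        return 0.0
    has_slack = np.any(wrow <= 0)

    def mass(lam: float) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(-1.0 - lam / pos).sum())

    if has_slack and mass(0.0) <= 1.0:
        lam = 0.0
    else:
        lo, hi = 0.0, 1.0
        if mass(0.0) > 1.0:
            while mass(hi) > 1.0:
                hi *= 2.0
        else:
            # no slack and the lambda = 0 mass falls short: lambda < 0
            lo = -1.0
            while mass(lo) < 1.0:
                lo *= 2.0
            hi = 0.0
        lam = brentq(lambda t: mass(t) - 1.0, lo, hi, xtol=1e-14, rtol=8.9e-16)
    p = np.exp(-1.0 - lam / pos)
    # -ln p = 1 + lam/w, hence each term is p * (w + lam)
    return float((p * (pos + lam)).sum())


def max_weighted_entropy(w: np.ndarray) -> float:
    """Theoretical maximum weighted entropy for a weight row or matrix.

    For a matrix the maximum is taken over rows (occupancy is free at the
    maximum and the objective is linear in it, so the most entropic
    achievable row wins).  All-zero weights are an error.
    """
    w = _check_weights(w)
    if not np.any(w > 0):
        raise DegenerateInputError("all weights are zero")
    if w.ndim == 1:
        return _row_max(w)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square (or a 1-D row)")
    return max(_row_max(w[i]) for i in range(w.shape[0]))


def weighted_entropy(msm: MarkovStateModel, w: np.ndarray) -> EntropyResult:
    """Occupancy-averaged weighted transition entropy, normalized to [0, 1]."""
    w = _check_weights(w)
    if w.shape != (msm.k, msm.k):
        raise ValidationError(f"weight matrix must be ({msm.k}, {msm.k})")
    H_raw = 0.0
    for i in range(msm.k):
        pi_i = msm.occupancy[i]
        if pi_i <= 0:
            continue
        row = msm.transition[i]
        p = np.where(row > _P_GUARD, row, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, -p * np.log(p), 0.0)
        H_raw += pi_i * float((w[i] * plogp).sum())
    if not np.any(w > 0):
        return EntropyResult(H_raw=0.0, H_max=0.0, H_norm=0.0)
    H_max = max_weighted_entropy(w)
    H_norm = H_raw / H_max if H_max > 0 else 0.0
    return EntropyResult(H_raw=float(H_raw), H_max=float(H_max), H_norm=float(H_norm))
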