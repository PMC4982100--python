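"""Classical (Torgerson) multidimensional scaling of dissimilarity matrices.

The doubly centered matrix B = -1/2 J D^2 J is eigendecomposed and the
top-m eigenvectors, scaled by the square roots of their (positive)
eigenvalues, give principal coordinates.  Hamming matrices over contact
maps need not be Euclidean-embeddable, so negative eigenvalues can occur;
they are excluded from the variance denominator and the most negative one
is reported as a diagnostic.  The captured-variance fraction is reported,
never assumed large: for contact-map data low-dimensional projections are
indicative only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contactspace import DistanceMatrix
from .errors import ValidationError
from .trajio import StructureSet, parse_source_label

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class Embedding:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``coords`` columns are ordered by descending eigenvalue; axes whose
    eigenvalue is nonpositive are zero columns.  ``variance_fraction`` is
    the share of the positive spectrum captured by the retained axes.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: float
    min_eigenvalue: float


def _as_matrix(dm) -> np.ndarray:
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("dissimilarity matrix must be symmetric")
    return d


def classical_mds(dm, m: int = 2) -> Embedding:
    """Embed a metric dissimilarity matrix into m principal coordinates.

    Eigenvector signs are fixed by making each retained axis's
    largest-magnitude entry positive, so repeated runs are reproducible.
    """
    D = _as_matrix(dm)
    n = D.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 points")
    if not (1 <= m <= n - 1):
        raise ValidationError(f"m must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    scale = np.max(np.abs(evals)) if np.max(np.abs(evals)) > 0 else 1.0
    tol = _EIG_TOL * scale
    coords = np.zeros((n, m))
    for a in range(m):
        lam = evals[a]
        if lam > tol:
            v = evecs[:, a]
            pivot = np.argmax(np.abs(v))
            if v[pivot] < 0:
                v = -v
            coords[:, a] = v * np.sqrt(lam)
    positive = evals[evals > tol]
    total = positive.sum()
    retained = evals[:m][evals[:m] > tol].sum()
    variance_fraction = float(retained / total) if total > 0 else 0.0
    return Embedding(
        coords=coords,
        eigenvalues=evals,
        variance_fraction=variance_fraction,
        min_eigenvalue=float(evals.min()),
    )


def embed_trajectories(
    sset: StructureSet,
    dm: DistanceMatrix,
    m: int = 2,
    label_filter=None,
) -> tuple[pd.DataFrame, Embedding]:
    """Plot-ready principal-coordinate table for trajectories on a background.

    Rows carry the source label split into kind / run_id / move_index so
    trajectory points can be ordered by move index (colour deepening
    toward the end of a run).  ``label_filter`` (label -> bool) subsets the
    pool before embedding - e.g. to drop stage-1 points by label.  At most
    one native structure is allowed.
    """
    if dm.n != len(sset):
        raise ValidationError("distance matrix does not match structure set")
    labels = list(sset.labels)
    keep = [
        i for i, lab in enumerate(labels) if label_filter is None or label_filter(lab)
    ]
    if not keep:
        raise ValidationError("label filter removed every structure")
    sub = dm.subset(keep)
    if sum(1 for i in keep if labels[i] == "native") > 1:
        raise ValidationError("native structure present more than once")
    emb = classical_mds(sub, m)
    rows = []
    for row, i in enumerate(keep):
        parsed = parse_source_label(labels[i])
        rec = {
            "label": labels[i],
            "kind": parsed["kind"],
            "run_id": parsed["run_id"],
            "move_index": parsed["move_index"],
        }
        for a in range(m):
            rec[f"coord_{a + 1}"] = emb.coords[row, a]
        rec["variance_fraction"] = emb.variance_fraction
        rows.append(rec)
    table = pd.DataFrame(rows)
    return table, emb
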