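"""Binary contact maps and Hamming dissimilarity between conformations.

A contact map marks every residue pair (i < j) whose C-alpha atoms lie
within a distance cutoff (8 A by default, ``<=`` at the boundary).  The
Hamming distance between two maps of the same chain counts pairs in
different contact states; it is a metric, and distances are kept as exact
integers throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, IncomparableStructuresError, ValidationError
from .trajio import CAStructure, StructureSet

DEFAULT_CUTOFF_A = 8.0


@dataclass(frozen=True)
class ContactMap:
    """Binary residue-pair contact pattern of one structure.

    ``bits`` is a condensed boolean vector over pairs i < j in the same
    order as :func:`scipy.spatial.distance.pdist`.
    """

    length: int
    bits: np.ndarray
    cutoff_A: float = DEFAULT_CUTOFF_A

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        expected = self.length * (self.length - 1) // 2
        if bits.shape != (expected,):
            raise ValidationError(
                f"bits must have {expected} entries for length {self.length}"
            )
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    @property
    def n_contacts(self) -> int:
        return int(np.count_nonzero(self.bits))


def pair_separations(length: int) -> np.ndarray:
    """Sequence separation |i - j| of each condensed pair, in pdist order."""
    i, j = np.triu_indices(length, k=1)
    return j - i


def contact_map(s: CAStructure, cutoff_A: float = DEFAULT_CUTOFF_A) -> ContactMap:
    """Compute the binary contact map of a CA structure.

    A pair is a contact iff its Euclidean CA distance is <= ``cutoff_A``;
    all pairs are considered (no minimum sequence separation).
    """
    if not cutoff_A > 0:
        raise ValidationError("cutoff_A must be positive")
    bits = pdist(s.coords) <= cutoff_A
    return ContactMap(length=s.length, bits=bits, cutoff_A=cutoff_A)


def _check_comparable(a: ContactMap, b: ContactMap) -> None:
    if a.length != b.length:
        raise IncomparableStructuresError(
            f"length mismatch: {a.length} vs {b.length}"
        )
    if a.cutoff_A != b.cutoff_A:
        raise IncomparableStructuresError(
            f"cutoff mismatch: {a.cutoff_A} vs {b.cutoff_A}"
        )


def hamming(a: ContactMap, b: ContactMap) -> int:
    """Number of residue pairs whose contact state differs between two maps."""
    _check_comparable(a, b)
    return int(np.count_nonzero(a.bits ^ b.bits))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric integer Hamming-distance matrix with aligned source labels."""

    d: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.array_equal(d, d.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValidationError("distances must be nonnegative")
        d = d.astype(np.int64, copy=True)
        d.setflags(write=False)
        object.__setattr__(self, "d", d)
        if len(self.labels) != d.shape[0]:
            raise ValidationError("labels length mismatch")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def subset(self, indices: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(indices, dtype=int)
        return DistanceMatrix(
            self.d[np.ix_(idx, idx)], tuple(self.labels[i] for i in idx)
        )


def maps_distance_matrix(
    maps: Sequence[ContactMap], labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise Hamming distances between precomputed contact maps."""
    if not maps:
        raise DegenerateInputError("empty map collection")
    first = maps[0]
    for m in maps[1:]:
        _check_comparable(first, m)
    X = np.stack([m.bits for m in maps]).astype(np.int64)
    # xor popcount via inner products: |a ^ b| = |a| + |b| - 2 a.b
    G = X @ X.T
    r = np.diag(G)
    D = r[:, None] + r[None, :] - 2 * G
    if labels is None:
        labels = [DEFAULT_LABEL] * len(maps)
    return DistanceMatrix(D, tuple(labels))


DEFAULT_LABEL = "decoy"


def pairwise_distance_matrix(
    sset: StructureSet, cutoff_A: float = DEFAULT_CUTOFF_A
) -> DistanceMatrix:
    """Contact maps then all-pairs Hamming distances for a structure set."""
    if len(sset) == 0:
        raise DegenerateInputError("empty structure set")
    maps = [contact_map(s, cutoff_A) for s in sset.structures]
    return maps_distance_matrix(maps, sset.labels)
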