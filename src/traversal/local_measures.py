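"""Per-residue sampling measures.

Two complementary views of how a fragment-assembly search treats each
residue of the chain:

* acceptance counts - how often an accepted move *changed* the backbone
  torsion triplet (phi, psi, omega) of the residue, per search stage;
* torsion-space coverage - what fraction of the unique triplets the
  fragment library makes available at that position was actually used at
  least once.

Triplet identity is defined after rounding to ``TORSION_DECIMALS`` (the
precision of the fragment text format); chain-terminal components that are
undefined (phi at residue 0, psi at residue L-1) are canonicalized to the
NA sentinel on both the "used" and the "available" side so they never
spoil the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trajio import TORSION_DECIMALS, FragmentLibrary, TrajectoryLog, Triplet

logger = logging.getLogger(__name__)

CUMULATIVE = "all"

Key = tuple[float | None, float | None, float | None]


def canonical_triplet(trip: Sequence[float | None], resi: int, length: int) -> Key:
    """Round a triplet for identity comparison, masking undefined termini."""
    phi, psi, omega = trip
    if resi == 0:
        phi = None
    if resi == length - 1:
        psi = None
    r = lambda a: None if a is None else round(float(a), TORSION_DECIMALS)
    return (r(phi), r(psi), r(omega))


@dataclass
class ResidueProfile:
    """Per-residue, per-stage sampling profile.

    ``counts[stage]`` holds accepted-change counts; coverage fields are
    present when the profile was produced by :func:`torsion_coverage`.
    Coverage is NaN at residues with no available triplets.
    """

    length: int
    stages: tuple[str, ...]
    counts: dict[str, np.ndarray] | None = None
    available: np.ndarray | None = None
    used_sets: dict[str, list[set]] | None = None
    coverage: dict[str, np.ndarray] | None = None
    mismatches: int = 0

    def relative_frequency(self, stage: str) -> np.ndarray:
        """Counts normalized by the stage total (NaN when the total is 0)."""
        if self.counts is None:
            raise ValidationError("profile has no counts")
        c = self.counts[stage].astype(float)
        tot = c.sum()
        return c / tot if tot > 0 else np.full_like(c, np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (residue, stage, count, rel_freq, available,
        used, coverage) suitable for the TSV the CLI writes."""
        rows = []
        stages = list(self.stages) + [CUMULATIVE]
        for stage in stages:
            have_counts = self.counts is not None and stage in self.counts
            have_cov = self.coverage is not None and stage in self.coverage
            if not have_counts and not have_cov:
                continue
            rel = self.relative_frequency(stage) if have_counts else None
            for r in range(self.length):
                rows.append(
                    {
                        "residue": r,
                        "stage": stage,
                        "count": int(self.counts[stage][r]) if have_counts else np.nan,
                        "rel_freq": rel[r] if rel is not None else np.nan,
                        "available": int(self.available[r])
                        if self.available is not None
                        else np.nan,
                        "used": len(self.used_sets[stage][r])
                        if self.used_sets is not None and stage in self.used_sets
                        else np.nan,
                        "coverage": self.coverage[stage][r] if have_cov else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def acceptance_counts(
    log: TrajectoryLog,
    mode: Literal["changed", "window"] = "changed",
) -> ResidueProfile:
    """Count accepted torsion-triplet changes per residue and stage.

    In the default ``"changed"`` mode a residue is incremented only when
    the triplet stored by the event differs from that residue's previous
    recorded triplet (a residue never seen before counts as changed).  The
    ``"window"`` mode counts every residue listed by the event regardless,
    which is the alternative reading of per-move counting.
    """
    L = log.length
    stages = log.stages
    counts = {s: np.zeros(L, dtype=np.int64) for s in stages}
    cumulative = np.zeros(L, dtype=np.int64)
    prev: dict[int, Key] = {}
    for ev in log.events:
        for resi, trip in ev.torsions:
            key = canonical_triplet(trip, resi, L)
            changed = mode == "window" or prev.get(resi, _UNSET) != key
            prev[resi] = key
            if changed:
                counts[ev.stage][resi] += 1
                cumulative[resi] += 1
    counts[CUMULATIVE] = cumulative
    return ResidueProfile(length=L, stages=stages, counts=counts)


_UNSET = object()


def available_triplets(
    lib: FragmentLibrary, length: int
) -> tuple[np.ndarray, list[set]]:
    """Unique triplets available per residue from every covering insertion.

    Residue ``r`` collects the triplet at offset ``p`` of every fragment in
    window ``w`` with ``w + p == r``, deduplicated under triplet identity.
    Returns (per-residue counts, per-residue key sets).
    """
    F = lib.fragment_length
    if lib.n_windows + F - 1 > length:
        raise ValidationError(
            f"library windows ({lib.n_windows}) exceed chain of length {length}"
        )
    sets: list[set] = [set() for _ in range(length)]
    for w, frags in enumerate(lib.windows):
        for frag in frags:
            for p in range(F):
                r = w + p
                sets[r].add(canonical_triplet(frag[p], r, length))
    return np.array([len(s) for s in sets], dtype=np.int64), sets


def torsion_coverage(log: TrajectoryLog, lib: FragmentLibrary) -> ResidueProfile:
    """Fraction of the available triplets used at least once, per residue.

    Coverage is reported per stage and cumulatively; residues with no
    available triplet get NaN.  Observed triplets matching no library
    triplet are tallied in ``mismatches`` (with a logged warning) and
    excluded from the numerator.
    """
    L = log.length
    avail_counts, avail_sets = available_triplets(lib, L)
    stages = log.stages
    used: dict[str, list[set]] = {
        s: [set() for _ in range(L)] for s in (*stages, CUMULATIVE)
    }
    mismatches = 0
    for ev in log.events:
        for resi, trip in ev.torsions:
            key = canonical_triplet(trip, resi, L)
            if key in avail_sets[resi]:
                used[ev.stage][resi].add(key)
                used[CUMULATIVE][resi].add(key)
            else:
                mismatches += 1
    if mismatches:
        logger.warning(
            "%d observed triplet(s) matched no library triplet", mismatches
        )
    coverage = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for stage, sets in used.items():
            u = np.array([len(s) for s in sets], dtype=float)
            coverage[stage] = np.where(
                avail_counts > 0, u / avail_counts, np.nan
            )
    return ResidueProfile(
        length=L,
        stages=stages,
        available=avail_counts,
        used_sets=used,
        coverage=coverage,
        mismatches=mismatches,
    )


def pool_coverage(profiles: Sequence[ResidueProfile]) -> ResidueProfile:
    """Union the used-triplet sets of several runs (same target/library).

    Mirrors comparing a set of short runs against one long run: pooled
    coverage is the coverage of the union of everything any run used, so
    it can never fall below any individual run at any residue.
    """
    if not profiles:
        raise ValidationError("no profiles to pool")
    first = profiles[0]
    if first.used_sets is None or first.available is None:
        raise ValidationError("profiles must carry coverage information")
    L = first.length
    stages: list[str] = []
    for p in profiles:
        if p.length != L or not np.array_equal(p.available, first.available):
            raise ValidationError("profiles disagree on chain/library")
        for s in p.stages:
            if s not in stages:
                stages.append(s)
    used: dict[str, list[set]] = {
        s: [set() for _ in range(L)] for s in (*stages, CUMULATIVE)
    }
    for p in profiles:
        for stage, sets in p.used_sets.items():
            for r in range(L):
                used.setdefault(stage, [set() for _ in range(L)])
                used[stage][r] |= sets[r]
    avail = first.available
    coverage = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for stage, sets in used.items():
            u = np.array([len(s) for s in sets], dtype=float)
            coverage[stage] = np.where(avail > 0, u / avail, np.nan)
    return ResidueProfile(
        length=L,
        stages=tuple(stages),
        available=avail,
        used_sets=used,
        coverage=coverage,
        mismatches=sum(p.mismatches for p in profiles),
    )


def aggregate_profiles(
    profiles: Sequence[ResidueProfile], column: str = "coverage"
) -> pd.DataFrame:
    """Median and IQR of a profile column across replicate runs.

    Reporting utility for plotting per-stage medians with interquartile
    bands across replicates.
    """
    frames = []
    for i, p in enumerate(profiles):
        f = p.to_frame()
        f["replicate"] = i
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    g = long.groupby(["residue", "stage"])[column]
    out = g.median().rename("median").to_frame()
    out["q1"] = g.quantile(0.25)
    out["q3"] = g.quantile(0.75)
    return out.reset_index()
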