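"""Per-residue acceptance counts and torsion-space coverage."""

from __future__ import annotations

import numpy as np
import pytest

from traversal import synthgen
from traversal.local_measures import (
    CUMULATIVE,
    acceptance_counts,
    aggregate_profiles,
    available_triplets,
    canonical_triplet,
    pool_coverage,
    torsion_coverage,
)
from traversal.trajio import FragmentLibrary, MoveEvent, TrajectoryLog


def _log(events, L=20, run_id="r"):
    return TrajectoryLog(run_id=run_id, length=L, events=list(events), snapshots=[])


def _frag(*triplets):
    return np.asarray(triplets, dtype=float)


def _event(move, stage, start, triplets, L=20, length=9):
    torsions = []
    for offset, trip in enumerate(triplets):
        resi = start + offset
        phi, psi, omega = trip
        torsions.append(
            (resi, (None if resi == 0 else phi, None if resi == L - 1 else psi, omega))
        )
    return MoveEvent(move, stage, start, length, tuple(torsions))


class TestAcceptanceCounts:
    def test_single_event_increments_window_residues(self):
        trips = [(-60.0 - i, -40.0 - i, 180.0) for i in range(9)]
        prof = acceptance_counts(_log([_event(1, "1", 0, trips)]))
        np.testing.assert_array_equal(prof.counts["1"][:9], np.ones(9, dtype=int))
        assert prof.counts["1"][9:].sum() == 0

    def test_identical_consecutive_event_counts_nothing(self):
        trips = [(-60.0, -40.0, 180.0)] * 9
        log = _log([_event(1, "1", 0, trips), _event(2, "1", 0, trips)])
        prof = acceptance_counts(log)
        np.testing.assert_array_equal(prof.counts["1"][:9], np.ones(9, dtype=int))

    def test_window_mode_counts_every_listed_residue(self):
        trips = [(-60.0, -40.0, 180.0)] * 9
        log = _log([_event(1, "1", 0, trips), _event(2, "1", 0, trips)])
        prof = acceptance_counts(log, mode="window")
        np.testing.assert_array_equal(prof.counts["1"][:9], 2 * np.ones(9, dtype=int))

    def test_matches_generator_schedule(self):
        log, truth = synthgen.gen_move_log(
            30, [("1", 60), ("2", 60)], seed=9, window_len=7
        )
        prof = acceptance_counts(log)
        for stage in ("1", "2"):
            np.testing.assert_array_equal(prof.counts[stage], truth.change_counts[stage])
        np.testing.assert_array_equal(prof.counts[CUMULATIVE], truth.cumulative_counts)

    def test_relative_frequencies_sum_to_one(self):
        log, _ = synthgen.gen_move_log(30, [("1", 50)], seed=2)
        prof = acceptance_counts(log)
        assert prof.relative_frequency("1").sum() == pytest.approx(1.0)

    def test_counts_per_event_bounded_by_fragment_length(self):
        log, _ = synthgen.gen_move_log(30, [("1", 80)], seed=3, window_len=9)
        for ev in log.events:
            prof = acceptance_counts(_log([ev], L=30))
            assert prof.counts[CUMULATIVE].sum() <= 9


class TestAvailableTriplets:
    def test_overlapping_windows_accumulate(self):
        # two 3-mer windows, one fragment each, all angles distinct:
        # residues covered by both windows see 2 triplets
        lib = FragmentLibrary(
            3,
            [
                [_frag((-60, -40, 180), (-61, -41, 180), (-62, -42, 180))],
                [_frag((-70, -50, 180), (-71, -51, 180), (-72, -52, 180))],
            ],
        )
        counts, _ = available_triplets(lib, 4)
        np.testing.assert_array_equal(counts, [1, 2, 2, 1])

    def test_identical_triplets_deduplicate(self):
        frag = _frag((-60, -40, 180), (-61, -41, 180), (-62, -42, 180))
        lib = FragmentLibrary(3, [[frag, frag.copy()]])
        counts, _ = available_triplets(lib, 3)
        np.testing.assert_array_equal(counts, [1, 1, 1])

    def test_matches_exhaustive_enumeration(self):
        lib = synthgen.gen_fragment_library(25, 9, n_frags=6, seed=1)
        counts, _ = available_triplets(lib, 25)
        expected = [set() for _ in range(25)]
        for w, frags in enumerate(lib.windows):
            for frag in frags:
                for p in range(9):
                    expected[w + p].add(canonical_triplet(frag[p], w + p, 25))
        np.testing.assert_array_equal(counts, [len(s) for s in expected])

    def test_window_exceeding_chain_rejected(self):
        lib = synthgen.gen_fragment_library(25, 9, n_frags=2, seed=1)
        with pytest.raises(Exception):
            available_triplets(lib, 20)


class TestTorsionCoverage:
    def test_every_triplet_used_gives_full_coverage(self):
        lib = synthgen.gen_fragment_library(12, 3, n_frags=4, seed=5)
        events = []
        move = 0
        for w, frags in enumerate(lib.windows):
            for frag in frags:
                move += 1
                events.append(_event(move, "1", w, [tuple(t) for t in frag], L=12, length=3))
        prof = torsion_coverage(_log(events, L=12), lib)
        np.testing.assert_allclose(prof.coverage[CUMULATIVE], 1.0)
        assert prof.mismatches == 0

    def test_empty_log_gives_zero_coverage(self):
        lib = synthgen.gen_fragment_library(12, 3, n_frags=4, seed=5)
        prof = torsion_coverage(_log([], L=12), lib)
        np.testing.assert_allclose(prof.coverage[CUMULATIVE], 0.0)

    def test_matches_generator_bookkeeping(self):
        lib = synthgen.gen_fragment_library(20, 5, n_frags=10, seed=7)
        subsets = [list(range(4)) for _ in lib.windows]  # known 40% subset
        log, truth = synthgen.gen_move_log(
            20, [("1", 120)], seed=8, library=lib, fragment_subsets=subsets
        )
        prof = torsion_coverage(log, lib)
        avail, _ = available_triplets(lib, 20)
        expected = np.array(
            [len(truth.cumulative_used[r]) / avail[r] for r in range(20)]
        )
        np.testing.assert_allclose(prof.coverage[CUMULATIVE], expected)
        assert prof.mismatches == 0

    def test_unknown_triplet_counts_as_mismatch(self):
        lib = synthgen.gen_fragment_library(12, 3, n_frags=2, seed=5)
        ev = _event(1, "1", 4, [(-10.0, 10.0, 170.0)] * 3, L=12, length=3)
        prof = torsion_coverage(_log([ev], L=12), lib)
        assert prof.mismatches == 3
        np.testing.assert_allclose(prof.coverage[CUMULATIVE], 0.0)

    def test_coverage_monotone_in_prefix_length(self):
        lib = synthgen.gen_fragment_library(20, 5, n_frags=8, seed=4)
        log, _ = synthgen.gen_move_log(20, [("1", 80)], seed=4, library=lib)
        prev = np.zeros(20)
        for cut in (10, 30, 50, 80):
            prefix = _log(log.events[:cut], L=20)
            cov = torsion_coverage(prefix, lib).coverage[CUMULATIVE]
            assert np.all(cov >= prev - 1e-12)
            prev = cov

    def test_pooled_short_runs_dominate_each_run(self):
        lib = synthgen.gen_fragment_library(20, 5, n_frags=8, seed=6)
        profiles = []
        for s in range(4):
            log, _ = synthgen.gen_move_log(20, [("1", 30)], seed=100 + s, library=lib)
            profiles.append(torsion_coverage(log, lib))
        pooled = pool_coverage(profiles)
        stacked = np.vstack([p.coverage[CUMULATIVE] for p in profiles])
        assert np.all(pooled.coverage[CUMULATIVE] >= stacked.max(axis=0) - 1e-12)


def test_aggregate_profiles_median_iqr():
    lib = synthgen.gen_fragment_library(15, 5, n_frags=6, seed=2)
    profiles = [
        torsion_coverage(
            synthgen.gen_move_log(15, [("1", 40)], seed=s, library=lib)[0], lib
        )
        for s in range(3)
    ]
    table = aggregate_profiles(profiles, "coverage")
    assert {"residue", "stage", "median", "q1", "q3"} <= set(table.columns)
    sub = table[table["stage"] == CUMULATIVE]
    assert len(sub) == 15
    assert np.all(sub["q1"] <= sub["median"] + 1e-12)
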