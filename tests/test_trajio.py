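"""IO layer: PDB CA traces, trajectory-log schema, fragment-library dialect."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traversal import synthgen, trajio
from traversal.errors import FormatError, ValidationError
from traversal.trajio import (
    MoveEvent,
    SnapshotRef,
    TrajectoryLog,
    read_ca_structure,
    read_fragment_library,
    read_trajectory_log,
    write_fragment_library,
    write_trajectory_log,
)

from conftest import atom_line


class TestReadCAStructure:
    def test_echoes_ca_coordinates(self, three_residue_pdb):
        s = read_ca_structure(three_residue_pdb)
        assert s.length == 3
        np.testing.assert_allclose(
            s.coords, [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]
        )
        assert s.author_resids == (1, 2, 3)

    def test_hetatm_only_is_a_format_error(self):
        text = atom_line(1, 1, 0, 0, 0, record="HETATM", resname="HOH") + "\nEND\n"
        with pytest.raises(FormatError):
            read_ca_structure(text)

    def test_multi_model_takes_first_model_only(self):
        lines = (
            ["MODEL        1"]
            + [atom_line(1, 1, 0, 0, 0), atom_line(2, 2, 3.8, 0, 0)]
            + ["ENDMDL", "MODEL        2"]
            + [atom_line(3, 1, 9, 9, 9), atom_line(4, 2, 12.8, 9, 9)]
            + ["ENDMDL", "END"]
        )
        s = read_ca_structure("\n".join(lines) + "\n")
        assert s.length == 2
        np.testing.assert_allclose(s.coords[0], [0, 0, 0])

    def test_altloc_resolved_by_highest_occupancy(self):
        lines = [
            atom_line(1, 1, 0, 0, 0, altloc="A", occupancy=0.4),
            atom_line(2, 1, 5, 5, 5, altloc="B", occupancy=0.6),
            atom_line(3, 2, 3.8, 0, 0),
            "END",
        ]
        s = read_ca_structure("\n".join(lines) + "\n")
        np.testing.assert_allclose(s.coords[0], [5, 5, 5])

    def test_duplicate_ca_after_altloc_resolution_errors(self):
        lines = [
            atom_line(1, 1, 0, 0, 0),
            atom_line(2, 1, 1, 1, 1),  # same residue, blank altloc, CA again
            "END",
        ]
        with pytest.raises(FormatError):
            read_ca_structure("\n".join(lines) + "\n")

    def test_residues_without_ca_are_skipped(self):
        lines = [
            atom_line(1, 1, 0, 0, 0),
            atom_line(2, 2, 1, 1, 1, name=" CB "),
            atom_line(3, 3, 3.8, 0, 0),
            "END",
        ]
        s = read_ca_structure("\n".join(lines) + "\n")
        assert s.length == 2

    def test_synthetic_pdb_round_trip(self, compact_chain):
        text = synthgen.synthetic_pdb(compact_chain)
        s = read_ca_structure(text)
        np.testing.assert_allclose(s.coords, compact_chain.coords, atol=5e-4)


def _toy_log(**kwargs) -> TrajectoryLog:
    defaults = dict(
        run_id="r1",
        length=20,
        events=[
            MoveEvent(10, "1", 0, 9, ((0, (None, 150.0, 180.0)), (1, (-60.0, -45.0, 180.0)))),
            MoveEvent(20, "1", 5, 9, ((5, (-120.0, 130.0, 179.5)),)),
        ],
        snapshots=[SnapshotRef(100, "snap_000100.pdb")],
    )
    defaults.update(kwargs)
    return TrajectoryLog(**defaults)


class TestTrajectoryLog:
    def test_two_event_log_parses(self):
        log = _toy_log()
        text = write_trajectory_log(log)
        back = read_trajectory_log(text)
        assert len(back.events) == 2
        assert back.events[0].move_index == 10
        assert back.events[1].window_start == 5

    def test_out_of_order_moves_rejected(self):
        with pytest.raises(ValidationError):
            _toy_log(
                events=[
                    MoveEvent(10, "1", 0, 9, ()),
                    MoveEvent(5, "1", 0, 9, ()),
                ]
            )

    def test_empty_events_one_snapshot_is_valid(self):
        log = _toy_log(events=[])
        back = read_trajectory_log(write_trajectory_log(log))
        assert back.events == []
        assert len(back.snapshots) == 1

    def test_window_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            _toy_log(events=[MoveEvent(1, "1", 15, 9, ())])

    def test_angle_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            _toy_log(events=[MoveEvent(1, "1", 0, 9, ((0, (None, 270.0, 180.0)),))])
        with pytest.raises(ValidationError):
            _toy_log(events=[MoveEvent(1, "1", 0, 9, ((0, (-180.0, 10.0, 180.0)),))])

    def test_missing_header_is_format_error(self):
        with pytest.raises(FormatError):
            read_trajectory_log("1\t1\t0\t9\t\n")

    def test_no_event_dropped(self):
        log, _ = synthgen.gen_move_log(25, [("1", 40), ("2", 40)], seed=5)
        text = write_trajectory_log(log)
        data_lines = [
            ln
            for ln in text.splitlines()
            if ln and not ln.startswith("#") and not ln.startswith("S\t")
        ]
        assert len(read_trajectory_log(text).events) == len(data_lines) == 80

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_round_trip_reproduces_log(self, data):
        """Write-then-read is the identity on any valid log (3-decimal angles)."""
        L = data.draw(st.integers(10, 30))
        n_events = data.draw(st.integers(0, 8))
        angle = st.integers(-179_999, 180_000).map(lambda m: m / 1000.0)
        events = []
        move = 0
        for _ in range(n_events):
            move += data.draw(st.integers(1, 50))
            start = data.draw(st.integers(0, L - 9))
            torsions = []
            for offset in data.draw(
                st.lists(st.integers(0, 8), unique=True, max_size=9)
            ):
                resi = start + offset
                phi = None if resi == 0 else data.draw(angle)
                psi = None if resi == L - 1 else data.draw(angle)
                torsions.append((resi, (phi, psi, data.draw(angle))))
            events.append(
                MoveEvent(move, data.draw(st.sampled_from(["1", "2", "3"])), start, 9,
                          tuple(torsions))
            )
        log = TrajectoryLog(run_id="hx", length=L, events=events, snapshots=[])
        assert read_trajectory_log(write_trajectory_log(log)) == log


FRAG_BLOCK = """\
 position:            1 neighbors:            2

 2lvb A   12 G H   -60.000   -45.000   180.000
 2lvb A   13 A H   -63.000   -42.000   179.000
 2lvb A   14 L H   -61.000   -44.000  -180.000

 1abc B    7 V E  -120.000   130.000   178.000
 1abc B    8 T E  -118.000   128.000   180.000
 1abc B    9 I E  -122.000   132.000   179.000
"""


class TestFragmentLibrary:
    def test_parses_position_block(self):
        lib = read_fragment_library(FRAG_BLOCK)
        assert lib.n_windows == 1
        assert len(lib.windows[0]) == 2
        assert lib.fragment_length == 3
        np.testing.assert_allclose(lib.windows[0][0][0], [-60.0, -45.0, 180.0])

    def test_short_fragment_is_length_error(self):
        bad = FRAG_BLOCK.replace(
            " 1abc B    9 I E  -122.000   132.000   179.000\n", ""
        )
        with pytest.raises(FormatError):
            read_fragment_library(bad)

    def test_unparseable_angle_field(self):
        bad = FRAG_BLOCK.replace("-60.000", "xx.xxx")
        with pytest.raises(FormatError):
            read_fragment_library(bad)

    def test_window_count_formula(self):
        # complete 9-mer library over a 91-residue chain has 91 - 9 + 1 windows
        lib = synthgen.gen_fragment_library(91, 9, n_frags=2, seed=0)
        assert lib.n_windows == 83
        back = read_fragment_library(write_fragment_library(lib))
        assert back.n_windows == 83

    def test_round_trip_preserves_triplets(self):
        lib = synthgen.gen_fragment_library(20, 9, n_frags=5, seed=3)
        back = read_fragment_library(write_fragment_library(lib))
        assert back.fragment_length == lib.fragment_length
        for w in range(lib.n_windows):
            for a, b in zip(lib.windows[w], back.windows[w]):
                np.testing.assert_array_equal(a, b)

    def test_noncontiguous_positions_rejected(self):
        bad = FRAG_BLOCK.replace("position:            1", "position:            3")
        with pytest.raises(FormatError):
            read_fragment_library(bad)


class TestStructureSet:
    def test_mixed_lengths_rejected(self):
        a = synthgen.gen_chain(10, 0.5, 0)
        b = synthgen.gen_chain(11, 0.5, 0)
        with pytest.raises(ValidationError):
            trajio.StructureSet([a, b], ["decoy", "decoy"])

    def test_label_parsing(self):
        parsed = trajio.parse_source_label(trajio.traj_label("r7", 300))
        assert parsed == {"kind": "trajectory", "run_id": "r7", "move_index": 300}
        with pytest.raises(ValidationError):
            trajio.parse_source_label("junk")
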