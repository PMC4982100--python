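"""Readers and writers for trajectory-analysis inputs.

Four input classes are handled here, and their on-disk schemas are the
contract everything downstream consumes:

* CA-only protein structures in PDB format (``read_ca_structure``);
* accepted-move trajectory logs in a versioned TSV schema
  (``read_trajectory_log`` / ``write_trajectory_log``);
* Rosetta-style fragment library text (``read_fragment_library`` /
  ``write_fragment_library``);
* labelled structure sets pooling decoys, trajectory snapshots and an
  optional native structure (``StructureSet``).

Residue indexing is 0-based and contiguous by order of appearance; author
residue numbers are kept as metadata only, so downstream math never sees
PDB numbering gaps.  Torsion angles are degrees in (-180, 180]; a missing
phi at the N-terminus or psi at the C-terminus is the ``None`` sentinel
(``NA`` on disk).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .errors import FormatError, ValidationError

#: number of decimals at which two torsion angles are considered identical;
#: matches the precision of the fragment text format.
TORSION_DECIMALS = 3

LOG_HEADER = "#traj_log v1"

Triplet = tuple[float | None, float | None, float | None]


def normalize_angle(a: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    m = ((a + 180.0) % 360.0) - 180.0
    if m <= -180.0:
        m += 360.0
    return m


def _check_angle(a: float | None, where: str) -> None:
    if a is None:
        return
    if not (-180.0 < a <= 180.0):
        raise ValidationError(f"angle {a!r} outside (-180, 180] in {where}")


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class CAStructure:
    """C-alpha trace of a single-chain structure.

    ``coords`` is an (L, 3) float array in Angstrom, one row per residue in
    chain order.  ``author_resids`` optionally records the original PDB
    residue numbers.
    """

    coords: np.ndarray
    author_resids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"coords must be (L, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValidationError("structure must contain at least one residue")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        if self.author_resids is not None and len(self.author_resids) != len(coords):
            raise ValidationError("author_resids length mismatch")

    @property
    def length(self) -> int:
        return self.coords.shape[0]


def read_ca_structure(source: str | IO[str]) -> CAStructure:
    """Parse the CA trace of the first model / single chain of a PDB file.

    Only ``ATOM`` records contribute.  For NMR-style multi-model files the
    first model is used.  Alternate locations are resolved to the highest
    occupancy (first seen on ties).  A residue whose CA is defined twice
    after altloc resolution is a format error, as is a file without any CA
    atom.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    parser = PDBParser(QUIET=False)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PDBConstructionWarning)
        structure = parser.get_structure("s", handle)
    for w in caught:
        if "defined twice" in str(w.message):
            raise FormatError(f"duplicate atom after altloc resolution: {w.message}")
    models = list(structure)
    if not models:
        raise FormatError("no models in PDB input")
    chains = [
        ch for ch in models[0] if any(res.id[0] == " " for res in ch)
    ]
    if len(chains) > 1:
        raise FormatError("multi-chain structures are not supported")
    if not chains:
        raise FormatError("no ATOM records with CA atoms found")
    coords: list[np.ndarray] = []
    resids: list[int] = []
    seen: set[tuple] = set()
    for res in chains[0]:
        if res.id[0] != " " or "CA" not in res:
            continue
        if res.id in seen:
            raise FormatError(f"duplicate residue {res.id} after altloc resolution")
        seen.add(res.id)
        coords.append(np.asarray(res["CA"].coord, dtype=float))
        resids.append(res.id[1])
    if not coords:
        raise FormatError("no ATOM records with CA atoms found")
    return CAStructure(np.vstack(coords), tuple(resids))


# ---------------------------------------------------------------------------
# trajectory logs


@dataclass(frozen=True)
class MoveEvent:
    """One accepted fragment insertion.

    ``torsions`` maps affected residue index -> (phi, psi, omega) after the
    move; residues inside the window whose stored values equal the previous
    backbone state are allowed (they simply do not count as changes).
    """

    move_index: int
    stage: str
    window_start: int
    window_len: int
    torsions: tuple[tuple[int, Triplet], ...]


@dataclass(frozen=True)
class SnapshotRef:
    """Pointer to a structure file emitted at a given accepted-move index."""

    move_index: int
    path: str


@dataclass
class TrajectoryLog:
    """Time-ordered record of accepted moves and snapshots for one run."""

    run_id: str
    length: int
    events: list[MoveEvent] = field(default_factory=list)
    snapshots: list[SnapshotRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("chain length must be >= 1")
        prev = None
        for ev in self.events:
            if prev is not None and ev.move_index <= prev:
                raise ValidationError(
                    f"move_index not strictly increasing at {ev.move_index}"
                )
            prev = ev.move_index
            if ev.window_start < 0 or ev.window_start + ev.window_len > self.length:
                raise ValidationError(
                    f"window ({ev.window_start}, {ev.window_len}) outside chain "
                    f"of length {self.length}"
                )
            for resi, trip in ev.torsions:
                if not (ev.window_start <= resi < ev.window_start + ev.window_len):
                    raise ValidationError(
                        f"torsion residue {resi} outside insertion window"
                    )
                for a in trip:
                    _check_angle(a, f"move {ev.move_index}, residue {resi}")

    @property
    def stages(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.stage, None)
        return tuple(seen)


def _format_angle(a: float | None) -> str:
    return "NA" if a is None else f"{a:.{TORSION_DECIMALS}f}"


def _parse_angle(tok: str, where: str) -> float | None:
    if tok == "NA":
        return None
    try:
        return float(tok)
    except ValueError as exc:
        raise FormatError(f"unparseable angle {tok!r} in {where}") from exc


def write_trajectory_log(log: TrajectoryLog) -> str:
    """Serialize a trajectory log to the versioned TSV schema."""
    lines = [LOG_HEADER, f"#run_id\t{log.run_id}", f"#length\t{log.length}"]
    snap_iter = iter(log.snapshots)
    pending = next(snap_iter, None)
    for ev in log.events:
        while pending is not None and pending.move_index < ev.move_index:
            lines.append(f"S\t{pending.move_index}\t{pending.path}")
            pending = next(snap_iter, None)
        entries = ";".join(
            f"{resi}:{_format_angle(p)}:{_format_angle(s)}:{_format_angle(o)}"
            for resi, (p, s, o) in ev.torsions
        )
        lines.append(
            f"{ev.move_index}\t{ev.stage}\t{ev.window_start}\t{ev.window_len}\t{entries}"
        )
    while pending is not None:
        lines.append(f"S\t{pending.move_index}\t{pending.path}")
        pending = next(snap_iter, None)
    return "\n".join(lines) + "\n"


def read_trajectory_log(source: str | IO[str]) -> TrajectoryLog:
    """Parse and validate a trajectory log (TSV schema, header ``#traj_log v1``).

    Out-of-order events, out-of-bounds windows and out-of-range angles all
    raise :class:`~traversal.errors.ValidationError`; schema problems raise
    :class:`~traversal.errors.FormatError`.  Every non-comment data line
    becomes exactly one event or snapshot - nothing is dropped silently.
    """
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()
    it = iter(enumerate(lines, start=1))
    header = None
    for _, line in it:
        if line.strip():
            header = line.strip()
            break
    if header != LOG_HEADER:
        raise FormatError(f"missing or wrong header; expected {LOG_HEADER!r}")
    run_id: str | None = None
    length: int | None = None
    events: list[MoveEvent] = []
    snapshots: list[SnapshotRef] = []
    for lineno, line in it:
        if not line.strip():
            continue
        if line.startswith("#run_id"):
            run_id = line.split("\t", 1)[1].strip()
            continue
        if line.startswith("#length"):
            length = int(line.split("\t", 1)[1])
            continue
        if line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "S":
            if len(fields) != 3:
                raise FormatError(f"line {lineno}: snapshot line needs 3 fields")
            snapshots.append(SnapshotRef(int(fields[1]), fields[2]))
            continue
        if len(fields) != 5:
            raise FormatError(f"line {lineno}: event line needs 5 fields")
        torsions = []
        if fields[4]:
            for entry in fields[4].split(";"):
                parts = entry.split(":")
                if len(parts) != 4:
                    raise FormatError(f"line {lineno}: bad torsion entry {entry!r}")
                resi = int(parts[0])
                trip = tuple(
                    _parse_angle(tok, f"line {lineno}") for tok in parts[1:]
                )
                torsions.append((resi, trip))
        events.append(
            MoveEvent(
                move_index=int(fields[0]),
                stage=fields[1],
                window_start=int(fields[2]),
                window_len=int(fields[3]),
                torsions=tuple(torsions),
            )
        )
    if run_id is None or length is None:
        raise FormatError("log is missing #run_id or #length metadata")
    return TrajectoryLog(run_id=run_id, length=length, events=events, snapshots=snapshots)


# ---------------------------------------------------------------------------
# fragment libraries

_POSITION_RE = re.compile(r"position:\s*(\d+)\s+neighbors:\s*(\d+)")


@dataclass
class FragmentLibrary:
    """Per-insertion-window fragment torsions.

    ``windows[w]`` is the list of fragments available at 0-based window
    start ``w``; each fragment is a (fragment_length, 3) array of
    (phi, psi, omega) in degrees.
    """

    fragment_length: int
    windows: list[list[np.ndarray]]

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValidationError("fragment_length must be >= 1")
        for w, frags in enumerate(self.windows):
            for f in frags:
                if f.shape != (self.fragment_length, 3):
                    raise ValidationError(
                        f"fragment at window {w} has shape {f.shape}, expected "
                        f"({self.fragment_length}, 3)"
                    )

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def read_fragment_library(source: str | IO[str]) -> FragmentLibrary:
    """Parse Rosetta-style fragment text.

    Blocks are headed by a line containing ``position:`` and ``neighbors:``;
    each fragment is a run of per-residue lines (source PDB id, chain,
    residue, SS letter, then phi/psi/omega columns), fragments separated by
    blank lines.  Window starts must be contiguous from position 1.  Other
    dialects fail loudly.
    """
    text = source if isinstance(source, str) else source.read()
    blocks: dict[int, list[np.ndarray]] = {}
    position: int | None = None
    current: list[tuple[float, float, float]] = []
    frag_len: int | None = None

    def flush(lineno: int) -> None:
        nonlocal current, frag_len
        if not current:
            return
        if position is None:
            raise FormatError(f"line {lineno}: fragment lines before any header")
        arr = np.asarray(current, dtype=float)
        if frag_len is None:
            frag_len = arr.shape[0]
        if arr.shape[0] != frag_len:
            raise FormatError(
                f"line {lineno}: fragment with {arr.shape[0]} residues, "
                f"expected {frag_len}"
            )
        blocks.setdefault(position, []).append(arr)
        current = []

    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _POSITION_RE.search(line)
        if m:
            flush(lineno)
            position = int(m.group(1))
            continue
        if not line.strip():
            flush(lineno)
            continue
        tokens = line.split()
        if len(tokens) < 8:
            raise FormatError(f"line {lineno}: expected >= 8 columns")
        try:
            angles = tuple(float(tok) for tok in tokens[5:8])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable angle field") from exc
        current.append(angles)
    flush(len(text.splitlines()))
    if not blocks:
        raise FormatError("no position blocks found")
    if frag_len is None:
        raise FormatError("no fragments found")
    n = max(blocks)
    if sorted(blocks) != list(range(1, n + 1)):
        raise FormatError("window starts are not contiguous from position 1")
    windows = [blocks[p] for p in range(1, n + 1)]
    return FragmentLibrary(fragment_length=frag_len, windows=windows)


def write_fragment_library(lib: FragmentLibrary) -> str:
    """Serialize a library to the Rosetta-style dialect read back by
    :func:`read_fragment_library` (round-trip exact at 3 decimals)."""
    out: list[str] = []
    for w, frags in enumerate(lib.windows):
        out.append(f" position: {w + 1:12d} neighbors: {len(frags):12d}")
        out.append("")
        for f in frags:
            for phi, psi, omega in f:
                out.append(
                    f" xxxx A   1 V L "
                    f"{phi:9.{TORSION_DECIMALS}f} {psi:9.{TORSION_DECIMALS}f} "
                    f"{omega:9.{TORSION_DECIMALS}f}"
                )
            out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# structure sets

DECOY_LABEL = "decoy"
NATIVE_LABEL = "native"


def traj_label(run_id: str, move_index: int) -> str:
    return f"trajectory:{run_id}:{move_index}"


def parse_source_label(label: str) -> dict:
    """Split a source label into kind / run_id / move_index."""
    if label == DECOY_LABEL:
        return {"kind": "decoy", "run_id": None, "move_index": None}
    if label == NATIVE_LABEL:
        return {"kind": "native", "run_id": None, "move_index": None}
    if label.startswith("trajectory:"):
        _, run_id, move_index = label.split(":")
        return {"kind": "trajectory", "run_id": run_id, "move_index": int(move_index)}
    raise ValidationError(f"unrecognized source label {label!r}")


@dataclass
class StructureSet:
    """Ordered collection of equal-length CA structures with source labels."""

    structures: list[CAStructure]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.structures) != len(self.labels):
            raise ValidationError("structures/labels length mismatch")
        if self.structures:
            L = self.structures[0].length
            for s in self.structures:
                if s.length != L:
                    raise ValidationError("all members must have equal length")
        for lab in self.labels:
            parse_source_label(lab)

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def chain_length(self) -> int:
        if not self.structures:
            raise ValidationError("empty structure set")
        return self.structures[0].length
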