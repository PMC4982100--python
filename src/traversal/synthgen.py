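"""Deterministic, seeded generators for every input class.

Everything the pipeline consumes can be synthesized here without any
external data: toy CA chains, basin-structured contact-map trajectories,
accepted-move logs, fragment libraries, labelled decoy/trajectory
structure sets and block-design tables.  Every generator is deterministic
per seed and returns the ground-truth bookkeeping its downstream consumer
needs for testing (true hidden states, exact per-residue change counts,
used-triplet sets, ...).

Contact-pattern basin prototypes are built from compact random-walk
chains rather than random bit patterns, so their distance geometry is
protein-plausible.  The ``regimes`` preset bundles three trajectory
styles - confined (high self-transition), noisy (cycle + noise mixture)
and explorative (uniform transitions) - mirroring the long-run /
short-runs / distribution-guided contrast the exploration-ordering tests
rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .blockstats import BlockDesignTable
from .contactspace import ContactMap, contact_map
from .errors import ValidationError
from .local_measures import canonical_triplet
from .trajio import (
    TORSION_DECIMALS,
    CAStructure,
    FragmentLibrary,
    MoveEvent,
    SnapshotRef,
    StructureSet,
    TrajectoryLog,
    normalize_angle,
    traj_label,
)

BOND_LENGTH_A = 3.8
_CLASH_A = 3.4

# (phi, psi) archetype means and spreads for helix / strand / coil
_ARCHETYPES = {
    "H": ((-63.0, -42.0), (5.0, 5.0)),
    "E": ((-120.0, 135.0), (12.0, 12.0)),
    "C": ((-90.0, 60.0), (40.0, 40.0)),
}


def _round_angle(a: float) -> float:
    r = round(normalize_angle(a), TORSION_DECIMALS)
    return 180.0 if r <= -180.0 else r  # rounding may hit the open endpoint


def _draw_triplet(rng: np.random.Generator, ss: str) -> tuple[float, float, float]:
    (mphi, mpsi), (sphi, spsi) = _ARCHETYPES[ss]
    phi = _round_angle(rng.normal(mphi, sphi))
    psi = _round_angle(rng.normal(mpsi, spsi))
    omega = _round_angle(rng.normal(180.0, 1.5))
    return phi, psi, omega


# ---------------------------------------------------------------------------
# chains and structure sets


def gen_chain(L: int, compactness: float = 0.5, seed: int = 0) -> CAStructure:
    """Self-avoiding 3-D random walk with 3.8 A virtual CA-CA bonds.

    ``compactness`` in [0, 1] biases each step back toward the current
    centroid, raising the 8 A contact density of the result.  Deterministic
    per seed.
    """
    if L < 3:
        raise ValidationError("need at least 3 residues")
    if not (0.0 <= compactness <= 1.0):
        raise ValidationError("compactness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    coords = np.zeros((L, 3))
    for i in range(1, L):
        centroid = coords[:i].mean(axis=0)
        placed = False
        best = None
        best_clearance = -np.inf
        for _ in range(300):
            direction = rng.normal(size=3)
            pull = centroid - coords[i - 1]
            norm_pull = np.linalg.norm(pull)
            if norm_pull > 1e-9:
                direction = direction + 1.2 * compactness * pull / norm_pull
            direction /= np.linalg.norm(direction)
            cand = coords[i - 1] + BOND_LENGTH_A * direction
            clearance = (
                np.linalg.norm(coords[: i - 1] - cand, axis=1).min() if i > 1 else np.inf
            )
            if clearance > best_clearance:
                best_clearance, best = clearance, cand
            if clearance >= _CLASH_A:
                coords[i] = cand
                placed = True
                break
        if not placed:
            coords[i] = best  # accept the least-clashing candidate
    return CAStructure(coords)


def gen_decoy_set(
    L: int, n: int, compactness: float = 0.7, seed: int = 0
) -> StructureSet:
    """n independent compact chains labelled as decoys."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    structures = [gen_chain(L, compactness, int(s)) for s in seeds]
    return StructureSet(structures, ["decoy"] * n)


# ---------------------------------------------------------------------------
# basin-structured trajectories


@dataclass
class BasinSpec:
    """Hidden-Markov emission model over contact-pattern basins.

    ``prototypes`` are b reference contact maps; the hidden state evolves
    by the row-stochastic matrix ``T`` and each emitted map is the current
    prototype with i.i.d. pair flips at ``flip_noise``.  Prototypes must be
    mutually distant (>= 5x the expected flips per emission) so basins
    stay identifiable.
    """

    prototypes: list[ContactMap]
    T: np.ndarray
    flip_noise: float
    steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        b = len(self.prototypes)
        T = np.asarray(self.T, dtype=float)
        if T.shape != (b, b) or np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0):
            raise ValidationError("T must be row-stochastic over the basins")
        self.T = T
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValidationError("flip_noise must be in [0, 0.5)")
        n_pairs = self.prototypes[0].bits.size
        expected_flips = self.flip_noise * n_pairs
        for i in range(b):
            for j in range(i + 1, b):
                dist = int(
                    np.count_nonzero(self.prototypes[i].bits ^ self.prototypes[j].bits)
                )
                if dist < 5 * expected_flips:
                    raise ValidationError(
                        f"prototypes {i} and {j} are only {dist} flips apart; "
                        "flip noise would blur the basins"
                    )

    @property
    def b(self) -> int:
        return len(self.prototypes)


def make_prototypes(
    L: int, b: int, seed: int = 0, compactness: float = 0.8
) -> list[ContactMap]:
    """Contact maps of b independent compact chains (basin references)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=b)
    return [contact_map(gen_chain(L, compactness, int(s))) for s in seeds]


def regime_transition_matrix(regime: str, b: int) -> np.ndarray:
    """Hidden transition matrix for a named exploration regime.

    ``confined``: 0.9 self-transition, remainder spread uniformly;
    ``noisy``: 0.5 deterministic-cycle step + 0.5 uniform mixture;
    ``explorative``: uniform over all states; ``cycle``: deterministic
    permutation 0 -> 1 -> ... -> 0.
    """
    uniform = np.full((b, b), 1.0 / b)
    cycle = np.zeros((b, b))
    cycle[np.arange(b), (np.arange(b) + 1) % b] = 1.0
    if regime == "confined":
        T = np.full((b, b), 0.1 / (b - 1))
        np.fill_diagonal(T, 0.9)
        return T
    if regime == "noisy":
        return 0.5 * cycle + 0.5 * uniform
    if regime == "explorative":
        return uniform
    if regime == "cycle":
        return cycle
    raise ValidationError(f"unknown regime {regime!r}")


REGIMES = ("confined", "noisy", "explorative")


def gen_state_sequence(
    T: np.ndarray, steps: int, rng: np.random.Generator, start: int | None = None
) -> np.ndarray:
    """Markov-chain sample of hidden basin states."""
    T = np.asarray(T, dtype=float)
    b = T.shape[0]
    states = np.empty(steps, dtype=np.int64)
    s = int(rng.integers(b)) if start is None else start
    for t in range(steps):
        states[t] = s
        s = int(rng.choice(b, p=T[s]))
    return states


def gen_trajectory(spec: BasinSpec) -> tuple[list[ContactMap], np.ndarray]:
    """Emit a contact-map series from a basin spec plus the true states."""
    rng = np.random.default_rng(spec.seed)
    states = gen_state_sequence(spec.T, spec.steps, rng)
    maps = []
    for s in states:
        proto = spec.prototypes[s]
        flips = rng.random(proto.bits.size) < spec.flip_noise
        maps.append(
            ContactMap(proto.length, proto.bits ^ flips, proto.cutoff_A)
        )
    return maps, states


def gen_background_maps(
    prototypes: Sequence[ContactMap],
    per_basin: int,
    flip_noise: float,
    seed: int = 0,
) -> list[ContactMap]:
    """Decoy-like background: noisy emissions from every basin prototype."""
    rng = np.random.default_rng(seed)
    maps = []
    for proto in prototypes:
        for _ in range(per_basin):
            flips = rng.random(proto.bits.size) < flip_noise
            maps.append(ContactMap(proto.length, proto.bits ^ flips, proto.cutoff_A))
    return maps


def uniform_tour(k: int) -> np.ndarray:
    """State sequence traversing every ordered pair of distinct states once.

    An Eulerian circuit of the complete digraph on k states (Hierholzer's
    algorithm, deterministic lowest-successor order).  Feeding it to
    ``build_msm`` gives exactly uniform off-diagonal transition counts and
    uniform occupancy - the maximal-uncertainty reference walk.
    """
    if k < 2:
        raise ValidationError("need k >= 2 states")
    remaining = {i: [j for j in range(k) if j != i] for i in range(k)}
    stack, tour = [0], []
    while stack:
        v = stack[-1]
        if remaining[v]:
            stack.append(remaining[v].pop(0))
        else:
            tour.append(stack.pop())
    return np.asarray(tour[::-1], dtype=np.int64)


# ---------------------------------------------------------------------------
# structure-level trajectories (for PDB-emitting fixtures)


def gen_structure_trajectory(
    L: int,
    b: int,
    steps: int,
    regime: str = "explorative",
    jitter_A: float = 0.4,
    seed: int = 0,
    run_id: str = "run0",
) -> tuple[StructureSet, np.ndarray]:
    """Coordinate-level realization of the basin model.

    Each snapshot is the current basin's prototype chain with isotropic
    coordinate jitter; returned labels carry the run id and a move index
    spaced 100 accepted moves apart.
    """
    rng = np.random.default_rng(seed)
    proto_seeds = rng.integers(0, 2**31 - 1, size=b)
    chains = [gen_chain(L, 0.8, int(s)) for s in proto_seeds]
    states = gen_state_sequence(regime_transition_matrix(regime, b), steps, rng)
    structures, labels = [], []
    for t, s in enumerate(states):
        coords = chains[s].coords + rng.normal(scale=jitter_A, size=(L, 3))
        structures.append(CAStructure(coords))
        labels.append(traj_label(run_id, (t + 1) * 100))
    return StructureSet(structures, labels), states


# ---------------------------------------------------------------------------
# move logs


@dataclass
class LogTruth:
    """Ground-truth bookkeeping retained by :func:`gen_move_log`."""

    change_counts: dict[str, np.ndarray]
    used_triplets: dict[str, list[set]]
    cumulative_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    cumulative_used: list[set] = field(default=None)  # type: ignore[assignment]


def _bias_rates(L: int, region_bias) -> np.ndarray:
    rates = np.ones(L)
    if region_bias:
        covered = np.zeros(L, dtype=bool)
        for (lo, hi), rate in region_bias:
            if lo < 0 or hi > L or lo >= hi:
                raise ValidationError(f"bad bias range ({lo}, {hi})")
            if covered[lo:hi].any():
                raise ValidationError("overlapping bias ranges")
            covered[lo:hi] = True
            if rate < 0:
                raise ValidationError("bias rates must be nonnegative")
            rates[lo:hi] = rate
    return rates


def gen_move_log(
    L: int,
    stage_plan: Sequence[tuple[str, int]],
    region_bias=None,
    seed: int = 0,
    window_len: int = 9,
    library: FragmentLibrary | None = None,
    fragment_subsets: Sequence[Sequence[int]] | None = None,
    spillover: float = 0.4,
    run_id: str = "run0",
    snapshot_every: int = 100,
) -> tuple[TrajectoryLog, LogTruth]:
    """Synthetic accepted-move log with exact change/usage bookkeeping.

    ``region_bias`` maps residue ranges to relative acceptance rates: each
    event picks a target residue proportionally to its rate, then a random
    window covering it.  Without a library, the target residue (plus, with
    probability ``spillover`` * rate, other positive-rate window residues)
    receives a fresh archetype triplet; unchanged window residues are
    restated verbatim so change-detection semantics get exercised.  With a
    ``library``, the event inserts a whole fragment (optionally restricted
    to ``fragment_subsets[window]``), which is what coverage tests need.

    The returned :class:`LogTruth` holds per-stage per-residue change
    counts and used-triplet sets, recorded while generating.
    """
    if library is not None:
        window_len = library.fragment_length
    if window_len > L:
        raise ValidationError("window longer than chain")
    rates = _bias_rates(L, region_bias)
    if rates.sum() <= 0:
        raise ValidationError("all acceptance rates are zero")
    prob = rates / rates.sum()
    rng = np.random.default_rng(seed)
    stages = [s for s, _ in stage_plan]
    truth = LogTruth(
        change_counts={s: np.zeros(L, dtype=np.int64) for s in stages},
        used_triplets={s: [set() for _ in range(L)] for s in stages},
        cumulative_counts=np.zeros(L, dtype=np.int64),
        cumulative_used=[set() for _ in range(L)],
    )
    # initial backbone: extended-chain-like state, never reproduced by draws
    current: dict[int, tuple] = {}
    events: list[MoveEvent] = []
    snapshots: list[SnapshotRef] = []
    move_index = 0
    max_rate = rates.max()
    n_windows = L - window_len + 1
    for stage, n_events in stage_plan:
        for _ in range(n_events):
            move_index += int(rng.integers(1, 4))
            target = int(rng.choice(L, p=prob))
            lo = max(0, target - window_len + 1)
            hi = min(target, n_windows - 1)
            w = int(rng.integers(lo, hi + 1))
            torsions = []
            if library is not None:
                frags = library.windows[w]
                choices = (
                    fragment_subsets[w] if fragment_subsets is not None else range(len(frags))
                )
                frag = frags[list(choices)[int(rng.integers(len(list(choices))))]]
                for p in range(window_len):
                    r = w + p
                    trip = tuple(float(a) for a in frag[p])
                    torsions.append((r, trip))
            else:
                for p in range(window_len):
                    r = w + p
                    is_target = r == target
                    roll = rng.random()  # consumed for every residue: reproducible
                    change = is_target or (
                        rates[r] > 0 and roll < spillover * rates[r] / max_rate
                    )
                    if change:
                        trip = _draw_triplet(rng, "C")
                    elif r in current:
                        trip = current[r]
                    else:
                        continue  # untouched residue: not listed
                    torsions.append((r, trip))
            for r, trip in torsions:
                key = canonical_triplet(trip, r, L)
                prev = current.get(r)
                current[r] = trip
                changed = prev is None or canonical_triplet(prev, r, L) != key
                if changed:
                    truth.change_counts[stage][r] += 1
                    truth.cumulative_counts[r] += 1
                truth.used_triplets[stage][r].add(key)
                truth.cumulative_used[r].add(key)
            # encode terminal NA sentinels as the log schema requires
            encoded = []
            for r, trip in torsions:
                phi, psi, omega = trip
                encoded.append(
                    (
                        r,
                        (
                            None if r == 0 else phi,
                            None if r == L - 1 else psi,
                            omega,
                        ),
                    )
                )
            events.append(
                MoveEvent(
                    move_index=move_index,
                    stage=stage,
                    window_start=w,
                    window_len=window_len,
                    torsions=tuple(encoded),
                )
            )
            if snapshot_every and move_index // snapshot_every > (
                snapshots[-1].move_index // snapshot_every if snapshots else 0
            ):
                snapshots.append(
                    SnapshotRef(move_index, f"snap_{move_index:06d}.pdb")
                )
    log = TrajectoryLog(run_id=run_id, length=L, events=events, snapshots=snapshots)
    return log, truth


# ---------------------------------------------------------------------------
# fragment libraries


def gen_fragment_library(
    L: int, fragment_length: int = 9, n_frags: int = 25, seed: int = 0
) -> FragmentLibrary:
    """Per-window fragments with helix/strand/coil archetype torsions."""
    if n_frags < 1:
        raise ValidationError("need at least one fragment per window")
    if fragment_length > L:
        raise ValidationError("fragment longer than chain")
    rng = np.random.default_rng(seed)
    ss_types = ("H", "E", "C")
    windows = []
    for _ in range(L - fragment_length + 1):
        frags = []
        for _ in range(n_frags):
            ss = ss_types[int(rng.integers(3))]
            frag = np.array(
                [_draw_triplet(rng, ss) for _ in range(fragment_length)], dtype=float
            )
            frags.append(frag)
        windows.append(frags)
    return FragmentLibrary(fragment_length=fragment_length, windows=windows)


# ---------------------------------------------------------------------------
# block-design tables


def gen_block_table(
    n_blocks: int,
    k_treatments: int,
    c_replicates: int,
    treatment_shifts: Sequence[float] | None = None,
    block_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> BlockDesignTable:
    """Gaussian complete-block observations with optional treatment shifts."""
    rng = np.random.default_rng(seed)
    shifts = np.zeros(k_treatments) if treatment_shifts is None else np.asarray(
        treatment_shifts, dtype=float
    )
    if shifts.shape != (k_treatments,):
        raise ValidationError("treatment_shifts length mismatch")
    block_eff = rng.normal(0.0, block_sd, size=n_blocks)
    values = (
        block_eff[:, None, None]
        + shifts[None, :, None]
        + rng.normal(0.0, noise_sd, size=(n_blocks, k_treatments, c_replicates))
    )
    return BlockDesignTable(
        values,
        tuple(f"block{i}" for i in range(n_blocks)),
        tuple(f"treat{j}" for j in range(k_treatments)),
    )


# ---------------------------------------------------------------------------
# PDB serialization for synthetic fixtures


def synthetic_pdb(s: CAStructure) -> str:
    """CA-only PDB text for a synthetic structure (fixture emission only)."""
    lines = []
    for i, (x, y, z) in enumerate(s.coords):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
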