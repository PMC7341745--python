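"""Metropolis Monte Carlo over sequence x rotamer space.

Moves pick a non-frozen position uniformly; at mutable positions a mutation
draw proposes a new (type, rotamer) pair uniformly over the position's
allowed combinations, otherwise the rotamer is redrawn for the current
type.  Both draws exclude the current choice when an alternative exists, so
the proposal is symmetric and detailed balance holds.  Acceptance is on the
folding-energy difference.  In NEA mode every step uses the precomputed
energy matrix (incremental deltas, periodically cross-checked against a
fresh reconstruction); FDB recomputes the full many-body energy per step
and is intended for small systems.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AA1_TO_AA3
from .energetics import (
    FDB,
    NEA,
    folded_energy,
    precompute_energy_matrix,
)
from .errors import InvalidConfigError, NoMovesError, PdzDesignError
from .params import ForceFieldParams
from .scaffold import BackboneScaffold, DesignSpec, MUTABLE
from .sidechain import RotamerLibrary, SystemState
from .unfolded import UnfoldedModel, unfolded_energy

__all__ = [
    "McConfig",
    "ArchiveEntry",
    "SequenceArchive",
    "initial_state",
    "propose_move",
    "metropolis_accept",
    "run_design",
    "energy_window",
]

_FDB_POSITION_WARN = 30


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo run settings.

    ``kt`` is in kcal/mol; ``kt_ladder`` optionally enables a small
    replica ladder with state swaps every ``swap_interval`` steps.
    ``p_mutation`` is the probability that a move at a mutable position is a
    mutation rather than a rotamer re-draw.
    """

    n_steps: int
    kt: float = 0.6
    kt_ladder: tuple[float, ...] | None = None
    swap_interval: int = 1000
    p_mutation: float = 0.3
    seed: int = 0
    archive_size: int = 2000

    def __post_init__(self):
        if self.n_steps < 0:
            raise InvalidConfigError("n_steps must be >= 0")
        if self.kt <= 0:
            raise InvalidConfigError("kT must be positive")
        if self.kt_ladder is not None and any(
            k <= 0 for k in self.kt_ladder
        ):
            raise InvalidConfigError("ladder kT values must be positive")
        if not 0.0 <= self.p_mutation <= 1.0:
            raise InvalidConfigError("p_mutation must be in [0, 1]")
        if self.archive_size < 1:
            raise InvalidConfigError("archive_size must be >= 1")
        if self.swap_interval < 1:
            raise InvalidConfigError("swap_interval must be >= 1")


@dataclass(frozen=True)
class ArchiveEntry:
    sequence: str
    energy: float  # best folding energy observed for this sequence
    rotamers: tuple[int, ...]  # rotamer vector at that best energy
    first_seen_step: int


@dataclass
class SequenceArchive:
    """Distinct sequences ordered by best folding energy (ascending)."""

    entries: list[ArchiveEntry]
    visits: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        seqs = [e.sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise PdzDesignError("archive sequences must be unique")
        energies = [e.energy for e in self.entries]
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise PdzDesignError("archive energies must ascend")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def best(self) -> ArchiveEntry:
        return self.entries[0]

    def energies(self) -> np.ndarray:
        return np.array([e.energy for e in self.entries])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "sequence": [e.sequence for e in self.entries],
                "energy_kcal_mol": [e.energy for e in self.entries],
                "step_first_seen": [e.first_seen_step for e in self.entries],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SequenceArchive":
        df = pd.read_csv(path, sep="\t")
        return cls(
            entries=[
                ArchiveEntry(
                    sequence=row["sequence"],
                    energy=float(row["energy_kcal_mol"]),
                    rotamers=(),
                    first_seen_step=int(row["step_first_seen"]),
                )
                for _, row in df.iterrows()
            ]
        )


def initial_state(
    scaffold: BackboneScaffold, spec: DesignSpec
) -> SystemState:
    """Deterministic start: native types (or the first allowed type where
    the native one is not allowed), rotamer 0 everywhere."""
    seq = []
    for i, aa in enumerate(scaffold.sequence):
        if spec.classes[i] == MUTABLE and aa not in spec.allowed[i]:
            seq.append(sorted(spec.allowed[i])[0])
        else:
            seq.append(aa)
    return SystemState(scaffold, "".join(seq), (0,) * len(scaffold))


def _position_combos(
    spec: DesignSpec, scaffold: BackboneScaffold, library: RotamerLibrary
) -> dict[int, list[tuple[str, int]]]:
    combos: dict[int, list[tuple[str, int]]] = {}
    for pos in spec.non_frozen_positions:
        if spec.classes[pos] == MUTABLE:
            types = sorted(spec.allowed[pos])
        else:
            types = [scaffold.residues[pos].name1]
        combos[pos] = [
            (aa, r)
            for aa in types
            for r in range(library.n_rotamers(AA1_TO_AA3[aa]))
        ]
    return combos


def propose_move(
    state: SystemState,
    spec: DesignSpec,
    library: RotamerLibrary,
    config: McConfig,
    rng: np.random.Generator,
) -> SystemState:
    """Symmetric single-position proposal (see module docstring)."""
    positions = spec.non_frozen_positions
    if not positions:
        raise NoMovesError("all positions are frozen")
    pos = positions[rng.integers(len(positions))]
    aa = state.sequence[pos]
    rot = state.rotamer_index[pos]
    mutate = (
        spec.classes[pos] == MUTABLE and rng.random() < config.p_mutation
    )
    if mutate:
        choices = [
            (a, r)
            for a in sorted(spec.allowed[pos])
            for r in range(library.n_rotamers(AA1_TO_AA3[a]))
            if (a, r) != (aa, rot)
        ]
    else:
        n_rot = library.n_rotamers(AA1_TO_AA3[aa])
        choices = [(aa, r) for r in range(n_rot) if r != rot]
    if not choices:  # no alternative exists: self-move
        return state
    new_aa, new_rot = choices[rng.integers(len(choices))]
    return state.with_change(pos, new_aa, new_rot)


def metropolis_accept(
    delta_e: float, kt: float, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, exp(-delta_e/kT))."""
    if kt <= 0:
        raise InvalidConfigError("kT must be positive")
    if delta_e <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_e / kt))


class _Walker:
    """One replica: current state, combo ids, and incremental energy."""

    def __init__(self, state, matrix, model, ff, mode, library, native):
        self.state = state
        self.matrix = matrix
        self.model = model
        self.ff = ff
        self.mode = mode
        self.library = library
        self.native = native
        self.e_unfolded = unfolded_energy(state.sequence, model)
        if matrix is not None:
            self.combo_ids = matrix.state_combos(state)
            self.e_folded = matrix.energy_of_combos(self.combo_ids)
        else:
            self.combo_ids = None
            self.e_folded = folded_energy(
                state, ff, mode, library, native
            ).total

    @property
    def delta(self) -> float:
        return self.e_folded - self.e_unfolded

    def propose(self, spec, config, rng):
        cand = propose_move(self.state, spec, self.library, config, rng)
        if cand is self.state:
            return cand, 0.0, None
        pos = next(
            i
            for i in range(len(self.state.sequence))
            if self.state.sequence[i] != cand.sequence[i]
            or self.state.rotamer_index[i] != cand.rotamer_index[i]
        )
        du = self.model.residue_term(
            cand.sequence[pos]
        ) - self.model.residue_term(self.state.sequence[pos])
        if self.matrix is not None:
            slot = self.matrix.positions.index(pos)
            new_c = self.matrix.combo_index[slot][
                (AA1_TO_AA3[cand.sequence[pos]], cand.rotamer_index[pos])
            ]
            df = self.matrix.delta(self.combo_ids, slot, new_c)
            return cand, df + du, (slot, new_c)
        df = (
            folded_energy(
                cand, self.ff, self.mode, self.library, self.native
            ).total
            - self.e_folded
        )
        return cand, df + du, None

    def apply(self, cand, delta_total, detail):
        du = unfolded_energy(cand.sequence, self.model) - self.e_unfolded
        self.e_folded += delta_total - du
        self.e_unfolded += du
        self.state = cand
        if detail is not None:
            slot, new_c = detail
            self.combo_ids[slot] = new_c


def run_design(
    scaffold: BackboneScaffold,
    spec: DesignSpec,
    library: RotamerLibrary,
    ff: ForceFieldParams,
    model: UnfoldedModel,
    mode: str,
    config: McConfig,
    track_visits: int = 0,
    log_path: str | Path | None = None,
) -> SequenceArchive:
    """Run the MC design and archive the best sequences.

    Fully reproducible from ``config.seed``.  ``track_visits=k`` records the
    visited (sequence, rotamer) state every k-th step (for sampling
    diagnostics); 0 disables tracking.  ``log_path`` writes one JSON line
    per proposal: step, replica, move type, delta_e, accepted.
    """
    if not spec.non_frozen_positions:
        raise NoMovesError("all positions are frozen")
    if mode == FDB and len(spec.non_frozen_positions) > _FDB_POSITION_WARN:
        warnings.warn(
            "FDB recomputes many-body Born radii each step; "
            f"> {_FDB_POSITION_WARN} design positions will be slow"
        )
    rng = np.random.default_rng(config.seed)
    matrix = (
        precompute_energy_matrix(scaffold, spec, library, ff)
        if mode == NEA
        else None
    )
    native = None
    kts = list(config.kt_ladder) if config.kt_ladder else [config.kt]
    walkers = [
        _Walker(
            initial_state(scaffold, spec), matrix, model, ff, mode,
            library, native,
        )
        for _ in kts
    ]

    best: dict[str, tuple[float, tuple[int, ...], int]] = {}
    visits: dict[tuple[str, tuple[int, ...]], int] = {}

    def archive(walker: _Walker, step: int):
        seq = walker.state.sequence
        d = walker.delta
        prev = best.get(seq)
        if prev is None:
            best[seq] = (d, walker.state.rotamer_index, step)
        elif d < prev[0]:
            best[seq] = (d, walker.state.rotamer_index, prev[2])

    for w in walkers:
        archive(w, 0)

    log = open(log_path, "w") if log_path is not None else None
    for step in range(1, config.n_steps + 1):
        for rep, (w, kt) in enumerate(zip(walkers, kts)):
            cand, delta_total, detail = w.propose(spec, config, rng)
            accepted = cand is not w.state and metropolis_accept(
                delta_total, kt, rng
            )
            if log is not None:
                move = (
                    "none"
                    if cand is w.state
                    else "mutation"
                    if cand.sequence != w.state.sequence
                    else "rotamer"
                )
                log.write(
                    json.dumps(
                        {
                            "step": step,
                            "replica": rep,
                            "move": move,
                            "delta_e": round(delta_total, 6),
                            "accepted": accepted,
                        }
                    )
                    + "\n"
                )
            if accepted:
                w.apply(cand, delta_total, detail)
                archive(w, step)
        if matrix is not None and step % 1000 == 0:
            for w in walkers:
                fresh = matrix.energy_of_combos(w.combo_ids)
                if abs(fresh - w.e_folded) > 1e-6:
                    raise PdzDesignError(
                        "incremental energy drifted from matrix "
                        f"reconstruction by {abs(fresh - w.e_folded):.2e}"
                    )
                w.e_folded = fresh
        if len(kts) > 1 and step % config.swap_interval == 0:
            for k in range(len(kts) - 1):
                a, b = walkers[k], walkers[k + 1]
                arg = (1.0 / kts[k] - 1.0 / kts[k + 1]) * (
                    b.delta - a.delta
                )
                if arg >= 0 or rng.random() < math.exp(arg):
                    walkers[k], walkers[k + 1] = b, a
        if track_visits and step % track_visits == 0:
            key = (
                walkers[0].state.sequence,
                walkers[0].state.rotamer_index,
            )
            visits[key] = visits.get(key, 0) + 1

    if log is not None:
        log.close()
    ordered = sorted(
        best.items(), key=lambda kv: (kv[1][0], kv[1][2])
    )[: config.archive_size]
    return SequenceArchive(
        entries=[
            ArchiveEntry(
                sequence=seq,
                energy=info[0],
                rotamers=info[1],
                first_seen_step=info[2],
            )
            for seq, info in ordered
        ],
        visits=visits if track_visits else None,
    )


def energy_window(archive: SequenceArchive, top_n: int) -> float:
    """Energy spread (max - min) among the top_n best archive entries."""
    if top_n < 1:
        raise InvalidConfigError("top_n must be >= 1")
    if not archive.entries:
        raise PdzDesignError("archive is empty")
    es = archive.energies()[:top_n]
    return float(es.max() - es.min())
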