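"""Side-chain topology, rotamer library, and full-atom state realization.

Side chains are united-atom (heavy atoms plus polar hydrogens).  Each atom
is placed by internal coordinates from the packaged topology table; chi
torsions come from the rotamer library or are passed explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .constants import AA1_TO_AA3, AA3_TO_AA1
from .errors import InvalidConfigError, PdzDesignError
from .geometry import place_atom
from .params import load_geometry
from .scaffold import BackboneScaffold, DesignSpec, FROZEN, MUTABLE

__all__ = [
    "ZRow",
    "ResidueTopology",
    "load_topology",
    "RotamerLibrary",
    "load_rotamer_library",
    "build_sidechain",
    "SystemState",
    "AtomSet",
    "realize_state",
]


@dataclass(frozen=True)
class ZRow:
    """One internal-coordinate row: place ``name`` from a1/a2/a3."""

    name: str
    atom_class: str
    charge: float
    a1: str
    a2: str
    a3: str
    bond: float
    angle: float
    chi: int | None  # 1-based chi index, or None
    dihedral: float | None  # fixed torsion if chi is None


@dataclass(frozen=True)
class ResidueTopology:
    name3: str
    rows: tuple[ZRow, ...]
    chis: tuple[tuple[str, str, str, str], ...]
    extra_bonds: tuple[tuple[str, str], ...]
    formal_charge: int

    @property
    def n_chi(self) -> int:
        return len(self.chis)

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rows)


@lru_cache(maxsize=None)
def load_topology() -> dict[str, ResidueTopology]:
    """Load the packaged per-residue side-chain topology table."""
    text = resources.files("pdzdesign.data").joinpath("topology.yaml")
    doc = yaml.safe_load(text.open())
    out = {}
    for name3, entry in doc["residues"].items():
        rows = []
        for r in entry["atoms"]:
            dih = r["dihedral"]
            rows.append(
                ZRow(
                    name=r["name"],
                    atom_class=r["class"],
                    charge=float(r["charge"]),
                    a1=r["a1"],
                    a2=r["a2"],
                    a3=r["a3"],
                    bond=float(r["bond"]),
                    angle=float(r["angle"]),
                    chi=dih.get("chi"),
                    dihedral=dih.get("value"),
                )
            )
        out[name3] = ResidueTopology(
            name3=name3,
            rows=tuple(rows),
            chis=tuple(tuple(q) for q in entry["chis"]),
            extra_bonds=tuple(tuple(b) for b in entry["extra_bonds"]),
            formal_charge=int(entry["formal_charge"]),
        )
    return out


@dataclass(frozen=True)
class RotamerLibrary:
    """Per-type chi-angle tuples (degrees); coarse, backbone-independent."""

    rotamers: dict[str, tuple[tuple[float, ...], ...]]

    def __post_init__(self):
        topo = load_topology()
        for name3, rots in self.rotamers.items():
            if not rots:
                raise PdzDesignError(f"{name3} has no rotamers")
            n_chi = topo[name3].n_chi
            for rot in rots:
                if len(rot) != n_chi:
                    raise PdzDesignError(
                        f"{name3} rotamer arity {len(rot)} != {n_chi}"
                    )
                if any(not (-180.0 < a <= 180.0) for a in rot):
                    raise PdzDesignError(
                        f"{name3} chi outside (-180, 180]: {rot}"
                    )

    def __getitem__(self, name3: str) -> tuple[tuple[float, ...], ...]:
        return self.rotamers[name3]

    def n_rotamers(self, name3: str) -> int:
        return len(self.rotamers[name3])


@lru_cache(maxsize=None)
def load_rotamer_library() -> RotamerLibrary:
    """Load the packaged canonical-well rotamer library."""
    text = resources.files("pdzdesign.data").joinpath("rotamers.csv")
    rots: dict[str, list[tuple[float, ...]]] = {}
    with text.open() as fh:
        for row in csv.DictReader(fh):
            chis = tuple(
                float(row[f"chi{k}"])
                for k in range(1, 5)
                if row[f"chi{k}"] != ""
            )
            rots.setdefault(row["type"], []).append(chis)
    return RotamerLibrary({k: tuple(v) for k, v in rots.items()})


def build_sidechain(
    scaffold: BackboneScaffold,
    position: int,
    name3: str,
    chi_angles: tuple[float, ...],
) -> dict[str, np.ndarray]:
    """Build side-chain coordinates for ``name3`` at a scaffold position.

    Atoms are placed sequentially from ideal internal coordinates with the
    requested chi torsions; measuring chi on the result reproduces the
    request to machine precision.  Returns a dict of side-chain atoms only.
    """
    if name3 == "GLY":
        raise InvalidConfigError("GLY has no side chain beyond HA")
    topo = load_topology()[name3]
    if len(chi_angles) != topo.n_chi:
        raise InvalidConfigError(
            f"{name3} needs {topo.n_chi} chi angles, got {len(chi_angles)}"
        )
    res = scaffold.residues[position]
    coords: dict[str, np.ndarray] = {
        "N": res.atoms["N"],
        "CA": res.atoms["CA"],
        "C": res.atoms["C"],
    }
    for row in topo.rows:
        dih = (
            chi_angles[row.chi - 1] if row.chi is not None else row.dihedral
        )
        coords[row.name] = place_atom(
            coords[row.a1], coords[row.a2], coords[row.a3],
            row.bond, row.angle, dih,
        )
    return {k: v for k, v in coords.items() if k not in ("N", "CA", "C")}


@dataclass(frozen=True)
class SystemState:
    """A point in design space: sequence plus rotamer index per position."""

    scaffold: BackboneScaffold
    sequence: str
    rotamer_index: tuple[int, ...]

    def __post_init__(self):
        n = len(self.scaffold)
        if len(self.sequence) != n or len(self.rotamer_index) != n:
            raise PdzDesignError("state length mismatch with scaffold")

    def validate(self, spec: DesignSpec, library: RotamerLibrary) -> None:
        for i, (cls, aa, rot) in enumerate(
            zip(spec.classes, self.sequence, self.rotamer_index)
        ):
            native = self.scaffold.residues[i].name1
            if cls == MUTABLE:
                if aa not in spec.allowed[i]:
                    raise PdzDesignError(
                        f"type {aa} not allowed at position {i}"
                    )
            elif aa != native:
                raise PdzDesignError(
                    f"position {i} is {cls} but carries {aa} != {native}"
                )
            n_rot = library.n_rotamers(AA1_TO_AA3[aa])
            if not 0 <= rot < n_rot:
                raise PdzDesignError(
                    f"rotamer index {rot} out of range at position {i}"
                )

    def with_change(self, position: int, aa: str, rot: int) -> "SystemState":
        seq = self.sequence[:position] + aa + self.sequence[position + 1:]
        rots = list(self.rotamer_index)
        rots[position] = rot
        return SystemState(self.scaffold, seq, tuple(rots))


def native_state(
    scaffold: BackboneScaffold, rotamer_index: int = 0
) -> SystemState:
    """The native-sequence reference state (rotamer 0 everywhere)."""
    return SystemState(
        scaffold, scaffold.sequence, (rotamer_index,) * len(scaffold)
    )


@dataclass
class AtomSet:
    """Realized full-atom coordinates with bookkeeping arrays."""

    names: list[str]
    res_index: np.ndarray  # scaffold position per atom (0-based)
    res_name3: list[str]
    coords: np.ndarray  # (n, 3)
    bonds: list[tuple[int, int]]
    is_backbone: np.ndarray  # bool per atom

    def __len__(self) -> int:
        return len(self.names)


_BB_ANGLE_H = 119.0  # H-N-C(prev) / H-N-CA angle used for amide H placement


def _backbone_hydrogen(
    scaffold: BackboneScaffold, position: int
) -> np.ndarray:
    geo = load_geometry()
    res = scaffold.residues[position]
    n_h = geo["bonds"]["N-H"]
    if position == 0:
        return place_atom(
            res.atoms["N"], res.atoms["CA"], res.atoms["C"],
            n_h, _BB_ANGLE_H, 180.0,
        )
    prev = scaffold.residues[position - 1]
    return place_atom(
        res.atoms["N"], prev.atoms["C"], prev.atoms["CA"],
        n_h, _BB_ANGLE_H, 180.0,
    )


def realize_state(state: SystemState, library: RotamerLibrary) -> AtomSet:
    """Build the full-atom coordinate set for a state.

    Backbone coordinates are taken verbatim from the scaffold (with amide
    hydrogens placed by ideal geometry); each side chain is built from its
    type and rotamer.
    """
    topo = load_topology()
    names: list[str] = []
    res_index: list[int] = []
    res_name3: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    is_bb: list[bool] = []
    index: dict[tuple[int, str], int] = {}

    def add(pos: int, name: str, xyz: np.ndarray, name3: str, bb: bool):
        index[(pos, name)] = len(names)
        names.append(name)
        res_index.append(pos)
        res_name3.append(name3)
        coords.append(np.asarray(xyz, dtype=float))
        is_bb.append(bb)

    for pos, (res, aa, rot) in enumerate(
        zip(state.scaffold.residues, state.sequence, state.rotamer_index)
    ):
        name3 = AA1_TO_AA3[aa]
        add(pos, "N", res.atoms["N"], name3, True)
        if name3 != "PRO":
            add(pos, "H", _backbone_hydrogen(state.scaffold, pos), name3, True)
            bonds.append((index[(pos, "N")], index[(pos, "H")]))
        add(pos, "CA", res.atoms["CA"], name3, True)
        add(pos, "C", res.atoms["C"], name3, True)
        add(pos, "O", res.atoms["O"], name3, True)
        bonds.append((index[(pos, "N")], index[(pos, "CA")]))
        bonds.append((index[(pos, "CA")], index[(pos, "C")]))
        bonds.append((index[(pos, "C")], index[(pos, "O")]))
        if pos > 0:
            bonds.append((index[(pos - 1, "C")], index[(pos, "N")]))
        if name3 != "GLY":
            chis = library[name3][rot]
            side = build_sidechain(state.scaffold, pos, name3, chis)
            for row in topo[name3].rows:
                add(pos, row.name, side[row.name], name3, False)
                bonds.append((index[(pos, row.a1)], index[(pos, row.name)]))
            for a, b in topo[name3].extra_bonds:
                bonds.append((index[(pos, a)], index[(pos, b)]))

    return AtomSet(
        names=names,
        res_index=np.array(res_index, dtype=int),
        res_name3=res_name3,
        coords=np.array(coords),
        bonds=bonds,
        is_backbone=np.array(is_bb, dtype=bool),
    )
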