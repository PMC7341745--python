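"""Backbone scaffolds, design specifications and sequence-space bookkeeping.

A scaffold is an immutable single-chain backbone (N/CA/C/O per residue) with
a native sequence.  A design spec classifies every position as mutable (free
to change type and rotamer), rotamer-only (wild-type identity kept, e.g.
ligand-contact positions) or frozen (native Gly/Pro), and lists the allowed
types per mutable position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .constants import AA3_TO_AA1, DESIGN_ALPHABET
from .errors import MissingAtomError, PdbParseError, PdzDesignError

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "BACKBONE_ATOMS",
    "Residue",
    "BackboneScaffold",
    "DesignSpec",
    "read_pdb",
    "write_pdb",
    "make_design_spec",
    "sequence_space_size",
]


@dataclass(frozen=True)
class Residue:
    """One residue of a scaffold: author numbering, type, backbone coords."""

    res_id: int
    name3: str
    atoms: dict[str, np.ndarray]  # N, CA, C, O -> (3,) float

    @property
    def name1(self) -> str:
        return AA3_TO_AA1[self.name3]


@dataclass(frozen=True)
class BackboneScaffold:
    """Fixed backbone of a single-chain protein.

    The backbone never changes after construction; side chains are built on
    top of it by the sidechain module.
    """

    residues: tuple[Residue, ...]
    chain_id: str = "A"

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.name1 for r in self.residues)

    @property
    def res_ids(self) -> tuple[int, ...]:
        return tuple(r.res_id for r in self.residues)

    def validate(self) -> None:
        if not self.residues:
            raise PdzDesignError("scaffold has no residues")
        ids = self.res_ids
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise PdzDesignError("residue ids are not strictly increasing")
        for res in self.residues:
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    raise MissingAtomError(
                        f"residue {res.res_id} ({res.name3}) lacks backbone "
                        f"atom {name}"
                    )
        for a, b in zip(self.residues, self.residues[1:]):
            d = float(np.linalg.norm(b.atoms["N"] - a.atoms["C"]))
            if d >= 2.0:
                raise PdzDesignError(
                    f"chain break: C({a.res_id})-N({b.res_id}) = {d:.2f} A"
                )

    def backbone_coords(self) -> np.ndarray:
        """(n_residues, 4, 3) array in N/CA/C/O order."""
        return np.array(
            [[r.atoms[a] for a in BACKBONE_ATOMS] for r in self.residues]
        )

    def coords_close(self, other: "BackboneScaffold", tol: float = 1e-3) -> bool:
        if self.sequence != other.sequence or self.res_ids != other.res_ids:
            return False
        return bool(
            np.all(
                np.abs(self.backbone_coords() - other.backbone_coords()) <= tol
            )
        )


def _to_atom_array(scaffold: BackboneScaffold) -> struc.AtomArray:
    n = 4 * len(scaffold)
    arr = struc.AtomArray(n)
    i = 0
    for res in scaffold.residues:
        for name in BACKBONE_ATOMS:
            arr.coord[i] = res.atoms[name]
            arr.atom_name[i] = name
            arr.element[i] = name[0]
            arr.res_id[i] = res.res_id
            arr.res_name[i] = res.name3
            arr.chain_id[i] = scaffold.chain_id
            arr.hetero[i] = False
            i += 1
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_pdb(scaffold: BackboneScaffold, path: str | Path) -> None:
    """Write the backbone as single-chain ATOM records (occupancy 1.00)."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array(scaffold))
    pdb_file.write(str(path))


def read_pdb(
    path: str | Path,
    chain: str | None = None,
    model: int = 1,
) -> BackboneScaffold:
    """Read a backbone scaffold from a PDB file.

    Keeps the first model and the first chain unless overridden; where
    alternate locations exist, altloc "A" (or blank) is retained.  Insertion
    codes are rejected.  A residue missing any of N/CA/C/O raises
    :class:`MissingAtomError` naming the residue.
    """
    path = Path(path)
    if not path.exists():
        raise PdbParseError(f"no such file: {path}")
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        arr = pdb_file.get_structure(
            model=model, altloc="all", extra_fields=["occupancy"]
        )
    except Exception as exc:  # no ATOM records, bad model index, ...
        raise PdbParseError(f"could not parse {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PdbParseError(f"{path} contains no ATOM records")
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise PdbParseError(f"{path} contains no polymer ATOM records")
    if "altloc_id" in arr.get_annotation_categories():
        keep = np.isin(arr.altloc_id, (".", "", " ", "A"))
        arr = arr[keep]
    if np.any(arr.ins_code != ""):
        raise PdbParseError(f"{path} uses insertion codes (unsupported)")
    chain_id = chain if chain is not None else str(arr.chain_id[0])
    arr = arr[arr.chain_id == chain_id]
    if arr.array_length() == 0:
        raise PdbParseError(f"chain {chain_id!r} not found in {path}")

    residues: list[Residue] = []
    for res_id in np.unique(arr.res_id):
        sub = arr[arr.res_id == res_id]
        name3 = str(sub.res_name[0])
        if name3 not in AA3_TO_AA1:
            raise PdbParseError(
                f"residue {int(res_id)} has unknown type {name3}"
            )
        atoms = {}
        for name in BACKBONE_ATOMS:
            hit = sub[sub.atom_name == name]
            if hit.array_length() == 0:
                raise MissingAtomError(
                    f"residue {int(res_id)} ({name3}) lacks backbone "
                    f"atom {name}"
                )
            atoms[name] = hit.coord[0].astype(float)
        residues.append(Residue(int(res_id), name3, atoms))
    return BackboneScaffold(tuple(residues), chain_id=chain_id)


# position classes
MUTABLE = "mutable"
ROTAMER_ONLY = "rotamer_only"
FROZEN = "frozen"


@dataclass(frozen=True)
class DesignSpec:
    """Per-position mutability classes and allowed types.

    ``classes[i]`` is one of {mutable, rotamer_only, frozen};
    ``allowed[i]`` is a frozenset of one-letter codes for mutable positions
    and None otherwise.
    """

    classes: tuple[str, ...]
    allowed: tuple[frozenset | None, ...]
    native_sequence: str = ""

    def __post_init__(self):
        if len(self.classes) != len(self.allowed):
            raise PdzDesignError("classes/allowed length mismatch")
        if self.native_sequence and len(self.native_sequence) != len(
            self.classes
        ):
            raise PdzDesignError("native sequence length mismatch")
        for i, (cls, types) in enumerate(zip(self.classes, self.allowed)):
            if cls not in (MUTABLE, ROTAMER_ONLY, FROZEN):
                raise PdzDesignError(f"unknown class {cls!r} at {i}")
            if cls == MUTABLE:
                if not types:
                    raise PdzDesignError(f"mutable position {i} allows nothing")
                bad = set(types) & {"G", "P"}
                if bad:
                    raise PdzDesignError(
                        f"Gly/Pro allowed at mutable position {i}: {bad}"
                    )
            elif types is not None:
                raise PdzDesignError(
                    f"non-mutable position {i} must have allowed=None"
                )

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def mutable_positions(self) -> tuple[int, ...]:
        return tuple(
            i for i, c in enumerate(self.classes) if c == MUTABLE
        )

    @property
    def non_frozen_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.classes) if c != FROZEN)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "native_sequence": self.native_sequence,
            "positions": [
                {
                    "class": cls,
                    "allowed": sorted(types) if types else None,
                }
                for cls, types in zip(self.classes, self.allowed)
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignSpec":
        doc = yaml.safe_load(Path(path).read_text())
        classes = tuple(p["class"] for p in doc["positions"])
        allowed = tuple(
            frozenset(p["allowed"]) if p["allowed"] else None
            for p in doc["positions"]
        )
        return cls(classes, allowed, doc.get("native_sequence", ""))


def make_design_spec(
    scaffold: BackboneScaffold,
    interface_ids: set[int] = frozenset(),
    extra_frozen: set[int] = frozenset(),
) -> DesignSpec:
    """Build the standard redesign spec for a scaffold.

    Native Gly/Pro positions are frozen; interface residues (given by author
    residue id) keep wild-type identity but explore rotamers; every other
    position may mutate to any of the 18 non-Gly/Pro types.
    """
    known = set(scaffold.res_ids)
    offenders = sorted((set(interface_ids) | set(extra_frozen)) - known)
    if offenders:
        raise PdzDesignError(f"unknown residue ids: {offenders}")
    classes: list[str] = []
    allowed: list[frozenset | None] = []
    for res in scaffold.residues:
        if res.name1 in "GP" or res.res_id in extra_frozen:
            classes.append(FROZEN)
            allowed.append(None)
        elif res.res_id in interface_ids:
            classes.append(ROTAMER_ONLY)
            allowed.append(None)
        else:
            classes.append(MUTABLE)
            allowed.append(frozenset(DESIGN_ALPHABET))
    return DesignSpec(
        tuple(classes), tuple(allowed), native_sequence=scaffold.sequence
    )


def sequence_space_size(spec: DesignSpec) -> int:
    """Exact number of sequences the spec admits (arbitrary precision)."""
    size = 1
    for types in spec.allowed:
        if types is not None:
            size *= len(types)
    return size
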