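"""Packaged parameter tables: force field, ideal geometry, pKa set.

The force-field table is a deliberately reduced, self-contained set (one LJ/
GB/surface-tension entry per united-atom class, integer-summing partial
charges per residue).  Its role is structural and algorithmic fidelity, not
force-field accuracy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

__all__ = [
    "AtomClass",
    "ForceFieldParams",
    "load_forcefield",
    "load_geometry",
    "load_pka",
]


@dataclass(frozen=True)
class AtomClass:
    """Nonbonded parameters for one united-atom class."""

    sigma: float  # LJ sigma, Angstrom
    epsilon: float  # LJ well depth, kcal/mol
    gb_radius: float  # intrinsic Born radius, Angstrom
    surface_tension: float  # kcal/mol/A^2


@dataclass(frozen=True)
class ForceFieldParams:
    """Global constants plus the per-class nonbonded table.

    eps_protein is the protein interior dielectric (dimensionless, default
    4), eps_water the solvent dielectric (80).  coulomb_k is the
    electrostatic constant in kcal*A/mol/e^2.  1-4 interactions are scaled
    by scale14_lj / scale14_coulomb; hct_scale is the uniform descreening
    scale factor applied to neighbour radii in the pairwise Born integral.
    """

    classes: dict[str, AtomClass] = field(default_factory=dict)
    eps_protein: float = 4.0
    eps_water: float = 80.0
    probe_radius: float = 1.4
    coulomb_k: float = 332.0636
    scale14_lj: float = 0.5
    scale14_coulomb: float = 1.0 / 1.2
    hct_scale: float = 0.8

    def __post_init__(self):
        if self.eps_protein < 1.0:
            raise ValueError("eps_protein must be >= 1")
        if self.eps_water <= self.eps_protein:
            raise ValueError("eps_water must exceed eps_protein")
        for name, cls in self.classes.items():
            if min(cls.sigma, cls.epsilon, cls.gb_radius) <= 0:
                raise ValueError(f"non-positive parameter for class {name}")


def _data(name: str):
    return resources.files("pdzdesign.data").joinpath(name)


@lru_cache(maxsize=None)
def load_forcefield(eps_protein: float = 4.0) -> ForceFieldParams:
    """Load the packaged reduced force-field table."""
    classes = {}
    with _data("atom_classes.csv").open() as fh:
        for row in csv.DictReader(fh):
            classes[row["class"]] = AtomClass(
                sigma=float(row["sigma"]),
                epsilon=float(row["epsilon"]),
                gb_radius=float(row["gb_radius"]),
                surface_tension=float(row["surface_tension"]),
            )
    return ForceFieldParams(classes=classes, eps_protein=eps_protein)


@lru_cache(maxsize=None)
def load_geometry() -> dict:
    """Ideal backbone covalent geometry and secondary-structure presets."""
    with _data("geometry.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def load_pka() -> dict:
    """EMBOSS-style pKa set for net-charge / pI estimation."""
    with _data("pka.yaml").open() as fh:
        return yaml.safe_load(fh)
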