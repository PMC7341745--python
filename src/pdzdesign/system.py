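"""Assignment of nonbonded parameters and exclusions to realized atoms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ForceFieldParams, load_geometry
from .sidechain import AtomSet, load_topology

__all__ = ["ParamSet", "parameterize"]


@dataclass
class ParamSet:
    """Per-atom nonbonded parameters and pair scale matrices.

    ``lj_scale``/``coul_scale`` are dense (n, n) matrices: 0 for bonded
    (1-2, 1-3) pairs and self, the packaged 1-4 factors for 1-4 pairs, and
    1 otherwise.
    """

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    rho: np.ndarray  # intrinsic Born radius
    tension: np.ndarray  # surface tension coefficient
    lj_scale: np.ndarray
    coul_scale: np.ndarray


def _atom_class_and_charge(atoms: AtomSet) -> tuple[list[str], np.ndarray]:
    geo = load_geometry()
    topo = load_topology()
    classes: list[str] = []
    charges = np.zeros(len(atoms))
    side = {
        name3: {row.name: (row.atom_class, row.charge) for row in t.rows}
        for name3, t in topo.items()
    }
    for i, (name, name3) in enumerate(zip(atoms.names, atoms.res_name3)):
        if atoms.is_backbone[i]:
            if name3 == "PRO":
                q = geo["backbone_charges_pro"][name]
            else:
                q = geo["backbone_charges"][name]
            if name == "CA" and name3 == "GLY":
                cls = geo["backbone_classes_gly"]["CA"]
            else:
                cls = geo["backbone_classes"][name]
        else:
            cls, q = side[name3][name]
        classes.append(cls)
        charges[i] = q
    return classes, charges


def _bond_distance_pairs(n: int, bonds) -> dict[tuple[int, int], int]:
    """Topological distances up to 3 bonds, as {(i<j): distance}."""
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    dist: dict[tuple[int, int], int] = {}
    for i in range(n):
        frontier = {i}
        seen = {i}
        for d in (1, 2, 3):
            frontier = {k for j in frontier for k in adj[j]} - seen
            seen |= frontier
            for j in frontier:
                if i < j:
                    key = (i, j)
                    if key not in dist:
                        dist[key] = d
    return dist


def parameterize(atoms: AtomSet, params: ForceFieldParams) -> ParamSet:
    """Assign class parameters and build pair scale matrices."""
    classes, charge = _atom_class_and_charge(atoms)
    table = params.classes
    sigma = np.array([table[c].sigma for c in classes])
    epsilon = np.array([table[c].epsilon for c in classes])
    rho = np.array([table[c].gb_radius for c in classes])
    tension = np.array([table[c].surface_tension for c in classes])

    n = len(atoms)
    lj_scale = np.ones((n, n))
    coul_scale = np.ones((n, n))
    np.fill_diagonal(lj_scale, 0.0)
    np.fill_diagonal(coul_scale, 0.0)
    for (i, j), d in _bond_distance_pairs(n, atoms.bonds).items():
        if d <= 2:
            lj_scale[i, j] = lj_scale[j, i] = 0.0
            coul_scale[i, j] = coul_scale[j, i] = 0.0
        else:  # 1-4
            lj_scale[i, j] = lj_scale[j, i] = params.scale14_lj
            coul_scale[i, j] = coul_scale[j, i] = params.scale14_coulomb
    return ParamSet(
        charge=charge,
        sigma=sigma,
        epsilon=epsilon,
        rho=rho,
        tension=tension,
        lj_scale=lj_scale,
        coul_scale=coul_scale,
    )
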