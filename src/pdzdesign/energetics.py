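"""Folded-state energy: molecular mechanics + Generalized Born + surface.

The energy of a realized state is

    E = E_LJ + E_Coulomb(eps_P) + E_GB + E_surf

with Still's analytic Generalized Born form over Hawkins-Cramer-Truhlar
(HCT) pairwise-descreened Born radii, and a nonpolar term built from atomic
surface tensions times analytic pairwise spherical-cap areas (exactly
pairwise-decomposable, which is what makes the NEA energy matrix exact).

Two solvation modes are provided:

* ``FDB`` (fluctuating dielectric boundary): Born radii are recomputed from
  the current state's atoms, preserving the many-body character of GB.
* ``NEA`` (native environment approximation): every atom sees a dielectric
  environment frozen at the native structure.  Backbone atoms keep their
  native radii verbatim; a designed side-chain atom is descreened against
  its own residue's current atoms plus the native atoms of all other
  residues.  This makes the total energy an exact sum of one- and two-body
  terms, precomputed by :func:`precompute_energy_matrix`.

The exact Shrake-Rupley surface (:func:`sasa`) is retained for geometric
queries (e.g. cavity work); the energy uses the cap model in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    PdzDesignError,
    UnsupportedModeError,
)
from .params import ForceFieldParams, load_geometry
from .scaffold import BackboneScaffold, DesignSpec, FROZEN
from .sidechain import (
    AtomSet,
    RotamerLibrary,
    SystemState,
    build_sidechain,
    load_rotamer_library,
    load_topology,
    native_state,
    realize_state,
)
from .system import ParamSet, parameterize, _bond_distance_pairs

__all__ = [
    "EnergyBreakdown",
    "BornRadiiSet",
    "EnergyMatrix",
    "Realized",
    "realize",
    "lj_energy",
    "hct_inverse_radius_terms",
    "born_radii",
    "gb_polarization_energy",
    "sasa",
    "folded_energy",
    "precompute_energy_matrix",
]

NEA = "NEA"
FDB = "FDB"

_B_MAX = 1000.0  # ceiling on effective Born radii (deep-burial guard)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Folded-state energy components in kcal/mol."""

    lj: float
    coulomb: float
    gb_polarization: float
    nonpolar_surface: float
    total: float

    def __post_init__(self):
        s = self.lj + self.coulomb + self.gb_polarization + self.nonpolar_surface
        if abs(s - self.total) > 1e-9:
            raise PdzDesignError("energy components do not sum to total")

    @classmethod
    def from_components(cls, lj, coulomb, gb, surf) -> "EnergyBreakdown":
        return cls(lj, coulomb, gb, surf, lj + coulomb + gb + surf)


@dataclass(frozen=True)
class BornRadiiSet:
    """Per-atom effective Born radii with provenance (NEA-frozen vs
    FDB-current)."""

    radii: np.ndarray
    provenance: str

    def __post_init__(self):
        if np.any(~np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise PdzDesignError("Born radii must be finite and positive")


@dataclass
class Realized:
    """A realized state: atoms plus assigned nonbonded parameters."""

    atoms: AtomSet
    pset: ParamSet


def realize(
    state: SystemState,
    ff: ForceFieldParams,
    library: RotamerLibrary | None = None,
) -> Realized:
    library = library or load_rotamer_library()
    atoms = realize_state(state, library)
    return Realized(atoms=atoms, pset=parameterize(atoms, ff))


# ---------------------------------------------------------------------------
# elementary terms


def lj_energy(
    sigma_i: float,
    eps_i: float,
    sigma_j: float,
    eps_j: float,
    r: float,
) -> float:
    """Lennard-Jones pair energy with Lorentz-Berthelot combining."""
    if r <= 0:
        raise DegenerateGeometryError("LJ requires r > 0")
    sigma = 0.5 * (sigma_i + sigma_j)
    eps = np.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    return float(4.0 * eps * (sr6 * sr6 - sr6))


def hct_inverse_radius_terms(
    d: np.ndarray, rho_i: float, a: np.ndarray
) -> np.ndarray:
    """HCT descreening integrals: reduction of atom i's inverse Born radius
    by neighbour spheres of (scaled) radius ``a`` at distances ``d``.

    This is the closed form of (1/4pi) * integral of 1/s^4 over the part of
    each neighbour sphere lying outside the core radius ``rho_i``.
    """
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(d < 1e-6):
        raise DegenerateGeometryError("coincident atoms in Born integral")
    U = d + a
    L = np.maximum(rho_i, np.abs(d - a))
    with np.errstate(divide="ignore", invalid="ignore"):
        band = (
            0.5 * (1.0 / L - 1.0 / U)
            - np.log(U / L) / (4.0 * d)
            + (d * d - a * a) / (8.0 * d) * (1.0 / U**2 - 1.0 / L**2)
        )
    # core entirely inside the neighbour sphere: add the full-shell part
    inner = a - d
    full = np.where(
        inner > rho_i, 1.0 / rho_i - 1.0 / np.maximum(inner, 1e-12), 0.0
    )
    out = np.where(U > rho_i, band + full, 0.0)
    return out


def _hct_radii(
    coords: np.ndarray,
    rho: np.ndarray,
    env_coords: np.ndarray,
    env_rho_scaled: np.ndarray,
    skip_self: bool,
) -> np.ndarray:
    """Born radii of ``coords`` descreened by an environment."""
    radii = np.empty(len(coords))
    for i, (x, rho_i) in enumerate(zip(coords, rho)):
        d = np.linalg.norm(env_coords - x, axis=1)
        if skip_self:
            mask = d > 1e-6
            if (len(d) - mask.sum()) > 1:
                raise DegenerateGeometryError(
                    "multiple atoms share one position"
                )
            d = d[mask]
            a = env_rho_scaled[mask]
        else:
            if np.any(d < 1e-6):
                raise DegenerateGeometryError(
                    "environment atom coincides with query atom"
                )
            a = env_rho_scaled
        inv = 1.0 / rho_i - np.sum(hct_inverse_radius_terms(d, rho_i, a))
        radii[i] = 1.0 / max(inv, 1.0 / _B_MAX)
    return radii


def born_radii(
    realized: Realized,
    ff: ForceFieldParams,
    mode: str = FDB,
    native: Realized | None = None,
) -> BornRadiiSet:
    """Effective Born radii for every atom of a realized state.

    FDB descreens each atom against all other atoms of the current state.
    NEA freezes the dielectric environment at the native structure (see
    module docstring); it requires ``native``.
    """
    atoms, pset = realized.atoms, realized.pset
    if mode == FDB:
        radii = _hct_radii(
            atoms.coords,
            pset.rho,
            atoms.coords,
            ff.hct_scale * pset.rho,
            skip_self=True,
        )
        return BornRadiiSet(radii, provenance="FDB-current")
    if mode != NEA:
        raise UnsupportedModeError(f"unknown solvation mode {mode!r}")
    if native is None:
        raise PdzDesignError("NEA mode requires the native realized state")

    nat_atoms, nat_pset = native.atoms, native.pset
    nat_b = _hct_radii(
        nat_atoms.coords,
        nat_pset.rho,
        nat_atoms.coords,
        ff.hct_scale * nat_pset.rho,
        skip_self=True,
    )
    nat_index = {
        (int(r), n): k
        for k, (r, n) in enumerate(zip(nat_atoms.res_index, nat_atoms.names))
    }
    radii = np.empty(len(atoms))
    for res in np.unique(atoms.res_index):
        own = atoms.res_index == res
        others_nat = nat_atoms.res_index != res
        env_coords = np.vstack(
            [atoms.coords[own], nat_atoms.coords[others_nat]]
        )
        env_rho = np.concatenate(
            [pset.rho[own], nat_pset.rho[others_nat]]
        )
        idx = np.where(own)[0]
        sub = _hct_radii(
            atoms.coords[own],
            pset.rho[own],
            env_coords,
            ff.hct_scale * env_rho,
            skip_self=True,
        )
        for local, k in enumerate(idx):
            if atoms.is_backbone[k]:
                radii[k] = nat_b[nat_index[(int(res), atoms.names[k])]]
            else:
                radii[k] = sub[local]
    return BornRadiiSet(radii, provenance="NEA-frozen")


def _f_gb(r2: np.ndarray, bi: np.ndarray, bj: np.ndarray) -> np.ndarray:
    bb = bi * bj
    return np.sqrt(r2 + bb * np.exp(-r2 / (4.0 * bb)))


def gb_polarization_energy(
    charges: np.ndarray,
    coords: np.ndarray,
    born: BornRadiiSet,
    ff: ForceFieldParams,
) -> float:
    """Still-form GB polarization energy, self terms included."""
    q = np.asarray(charges, dtype=float)
    x = np.asarray(coords, dtype=float)
    b = born.radii
    if len(q) != len(b):
        raise PdzDesignError("Born radii inconsistent with atom count")
    pref = -0.5 * ff.coulomb_k * (1.0 / ff.eps_protein - 1.0 / ff.eps_water)
    diff = x[:, None, :] - x[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    fgb = _f_gb(r2, b[:, None], b[None, :])
    return float(pref * np.sum(np.outer(q, q) / fgb))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface areas (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise PdzDesignError("radii must be positive")
    pts = _sphere_points(n_points)
    ext = radii + probe
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        surf = coords[i] + ext[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d < 1e-9:
                # coincident duplicates: the union area is credited to the
                # lowest-index copy (deterministic tie-break)
                if j < i and ext[j] >= ext[i]:
                    exposed[:] = False
                    break
                continue
            if d >= ext[i] + ext[j]:
                continue
            exposed &= (
                np.linalg.norm(surf - coords[j], axis=1) >= ext[j]
            )
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * exposed.mean()
    return areas


def _cap_matrix(
    xi: np.ndarray, Ri: np.ndarray, xj: np.ndarray, Rj: np.ndarray
) -> np.ndarray:
    """cap[i, j]: area of sphere i buried inside sphere j (analytic lens)."""
    diff = xi[:, None, :] - xj[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    d = np.maximum(d, 1e-9)
    h = Ri[:, None] - (d * d + Ri[:, None] ** 2 - Rj[None, :] ** 2) / (2 * d)
    h = np.clip(h, 0.0, 2.0 * Ri[:, None])
    h[d >= Ri[:, None] + Rj[None, :]] = 0.0
    return 2.0 * np.pi * Ri[:, None] * h


# ---------------------------------------------------------------------------
# full-state energy


def _pair_sums(realized: Realized, born: BornRadiiSet, ff: ForceFieldParams):
    """All pair + self sums for one realized state; returns the breakdown."""
    x = realized.atoms.coords
    p = realized.pset
    n = len(x)
    diff = x[:, None, :] - x[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    np.fill_diagonal(r2, 1.0)
    r = np.sqrt(r2)
    iu = np.triu_indices(n, k=1)
    if np.any(r[iu] < 1e-6):
        raise DegenerateGeometryError("coincident atoms in energy evaluation")

    sig = 0.5 * (p.sigma[:, None] + p.sigma[None, :])
    eps = np.sqrt(p.epsilon[:, None] * p.epsilon[None, :])
    sr6 = (sig / r) ** 6
    lj = float(np.sum((p.lj_scale * 4.0 * eps * (sr6 * sr6 - sr6))[iu]))

    qq = np.outer(p.charge, p.charge)
    coul = float(
        ff.coulomb_k / ff.eps_protein * np.sum((p.coul_scale * qq / r)[iu])
    )

    b = born.radii
    pref = -0.5 * ff.coulomb_k * (1.0 / ff.eps_protein - 1.0 / ff.eps_water)
    fgb = _f_gb(r2, b[:, None], b[None, :])
    np.fill_diagonal(fgb, b)
    gb = float(pref * np.sum(qq / fgb))

    R = p.rho + ff.probe_radius
    caps = _cap_matrix(x, R, x, R)
    np.fill_diagonal(caps, 0.0)
    area = 4.0 * np.pi * R * R - caps.sum(axis=1)
    surf = float(np.sum(p.tension * area))
    return lj, coul, gb, surf


def folded_energy(
    state: SystemState,
    ff: ForceFieldParams,
    mode: str = FDB,
    library: RotamerLibrary | None = None,
    native: SystemState | None = None,
) -> EnergyBreakdown:
    """Physics-based folded-state energy of a design state."""
    library = library or load_rotamer_library()
    realized = realize(state, ff, library)
    if mode == NEA:
        nat = native or native_state(state.scaffold)
        nat_real = realize(nat, ff, library)
        born = born_radii(realized, ff, NEA, native=nat_real)
    elif mode == FDB:
        born = born_radii(realized, ff, FDB)
    else:
        raise UnsupportedModeError(f"unknown solvation mode {mode!r}")
    lj, coul, gb, surf = _pair_sums(realized, born, ff)
    return EnergyBreakdown.from_components(lj, coul, gb, surf)


# ---------------------------------------------------------------------------
# NEA energy matrix


@dataclass
class EnergyMatrix:
    """Exact one/two-body decomposition of the NEA folded energy.

    ``combos[p]`` lists the (type, rotamer) choices of design position p;
    ``self_terms[p][c]`` and ``pair_terms[(p, q)][c, c']`` are kcal/mol.
    Reconstruction: E = e_bb + sum_p self + sum_{p<q} pair.
    """

    positions: tuple[int, ...]
    combos: list[list[tuple[str, int]]]
    e_bb: float
    self_terms: list[np.ndarray]
    pair_terms: dict[tuple[int, int], np.ndarray]
    combo_index: list[dict[tuple[str, int], int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.combo_index:
            self.combo_index = [
                {c: k for k, c in enumerate(cs)} for cs in self.combos
            ]

    def pair(self, p: int, q: int) -> np.ndarray:
        """Symmetric access to the (p, q) block."""
        if p < q:
            return self.pair_terms[(p, q)]
        return self.pair_terms[(q, p)].T

    def state_combos(self, state: SystemState) -> list[int]:
        from .constants import AA1_TO_AA3

        out = []
        for k, pos in enumerate(self.positions):
            key = (AA1_TO_AA3[state.sequence[pos]], state.rotamer_index[pos])
            out.append(self.combo_index[k][key])
        return out

    def energy_of_combos(self, combo_ids: list[int]) -> float:
        e = self.e_bb
        for k, c in enumerate(combo_ids):
            e += self.self_terms[k][c]
        for k in range(len(combo_ids)):
            for m in range(k + 1, len(combo_ids)):
                e += self.pair_terms[(k, m)][combo_ids[k], combo_ids[m]]
        return float(e)

    def energy(self, state: SystemState) -> float:
        return self.energy_of_combos(self.state_combos(state))

    def delta(
        self, combo_ids: list[int], k: int, new_c: int
    ) -> float:
        """Energy change for switching design slot k to combo new_c."""
        old_c = combo_ids[k]
        d = self.self_terms[k][new_c] - self.self_terms[k][old_c]
        for m in range(len(combo_ids)):
            if m == k:
                continue
            block = self.pair(k, m)
            d += block[new_c, combo_ids[m]] - block[old_c, combo_ids[m]]
        return float(d)


def _group_pair_terms(
    xa, qa, sa, ea, Ra, ta, ba,
    xb, qb, sb, eb, Rb, tb, bb,
    lj_scale, coul_scale, ff,
) -> float:
    """Sum of all pair terms between atom group a and atom group b."""
    diff = xa[:, None, :] - xb[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    r = np.sqrt(np.maximum(r2, 1e-12))
    sig = 0.5 * (sa[:, None] + sb[None, :])
    eps = np.sqrt(ea[:, None] * eb[None, :])
    sr6 = (sig / r) ** 6
    lj = np.sum(lj_scale * 4.0 * eps * (sr6 * sr6 - sr6))
    qq = qa[:, None] * qb[None, :]
    coul = ff.coulomb_k / ff.eps_protein * np.sum(coul_scale * qq / r)
    pref = -0.5 * ff.coulomb_k * (1.0 / ff.eps_protein - 1.0 / ff.eps_water)
    gb = pref * 2.0 * np.sum(qq / _f_gb(r2, ba[:, None], bb[None, :]))
    d = np.maximum(r, 1e-9)
    ha = Ra[:, None] - (d * d + Ra[:, None] ** 2 - Rb[None, :] ** 2) / (2 * d)
    ha = np.clip(ha, 0.0, 2.0 * Ra[:, None])
    ha[d >= Ra[:, None] + Rb[None, :]] = 0.0
    hb = Rb[None, :] - (d * d + Rb[None, :] ** 2 - Ra[:, None] ** 2) / (2 * d)
    hb = np.clip(hb, 0.0, 2.0 * Rb[None, :])
    hb[d >= Ra[:, None] + Rb[None, :]] = 0.0
    surf = -np.sum(
        ta[:, None] * 2.0 * np.pi * Ra[:, None] * ha
        + tb[None, :] * 2.0 * np.pi * Rb[None, :] * hb
    )
    return float(lj + coul + gb + surf)


def precompute_energy_matrix(
    scaffold: BackboneScaffold,
    spec: DesignSpec,
    library: RotamerLibrary,
    ff: ForceFieldParams,
    mode: str = NEA,
) -> EnergyMatrix:
    """Precompute the pairwise NEA energy decomposition.

    Only the NEA mode is decomposable (FDB Born radii couple all positions);
    requesting FDB raises :class:`UnsupportedModeError`.  Frozen positions
    are assumed to carry their native type and rotamer 0 and are folded into
    the constant term.
    """
    from .constants import AA1_TO_AA3

    if mode == FDB:
        raise UnsupportedModeError(
            "FDB is many-body; no pairwise decomposition exists"
        )
    if mode != NEA:
        raise UnsupportedModeError(f"unknown solvation mode {mode!r}")

    topo = load_topology()
    nat = native_state(scaffold)
    nat_real = realize(nat, ff, library)
    nat_atoms, nat_pset = nat_real.atoms, nat_real.pset
    nat_born = born_radii(nat_real, ff, FDB).radii

    design = list(spec.non_frozen_positions)
    design_set = set(design)
    env_mask = nat_atoms.is_backbone | np.array(
        [r not in design_set for r in nat_atoms.res_index]
    )
    env_idx = np.where(env_mask)[0]

    # constant term: all pairs within the environment
    ex = nat_atoms.coords[env_idx]
    ep = nat_pset
    eq, es, ee = ep.charge[env_idx], ep.sigma[env_idx], ep.epsilon[env_idx]
    eR = ep.rho[env_idx] + ff.probe_radius
    et, eb = ep.tension[env_idx], nat_born[env_idx]
    n_env = len(env_idx)
    lj_sc = ep.lj_scale[np.ix_(env_idx, env_idx)]
    co_sc = ep.coul_scale[np.ix_(env_idx, env_idx)]
    iu = np.triu_indices(n_env, k=1)
    pref = -0.5 * ff.coulomb_k * (1.0 / ff.eps_protein - 1.0 / ff.eps_water)
    diffe = ex[:, None, :] - ex[None, :, :]
    r2e = np.sum(diffe * diffe, axis=-1)
    np.fill_diagonal(r2e, 1.0)
    re = np.sqrt(r2e)
    sig = 0.5 * (es[:, None] + es[None, :])
    epsm = np.sqrt(ee[:, None] * ee[None, :])
    sr6 = (sig / re) ** 6
    lj_const = float(np.sum((lj_sc * 4.0 * epsm * (sr6 * sr6 - sr6))[iu]))
    qqe = np.outer(eq, eq)
    coul_const = float(
        ff.coulomb_k / ff.eps_protein * np.sum((co_sc * qqe / re)[iu])
    )
    fgbe = _f_gb(r2e, eb[:, None], eb[None, :])
    np.fill_diagonal(fgbe, eb)
    gb_const = float(pref * np.sum(qqe / fgbe))
    capse = _cap_matrix(ex, eR, ex, eR)
    np.fill_diagonal(capse, 0.0)
    surf_const = float(
        np.sum(et * (4.0 * np.pi * eR * eR - capse.sum(axis=1)))
    )
    e_bb = lj_const + coul_const + gb_const + surf_const

    # per-design-position combos
    combos: list[list[tuple[str, int]]] = []
    combo_data: list[list[dict]] = []
    self_terms: list[np.ndarray] = []
    geo = load_geometry()

    for pos in design:
        if spec.classes[pos] == FROZEN:  # pragma: no cover
            continue
        if spec.allowed[pos] is None:
            types3 = [scaffold.residues[pos].name3]
        else:
            types3 = sorted(AA1_TO_AA3[a] for a in spec.allowed[pos])
        cl: list[tuple[str, int]] = []
        cd: list[dict] = []
        own_bb = (nat_atoms.res_index == pos) & nat_atoms.is_backbone
        others_nat = nat_atoms.res_index != pos
        own_bb_idx = np.where(own_bb)[0]
        sterm = []
        for name3 in types3:
            t = topo[name3]
            for rot, chis in enumerate(library[name3]):
                if name3 == "GLY":
                    sc_names: list[str] = []
                    sx = np.zeros((0, 3))
                else:
                    side = build_sidechain(scaffold, pos, name3, chis)
                    sc_names = [row.name for row in t.rows]
                    sx = np.array([side[n] for n in sc_names])
                cls_table = ff.classes
                scl = [row.atom_class for row in t.rows]
                sq = np.array([row.charge for row in t.rows])
                ss = np.array([cls_table[c].sigma for c in scl])
                se = np.array([cls_table[c].epsilon for c in scl])
                srho = np.array([cls_table[c].gb_radius for c in scl])
                st = np.array([cls_table[c].surface_tension for c in scl])
                # Born radii: own backbone + own side chain + native others
                envx = np.vstack(
                    [
                        nat_atoms.coords[own_bb_idx],
                        sx,
                        nat_atoms.coords[others_nat],
                    ]
                )
                envr = np.concatenate(
                    [
                        nat_pset.rho[own_bb_idx],
                        srho,
                        nat_pset.rho[others_nat],
                    ]
                )
                sb = (
                    _hct_radii(
                        sx, srho, envx, ff.hct_scale * envr, skip_self=True
                    )
                    if len(sx)
                    else np.zeros(0)
                )
                # scale factors vs environment from a bonded mini-graph
                lj_sc_env, co_sc_env = _env_scales(
                    scaffold, pos, name3, sc_names, env_idx, nat_atoms, ff
                )
                # intra side-chain scales
                lj_in, co_in = _intra_scales(name3, sc_names, ff)
                e_self = 0.0
                if len(sx):
                    # side chain vs environment
                    e_self += _group_pair_terms(
                        sx, sq, ss, se, srho + ff.probe_radius, st, sb,
                        ex, eq, es, ee, eR, et, eb,
                        lj_scale=lj_sc_env,
                        coul_scale=co_sc_env,
                        ff=ff,
                    )
                    # intra side chain (upper triangle)
                    m = len(sx)
                    if m > 1:
                        mu = np.zeros((m, m))
                        mu[np.triu_indices(m, k=1)] = 1.0
                        diffs = sx[:, None, :] - sx[None, :, :]
                        r2s = np.sum(diffs * diffs, axis=-1)
                        np.fill_diagonal(r2s, 1.0)
                        rs = np.sqrt(r2s)
                        sgs = 0.5 * (ss[:, None] + ss[None, :])
                        eps_s = np.sqrt(se[:, None] * se[None, :])
                        sr6s = (sgs / rs) ** 6
                        e_self += float(
                            np.sum(
                                (lj_in * 4.0 * eps_s * (sr6s**2 - sr6s))[
                                    np.triu_indices(m, k=1)
                                ]
                            )
                        )
                        qqs = np.outer(sq, sq)
                        e_self += float(
                            ff.coulomb_k
                            / ff.eps_protein
                            * np.sum(
                                (co_in * qqs / rs)[np.triu_indices(m, k=1)]
                            )
                        )
                        fgbs = _f_gb(r2s, sb[:, None], sb[None, :])
                        np.fill_diagonal(fgbs, sb)
                        e_self += float(pref * np.sum(qqs / fgbs))
                        Rs = srho + ff.probe_radius
                        capss = _cap_matrix(sx, Rs, sx, Rs)
                        np.fill_diagonal(capss, 0.0)
                        e_self += float(
                            np.sum(
                                st
                                * (
                                    4.0 * np.pi * Rs * Rs
                                    - capss.sum(axis=1)
                                )
                            )
                        )
                    else:
                        Rs = srho + ff.probe_radius
                        e_self += float(pref * sq[0] ** 2 / sb[0])
                        e_self += float(st[0] * 4.0 * np.pi * Rs[0] ** 2)
                sterm.append(e_self)
                cl.append((name3, rot))
                cd.append(
                    dict(
                        x=sx, q=sq, s=ss, e=se,
                        R=srho + ff.probe_radius, t=st, b=sb,
                    )
                )
        combos.append(cl)
        combo_data.append(cd)
        self_terms.append(np.array(sterm))

    # pair terms between design positions (all scales 1: side chains of
    # distinct residues are always >= 5 bonds apart)
    pair_terms: dict[tuple[int, int], np.ndarray] = {}
    stacks = [_stack_combos(cd) for cd in combo_data]
    for k in range(len(design)):
        for m in range(k + 1, len(design)):
            A = combo_data[k]
            block = np.zeros((len(A), len(combo_data[m])))
            for ia, ca in enumerate(A):
                if len(ca["x"]) == 0:
                    continue
                block[ia] = _batched_cross(ca, stacks[m], ff)
            pair_terms[(k, m)] = block

    return EnergyMatrix(
        positions=tuple(design),
        combos=combos,
        e_bb=e_bb,
        self_terms=self_terms,
        pair_terms=pair_terms,
    )


def _stack_combos(combo_data: list[dict]) -> dict:
    """Pad a position's combos into dense arrays for vectorized pair terms.

    Pad atoms sit far away with zero charge/epsilon/radius, so every term
    they enter vanishes.
    """
    n_c = len(combo_data)
    m = max((len(c["x"]) for c in combo_data), default=0)
    m = max(m, 1)
    x = np.full((n_c, m, 3), 1.0e5)
    x += np.arange(n_c)[:, None, None] * 10.0  # keep pad atoms apart
    q = np.zeros((n_c, m))
    s = np.full((n_c, m), 1.0)
    e = np.zeros((n_c, m))
    R = np.zeros((n_c, m))
    t = np.zeros((n_c, m))
    b = np.ones((n_c, m))
    for i, c in enumerate(combo_data):
        k = len(c["x"])
        if k:
            x[i, :k] = c["x"]
            q[i, :k] = c["q"]
            s[i, :k] = c["s"]
            e[i, :k] = c["e"]
            R[i, :k] = c["R"]
            t[i, :k] = c["t"]
            b[i, :k] = c["b"]
    return dict(x=x, q=q, s=s, e=e, R=R, t=t, b=b)


def _batched_cross(ca: dict, stack: dict, ff: ForceFieldParams) -> np.ndarray:
    """Pair-term sums of one combo's atoms against all combos of another
    position; returns one value per target combo."""
    xa = ca["x"]  # (ma, 3)
    xb = stack["x"]  # (nc, mb, 3)
    diff = xa[None, :, None, :] - xb[:, None, :, :]  # (nc, ma, mb, 3)
    r2 = np.sum(diff * diff, axis=-1)
    r = np.sqrt(np.maximum(r2, 1e-12))
    sig = 0.5 * (ca["s"][None, :, None] + stack["s"][:, None, :])
    eps = np.sqrt(ca["e"][None, :, None] * stack["e"][:, None, :])
    sr6 = (sig / r) ** 6
    lj = np.sum(4.0 * eps * (sr6 * sr6 - sr6), axis=(1, 2))
    qq = ca["q"][None, :, None] * stack["q"][:, None, :]
    coul = ff.coulomb_k / ff.eps_protein * np.sum(qq / r, axis=(1, 2))
    pref = -0.5 * ff.coulomb_k * (1.0 / ff.eps_protein - 1.0 / ff.eps_water)
    fgb = _f_gb(r2, ca["b"][None, :, None], stack["b"][:, None, :])
    gb = pref * 2.0 * np.sum(qq / fgb, axis=(1, 2))
    Ra = ca["R"][None, :, None]
    Rb = stack["R"][:, None, :]
    far = r >= Ra + Rb
    ha = np.clip(Ra - (r2 + Ra**2 - Rb**2) / (2 * r), 0.0, 2.0 * Ra)
    hb = np.clip(Rb - (r2 + Rb**2 - Ra**2) / (2 * r), 0.0, 2.0 * Rb)
    ha = np.where(far, 0.0, ha)
    hb = np.where(far, 0.0, hb)
    surf = -np.sum(
        ca["t"][None, :, None] * 2.0 * np.pi * Ra * ha
        + stack["t"][:, None, :] * 2.0 * np.pi * Rb * hb,
        axis=(1, 2),
    )
    return lj + coul + gb + surf


def _residue_graph(name3: str, sc_names: list[str]):
    """Bond graph of one residue's side chain + backbone + peptide stubs."""
    topo = load_topology()[name3]
    nodes = ["N", "H", "CA", "C", "O", "prevC", "nextN"] + list(sc_names)
    bonds = [
        ("N", "H"), ("N", "CA"), ("CA", "C"), ("C", "O"),
        ("prevC", "N"), ("C", "nextN"),
    ]
    for row in topo.rows:
        bonds.append((row.a1, row.name))
    bonds.extend(topo.extra_bonds)
    idx = {n: i for i, n in enumerate(nodes)}
    pairs = _bond_distance_pairs(
        len(nodes), [(idx[a], idx[b]) for a, b in bonds if a in idx and b in idx]
    )
    return nodes, idx, pairs


def _scales_from_graph(pairs, idx, a_names, b_keys, ff):
    """Scale matrices for group a (side chain) vs group b (named keys)."""
    lj = np.ones((len(a_names), len(b_keys)))
    co = np.ones((len(a_names), len(b_keys)))
    for i, an in enumerate(a_names):
        for j, bn in enumerate(b_keys):
            if bn is None or bn not in idx:
                continue
            key = (min(idx[an], idx[bn]), max(idx[an], idx[bn]))
            d = pairs.get(key)
            if d is None:
                continue
            if d <= 2:
                lj[i, j] = co[i, j] = 0.0
            elif d == 3:
                lj[i, j] = ff.scale14_lj
                co[i, j] = ff.scale14_coulomb
    return lj, co


def _env_scales(scaffold, pos, name3, sc_names, env_idx, nat_atoms, ff):
    """LJ/Coulomb scales between a candidate side chain and the environment."""
    _, idx, pairs = _residue_graph(name3, sc_names)
    b_keys = []
    for k in env_idx:
        r = int(nat_atoms.res_index[k])
        nm = nat_atoms.names[k]
        if r == pos:
            b_keys.append(nm)
        elif r == pos - 1 and nm == "C":
            b_keys.append("prevC")
        elif r == pos + 1 and nm == "N":
            b_keys.append("nextN")
        else:
            b_keys.append(None)
    return _scales_from_graph(pairs, idx, sc_names, b_keys, ff)


def _intra_scales(name3, sc_names, ff):
    _, idx, pairs = _residue_graph(name3, sc_names)
    return _scales_from_graph(pairs, idx, sc_names, list(sc_names), ff)
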