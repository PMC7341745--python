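"""Extended-peptide unfolded state and the folding energy difference.

The unfolded reference is strictly additive over residues: a per-type
extended-tripeptide energy E_ext(t), calibrated once from Ala-t-Ala in an
extended backbone, plus a per-type chemical potential mu_t (default 0) that
biases sequence composition.  The design objective is
delta = E_folded - E_unfolded; lower delta = more favourable fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import AA1_ALL
from .energetics import FDB, folded_energy
from .errors import PdzDesignError
from .params import ForceFieldParams
from .sidechain import RotamerLibrary, SystemState, load_rotamer_library
from .synthetic import build_backbone

__all__ = [
    "UnfoldedModel",
    "FoldingEnergy",
    "calibrate_extended_energies",
    "unfolded_energy",
    "folding_energy",
]

_EXTENDED_PHI_PSI = (-139.0, 135.0)


@dataclass(frozen=True)
class UnfoldedModel:
    """Per-type extended-state energies and chemical potentials (kcal/mol)."""

    e_ext: dict[str, float]
    mu: dict[str, float] = field(
        default_factory=lambda: {aa: 0.0 for aa in AA1_ALL}
    )

    def __post_init__(self):
        for table, name in ((self.e_ext, "e_ext"), (self.mu, "mu")):
            missing = set(AA1_ALL) - set(table)
            if missing:
                raise PdzDesignError(
                    f"{name} table missing types: {sorted(missing)}"
                )

    def residue_term(self, aa: str) -> float:
        return self.e_ext[aa] + self.mu[aa]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"e_ext": self.e_ext, "mu": self.mu})
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnfoldedModel":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(e_ext=doc["e_ext"], mu=doc.get("mu") or
                   {aa: 0.0 for aa in AA1_ALL})


def calibrate_extended_energies(
    ff: ForceFieldParams,
    library: RotamerLibrary | None = None,
) -> dict[str, float]:
    """E_ext(t): minimum over rotamers of the extended Ala-t-Ala energy.

    The flanking-alanine contribution is a constant shift common to all
    types and cancels in energy differences.  Deterministic.
    """
    library = library or load_rotamer_library()
    table: dict[str, float] = {}
    for aa in AA1_ALL:
        scaffold = build_backbone([_EXTENDED_PHI_PSI] * 3, f"A{aa}A")
        best = None
        for rot in range(library.n_rotamers(
            scaffold.residues[1].name3
        )):
            state = SystemState(scaffold, f"A{aa}A", (0, rot, 0))
            e = folded_energy(state, ff, FDB, library).total
            best = e if best is None else min(best, e)
        table[aa] = float(best)
    return table


def unfolded_energy(sequence: str, model: UnfoldedModel) -> float:
    """Additive, conformation-independent unfolded-state energy."""
    if not sequence:
        raise PdzDesignError("empty sequence")
    unknown = set(sequence) - set(AA1_ALL)
    if unknown:
        raise PdzDesignError(f"unknown residue codes: {sorted(unknown)}")
    return float(sum(model.residue_term(aa) for aa in sequence))


@dataclass(frozen=True)
class FoldingEnergy:
    """Folded/unfolded energies and their difference (the design objective)."""

    e_folded: float
    e_unfolded: float
    delta: float
    mode: str

    def __post_init__(self):
        if abs(self.delta - (self.e_folded - self.e_unfolded)) > 1e-9:
            raise PdzDesignError("delta must equal folded - unfolded")


def folding_energy(
    state: SystemState,
    model: UnfoldedModel,
    ff: ForceFieldParams,
    mode: str,
    library: RotamerLibrary | None = None,
    native: SystemState | None = None,
) -> FoldingEnergy:
    """delta = folded total - unfolded; lower is more favourable."""
    e_f = folded_energy(state, ff, mode, library, native).total
    e_u = unfolded_energy(state.sequence, model)
    return FoldingEnergy(
        e_folded=e_f, e_unfolded=e_u, delta=e_f - e_u, mode=mode
    )
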