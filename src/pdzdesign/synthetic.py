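"""Seeded generators for every input the design pipeline consumes.

Scaffolds are ideal-geometry mini-proteins (helix, beta hairpin, or a
helix + hairpin combination) built from standard peptide covalent geometry;
reference alignments emulate a homolog family by uniform per-position
substitution of a consensus; fold-recognition tables emulate an external
scorer with a two-component log10 E-value mixture; melt curves are Boltzmann
sigmoids with Gaussian noise.  Every generator is a pure function of its
config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AA1_ALL, AA1_TO_AA3
from .errors import InvalidConfigError
from .filtering import FoldRecognitionRecord, ReferenceAlignment
from .geometry import place_atom
from .params import load_geometry
from .scaffold import BackboneScaffold, Residue
from .thermal import MeltCurve, boltzmann_sigmoid

__all__ = [
    "SyntheticScaffoldConfig",
    "SyntheticMsaConfig",
    "SyntheticMeltConfig",
    "topology_phi_psi",
    "build_backbone",
    "make_scaffold",
    "make_reference_msa",
    "make_fold_recognition_table",
    "make_melt_curve",
]

TOPOLOGIES = ("helix", "hairpin", "helix-hairpin")

# fixed type-I'-like turn torsions used at the hairpin apex
_TURN = [(-60.0, -30.0), (-90.0, 0.0)]


@dataclass(frozen=True)
class SyntheticScaffoldConfig:
    n_residues: int
    topology: str = "helix"
    sequence: str = "poly-ALA"
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 3:
            raise InvalidConfigError("n_residues must be >= 3")
        if self.topology not in TOPOLOGIES:
            raise InvalidConfigError(
                f"topology must be one of {TOPOLOGIES}"
            )
        if self.sequence != "poly-ALA":
            if len(self.sequence) != self.n_residues:
                raise InvalidConfigError(
                    "sequence length must equal n_residues"
                )
            bad = set(self.sequence) - set(AA1_ALL)
            if bad:
                raise InvalidConfigError(f"unknown residue codes {bad}")


@dataclass(frozen=True)
class SyntheticMsaConfig:
    consensus: str
    n_sequences: int
    substitution_rate: float
    seed: int = 0

    def __post_init__(self):
        if not self.consensus:
            raise InvalidConfigError("consensus must be non-empty")
        bad = set(self.consensus) - set(AA1_ALL)
        if bad:
            raise InvalidConfigError(f"unknown residue codes {bad}")
        if self.n_sequences < 1:
            raise InvalidConfigError("n_sequences must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise InvalidConfigError("substitution_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticMeltConfig:
    t_half: float = 50.0
    slope: float = 1.5
    f_min: float = 0.0
    f_max: float = 1.0
    noise_sd: float = 0.0
    t_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.arange(25.0, 75.5, 0.5))
    )
    seed: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise InvalidConfigError("slope must be positive")
        if self.f_max <= self.f_min:
            raise InvalidConfigError("f_max must exceed f_min")
        if len(self.t_grid) < 2 or np.any(np.diff(self.t_grid) <= 0):
            raise InvalidConfigError("t_grid must strictly increase")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


def topology_phi_psi(topology: str, n: int) -> list[tuple[float, float]]:
    """Per-residue target (phi, psi) for a synthetic topology."""
    geo = load_geometry()
    helix = tuple(geo["phi_psi"]["helix"])
    strand = tuple(geo["phi_psi"]["strand"])
    if topology == "helix":
        return [helix] * n
    if topology == "hairpin":
        mid = n // 2
        out = [strand] * n
        out[max(mid - 1, 0)] = _TURN[0]
        out[min(mid, n - 1)] = _TURN[1]
        return out
    if topology == "helix-hairpin":
        n_helix = n // 2
        return [helix] * n_helix + topology_phi_psi(
            "hairpin", n - n_helix
        )
    raise InvalidConfigError(f"unknown topology {topology!r}")


def build_backbone(
    phi_psi: list[tuple[float, float]],
    sequence: str,
    chain_id: str = "A",
) -> BackboneScaffold:
    """Ideal-geometry backbone from per-residue (phi, psi), omega = 180."""
    geo = load_geometry()
    b = geo["bonds"]
    a = geo["angles"]
    omega = geo["omega"]
    n = len(phi_psi)
    if len(sequence) != n:
        raise InvalidConfigError("sequence/torsion length mismatch")
    coords: list[dict[str, np.ndarray]] = []
    # seed the first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([b["N-CA"], 0.0, 0.0])
    ang = np.radians(a["N-CA-C"])
    c0 = ca0 + b["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        ni = place_atom(
            prev["C"], prev["CA"], prev["N"],
            b["C-N"], a["CA-C-N"], psi_prev,
        )
        cai = place_atom(
            ni, prev["C"], prev["CA"], b["N-CA"], a["C-N-CA"], omega
        )
        ci = place_atom(
            cai, ni, prev["C"], b["CA-C"], a["N-CA-C"], phi_psi[i][0]
        )
        coords.append({"N": ni, "CA": cai, "C": ci})
    # carbonyl oxygens: anti to the following N (torsion psi + 180)
    for i in range(n):
        psi = phi_psi[i][1]
        coords[i]["O"] = place_atom(
            coords[i]["C"], coords[i]["CA"], coords[i]["N"],
            b["C-O"], a["CA-C-O"], psi + 180.0,
        )
    residues = tuple(
        Residue(
            res_id=i + 1,
            name3=AA1_TO_AA3[sequence[i]],
            atoms={k: v.round(12) for k, v in coords[i].items()},
        )
        for i in range(n)
    )
    return BackboneScaffold(residues, chain_id=chain_id)


def make_scaffold(config: SyntheticScaffoldConfig) -> BackboneScaffold:
    """Ideal-geometry mini-protein scaffold; deterministic for a config."""
    seq = (
        "A" * config.n_residues
        if config.sequence == "poly-ALA"
        else config.sequence
    )
    return build_backbone(
        topology_phi_psi(config.topology, config.n_residues), seq
    )


def make_reference_msa(config: SyntheticMsaConfig) -> ReferenceAlignment:
    """Homolog-family stand-in: uniform substitutions of a consensus."""
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AA1_ALL))
    seqs = []
    for k in range(config.n_sequences):
        chars = list(config.consensus)
        hit = rng.random(len(chars)) < config.substitution_rate
        for i in np.where(hit)[0]:
            choices = [c for c in alphabet if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        seqs.append("".join(chars))
    return ReferenceAlignment(
        ids=tuple(f"ref_{k:04d}" for k in range(config.n_sequences)),
        sequences=tuple(seqs),
    )


def make_fold_recognition_table(
    n: int,
    frac_hits: float,
    seed: int = 0,
    hit_mean: float = -40.0,
    hit_sd: float = 2.0,
    background_mean: float = -10.0,
    background_sd: float = 5.0,
    hit_length_mean: float = 80.0,
    background_length_mean: float = 40.0,
    length_sd: float = 5.0,
) -> list[FoldRecognitionRecord]:
    """External fold-recognition stand-in: a two-component score mixture."""
    if n < 0:
        raise InvalidConfigError("n must be >= 0")
    if not 0.0 <= frac_hits <= 1.0:
        raise InvalidConfigError("frac_hits must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        is_hit = rng.random() < frac_hits
        if is_hit:
            log10e = rng.normal(hit_mean, hit_sd)
            length = rng.normal(hit_length_mean, length_sd)
            family = "PDZ"
        else:
            log10e = rng.normal(background_mean, background_sd)
            length = rng.normal(background_length_mean, length_sd)
            family = "other"
        records.append(
            FoldRecognitionRecord(
                seq_id=f"seq_{k:05d}",
                family=family,
                log10_evalue=float(log10e),
                match_length=max(int(round(length)), 0),
            )
        )
    return records


def _sphere_shell(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return radius * np.column_stack(
        [s * np.cos(theta), s * np.sin(theta), z]
    )


def make_planted_cascade(seed: int = 0) -> dict:
    """A 200-sequence filtering benchmark with known per-stage violations.

    Each candidate carries at most one planted defect, placed so it passes
    every earlier stage: 40 high-energy, 20 near-neutral pI (two His), 30
    weak fold-recognition hits, 15 scrambled at the similarity-scored
    positions, 10 with a hollow-shell structure (buried cavity), 12 with +6
    formal charge, 8 with sixteen drastic substitutions, 65 clean.  The
    similarity stage scores positions 0-9 only, so composition planted at
    positions >= 10 cannot disturb it.  Returns candidates, structures,
    records, references, config, wildtype and the expected survivor chain.
    """
    from .filtering import Candidate, FilterConfig, FoldRecognitionRecord

    n = 200
    wildtype = "A" * 40
    groups = (
        ["clean"] * 65 + ["pi"] * 20 + ["fold"] * 30 + ["sim"] * 15
        + ["cavity"] * 10 + ["charge"] * 12 + ["drastic"] * 8
        + ["energy"] * 40
    )
    serial_alphabet = "AST"
    solid = np.array(
        [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [1.5, 2.6, 0.0],
         [1.5, 0.9, 2.4]]
    )
    shell = _sphere_shell(120, 6.0)
    candidates, structures, records = [], {}, {}
    for i, group in enumerate(groups):
        seq = list(wildtype)
        # unique benign serial tag at positions 30..37
        k = i
        for p in range(30, 38):
            seq[p] = serial_alphabet[k % 3]
            k //= 3
        if group == "pi":
            seq[10:12] = "HH"
        elif group == "sim":
            seq[0:10] = "WYFWYFWYFW"
        elif group == "charge":
            seq[10:16] = "KKKKKK"
        elif group == "drastic":
            seq[10:26] = "W" * 16
        seq_id = f"cand_{i:04d}"
        energy = 1000.0 + i if group == "energy" else float(i)
        candidates.append(Candidate(seq_id, "".join(seq), energy))
        if group == "fold":
            records[seq_id] = FoldRecognitionRecord(
                seq_id, "other", -10.0, 40
            )
        else:
            records[seq_id] = FoldRecognitionRecord(seq_id, "PDZ", -40.0, 80)
        coords = shell if group == "cavity" else solid
        structures[seq_id] = (coords, np.full(len(coords), 1.7))
    from .filtering import ReferenceAlignment

    references = ReferenceAlignment(
        ids=("ref_0", "ref_1", "ref_2"),
        sequences=(wildtype, wildtype, wildtype),
    )
    config = FilterConfig(
        top_n=160, similarity_positions=tuple(range(10))
    )
    return {
        "candidates": candidates,
        "structures": structures,
        "records": records,
        "references": references,
        "config": config,
        "wildtype": wildtype,
        "expected_chain": [200, 160, 140, 110, 95, 85, 73, 65],
        "planted_counts": {
            "energy_top_n": 40,
            "isoelectric_point": 20,
            "fold_recognition": 30,
            "blosum_similarity": 15,
            "buried_cavity": 10,
            "formal_charge": 12,
            "drastic_mutations": 8,
        },
    }


def make_melt_curve(
    config: SyntheticMeltConfig, replicate_id: str = ""
) -> MeltCurve:
    """Sigmoidal melt curve with seeded Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.t_grid, dtype=float)
    f = boltzmann_sigmoid(
        t, config.f_min, config.f_max, config.t_half, config.slope
    )
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd, size=len(t))
    return MeltCurve(temperatures=t, fluorescence=f, replicate_id=replicate_id)
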