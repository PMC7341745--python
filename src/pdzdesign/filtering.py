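"""Empirical candidate-selection cascade for designed sequences.

Seven stages, applied in order: (1) top-N folding-energy cut, (2) exclusion
of isoelectric points near physiological pH, (3) fold-recognition confidence
(match length above the survivors' mean and log10 E-value below a
threshold), (4) substitution-matrix similarity to a reference alignment at
or above the survivors' mean, (5) no buried cavity, (6) unsigned formal
charge below a limit, (7) a cap on drastic mutations.  Stages 3-4 use means
over the sequences entering the stage, so they are order-sensitive; stages
5-7 are independent per-sequence predicates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix

from .constants import AA1_ALL
from .errors import InvalidConfigError, PdzDesignError
from .params import load_pka

__all__ = [
    "ReferenceAlignment",
    "FoldRecognitionRecord",
    "FilterConfig",
    "Candidate",
    "FilterStage",
    "FilterReport",
    "net_charge",
    "isoelectric_point",
    "formal_charge",
    "blosum_similarity",
    "drastic_mutation_count",
    "detect_cavities",
    "apply_fold_recognition_filter",
    "run_cascade",
    "read_fold_recognition_tsv",
    "write_fold_recognition_tsv",
    "read_msa_fasta",
    "write_msa_fasta",
]


@dataclass(frozen=True)
class ReferenceAlignment:
    """Ungapped, template-anchored reference alignment (Pfam stand-in)."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if not self.sequences:
            raise InvalidConfigError("alignment has no sequences")
        w = len(self.sequences[0])
        if any(len(s) != w for s in self.sequences):
            raise InvalidConfigError("alignment sequences differ in length")
        if len(self.ids) != len(self.sequences):
            raise InvalidConfigError("ids/sequences length mismatch")

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


def write_msa_fasta(aln: ReferenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_msa_fasta(path: str | Path) -> ReferenceAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return ReferenceAlignment(
        ids=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )


@dataclass(frozen=True)
class FoldRecognitionRecord:
    """One fold-recognition hit (external tool stand-in)."""

    seq_id: str
    family: str
    log10_evalue: float
    match_length: int

    def __post_init__(self):
        if self.match_length < 0:
            raise InvalidConfigError("match_length must be >= 0")


def write_fold_recognition_tsv(
    records: list[FoldRecognitionRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "id": [r.seq_id for r in records],
            "family": [r.family for r in records],
            "log10_evalue": [r.log10_evalue for r in records],
            "match_length": [r.match_length for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fold_recognition_tsv(path: str | Path) -> list[FoldRecognitionRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        FoldRecognitionRecord(
            seq_id=str(row["id"]),
            family=str(row["family"]),
            log10_evalue=float(row["log10_evalue"]),
            match_length=int(row["match_length"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# per-sequence statistics


def net_charge(
    sequence: str,
    ph: float,
    pka_set: dict | None = None,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    pka = pka_set or load_pka()
    unknown = set(sequence) - set(AA1_ALL)
    if unknown:
        raise PdzDesignError(f"unknown residue codes: {sorted(unknown)}")
    q = 0.0
    for aa, pk in pka["basic"].items():
        q += sequence.count(aa) / (1.0 + 10.0 ** (ph - pk))
    for aa, pk in pka["acidic"].items():
        q -= sequence.count(aa) / (1.0 + 10.0 ** (pk - ph))
    if include_termini:
        q += 1.0 / (1.0 + 10.0 ** (ph - pka["n_terminus"]))
        q -= 1.0 / (1.0 + 10.0 ** (pka["c_terminus"] - ph))
    return q


def isoelectric_point(
    sequence: str,
    pka_set: dict | None = None,
    include_termini: bool = True,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Sequences whose charge never changes sign (e.g. blocked poly-Asp) get
    the corresponding boundary pH by convention, with a warning.
    """
    if not sequence:
        raise PdzDesignError("empty sequence")
    lo, hi = 0.0, 14.0
    q_lo = net_charge(sequence, lo, pka_set, include_termini)
    q_hi = net_charge(sequence, hi, pka_set, include_termini)
    if q_lo <= 0.0:
        warnings.warn("net charge never positive; pI set to acidic boundary")
        return lo
    if q_hi >= 0.0:
        warnings.warn("net charge never negative; pI set to basic boundary")
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set, include_termini) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def formal_charge(sequence: str, ph: float = 7.0) -> int:
    """Integer formal charge: +1 per Arg/Lys, -1 per Asp/Glu, His neutral,
    termini cancelling (one + and one -)."""
    unknown = set(sequence) - set(AA1_ALL)
    if unknown:
        raise PdzDesignError(f"unknown residue codes: {sorted(unknown)}")
    return (
        sequence.count("R")
        + sequence.count("K")
        - sequence.count("D")
        - sequence.count("E")
    )


@lru_cache(maxsize=None)
def _load_matrix(name: str) -> dict[tuple[str, str], float]:
    """Canonical substitution matrix as a symbol-pair lookup."""
    alph = ProteinSequence.alphabet
    mat = SubstitutionMatrix(alph, alph, name.upper())
    return {
        (a, b): float(mat.get_score(a, b))
        for a in AA1_ALL
        for b in AA1_ALL
    }


def blosum_similarity(
    sequence: str,
    reference: ReferenceAlignment,
    matrix: str = "BLOSUM62",
    positions: tuple[int, ...] | None = None,
) -> tuple[float, list[float]]:
    """Template-anchored similarity of a sequence to every reference.

    Returns (best-hit score, per-reference score list); scores are sums of
    substitution-matrix entries over the chosen positions (all by default).
    """
    if len(sequence) != reference.width:
        raise PdzDesignError(
            f"sequence length {len(sequence)} != alignment width "
            f"{reference.width}"
        )
    mat = _load_matrix(matrix)
    cols = range(len(sequence)) if positions is None else positions
    scores = []
    for ref in reference.sequences:
        scores.append(
            float(sum(mat[sequence[i], ref[i]] for i in cols))
        )
    best = max(scores) if scores else 0.0
    if positions is not None and len(tuple(positions)) == 0:
        best = 0.0
    return best, scores


def drastic_mutation_count(
    sequence: str,
    wildtype: str,
    matrix: str = "BLOSUM62",
    threshold: float = -2.0,
) -> int:
    """Mutations whose substitution score is at or below the threshold."""
    if len(sequence) != len(wildtype):
        raise PdzDesignError("sequence/wildtype length mismatch")
    mat = _load_matrix(matrix)
    return sum(
        1
        for a, w in zip(sequence, wildtype)
        if a != w and mat[w, a] <= threshold
    )


def detect_cavities(
    coords: np.ndarray,
    radii: np.ndarray,
    grid_spacing: float = 1.0,
    probe: float = 1.4,
    min_volume: float = 0.0,
) -> list[float]:
    """Buried-cavity volumes (A^3) by occupancy grid + flood fill.

    Voxels within (radius + probe) of an atom are occupied; free-space
    components not reachable from the bounding-box boundary are cavities.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(coords) == 0:
        raise PdzDesignError("need at least one atom")
    if grid_spacing <= 0:
        raise PdzDesignError("grid spacing must be positive")
    ext = radii + probe
    lo = (coords - ext[:, None]).min(axis=0) - 2 * grid_spacing
    hi = (coords + ext[:, None]).max(axis=0) + 2 * grid_spacing
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    axes = [
        lo[k] + grid_spacing * np.arange(shape[k]) for k in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    occupied = np.zeros(shape, dtype=bool)
    for c, e in zip(coords, ext):
        d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        occupied |= d2 <= e * e
    free = ~occupied
    labels, n_lab = ndimage.label(free)
    if n_lab == 0:
        return []
    boundary = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            boundary.update(np.unique(labels[tuple(sl)]))
    boundary.discard(0)
    volumes = []
    for lab in range(1, n_lab + 1):
        if lab in boundary:
            continue
        vol = float(np.sum(labels == lab)) * grid_spacing**3
        if vol >= min_volume:
            volumes.append(vol)
    return sorted(volumes, reverse=True)


def apply_fold_recognition_filter(
    records: list[FoldRecognitionRecord],
    threshold_log10e: float = -31.0,
) -> set[str]:
    """Ids with match length strictly above the mean and log10 E below the
    threshold."""
    if not records:
        raise PdzDesignError("no fold-recognition records")
    mean_len = float(np.mean([r.match_length for r in records]))
    return {
        r.seq_id
        for r in records
        if r.match_length > mean_len and r.log10_evalue < threshold_log10e
    }


# ---------------------------------------------------------------------------
# the cascade


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the seven-stage cascade (defaults per the study)."""

    top_n: int = 2000
    pi_window: tuple[float, float] = (6.5, 8.5)
    fold_log10e_threshold: float = -31.0
    similarity_matrix: str = "BLOSUM40"
    similarity_positions: tuple[int, ...] | None = None
    cavity_min_volume: float = 30.0
    cavity_grid_spacing: float = 1.0
    cavity_probe: float = 1.4
    charge_limit: int = 6
    drastic_matrix: str = "BLOSUM62"
    drastic_threshold: float = -2.0
    drastic_max: int = 15

    def __post_init__(self):
        if self.pi_window[0] > self.pi_window[1]:
            raise InvalidConfigError("pI window must be ordered")
        if self.top_n < 0:
            raise InvalidConfigError("top_n must be >= 0")


@dataclass(frozen=True)
class Candidate:
    """A designed sequence entering the cascade."""

    seq_id: str
    sequence: str
    energy: float


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int
    values: dict[str, float] = field(default_factory=dict)
    passed: dict[str, bool] = field(default_factory=dict)


@dataclass
class FilterReport:
    """Per-stage attrition and per-sequence provenance."""

    stages: list[FilterStage]
    survivors: list[str]

    def __post_init__(self):
        counts = [s.n_in for s in self.stages] + [
            self.stages[-1].n_out if self.stages else 0
        ]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise PdzDesignError("stage counts must be non-increasing")

    def eliminated_at(self, seq_id: str) -> str | None:
        for stage in self.stages:
            if seq_id in stage.passed and not stage.passed[seq_id]:
                return stage.name
        return None

    def to_json(self, path: str | Path) -> None:
        doc = {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "values": s.values,
                    "passed": s.passed,
                }
                for s in self.stages
            ],
            "survivors": self.survivors,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def run_cascade(
    candidates: list[Candidate],
    structures: dict[str, tuple[np.ndarray, np.ndarray]] | None,
    references: ReferenceAlignment | None,
    records: dict[str, FoldRecognitionRecord] | None,
    config: FilterConfig = FilterConfig(),
    wildtype: str | None = None,
) -> FilterReport:
    """Apply the seven-stage cascade in order and report attrition.

    ``structures`` maps id -> (coords, radii) for cavity detection;
    ``records`` maps id -> fold-recognition record.  A missing structure or
    record for a sequence still alive at that stage raises an error naming
    the sequence.
    """
    stages: list[FilterStage] = []
    alive = list(candidates)

    # 1: energy cut
    ranked = sorted(alive, key=lambda c: (c.energy, c.seq_id))
    kept = ranked[: config.top_n]
    kept_ids = {c.seq_id for c in kept}
    stages.append(
        FilterStage(
            "energy_top_n",
            len(alive),
            len(kept),
            values={c.seq_id: c.energy for c in alive},
            passed={c.seq_id: c.seq_id in kept_ids for c in alive},
        )
    )
    alive = kept

    # 2: pI exclusion window (inclusive endpoints)
    lo, hi = config.pi_window
    vals = {c.seq_id: isoelectric_point(c.sequence) for c in alive}
    passed = {i: not (lo <= v <= hi) for i, v in vals.items()}
    stages.append(
        FilterStage(
            "isoelectric_point",
            len(alive),
            sum(passed.values()),
            vals,
            passed,
        )
    )
    alive = [c for c in alive if passed[c.seq_id]]

    # 3: fold recognition (mean over this stage's input)
    if alive:
        if records is None:
            raise PdzDesignError("fold-recognition records required")
        missing = [c.seq_id for c in alive if c.seq_id not in records]
        if missing:
            raise PdzDesignError(
                f"no fold-recognition record for: {missing[:5]}"
            )
        subset = [records[c.seq_id] for c in alive]
        surviving = apply_fold_recognition_filter(
            subset, config.fold_log10e_threshold
        )
        vals = {r.seq_id: r.log10_evalue for r in subset}
        passed = {c.seq_id: c.seq_id in surviving for c in alive}
    else:
        vals, passed = {}, {}
    stages.append(
        FilterStage(
            "fold_recognition",
            len(alive),
            sum(passed.values()),
            vals,
            passed,
        )
    )
    alive = [c for c in alive if passed.get(c.seq_id, False)]

    # 4: similarity at or above the mean of this stage's input
    if alive:
        if references is None:
            raise PdzDesignError("reference alignment required")
        vals = {
            c.seq_id: blosum_similarity(
                c.sequence,
                references,
                config.similarity_matrix,
                config.similarity_positions,
            )[0]
            for c in alive
        }
        mean_score = float(np.mean(list(vals.values())))
        passed = {i: v >= mean_score for i, v in vals.items()}
    else:
        vals, passed = {}, {}
    stages.append(
        FilterStage(
            "blosum_similarity",
            len(alive),
            sum(passed.values()),
            vals,
            passed,
        )
    )
    alive = [c for c in alive if passed.get(c.seq_id, False)]

    # 5: buried cavities
    if alive:
        if structures is None:
            raise PdzDesignError("structures required for cavity stage")
        missing = [c.seq_id for c in alive if c.seq_id not in structures]
        if missing:
            raise PdzDesignError(f"no structure for: {missing[:5]}")
        vals, passed = {}, {}
        for c in alive:
            coords, radii = structures[c.seq_id]
            cavities = detect_cavities(
                coords,
                radii,
                grid_spacing=config.cavity_grid_spacing,
                probe=config.cavity_probe,
                min_volume=config.cavity_min_volume,
            )
            vals[c.seq_id] = cavities[0] if cavities else 0.0
            passed[c.seq_id] = not cavities
    else:
        vals, passed = {}, {}
    stages.append(
        FilterStage(
            "buried_cavity", len(alive), sum(passed.values()), vals, passed
        )
    )
    alive = [c for c in alive if passed.get(c.seq_id, False)]

    # 6: unsigned formal charge strictly below the limit
    vals = {c.seq_id: float(formal_charge(c.sequence)) for c in alive}
    passed = {i: abs(v) < config.charge_limit for i, v in vals.items()}
    stages.append(
        FilterStage(
            "formal_charge", len(alive), sum(passed.values()), vals, passed
        )
    )
    alive = [c for c in alive if passed[c.seq_id]]

    # 7: drastic mutations
    if alive:
        if wildtype is None:
            raise PdzDesignError("wildtype sequence required")
        vals = {
            c.seq_id: float(
                drastic_mutation_count(
                    c.sequence,
                    wildtype,
                    config.drastic_matrix,
                    config.drastic_threshold,
                )
            )
            for c in alive
        }
        passed = {i: v <= config.drastic_max for i, v in vals.items()}
    else:
        vals, passed = {}, {}
    stages.append(
        FilterStage(
            "drastic_mutations",
            len(alive),
            sum(passed.values()),
            vals,
            passed,
        )
    )
    alive = [c for c in alive if passed.get(c.seq_id, False)]

    return FilterReport(
        stages=stages, survivors=[c.seq_id for c in alive]
    )
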