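"""Generate every input the design pipeline consumes.

Builds a synthetic mini-protein scaffold (helix + hairpin), a design spec
freezing two ligand-contact positions, a reference alignment standing in
for a homolog family, a fold-recognition score table, and DSF melt curves.
Everything is seeded and written under results/inputs/.
"""

from pathlib import Path

import numpy as np

from pdzdesign import (
    make_design_spec,
    make_fold_recognition_table,
    make_melt_curve,
    make_reference_msa,
    make_scaffold,
    write_pdb,
)
from pdzdesign.filtering import write_fold_recognition_tsv, write_msa_fasta
from pdzdesign.synthetic import (
    SyntheticMeltConfig,
    SyntheticMsaConfig,
    SyntheticScaffoldConfig,
)
from pdzdesign.thermal import write_melt_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2024
N_RESIDUES = 10
INTERFACE_IDS = {1, 10}  # author numbering: first and last residue

scaffold = make_scaffold(
    SyntheticScaffoldConfig(N_RESIDUES, "helix-hairpin", seed=SEED)
)
write_pdb(scaffold, OUT / "scaffold.pdb")
spec = make_design_spec(scaffold, interface_ids=INTERFACE_IDS)
spec.to_yaml(OUT / "design_spec.yaml")
print(
    f"scaffold: {N_RESIDUES} residues (helix-hairpin), "
    f"{len(spec.mutable_positions)} mutable positions, "
    f"{len(INTERFACE_IDS)} interface positions kept wild type"
)

msa = make_reference_msa(
    SyntheticMsaConfig(scaffold.sequence, n_sequences=50,
                       substitution_rate=0.1, seed=SEED)
)
write_msa_fasta(msa, OUT / "reference_msa.fasta")
ident = np.mean(
    [
        sum(a == b for a, b in zip(s, scaffold.sequence)) / len(s)
        for s in msa.sequences
    ]
)
print(f"reference MSA: {len(msa)} sequences, mean identity {ident:.2f}")

records = make_fold_recognition_table(50, frac_hits=0.8, seed=SEED)
write_fold_recognition_tsv(records, OUT / "fold_recognition.tsv")
n_conf = sum(r.log10_evalue < -31 for r in records)
print(f"fold-recognition table: {len(records)} rows, {n_conf} confident hits")

for name, (t_half, sd) in {
    "apo": (50.0, 0.2),
    "holo": (51.5, 0.2),
}.items():
    for k, c in enumerate((-1.0, 0.0, 1.0)):
        curve = make_melt_curve(
            SyntheticMeltConfig(
                t_half=t_half + sd * c, slope=1.5, noise_sd=0.01,
                seed=SEED + 10 * k,
            ),
            replicate_id=f"{name}_{k}",
        )
        write_melt_csv(curve, OUT / f"melt_{name}_{k}.csv")
print("melt curves: 3 apo + 3 holo replicates written")
print(f"all inputs under {OUT}")
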