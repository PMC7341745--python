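"""DSF thermal-shift analysis: T1/2 per replicate and the binding call.

Fits Boltzmann sigmoids to the apo/holo melt-curve replicates from 01 and
applies the significance rule (shift > sum of the two replicate standard
deviations).  Also reprints the study-style table recomputed from replicate
statistics used as generator parameters.
"""

from pathlib import Path

from pdzdesign import fit_t_half, thermal_shift, thermal_shift_from_stats
from pdzdesign.thermal import read_melt_csv

ROOT = Path(__file__).resolve().parents[1] / "results"

apo = [
    read_melt_csv(ROOT / "inputs" / f"melt_apo_{k}.csv", f"apo_{k}")
    for k in range(3)
]
holo = [
    read_melt_csv(ROOT / "inputs" / f"melt_holo_{k}.csv", f"holo_{k}")
    for k in range(3)
]
for curve in apo + holo:
    print(f"  {curve.replicate_id}: T1/2 = {fit_t_half(curve):.2f} C")
res = thermal_shift(apo, holo)
print(
    f"apo {res.t_half_apo:.2f} +- {res.sd_apo:.2f} C, "
    f"holo {res.t_half_holo:.2f} +- {res.sd_holo:.2f} C"
)
print(
    f"delta T1/2 = {res.delta:+.2f} C -> "
    f"{'binding' if res.significant else 'no significant shift'}"
)

print("\nstudy-style table from printed replicate statistics:")
table = {
    "CASK/SDC1": ((57.2, 0.2), (58.4, 0.1)),
    "CASK/Caspr4": ((57.2, 0.2), (58.7, 0.1)),
    "CASK/NRXN": ((57.2, 0.2), (58.1, 0.2)),
    "FDB-1350/NRXN": ((49.8, 0.4), (51.3, 0.2)),
    "FDB-1669/NRXN": ((49.1, 0.1), (50.1, 0.1)),
    "FDB-1555/NRXN": ((49.9, 0.2), (50.5, 0.6)),
}
for name, ((ta, sa), (th, sh)) in table.items():
    r = thermal_shift_from_stats(ta, sa, th, sh)
    flag = "significant" if r.significant else "-"
    print(f"  {name:<14} delta = {r.delta:+.1f} C  {flag}")
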