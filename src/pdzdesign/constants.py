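"""Amino-acid code tables shared across the package."""

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}
AA1_ALL = "ACDEFGHIKLMNPQRSTVWY"

#: the 18 types a mutable position may adopt (all twenty minus Gly/Pro)
DESIGN_ALPHABET = frozenset(AA1_ALL) - {"G", "P"}
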