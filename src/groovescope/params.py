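"""Residue-level charge/radius parameter sets.

The electrostatics here is residue-level: each ionizable residue's formal
side-chain charge is placed on one representative side-chain atom, and radii
are element-based van der Waals values. This is deliberately coarser than a
force-field charge set; the pH-driven sign/shape changes of the potential are
carried entirely by the formal charges.
"""

from __future__ import annotations

# van der Waals radii (Å), Bondi-style values; fallback for odd elements
ELEMENT_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70

# atom carrying the formal side-chain charge, per ionizable residue type
REPRESENTATIVE_ATOM: dict[str, str] = {
    "ASP": "CG",   # carboxylate carbon
    "GLU": "CD",   # carboxylate carbon
    "HIS": "ND1",  # imidazole nitrogen
    "LYS": "NZ",   # ammonium nitrogen
    "ARG": "CZ",   # guanidinium carbon
    "TYR": "OH",   # phenolic oxygen
    "CYS": "SG",   # thiolate sulfur
}

IONIZABLE_RESIDUES = frozenset(REPRESENTATIVE_ATOM)

STANDARD_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL DUM""".split()
)

# textbook intrinsic pKa values, used by synthetic scenarios for the
# always-charged residue classes
MODEL_PKA: dict[str, float] = {
    "ASP": 3.7,
    "GLU": 4.2,
    "HIS": 6.0,
    "TYR": 10.1,
    "LYS": 10.4,
    "ARG": 12.5,
    "CYS": 8.5,
}


def element_radius(element: str) -> float:
    return ELEMENT_RADII.get(element.strip().upper(), DEFAULT_RADIUS)
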