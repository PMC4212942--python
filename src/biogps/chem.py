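"""Chemical typing tables shared by pocket detection and field calculation.

Donor/acceptor assignment is name-based (residue + atom name), the transparent
stand-in for a force field's internal atom typing. Only polymer atoms of the
20 standard amino acids are ever typed.
"""

from __future__ import annotations

# Van der Waals radii, Å (Bondi-style values, H omitted from occlusion checks).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain H-bond donor heavy atoms (N/O carrying at least one H).
_SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
    "CYS": frozenset({"SG"}),
}

# Side-chain H-bond acceptor heavy atoms.
_SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def is_donor(residue_name: str, atom_name: str) -> bool:
    """True for H-bond-donor heavy atoms (backbone amide N, polar side chains)."""
    if atom_name == "N" and residue_name != "PRO":
        return True
    return atom_name in _SIDECHAIN_DONORS.get(residue_name, frozenset())


def is_acceptor(residue_name: str, atom_name: str) -> bool:
    """True for H-bond-acceptor heavy atoms (backbone carbonyl O, polar side chains)."""
    if atom_name == "O":
        return True
    return atom_name in _SIDECHAIN_ACCEPTORS.get(residue_name, frozenset())


def is_nonpolar_carbon(element: str, bonded_elements: list[str]) -> bool:
    """Hydrophobic carbon: a C bonded only to C and H (or to nothing resolvable)."""
    if element.upper() != "C":
        return False
    return all(e.upper() in ("C", "H") for e in bonded_elements)
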