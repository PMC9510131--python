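"""Reference data tables used by the energetics and assembly modules.

The tables are shipped as code so the package has no runtime data files:

* ``SASA_RADII`` — NACCESS-style atomic radii per (residue, atom name),
  as used by the contact-based binding-affinity predictor's solvent
  accessibility step (values extracted from the FreeSASA ``naccess``
  standard classifier).
* ``MAX_SASA`` — theoretical per-residue maximum accessible surface
  areas (Tien et al. 2013, theoretical set) for relative-SASA
  normalisation.
* ``IC_CLASS`` / ``NIS_CLASS`` — residue character tables (charged /
  polar / apolar) for interfacial-contact classification and for the
  non-interacting-surface composition, respectively.  The two tables
  differ only for CYS and HIS, mirroring the published predictor.
* ``VDW_RADII`` — Bondi van der Waals radii per element for steric
  clash detection.
* ``DG_COEFFICIENTS`` — the linear binding-affinity model.
"""

from __future__ import annotations

# fmt: off
_BACKBONE = {"N": 1.65, "CA": 1.87, "C": 1.76, "O": 1.40, "OXT": 1.40}

_SIDECHAINS = {
    "ALA": {"CB": 1.87},
    "ARG": {"CB": 1.87, "CG": 1.87, "CD": 1.87, "NE": 1.65, "CZ": 1.76,
            "NH1": 1.65, "NH2": 1.65},
    "ASN": {"CB": 1.87, "CG": 1.76, "OD1": 1.40, "ND2": 1.65},
    "ASP": {"CB": 1.87, "CG": 1.76, "OD1": 1.40, "OD2": 1.40},
    "CYS": {"CB": 1.87, "SG": 1.85},
    "GLN": {"CB": 1.87, "CG": 1.87, "CD": 1.76, "OE1": 1.40, "NE2": 1.65},
    "GLU": {"CB": 1.87, "CG": 1.87, "CD": 1.76, "OE1": 1.40, "OE2": 1.40},
    "GLY": {},
    "HIS": {"CB": 1.87, "CG": 1.76, "ND1": 1.65, "CD2": 1.76, "CE1": 1.76,
            "NE2": 1.65},
    "ILE": {"CB": 1.87, "CG1": 1.87, "CG2": 1.87, "CD1": 1.87},
    "LEU": {"CB": 1.87, "CG": 1.87, "CD1": 1.87, "CD2": 1.87},
    "LYS": {"CB": 1.87, "CG": 1.87, "CD": 1.87, "CE": 1.87, "NZ": 1.50},
    "MET": {"CB": 1.87, "CG": 1.87, "SD": 1.85, "CE": 1.87},
    "PHE": {"CB": 1.87, "CG": 1.76, "CD1": 1.76, "CD2": 1.76, "CE1": 1.76,
            "CE2": 1.76, "CZ": 1.76},
    "PRO": {"CB": 1.87, "CG": 1.87, "CD": 1.87},
    "SER": {"CB": 1.87, "OG": 1.40},
    "THR": {"CB": 1.87, "OG1": 1.40, "CG2": 1.87},
    "TRP": {"CB": 1.87, "CG": 1.76, "CD1": 1.76, "CD2": 1.76, "NE1": 1.65,
            "CE2": 1.76, "CE3": 1.76, "CZ2": 1.76, "CZ3": 1.76, "CH2": 1.76},
    "TYR": {"CB": 1.87, "CG": 1.76, "CD1": 1.76, "CD2": 1.76, "CE1": 1.76,
            "CE2": 1.76, "CZ": 1.76, "OH": 1.40},
    "VAL": {"CB": 1.87, "CG1": 1.87, "CG2": 1.87},
}
# fmt: on

#: NACCESS-style radius per (3-letter residue, atom name), Å.
SASA_RADII: dict[str, dict[str, float]] = {
    res: {**_BACKBONE, **side} for res, side in _SIDECHAINS.items()
}

#: Element fallback radii for atoms not covered by :data:`SASA_RADII`
#: (hetero groups, unusual names), Å.
SASA_ELEMENT_RADII: dict[str, float] = {
    "C": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
}
SASA_DEFAULT_RADIUS = 1.80

#: Theoretical maximum accessible surface area per residue type
#: (Tien et al. 2013), Å² — denominators for relative SASA.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

# Residue character: "C" charged, "P" polar, "A" apolar.
# Contact classification counts HIS as charged and CYS as apolar;
# the surface-composition table counts both as polar.
_COMMON = {
    "ALA": "A", "GLY": "A", "ILE": "A", "LEU": "A", "MET": "A",
    "PHE": "A", "PRO": "A", "VAL": "A",
    "ASN": "P", "GLN": "P", "SER": "P", "THR": "P", "TRP": "P", "TYR": "P",
    "ARG": "C", "LYS": "C", "ASP": "C", "GLU": "C",
}

#: Character table for interfacial-contact classification.
IC_CLASS: dict[str, str] = {**_COMMON, "CYS": "A", "HIS": "C"}

#: Character table for the non-interacting-surface composition.
NIS_CLASS: dict[str, str] = {**_COMMON, "CYS": "P", "HIS": "P"}

#: Bondi van der Waals radii per element symbol, Å (clash detection).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
}
VDW_DEFAULT_RADIUS = 1.70

#: Linear binding-affinity model: kcal/mol per unit of each term.
DG_COEFFICIENTS: dict[str, float] = {
    "ic_cc": -0.09459,   # charged/charged contacts
    "ic_ca": -0.10007,   # charged/apolar contacts
    "ic_pp": 0.19577,    # polar/polar contacts
    "ic_pa": -0.22671,   # polar/apolar contacts
    "pct_apolar": 0.18681,   # % apolar non-interacting surface
    "pct_charged": 0.13810,  # % charged non-interacting surface
    "intercept": -15.9433,
}

#: Standard 3-letter -> 1-letter amino acid code.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def sasa_radius(res_name: str, atom_name: str, element: str) -> float:
    """Radius used in solvent-accessibility integration, Å."""
    try:
        return SASA_RADII[res_name][atom_name]
    except KeyError:
        return SASA_ELEMENT_RADII.get(element.upper(), SASA_DEFAULT_RADIUS)


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius for an element symbol, Å."""
    return VDW_RADII.get(element.upper(), VDW_DEFAULT_RADIUS)
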