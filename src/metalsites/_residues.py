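"""Residue and element lookup tables shared across the package."""

# Standard amino acids, three-letter -> one-letter.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Common modified residues mapped to their standard parent (chemical-component
# parent relationships).  Non-exhaustive: anything absent maps to 'X'.
MODIFIED_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine ligates like Cys for our purposes
    "CSO": "CYS",
    "CSD": "CYS",
    "CME": "CYS",
    "OCS": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "KCX": "LYS",
    "HYP": "PRO",
    "PCA": "GLU",
    "FME": "MET",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

# Element symbols of all metals (and common hetero elements) used when the
# element column is blank and must be inferred from the atom name.
KNOWN_ELEMENTS = {
    "ZN", "MN", "FE", "CO", "NI", "CU", "CD", "CA", "MG", "NA", "K",
    "HG", "PB", "MO", "W", "V", "CR", "SR", "BA", "LI", "CS", "RB",
    "C", "N", "O", "S", "P", "H", "SE", "CL", "BR", "I", "F",
}

METAL_ELEMENTS = {
    "ZN", "MN", "FE", "CO", "NI", "CU", "CD", "CA", "MG", "NA", "K",
    "HG", "PB", "MO", "W", "V", "CR", "SR", "BA", "LI", "CS", "RB",
}


def standard_parent(resname: str) -> str | None:
    """Return the standard amino-acid name for *resname*, or None."""
    resname = resname.strip().upper()
    if resname in AA3_TO_1:
        return resname
    return MODIFIED_PARENT.get(resname)


def one_letter(resname: str) -> str:
    """One-letter code for a residue name; 'X' for nonstandard residues."""
    parent = standard_parent(resname)
    return AA3_TO_1[parent] if parent else "X"


def is_standard_aa(resname: str) -> bool:
    return standard_parent(resname) is not None


def is_water(resname: str) -> bool:
    return resname.strip().upper() in WATER_NAMES
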