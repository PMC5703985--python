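"""Reading and writing the legacy PDB dialect the pipeline depends on.

Metal coordination evidence comes exclusively from LINK records, resolution
from REMARK 2, crystallisation pH from REMARK 200 and sequences from SEQRES —
so this module parses exactly those records (plus ATOM/HETATM coordinates)
with wwPDB v3.3 column positions, tolerating the usual real-world mess:
missing element columns, pH ranges, NULL fields, unparseable lines.

Only altloc ' ' and 'A' conformers are kept; a LINK naming a discarded
altloc stays unresolved.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from ._residues import (
    AA1_TO_3,
    KNOWN_ELEMENTS,
    is_standard_aa,
    is_water,
    one_letter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "LinkEndpoint",
    "LinkRecord",
    "StructureModel",
    "StructureParseError",
    "parse_structure",
    "write_structure",
    "chain_sequence",
]


class StructureParseError(ValueError):
    """Raised when the input cannot be interpreted as a structure."""


@dataclass(slots=True)
class AtomRecord:
    serial: int
    name: str
    altloc: str
    residue_name: str
    chain: str
    residue_number: int
    insertion_code: str
    x: float
    y: float
    z: float
    element: str
    record_kind: str  # "ATOM" or "HETATM"

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(slots=True, frozen=True)
class LinkEndpoint:
    name: str
    altloc: str
    residue_name: str
    chain: str
    residue_number: int
    insertion_code: str


@dataclass(slots=True)
class LinkRecord:
    atom1: LinkEndpoint
    atom2: LinkEndpoint
    symmetry1: str = ""
    symmetry2: str = ""
    distance: float | None = None


IDENTITY_SYMOPS = {"", "1555"}


@dataclass(slots=True)
class StructureModel:
    pdb_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    links: list[LinkRecord] = field(default_factory=list)
    resolution: float | None = None
    ph: float | None = None
    method: str | None = None
    chain_sequences: dict[str, str] = field(default_factory=dict)

    def find_atom(self, ep: LinkEndpoint) -> AtomRecord | None:
        """Resolve a LINK endpoint to an atom in this model, or None."""
        for atom in self.atoms:
            if (
                atom.name == ep.name
                and atom.chain == ep.chain
                and atom.residue_number == ep.residue_number
                and atom.residue_name == ep.residue_name
                and atom.insertion_code == ep.insertion_code
                and (ep.altloc in ("", atom.altloc))
            ):
                return atom
        return None

    def unresolved_links(self) -> list[LinkRecord]:
        """LINK records with at least one endpoint that does not resolve.

        Endpoints carrying a non-identity symmetry operator are counted as
        unresolved: the partner atom lives in a symmetry mate we never build.
        """
        out = []
        for link in self.links:
            if link.symmetry1 not in IDENTITY_SYMOPS or link.symmetry2 not in IDENTITY_SYMOPS:
                out.append(link)
            elif self.find_atom(link.atom1) is None or self.find_atom(link.atom2) is None:
                out.append(link)
        return out

    def chains(self) -> list[str]:
        seen = dict.fromkeys(self.chain_sequences)
        for atom in self.atoms:
            seen.setdefault(atom.chain)
        return list(seen)


# --- element inference -------------------------------------------------------


def _infer_element(name: str, resname: str) -> str:
    """Infer the element when columns 77-78 are blank.

    Two-letter symbols are only trusted outside standard residues: the atom
    'CD' in the free-ion residue CD is cadmium, while 'CD1' in LEU is carbon.
    """
    alpha = "".join(c for c in name if c.isalpha()).upper()
    if not alpha:
        return ""
    if is_standard_aa(resname):
        if alpha == "SE":  # selenomethionine / selenocysteine selenium
            return "SE"
        return alpha[0]
    if alpha[:2] in KNOWN_ELEMENTS and (len(alpha) == 2 or alpha[:2] == resname.strip().upper()):
        return alpha[:2]
    return alpha[0]


# --- parsing -----------------------------------------------------------------

_RES_RE = re.compile(r"REMARK   2 RESOLUTION\.\s+(\d+(?:\.\d+)?)\s+ANGSTROM", re.IGNORECASE)
_PH_RE = re.compile(r"REMARK 200\s+PH\s*:\s*(.*)")
_RANGE_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)$")


def _parse_ph_value(raw: str) -> float | None:
    raw = raw.strip().rstrip(";").strip()
    if not raw or raw.upper() in ("NULL", "NONE", "N/A"):
        return None
    m = _RANGE_RE.match(raw)
    if m:  # a range like "7.0-8.0": take the midpoint
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    try:
        return float(raw)
    except ValueError:
        logger.warning("unparseable REMARK 200 pH value %r", raw)
        return None


def _parse_atom_line(line: str, kind: str) -> AtomRecord | None:
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        return None
    element = line[76:78].strip().upper()
    if not element:
        element = _infer_element(name, resname)
    if not element or not all(math.isfinite(v) for v in (x, y, z)):
        return None
    return AtomRecord(serial, name, altloc, resname, chain, resnum, icode, x, y, z, element, kind)


def _parse_link_endpoint(line: str, base: int) -> LinkEndpoint | None:
    try:
        name = line[base : base + 4].strip()
        altloc = line[base + 4].strip()
        resname = line[base + 5 : base + 8].strip()
        chain = line[base + 9].strip()
        resnum = int(line[base + 10 : base + 14])
        icode = line[base + 14].strip()
    except (ValueError, IndexError):
        return None
    if not name or not resname:
        return None
    return LinkEndpoint(name, altloc, resname, chain, resnum, icode)


def _parse_link_line(line: str) -> LinkRecord | None:
    line = line.rstrip("\n").ljust(80)
    ep1 = _parse_link_endpoint(line, 12)
    ep2 = _parse_link_endpoint(line, 42)
    if ep1 is None or ep2 is None:
        return None
    sym1 = line[59:65].strip()
    sym2 = line[66:72].strip()
    dist_raw = line[73:78].strip()
    distance = None
    if dist_raw:
        try:
            distance = float(dist_raw)
        except ValueError:
            distance = None
        if distance is not None and distance <= 0:
            distance = None
    return LinkRecord(ep1, ep2, sym1, sym2, distance)


def parse_structure(text: str, pdb_id: str | None = None) -> StructureModel:
    """Parse a PDB-format character stream into a :class:`StructureModel`.

    Unrecognised record types are ignored; lines of known types that fail
    column parsing are skipped with a log message, never fatal.  An input
    with no ATOM/HETATM records raises :class:`StructureParseError`.
    """
    model = StructureModel(pdb_id=pdb_id or "XXXX")
    seqres: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, rec.strip())
            if atom is None:
                logger.warning("skipping malformed %s record at line %d", rec.strip(), lineno)
            elif atom.altloc in ("", "A"):
                model.atoms.append(atom)
        elif rec == "LINK  ":
            link = _parse_link_line(line)
            if link is None:
                logger.warning("skipping malformed LINK record at line %d", lineno)
            else:
                model.links.append(link)
        elif rec == "SEQRES":
            chain = line[11] if len(line) > 11 else " "
            chain = chain.strip()
            names = line[19:].split()
            seqres.setdefault(chain, []).extend(names)
        elif rec == "REMARK":
            m = _RES_RE.match(line)
            if m:
                model.resolution = float(m.group(1))
                continue
            m = _PH_RE.match(line)
            if m:
                model.ph = _parse_ph_value(m.group(1))
        elif rec == "EXPDTA":
            model.method = line[10:].strip() or None
        elif rec == "HEADER" and pdb_id is None:
            code = line[62:66].strip()
            if code:
                model.pdb_id = code
    if not model.atoms:
        raise StructureParseError("not a structure: no ATOM/HETATM records")
    if seqres:
        model.chain_sequences = {
            ch: "".join(one_letter(n) for n in names) for ch, names in seqres.items()
        }
    else:
        model.chain_sequences = {
            ch: seq for ch in model.chains() if (seq := _atom_derived_sequence(model, ch))
        }
    if model.ph is not None and not (0.0 <= model.ph <= 14.0):
        logger.warning("pH %s outside [0, 14]; treating as absent", model.ph)
        model.ph = None
    return model


def _atom_derived_sequence(model: StructureModel, chain: str) -> str:
    seen: dict[tuple[int, str], str] = {}
    for atom in model.atoms:
        if atom.chain != chain or is_water(atom.residue_name):
            continue
        if not is_standard_aa(atom.residue_name):
            continue
        seen.setdefault((atom.residue_number, atom.insertion_code), one_letter(atom.residue_name))
    return "".join(seen[k] for k in sorted(seen))


def chain_sequence(model: StructureModel, chain: str) -> str:
    """One-letter sequence of *chain* (SEQRES preferred, ATOM-derived else)."""
    if chain in model.chain_sequences:
        return model.chain_sequences[chain]
    if chain in model.chains():
        return _atom_derived_sequence(model, chain)
    raise KeyError(f"unknown chain {chain!r}")


# --- writing -----------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def _format_link_endpoint(ep: LinkEndpoint, element_hint: str = "") -> str:
    name = _format_atom_name(ep.name, element_hint or _infer_element(ep.name, ep.residue_name))
    return (
        f"{name}{ep.altloc or ' '}{ep.residue_name:>3s} {ep.chain or ' '}"
        f"{ep.residue_number:>4d}{ep.insertion_code or ' '}"
    )


def write_structure(model: StructureModel) -> str:
    """Serialise *model* to PDB text that re-parses to an equal model."""
    lines: list[str] = []
    lines.append(f"HEADER    METAL BINDING PROTEIN                   01-JAN-00   {model.pdb_id:<4s}")
    if model.method:
        lines.append(f"EXPDTA    {model.method}")
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    if model.ph is not None:
        lines.append(f"REMARK 200  PH                             : {model.ph:.2f}")
    for chain, seq in model.chain_sequences.items():
        total = len(seq)
        for i in range(0, total, 13):
            block = seq[i : i + 13]
            names = " ".join(AA1_TO_3.get(c, "UNK") for c in block)
            lines.append(f"SEQRES {i // 13 + 1:>3d} {chain or ' '} {total:>4d}  {names}")
    for link in model.links:
        e1 = _format_link_endpoint(link.atom1)
        e2 = _format_link_endpoint(link.atom2)
        sym1 = f"{link.symmetry1:>6s}" if link.symmetry1 else "      "
        sym2 = f"{link.symmetry2:>6s}" if link.symmetry2 else "      "
        dist = f"{link.distance:5.2f}" if link.distance is not None else "     "
        lines.append(f"LINK        {e1}               {e2}  {sym1} {sym2} {dist}")
    for atom in model.atoms:
        if atom.serial > 99999:
            raise ValueError(f"atom serial overflow: {atom.serial} > 99999")
        name = _format_atom_name(atom.name, atom.element)
        lines.append(
            f"{atom.record_kind:<6s}{atom.serial:>5d} {name}{atom.altloc or ' '}"
            f"{atom.residue_name:>3s} {atom.chain or ' '}{atom.residue_number:>4d}"
            f"{atom.insertion_code or ' '}   "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
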