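"""Synthetic PDB corpora and MSAs with fully enumerable ground truth.

Every pipeline stage is tested against corpora generated here: PDB files
containing a scaffold protein chain, a metal HETATM, ligating atoms placed on
the vertices of a chosen ideal-geometry template (scaled to a 2.1 A mean bond
length, plus optional Gaussian noise), one LINK record per metal-ligand bond,
REMARK 2 resolution, REMARK 200 pH and SEQRES.  The accompanying manifest
knows each site's intended fate in the filtration cascade and computes the
expected statistics by direct enumeration — simple integer arithmetic over
the planted site specs that never calls the analysis code it is used to
check.

Scaffolds are deliberately minimal: only the ligating atom positions matter
to any implemented statistic, so side-chain realism is not attempted.  The
scaffold sequence is random per structure (poly-Ala would make every entry
one redundancy cluster); planted redundancy families reuse a family sequence
with <10% point mutations outside ligand positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._residues import AA3_TO_1, one_letter
from .geometry import build_template_library

__all__ = [
    "ProteinLigand",
    "SiteSpec",
    "CorpusRequest",
    "PlantedStructure",
    "CorpusManifest",
    "generate_structure",
    "generate_corpus",
    "MsaProfileSpec",
    "generate_msa",
]

MEAN_BOND_LENGTH = 2.1  # Angstrom, typical divalent d-block metal-O/N bond

_TEMPLATES = {t.code: t for t in build_template_library()}

_AA_LETTERS = sorted(AA3_TO_1.values())

# residue name and atom name for the metal of each species label
_METAL_ATOMS = {
    "MN": ("MN", "MN"), "ZN": ("ZN", "ZN"), "NI": ("NI", "NI"),
    "FE3": ("FE", "FE"), "FE2": ("FE2", "FE"), "CO": ("CO", "CO"),
    "CU": ("CU", "CU"), "CD": ("CD", "CD"), "CA": ("CA", "CA"),
    "MG": ("MG", "MG"),
}
_METAL_ELEMENT = {
    "MN": "MN", "ZN": "ZN", "NI": "NI", "FE3": "FE", "FE2": "FE",
    "CO": "CO", "CU": "CU", "CD": "CD", "CA": "CA", "MG": "MG",
}


@dataclass(frozen=True)
class ProteinLigand:
    """One ligating residue with the atom(s) it binds through."""

    residue_name: str
    atom_names: tuple[str, ...]  # two entries = bidentate chelation

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass(frozen=True)
class SiteSpec:
    metal: str  # species label, e.g. "ZN" or "FE2"
    ligands: tuple[ProteinLigand, ...]
    geometry_code: str
    noise_sigma: float = 0.0
    include_waters: int = 0
    decoy_ligand: tuple[str, str, str] | None = None  # (resname, atom, element)
    resolution: float | None = 1.8
    ph: float | None = 7.0

    @property
    def n_protein_atoms(self) -> int:
        return sum(lig.n_atoms for lig in self.ligands)

    @property
    def coordination_number(self) -> int:
        return self.n_protein_atoms + self.include_waters + (1 if self.decoy_ligand else 0)

    def __post_init__(self):
        tmpl = _TEMPLATES.get(self.geometry_code)
        if tmpl is None:
            raise ValueError(f"unknown geometry template {self.geometry_code!r}")
        if tmpl.coordination_number != self.coordination_number:
            raise ValueError(
                f"geometry {self.geometry_code} is CN {tmpl.coordination_number} "
                f"but the spec declares {self.coordination_number} ligand atoms"
            )
        if self.metal not in _METAL_ATOMS:
            raise ValueError(f"unknown metal species {self.metal!r}")


# --- structure generation ------------------------------------------------------

_LIGAND_RESNUM_START = 5
_LIGAND_RESNUM_SPACING = 4


def _ligand_positions(n: int) -> list[int]:
    return [_LIGAND_RESNUM_START + _LIGAND_RESNUM_SPACING * k for k in range(n)]


def _scaffold_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LETTERS, size=length))


def _add_site(
    model,
    spec: SiteSpec,
    chain: str,
    center: np.ndarray,
    serial0: int,
    rng: np.random.Generator,
    sequence: str,
) -> tuple[int, str]:
    """Append one planted site (scaffold + metal + ligands + LINKs) to *model*."""
    from .pdb_io import AtomRecord, LinkEndpoint, LinkRecord

    tmpl = _TEMPLATES[spec.geometry_code]
    vertices = tmpl.vertices * MEAN_BOND_LENGTH
    if spec.noise_sigma > 0:
        vertices = vertices + rng.normal(0.0, spec.noise_sigma, size=vertices.shape)
    vertices = np.round(vertices + center, 3)
    metal_xyz = np.round(center, 3)

    positions = _ligand_positions(len(spec.ligands))
    seq = list(sequence)
    for pos, lig in zip(positions, spec.ligands):
        seq[pos - 1] = one_letter(lig.residue_name)
    seq = "".join(seq)

    rev = {v: k for k, v in AA3_TO_1.items()}
    serial = serial0
    # scaffold CA trace, away from the binding site
    for i, letter in enumerate(seq, start=1):
        xyz = np.round([1.5 * i, -20.0 + (10.0 if chain != "A" else 0.0), -20.0], 3)
        model.atoms.append(
            AtomRecord(serial, "CA", "", rev[letter], chain, i, "",
                       float(xyz[0]), float(xyz[1]), float(xyz[2]), "C", "ATOM")
        )
        serial += 1

    m_res, m_name = _METAL_ATOMS[spec.metal]
    m_elem = _METAL_ELEMENT[spec.metal]
    m_resnum = 101
    ligand_atoms = []  # (name, resname, resnum, xyz, element, kind)
    vi = 0
    for pos, lig in zip(positions, spec.ligands):
        for atom_name in lig.atom_names:
            ligand_atoms.append(
                (atom_name, lig.residue_name, pos, vertices[vi], atom_name[0], "ATOM")
            )
            vi += 1
    for w in range(spec.include_waters):
        ligand_atoms.append(("O", "HOH", 201 + w, vertices[vi], "O", "HETATM"))
        vi += 1
    if spec.decoy_ligand:
        resname, atom_name, element = spec.decoy_ligand
        ligand_atoms.append((atom_name, resname, 301, vertices[vi], element, "HETATM"))
        vi += 1

    metal_ep = LinkEndpoint(m_name, "", m_res, chain, m_resnum, "")
    for atom_name, resname, resnum, xyz, element, kind in ligand_atoms:
        model.atoms.append(
            AtomRecord(serial, atom_name, "", resname, chain, resnum,
                       "", float(xyz[0]), float(xyz[1]), float(xyz[2]), element, kind)
        )
        serial += 1
        dist = round(float(np.linalg.norm(xyz - metal_xyz)), 2)
        model.links.append(
            LinkRecord(
                metal_ep,
                LinkEndpoint(atom_name, "", resname, chain, resnum, ""),
                "1555", "1555", dist,
            )
        )
    model.atoms.append(
        AtomRecord(serial, m_name, "", m_res, chain, m_resnum, "",
                   float(metal_xyz[0]), float(metal_xyz[1]), float(metal_xyz[2]),
                   m_elem, "HETATM")
    )
    serial += 1
    model.chain_sequences[chain] = seq
    return serial, seq


def generate_structure(
    spec: SiteSpec,
    seed: int | np.random.Generator = 0,
    pdb_id: str = "SYN1",
    sequence: str | None = None,
    symmetric_copies: int = 1,
) -> tuple[str, dict]:
    """Emit PDB text with one planted metal site (or symmetric copies of it).

    Returns the file text and a ground-truth record.  Deterministic for a
    fixed (spec, seed).  ``symmetric_copies`` > 1 plants the identical site
    in additional chains, emulating the symmetry-related sites of
    homo-oligomer crystals.
    """
    from .pdb_io import StructureModel, write_structure

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_res = len(spec.ligands)
    length = _ligand_positions(n_res)[-1] + 5 if n_res else 20
    if sequence is None:
        sequence = _scaffold_sequence(rng, max(length, 20))
    if len(sequence) < length:
        raise ValueError("sequence too short for the declared ligand count")

    model = StructureModel(
        pdb_id=pdb_id,
        resolution=spec.resolution,
        ph=spec.ph,
        method="X-RAY DIFFRACTION",
    )
    chains = [chr(ord("A") + k) for k in range(symmetric_copies)]
    serial = 1
    final_seq = sequence
    for k, chain in enumerate(chains):
        center = np.array([30.0, 30.0 + 40.0 * k, 30.0])
        serial, final_seq = _add_site(model, spec, chain, center, serial, rng, sequence)
    text = write_structure(model)
    truth = {
        "pdb_id": pdb_id,
        "spec": spec,
        "sequence": final_seq,
        "chains": chains,
        "n_sites_planted": symmetric_copies,
    }
    return text, truth


# --- corpus generation -----------------------------------------------------------

# Palette of site designs cycled over structures.  Each entry is
# (metal, ligands, geometry, waters).  Quartet sites (exactly four distinct
# residues) and chelated sites are both represented.
_SITE_PALETTE: tuple[tuple[str, tuple[ProteinLigand, ...], str, int], ...] = (
    ("ZN", (ProteinLigand("CYS", ("SG",)), ProteinLigand("CYS", ("SG",)),
            ProteinLigand("HIS", ("NE2",)), ProteinLigand("HIS", ("ND1",))), "tet", 0),
    ("MN", (ProteinLigand("ASP", ("OD1",)), ProteinLigand("ASP", ("OD1",)),
            ProteinLigand("GLU", ("OE1",))), "oct", 3),
    ("FE2", (ProteinLigand("GLU", ("OE1",)), ProteinLigand("GLU", ("OE1",)),
             ProteinLigand("GLU", ("OE2",)), ProteinLigand("HIS", ("NE2",))), "oct", 2),
    ("CU", (ProteinLigand("HIS", ("ND1",)), ProteinLigand("HIS", ("NE2",)),
            ProteinLigand("HIS", ("ND1",))), "tri", 0),
    ("CD", (ProteinLigand("ASP", ("OD1", "OD2")), ProteinLigand("GLU", ("OE1",)),
            ProteinLigand("HIS", ("NE2",))), "spy", 1),
    ("NI", (ProteinLigand("HIS", ("NE2",)), ProteinLigand("HIS", ("NE2",)),
            ProteinLigand("HIS", ("ND1",)), ProteinLigand("ASP", ("OD1",))), "oct", 2),
    ("CO", (ProteinLigand("ASP", ("OD1",)), ProteinLigand("GLU", ("OE1",)),
            ProteinLigand("GLU", ("OE2",)), ProteinLigand("HIS", ("NE2",))), "oct", 2),
    ("FE3", (ProteinLigand("HIS", ("NE2",)), ProteinLigand("HIS", ("ND1",)),
             ProteinLigand("GLU", ("OE1", "OE2"))), "spy", 1),
)

_PH_CYCLE: tuple[float | None, ...] = (6.0, 6.5, 7.0, 8.5, None, 5.2, 7.8, 8.0)


@dataclass(frozen=True)
class CorpusRequest:
    n_survivors: int = 20
    n_resolution_fail: int = 0
    n_coligand_fail: int = 0
    n_protein_min_fail: int = 0
    n_redundancy_families: int = 0
    copies_per_family: int = 1  # structures per family incl. the founder
    n_symmetric_dup: int = 0
    noise_sigma: float = 0.02
    identity_threshold: float = 0.9


@dataclass
class PlantedStructure:
    pdb_id: str
    spec: SiteSpec
    fate: str  # survive | resolution | coligand | protein_atoms | redundant
    family: str
    n_sites_planted: int = 1


@dataclass
class CorpusManifest:
    """Ground truth for a generated corpus, with expected statistics
    computed by direct enumeration over the planted site specs."""

    structures: list[PlantedStructure] = field(default_factory=list)
    identity_threshold: float = 0.9

    # -- enumeration helpers (pure arithmetic; no pipeline calls) --

    def expected_representatives(self) -> set[str]:
        reps: dict[str, str] = {}
        for s in self.structures:
            if s.family not in reps or s.pdb_id < reps[s.family]:
                reps[s.family] = s.pdb_id
        return set(reps.values())

    def _representative_structures(self) -> list[PlantedStructure]:
        reps = self.expected_representatives()
        return [s for s in self.structures if s.pdb_id in reps]

    def expected_stage_counts(self, dddd: bool = False) -> list[tuple[str, int, int]]:
        reps = self._representative_structures()
        current = list(reps)  # one site each after symmetric-duplicate removal
        counts = []
        if not dddd:
            survive = [s for s in current if s.fate != "resolution"]
            counts.append(("resolution", len(current), len(survive)))
            current = survive
        survive = [s for s in current if s.spec.decoy_ligand is None]
        counts.append(("coligand", len(current), len(survive)))
        current = survive
        survive = [s for s in current if s.spec.n_protein_atoms >= 2]
        counts.append(("protein_atoms", len(current), len(survive)))
        current = survive
        if dddd:
            survive = [s for s in current
                       if any(l.residue_name == "ASP" for l in s.spec.ligands)]
            counts.append(("link_component", len(current), len(survive)))
        return counts

    def expected_survivors(self) -> list[PlantedStructure]:
        return [
            s
            for s in self._representative_structures()
            if s.fate == "survive"
        ]

    def expected_propensity(self, mode: str = "by_atom") -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in self.expected_survivors():
            tab = out.setdefault(s.spec.metal, {})
            for lig in s.spec.ligands:
                aa = one_letter(lig.residue_name)
                tab[aa] = tab.get(aa, 0) + (lig.n_atoms if mode == "by_atom" else 1)
        return out

    def expected_cn(self) -> dict[str, dict[int, int]]:
        out: dict[str, dict[int, int]] = {}
        for s in self.expected_survivors():
            tab = out.setdefault(s.spec.metal, {})
            cn = s.spec.coordination_number
            tab[cn] = tab.get(cn, 0) + 1
        return out

    def expected_geometry(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in self.expected_survivors():
            tab = out.setdefault(s.spec.metal, {})
            tab[s.spec.geometry_code] = tab.get(s.spec.geometry_code, 0) + 1
        return out

    def expected_quartets(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in self.expected_survivors():
            if len(s.spec.ligands) != 4:
                continue
            key = "".join(sorted(one_letter(l.residue_name) for l in s.spec.ligands))
            tab = out.setdefault(s.spec.metal, {})
            tab[key] = tab.get(key, 0) + 1
        return out

    def expected_ph_bins(self) -> dict[str, int]:
        bins = {"acidic": 0, "mild_acidic": 0, "neutral": 0, "basic": 0}
        for s in self.expected_survivors():
            ph = s.spec.ph
            if ph is None:
                continue
            if ph <= 6.0:
                bins["acidic"] += 1
            elif ph < 7.0:
                bins["mild_acidic"] += 1
            elif ph < 8.0:
                bins["neutral"] += 1
            else:
                bins["basic"] += 1
        return bins


def _mutate_sequence(seq: str, rng: np.random.Generator, n_res: int, rate: float = 0.06) -> str:
    """Point-mutate below the redundancy threshold, avoiding ligand positions."""
    protected = set(_ligand_positions(n_res))
    out = list(seq)
    n_mut = max(1, int(len(seq) * rate))
    candidates = [i for i in range(len(seq)) if (i + 1) not in protected]
    picks = rng.choice(candidates, size=min(n_mut, len(candidates)), replace=False)
    for i in picks:
        choices = [c for c in _AA_LETTERS if c != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def generate_corpus(
    request: CorpusRequest, seed: int = 0
) -> tuple[dict[str, str], CorpusManifest]:
    """Generate a corpus of PDB files with planted filter fates.

    Returns ({pdb_id: file text}, manifest).  Deterministic for a fixed
    (request, seed).  Scaffold sequences are unique random sequences except
    within planted redundancy families.
    """
    rng = np.random.default_rng(seed)
    files: dict[str, str] = {}
    manifest = CorpusManifest(identity_threshold=request.identity_threshold)
    idx = 0

    def next_id() -> str:
        nonlocal idx
        pdb_id = f"S{idx:03d}"
        idx += 1
        return pdb_id

    def palette_spec(k: int, **overrides) -> SiteSpec:
        metal, ligands, geom, waters = _SITE_PALETTE[k % len(_SITE_PALETTE)]
        base = SiteSpec(
            metal=metal, ligands=ligands, geometry_code=geom,
            noise_sigma=request.noise_sigma, include_waters=waters,
            resolution=1.8, ph=_PH_CYCLE[k % len(_PH_CYCLE)],
        )
        return replace(base, **overrides) if overrides else base

    def emit(spec: SiteSpec, fate: str, family: str | None = None,
             sequence: str | None = None, copies: int = 1) -> str:
        pdb_id = next_id()
        text, truth = generate_structure(
            spec, rng, pdb_id=pdb_id, sequence=sequence, symmetric_copies=copies
        )
        files[pdb_id] = text
        manifest.structures.append(
            PlantedStructure(pdb_id, spec, fate, family or pdb_id, copies)
        )
        return pdb_id

    for k in range(request.n_survivors):
        emit(palette_spec(k), "survive")
    for k in range(request.n_resolution_fail):
        emit(palette_spec(k, resolution=2.4), "resolution")
    for k in range(request.n_coligand_fail):
        metal, ligands, geom, waters = _SITE_PALETTE[k % len(_SITE_PALETTE)]
        # swap the waters (or one protein slot's worth of CN) for a decoy:
        # keep CN identical to the palette geometry by trading one water
        if waters == 0:
            # grow the geometry by one vertex is not possible; use a CN+1 shape
            geom_up = {"tet": "spy", "tri": "tet", "oct": "pbp", "spy": "oct"}[geom]
            spec = SiteSpec(metal, ligands, geom_up,
                            noise_sigma=request.noise_sigma, include_waters=0,
                            decoy_ligand=("GOL", "O1", "O"), resolution=1.8,
                            ph=_PH_CYCLE[k % len(_PH_CYCLE)])
        else:
            spec = SiteSpec(metal, ligands, geom,
                            noise_sigma=request.noise_sigma, include_waters=waters - 1,
                            decoy_ligand=("GOL", "O1", "O"), resolution=1.8,
                            ph=_PH_CYCLE[k % len(_PH_CYCLE)])
        emit(spec, "coligand")
    for k in range(request.n_protein_min_fail):
        spec = SiteSpec(
            "ZN", (ProteinLigand("ASP", ("OD1",)),), "tet",
            noise_sigma=request.noise_sigma, include_waters=3,
            resolution=1.8, ph=_PH_CYCLE[k % len(_PH_CYCLE)],
        )
        emit(spec, "protein_atoms")
    for f in range(request.n_redundancy_families):
        spec = palette_spec(f)
        n_res = len(spec.ligands)
        length = _ligand_positions(n_res)[-1] + 5
        base_seq = _scaffold_sequence(rng, max(length, 20))
        family = emit(spec, "survive", sequence=base_seq)
        for _ in range(max(request.copies_per_family - 1, 0)):
            emit(spec, "redundant", family=family,
                 sequence=_mutate_sequence(base_seq, rng, n_res))
    for k in range(request.n_symmetric_dup):
        emit(palette_spec(k), "survive", copies=2)
    return files, manifest


# --- synthetic MSAs --------------------------------------------------------------


@dataclass(frozen=True)
class MsaProfileSpec:
    """A clade-MSA emulation: 30 A-site positions with planted distributions.

    ``position_distributions`` maps block position (1-30) to a residue
    distribution; unlisted positions use the background.  The reference row
    is YiiP-like, with the quartet anchors D45, D49, H153 and D157 and the
    A-site blocks at reference residues 40-54 and 148-162.
    ``insertion_columns`` adds alignment columns (gap in the reference)
    after the given reference residue numbers.
    """

    n_sequences: int = 50
    position_distributions: dict[int, dict[str, float]] = field(default_factory=dict)
    background: dict[str, float] | None = None  # None = uniform over 20
    insertion_columns: tuple[int, ...] = ()  # reference residue numbers
    reference_length: int = 170
    reference_id: str = "YiiP"

    def __post_init__(self):
        for pos, dist in self.position_distributions.items():
            if not 1 <= pos <= 30:
                raise ValueError(f"block position {pos} outside 1-30")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution at position {pos} sums to {total}")


_YIIP_ANCHOR_NUMS = (45, 49, 153, 157)
_YIIP_ANCHOR_CODES = ("D", "D", "H", "D")


def _block_residue_numbers(flank: int = 5) -> list[int]:
    nums = []
    for first, second in ((45, 49), (153, 157)):
        nums.extend(range(first - flank, second + flank + 1))
    return nums


def consensus_letters(spec: MsaProfileSpec) -> dict[int, str]:
    """Most probable residue per planted block position (enumeration oracle)."""
    out = {}
    for pos, dist in spec.position_distributions.items():
        best = max(dist.values())
        out[pos] = sorted(c for c, p in dist.items() if p == best)[0]
    return out


def hdhd_clade_spec(n_sequences: int = 50, conservation: float = 1.0) -> MsaProfileSpec:
    """A clade profile planting the HD-HD quartet at the anchor positions."""
    dists = {}
    for pos, letter in zip((6, 10, 21, 25), "HDHD"):
        rest = (1.0 - conservation) / 19.0
        dists[pos] = {c: (conservation if c == letter else rest) for c in _AA_LETTERS}
    return MsaProfileSpec(n_sequences=n_sequences, position_distributions=dists)


def generate_msa(spec: MsaProfileSpec, seed: int = 0) -> tuple[str, dict]:
    """Aligned FASTA text for a synthetic clade MSA, plus ground truth.

    The reference row is included (first record).  Ground truth records the
    planted alignment columns of the 30 block positions and the sampled
    per-position counts.
    """
    rng = np.random.default_rng(seed)
    ref_res = list(_scaffold_sequence(rng, spec.reference_length))
    for num, code in zip(_YIIP_ANCHOR_NUMS, _YIIP_ANCHOR_CODES):
        ref_res[num - 1] = code

    insertion_after = sorted(spec.insertion_columns)
    # alignment column layout: reference residues 1..L with insertion columns
    columns: list[int | None] = []  # reference residue number or None (insertion)
    for num in range(1, spec.reference_length + 1):
        columns.append(num)
        if num in insertion_after:
            columns.append(None)
    res2col = {num: i for i, num in enumerate(columns) if num is not None}
    block_nums = _block_residue_numbers()
    planted_columns = [res2col[num] for num in block_nums]
    block_pos_of_num = {num: i + 1 for i, num in enumerate(block_nums)}

    if spec.background:
        bg_codes = sorted(spec.background)
        bg_probs = np.array([spec.background[c] for c in bg_codes])
        bg_probs = bg_probs / bg_probs.sum()
    else:
        bg_codes, bg_probs = _AA_LETTERS, np.full(20, 1 / 20)

    rows = []
    ref_row = "".join(ref_res[num - 1] if num is not None else "-" for num in columns)
    rows.append((spec.reference_id, ref_row))
    counts: dict[int, dict[str, int]] = {i: {} for i in range(1, 31)}
    for s in range(spec.n_sequences):
        chars = []
        for num in columns:
            if num is None:
                chars.append(str(rng.choice(bg_codes, p=bg_probs)))
                continue
            pos = block_pos_of_num.get(num)
            if pos is not None and pos in spec.position_distributions:
                dist = spec.position_distributions[pos]
                codes = sorted(dist)
                probs = np.array([dist[c] for c in codes])
                ch = str(rng.choice(codes, p=probs / probs.sum()))
            else:
                ch = str(rng.choice(bg_codes, p=bg_probs))
            if pos is not None:
                counts[pos][ch] = counts[pos].get(ch, 0) + 1
            chars.append(ch)
        rows.append((f"seq{s:04d}", "".join(chars)))

    fasta = "".join(f">{name}\n{seq}\n" for name, seq in rows)
    truth = {
        "planted_columns": planted_columns,
        "block_residue_numbers": block_nums,
        "counts": counts,
        "reference_id": spec.reference_id,
        "n_sequences": spec.n_sequences,
    }
    return fasta, truth
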