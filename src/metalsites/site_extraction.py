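"""Metal-binding-site construction from LINK records and the filtration cascade.

A metal site is one metal ion (identified either by its atom label, e.g. ZN,
or by its free-ion residue component, e.g. FE2 for ferrous iron) together
with every atom the structure's LINK records bond to it.  Ligating atoms are
classed as protein (standard amino acid, modified residues mapped to their
parent), water, or other.  Coordination evidence comes from LINK records
only — no distance-based rescue.

The filtration cascade mirrors the selection used for the statistics:
resolution cut-off, water-only co-ligands, a minimum number of
protein-related ligating atoms, and optionally a required ligating residue
(the Asp requirement of the DDDD-quartet variant).  Per-stage counts are
collected in a :class:`FilterReport`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

from ._residues import is_standard_aa, is_water, one_letter, standard_parent
from .pdb_io import IDENTITY_SYMOPS, AtomRecord, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "MetalSpec",
    "LigandAtom",
    "MetalSite",
    "FilterConfig",
    "FilterReport",
    "DEFAULT_METALS",
    "DDDD_METALS",
    "STANDARD_FILTER",
    "DDDD_FILTER",
    "build_sites",
    "apply_filters",
    "dedup_equivalent_sites",
    "sites_to_tsv",
]


@dataclass(frozen=True)
class MetalSpec:
    """One metal species of interest.

    ``label`` distinguishes species that share an element: ferrous iron is
    recognised by its residue component FE2, ferric iron by the bare FE atom
    label in residue FE.
    """

    label: str  # species label used in all tables, e.g. "ZN", "FE2", "FE3"
    element: str
    het_codes: tuple[str, ...]  # accepted free-ion residue names
    atom_names: tuple[str, ...]  # accepted metal atom labels

    def matches(self, atom: AtomRecord) -> bool:
        return (
            atom.record_kind == "HETATM"
            and atom.element.upper() == self.element
            and atom.residue_name.upper() in self.het_codes
            and atom.name.upper() in self.atom_names
        )


# The eight species of the main statistics: seven divalent d-block cations
# plus ferric iron as the reference for the iron oxidation state.
DEFAULT_METALS: tuple[MetalSpec, ...] = (
    MetalSpec("MN", "MN", ("MN",), ("MN",)),
    MetalSpec("ZN", "ZN", ("ZN",), ("ZN",)),
    MetalSpec("NI", "NI", ("NI",), ("NI",)),
    MetalSpec("FE3", "FE", ("FE",), ("FE",)),
    MetalSpec("FE2", "FE", ("FE2",), ("FE", "FE2")),
    MetalSpec("CO", "CO", ("CO",), ("CO",)),
    MetalSpec("CU", "CU", ("CU",), ("CU",)),
    MetalSpec("CD", "CD", ("CD",), ("CD",)),
)

# The DDDD-variant adds the two hard divalent cations considered as candidate
# incoming ions of the antiport cycle.
DDDD_METALS: tuple[MetalSpec, ...] = DEFAULT_METALS + (
    MetalSpec("CA", "CA", ("CA",), ("CA",)),
    MetalSpec("MG", "MG", ("MG",), ("MG",)),
)


@dataclass(frozen=True)
class LigandAtom:
    atom: AtomRecord
    ligand_class: str  # "protein" | "water" | "other"
    bond_length: float  # Angstrom, recomputed from coordinates

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        a = self.atom
        return (a.chain, a.residue_name, a.residue_number, a.insertion_code)


@dataclass
class MetalSite:
    structure_id: str
    metal: AtomRecord
    species: MetalSpec
    ligands: list[LigandAtom]

    @property
    def site_id(self) -> str:
        m = self.metal
        return f"{self.structure_id}:{self.species.label}:{m.chain}{m.residue_number}"

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def n_protein_atoms(self) -> int:
        return sum(1 for lig in self.ligands if lig.ligand_class == "protein")

    @property
    def protein_ligands(self) -> list[LigandAtom]:
        return [lig for lig in self.ligands if lig.ligand_class == "protein"]

    def residue_multiset(self) -> dict[tuple[str, str, int, str], int]:
        """Distinct ligating protein residues with their per-residue atom counts."""
        out: dict[tuple[str, str, int, str], int] = {}
        for lig in self.protein_ligands:
            out[lig.residue_key] = out.get(lig.residue_key, 0) + 1
        return out

    def distinct_protein_residues(self) -> list[tuple[str, str, int, str]]:
        return list(self.residue_multiset())

    def residue_composition(self) -> str:
        """Sorted one-letter composition of distinct ligating residues."""
        return "".join(sorted(one_letter(key[1]) for key in self.distinct_protein_residues()))

    def has_other_ligand(self) -> bool:
        return any(lig.ligand_class == "other" for lig in self.ligands)

    def ligates_residue(self, resname: str) -> bool:
        resname = resname.upper()
        return any(
            lig.atom.residue_name.upper() == resname
            or standard_parent(lig.atom.residue_name) == resname
            for lig in self.protein_ligands
        )

    def site_coordinates(self):
        """(CN+1, 3) array, metal first — the geometry-assignment input."""
        import numpy as np

        rows = [self.metal.coords] + [lig.atom.coords for lig in self.ligands]
        return np.asarray(rows, dtype=float)


def _classify_ligand(atom: AtomRecord) -> str:
    if is_water(atom.residue_name):
        return "water"
    if is_standard_aa(atom.residue_name) and atom.record_kind in ("ATOM", "HETATM"):
        # modified residues (e.g. MSE) arrive as HETATM but belong to the chain
        if atom.record_kind == "ATOM" or standard_parent(atom.residue_name):
            return "protein"
    return "other"


def _distance(a: AtomRecord, b: AtomRecord) -> float:
    return math.dist(a.coords, b.coords)


def build_sites(model: StructureModel, metals: tuple[MetalSpec, ...] = DEFAULT_METALS) -> list[MetalSite]:
    """One :class:`MetalSite` per matching metal ion with >= 1 resolved LINK partner.

    LINK endpoints carrying a non-identity symmetry operator point into a
    symmetry mate that is not present in the model; those partners are
    dropped (and logged).  A metal whose every LINK is unresolved yields no
    site, matching the criterion that coordination must be evidenced by
    usable LINK records.
    """
    sites: list[MetalSite] = []
    for atom in model.atoms:
        spec = next((m for m in metals if m.matches(atom)), None)
        if spec is None:
            continue
        ligands: list[LigandAtom] = []
        seen: set[int] = set()
        for link in model.links:
            for self_ep, other_ep, sym in (
                (link.atom1, link.atom2, link.symmetry2),
                (link.atom2, link.atom1, link.symmetry1),
            ):
                if (
                    self_ep.name != atom.name
                    or self_ep.chain != atom.chain
                    or self_ep.residue_number != atom.residue_number
                    or self_ep.residue_name != atom.residue_name
                ):
                    continue
                if sym not in IDENTITY_SYMOPS:
                    logger.info(
                        "%s: dropping LINK partner of %s under symop %s",
                        model.pdb_id, spec.label, sym,
                    )
                    continue
                partner = model.find_atom(other_ep)
                if partner is None:
                    logger.warning("%s: unresolved LINK endpoint %s", model.pdb_id, other_ep)
                    continue
                if id(partner) in seen or partner is atom:
                    continue
                seen.add(id(partner))
                ligands.append(
                    LigandAtom(partner, _classify_ligand(partner), _distance(atom, partner))
                )
        if ligands:
            sites.append(MetalSite(model.pdb_id, atom, spec, ligands))
    return sites


# --- the filtration cascade ---------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    max_resolution: float | None = 2.0
    require_protein_atoms_min: int = 2
    allow_only_water_coligands: bool = True
    require_link_component: str | None = None
    metals: tuple[MetalSpec, ...] = DEFAULT_METALS

    def __post_init__(self):
        if self.require_protein_atoms_min < 0:
            raise ValueError("require_protein_atoms_min must be >= 0")
        if self.require_protein_atoms_min == 0 and self.allow_only_water_coligands:
            logger.warning("FilterConfig allows sites with no protein atoms at all")


# the main-statistics criteria and the DDDD-quartet variant
STANDARD_FILTER = FilterConfig()
DDDD_FILTER = FilterConfig(
    max_resolution=None, require_link_component="ASP", metals=DDDD_METALS
)


@dataclass
class FilterReport:
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, survivors: list[MetalSite], dropped: list[MetalSite]):
        self.stages.append(
            {
                "stage": name,
                "input": n_in,
                "surviving": len(survivors),
                "dropped_ids": [s.site_id for s in dropped],
            }
        )

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s["stage"], s["input"], s["surviving"]) for s in self.stages]

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages}, indent=1)


def apply_filters(
    sites: list[MetalSite],
    models: dict[str, StructureModel],
    config: FilterConfig = STANDARD_FILTER,
) -> tuple[list[MetalSite], FilterReport]:
    """Run the cascade and report per-stage counts.

    Stage order: resolution -> water-only co-ligands -> minimum protein
    atoms -> required ligating component.  Counts are non-increasing; the
    final stage's survivors are returned.
    """
    report = FilterReport()
    current = list(sites)

    def run_stage(name: str, keep) -> None:
        nonlocal current
        n_in = len(current)
        survivors = [s for s in current if keep(s)]
        dropped = [s for s in current if not keep(s)]
        report.add(name, n_in, survivors, dropped)
        current = survivors

    if config.max_resolution is not None:
        def res_ok(site: MetalSite) -> bool:
            model = models[site.structure_id]
            return model.resolution is not None and model.resolution <= config.max_resolution
        run_stage("resolution", res_ok)
    if config.allow_only_water_coligands:
        run_stage("coligand", lambda s: not s.has_other_ligand())
    run_stage(
        "protein_atoms",
        lambda s: s.n_protein_atoms >= config.require_protein_atoms_min,
    )
    if config.require_link_component is not None:
        run_stage(
            "link_component",
            lambda s, rn=config.require_link_component: s.ligates_residue(rn),
        )
    return current, report


def _site_fingerprint(site: MetalSite) -> tuple:
    """Equivalence fingerprint: species + residue names, ligating atom names
    and sequence-position offsets within their chains (waters by count)."""
    protein = []
    per_chain_min: dict[str, int] = {}
    for lig in site.protein_ligands:
        ch = lig.atom.chain
        per_chain_min[ch] = min(per_chain_min.get(ch, 1 << 30), lig.atom.residue_number)
    for lig in site.protein_ligands:
        a = lig.atom
        protein.append((a.residue_name, a.name, a.residue_number - per_chain_min[a.chain]))
    n_water = sum(1 for lig in site.ligands if lig.ligand_class == "water")
    n_other = sum(1 for lig in site.ligands if lig.ligand_class == "other")
    return (site.species.label, tuple(sorted(protein)), n_water, n_other)


def dedup_equivalent_sites(sites: list[MetalSite]) -> list[MetalSite]:
    """Keep one representative per group of symmetry-equivalent sites.

    All sites must come from one structure.  Sites are equivalent when they
    share species and residue-offset fingerprint (which catches NCS copies
    in homo-oligomers as well as LINK-duplicated sites); the representative
    is the lexicographically first (chain, residue_number) metal.
    """
    if not sites:
        return []
    ids = {s.structure_id for s in sites}
    if len(ids) > 1:
        raise ValueError(f"sites from multiple structures: {sorted(ids)}")
    groups: dict[tuple, MetalSite] = {}
    for site in sites:
        key = _site_fingerprint(site)
        held = groups.get(key)
        if held is None or (site.metal.chain, site.metal.residue_number) < (
            held.metal.chain,
            held.metal.residue_number,
        ):
            groups[key] = site
    chosen = set(id(s) for s in groups.values())
    return [s for s in sites if id(s) in chosen]


def sites_to_tsv(sites: list[MetalSite]) -> str:
    """One site per row: pdb_id, metal, chain, resnum, CN, protein atoms, multiset."""
    lines = ["pdb_id\tmetal\tchain\tresnum\tcn\tn_protein_atoms\tresidue_multiset"]
    for s in sites:
        parts = [
            f"{key[1]}{key[2]}{key[0]}x{count}"
            for key, count in sorted(s.residue_multiset().items())
        ]
        lines.append(
            f"{s.structure_id}\t{s.species.label}\t{s.metal.chain}\t{s.metal.residue_number}"
            f"\t{s.coordination_number}\t{s.n_protein_atoms}\t{','.join(parts)}"
        )
    return "\n".join(lines) + "\n"
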