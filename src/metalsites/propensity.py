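"""Binding statistics over filtered metal sites.

All quantities are per-metal descriptive fractions:

* amino-acid propensities, counted by ligating atom (a residue chelating
  through two atoms counts twice) or by distinct residue;
* coordination-number distributions (waters count as ligands);
* coordination-geometry distributions over sites with a defined (non-
  irregular) geometry — so per metal the CN pool is always at least as large
  as the geometry pool;
* pH-stratified variants over four crystallisation-pH bins;
* quartet profiles over sites ligated by exactly four distinct residues,
  keyed by the sorted one-letter composition, cysteine-containing quartets
  flagged apart.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from ._residues import one_letter
from .geometry import GeometryAssignment
from .site_extraction import MetalSite

__all__ = [
    "PropensityTable",
    "CNDistribution",
    "GeometryDistribution",
    "QuartetProfile",
    "PH_BINS",
    "ph_bin_label",
    "compute_propensities",
    "cn_distribution",
    "geometry_distribution",
    "stratify_by_ph",
    "extract_quartets",
    "table_to_tsv",
]


@dataclass
class FractionTable:
    """metal species -> key -> (count, fraction); fractions sum to 1 per metal."""

    counts: dict[str, Counter] = field(default_factory=lambda: defaultdict(Counter))

    def add(self, metal: str, key, n: int = 1) -> None:
        self.counts[metal][key] += n

    def denominator(self, metal: str) -> int:
        return sum(self.counts[metal].values())

    def fraction(self, metal: str, key) -> float:
        total = self.denominator(metal)
        return self.counts[metal][key] / total if total else 0.0

    def fractions(self, metal: str) -> dict:
        total = self.denominator(metal)
        return {k: v / total for k, v in sorted(self.counts[metal].items()) if total}

    def metals(self) -> list[str]:
        return sorted(self.counts)

    def as_dict(self) -> dict:
        return {
            metal: {
                str(k): {"count": v, "fraction": self.fraction(metal, k)}
                for k, v in sorted(self.counts[metal].items())
            }
            for metal in self.metals()
        }


@dataclass
class PropensityTable(FractionTable):
    mode: str = "by_atom"


@dataclass
class CNDistribution(FractionTable):
    pass


@dataclass
class GeometryDistribution(FractionTable):
    pass


@dataclass
class QuartetProfile(FractionTable):
    def cysteine_keys(self, metal: str) -> list[str]:
        return [k for k in self.counts[metal] if "C" in k]


def compute_propensities(sites: list[MetalSite], mode: str = "by_atom") -> PropensityTable:
    """Amino-acid propensities per metal.

    ``by_atom`` counts every metal-(protein atom) bond; ``by_residue``
    counts each distinct ligating residue once.  Waters and non-protein
    ligands never contribute.
    """
    if mode not in ("by_atom", "by_residue"):
        raise ValueError(f"unknown mode {mode!r}")
    table = PropensityTable(mode=mode)
    for site in sites:
        metal = site.species.label
        if mode == "by_atom":
            for lig in site.protein_ligands:
                table.add(metal, one_letter(lig.atom.residue_name))
        else:
            for key in site.distinct_protein_residues():
                table.add(metal, one_letter(key[1]))
    return table


def cn_distribution(sites: list[MetalSite]) -> CNDistribution:
    """Coordination-number counts per metal; every site contributes once."""
    table = CNDistribution()
    for site in sites:
        table.add(site.species.label, site.coordination_number)
    return table


def geometry_distribution(assignments: list[tuple[MetalSite, GeometryAssignment]]) -> GeometryDistribution:
    """Geometry counts per metal over sites with a defined geometry only."""
    table = GeometryDistribution()
    for site, assignment in assignments:
        if assignment.regularity == "irregular" or assignment.best_code is None:
            continue
        table.add(site.species.label, assignment.best_code)
    return table


# Crystallisation-pH bins: <=6, (6, 7), [7, 8), >=8 — a partition of [0, 14].
PH_BINS = ("acidic", "mild_acidic", "neutral", "basic")


def ph_bin_label(ph: float) -> str:
    if ph <= 6.0:
        return "acidic"
    if ph < 7.0:
        return "mild_acidic"
    if ph < 8.0:
        return "neutral"
    return "basic"


def stratify_by_ph(
    sites: list[MetalSite], models: dict
) -> dict[str, tuple[PropensityTable, CNDistribution]]:
    """Per-pH-bin propensity and CN tables.

    Sites from structures lacking a recorded pH are excluded from this
    analysis only; every pH-bearing site lands in exactly one bin.
    """
    binned: dict[str, list[MetalSite]] = {label: [] for label in PH_BINS}
    for site in sites:
        ph = models[site.structure_id].ph
        if ph is None:
            continue
        binned[ph_bin_label(ph)].append(site)
    return {
        label: (compute_propensities(group, "by_atom"), cn_distribution(group))
        for label, group in binned.items()
    }


def extract_quartets(sites: list[MetalSite]) -> QuartetProfile:
    """Quartet profile: sites ligated by exactly four distinct protein residues.

    Waters are permitted alongside; sites with other co-ligands were already
    dropped upstream.  The key is the alphabetically sorted one-letter
    composition, e.g. "DDHH".
    """
    profile = QuartetProfile()
    for site in sites:
        if len(site.distinct_protein_residues()) != 4:
            continue
        profile.add(site.species.label, site.residue_composition())
    return profile


def table_to_tsv(table: FractionTable, key_header: str = "key") -> str:
    lines = [f"metal\t{key_header}\tcount\tfraction"]
    for metal in table.metals():
        for key, count in sorted(table.counts[metal].items()):
            lines.append(f"{metal}\t{key}\t{count}\t{table.fraction(metal, key):.12g}")
    return "\n".join(lines) + "\n"
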