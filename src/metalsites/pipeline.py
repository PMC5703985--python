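"""End-to-end orchestration: scan a PDB corpus, produce every statistics table.

The scan follows the selection procedure of the metal statistics: parse all
files, collapse >90%-identity redundant entries to one representative, build
metal sites from LINK records, keep one representative of symmetry-equivalent
sites per structure, run the filtration cascade, then compute propensity, CN,
geometry, pH-stratified and quartet tables.

Two shipped presets make the two published selection recipes executable:
``standard-2016`` (X-ray, resolution <= 2.0 A, water-only co-ligands, >= 2
protein atoms) and ``dddd-variant`` (no resolution/method limit, Asp must be
among the LINKed components, Ca and Mg added to the species list).
"""

from __future__ import annotations

import glob as globmod
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import asite as asite_mod
from .geometry import (
    DISTORTED_MAX_RMSD,
    REGULAR_MAX_RMSD,
    assign_geometry,
    load_template_library,
)
from .pdb_io import StructureModel, StructureParseError, parse_structure
from .propensity import (
    cn_distribution,
    compute_propensities,
    extract_quartets,
    geometry_distribution,
    stratify_by_ph,
    table_to_tsv,
)
from .redundancy import cluster_representatives, longest_chain_seq
from .site_extraction import (
    DDDD_FILTER,
    DDDD_METALS,
    DEFAULT_METALS,
    STANDARD_FILTER,
    FilterConfig,
    FilterReport,
    MetalSite,
    apply_filters,
    build_sites,
    dedup_equivalent_sites,
    sites_to_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanResult", "run_scan", "run_asite", "PRESETS"]

PRESETS = {
    "standard-2016": STANDARD_FILTER,
    "dddd-variant": DDDD_FILTER,
}


@dataclass(frozen=True)
class RunConfig:
    inputs: tuple[str, ...]
    output_dir: str = "metalsites_out"
    preset: str = "standard-2016"
    max_resolution: float | None = "preset"  # type: ignore[assignment]
    require_protein_atoms_min: int | None = None
    allow_only_water_coligands: bool | None = None
    require_link_component: str | None = "preset"  # type: ignore[assignment]
    identity_threshold: float = 0.9
    do_geometry: bool = True
    do_ph: bool = True
    do_quartets: bool = True
    propensity_modes: tuple[str, ...] = ("by_atom", "by_residue")
    regular_max_rmsd: float = REGULAR_MAX_RMSD
    distorted_max_rmsd: float = DISTORTED_MAX_RMSD
    seed: int = 0

    def filter_config(self) -> FilterConfig:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        cfg = PRESETS[self.preset]
        kwargs = {}
        if self.max_resolution != "preset":
            kwargs["max_resolution"] = self.max_resolution
        if self.require_protein_atoms_min is not None:
            kwargs["require_protein_atoms_min"] = self.require_protein_atoms_min
        if self.allow_only_water_coligands is not None:
            kwargs["allow_only_water_coligands"] = self.allow_only_water_coligands
        if self.require_link_component != "preset":
            kwargs["require_link_component"] = self.require_link_component
        return replace(cfg, **kwargs) if kwargs else cfg

    # -- flat key=value round-trip --

    def to_key_values(self) -> str:
        lines = []
        for key, value in sorted(self.__dict__.items()):
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_key_values(cls, text: str) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs: dict = {}
        def parse_opt_float(v):
            return None if v in ("None", "") else ("preset" if v == "preset" else float(v))
        for key, value in raw.items():
            if key in ("inputs", "propensity_modes"):
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif key in ("max_resolution",):
                kwargs[key] = parse_opt_float(value)
            elif key in ("require_protein_atoms_min",):
                kwargs[key] = None if value == "None" else int(value)
            elif key in ("allow_only_water_coligands",):
                kwargs[key] = None if value == "None" else value == "True"
            elif key in ("require_link_component",):
                kwargs[key] = None if value == "None" else value
            elif key in ("identity_threshold", "regular_max_rmsd", "distorted_max_rmsd"):
                kwargs[key] = float(value)
            elif key in ("do_geometry", "do_ph", "do_quartets"):
                kwargs[key] = value == "True"
            elif key == "seed":
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class ScanResult:
    models: dict[str, StructureModel]
    representatives: list[str]
    sites_before_filters: list[MetalSite]
    surviving_sites: list[MetalSite]
    report: FilterReport
    tables: dict[str, object] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> text


def _collect_inputs(patterns: tuple[str, ...]) -> list[Path]:
    paths: list[Path] = []
    for pattern in patterns:
        p = Path(pattern)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.pdb")) + sorted(p.glob("*.ent")))
        elif any(ch in pattern for ch in "*?["):
            paths.extend(Path(m) for m in sorted(globmod.glob(pattern)))
        elif p.exists():
            paths.append(p)
    return paths


def scan_corpus(
    models: dict[str, StructureModel], config: RunConfig
) -> ScanResult:
    """Run redundancy reduction, site building, dedup and filters on parsed models."""
    fcfg = config.filter_config()
    entries = [longest_chain_seq(m) for m in models.values()]
    reps = cluster_representatives(entries, config.identity_threshold)
    rep_set = set(reps)
    dropped_redundant = sorted(set(models) - rep_set)
    for pdb_id in dropped_redundant:
        logger.info("dropped as redundant: %s", pdb_id)

    sites: list[MetalSite] = []
    for pdb_id in sorted(rep_set):
        model = models[pdb_id]
        built = build_sites(model, fcfg.metals)
        kept = dedup_equivalent_sites(built)
        for dup in set(s.site_id for s in built) - set(s.site_id for s in kept):
            logger.info("dropped as symmetry-equivalent: %s", dup)
        sites.extend(kept)

    surviving, report = apply_filters(sites, models, fcfg)
    # prepend the redundancy stage so the report covers the whole cascade
    report.stages.insert(
        0,
        {
            "stage": "redundancy",
            "input": len(models),
            "surviving": len(rep_set),
            "dropped_ids": dropped_redundant,
        },
    )
    return ScanResult(models, sorted(rep_set), sites, surviving, report)


def compute_tables(result: ScanResult, config: RunConfig) -> None:
    """Fill ``result.tables`` and ``result.outputs`` with every requested statistic."""
    sites = result.surviving_sites
    outputs = result.outputs
    tables = result.tables
    for mode in config.propensity_modes:
        table = compute_propensities(sites, mode)
        tables[f"propensity_{mode}"] = table
        outputs[f"propensity_{mode}.tsv"] = table_to_tsv(table, "residue")
    cn = cn_distribution(sites)
    tables["cn"] = cn
    outputs["cn_distribution.tsv"] = table_to_tsv(cn, "coordination_number")
    if config.do_geometry:
        library = load_template_library()
        assignments = [
            (s, assign_geometry(s, library, (config.regular_max_rmsd, config.distorted_max_rmsd)))
            for s in sites
        ]
        tables["assignments"] = assignments
        geo = geometry_distribution(assignments)
        tables["geometry"] = geo
        outputs["geometry_distribution.tsv"] = table_to_tsv(geo, "geometry")
        lines = ["site_id\tcn\tcode\trmsd\trmsd_normalized\tregularity"]
        for s, a in assignments:
            lines.append(
                f"{a.site_id}\t{a.coordination_number}\t{a.best_code or 'irregular'}"
                f"\t{a.rmsd:.6g}\t{a.rmsd_normalized:.6g}\t{a.regularity}"
            )
        outputs["geometry_assignments.tsv"] = "\n".join(lines) + "\n"
    if config.do_ph:
        ph_tables = stratify_by_ph(sites, result.models)
        tables["ph"] = ph_tables
        for label, (prop, cndist) in ph_tables.items():
            outputs[f"ph_{label}_propensity_by_atom.tsv"] = table_to_tsv(prop, "residue")
            outputs[f"ph_{label}_cn.tsv"] = table_to_tsv(cndist, "coordination_number")
    if config.do_quartets:
        quartets = extract_quartets(sites)
        tables["quartets"] = quartets
        outputs["quartets.tsv"] = table_to_tsv(quartets, "quartet")
    outputs["sites.tsv"] = sites_to_tsv(sites)
    outputs["filter_report.json"] = result.report.to_json()
    per_metal = {}
    for s in sites:
        per_metal[s.species.label] = per_metal.get(s.species.label, 0) + 1
    outputs["summary.json"] = json.dumps(
        {
            "n_input_files": len(result.models),
            "n_representative_files": len(result.representatives),
            "n_sites_considered": len(result.sites_before_filters),
            "n_sites_used": len(sites),
            "used_metals_per_species": dict(sorted(per_metal.items())),
            "ph_bins": "acidic: pH<=6; mild_acidic: 6<pH<7; neutral: 7<=pH<8; basic: pH>=8",
        },
        indent=1,
    )


def run_scan(config: RunConfig) -> ScanResult:
    """Parse inputs, run the full scan and write all outputs to ``output_dir``."""
    paths = _collect_inputs(config.inputs)
    if not paths:
        raise FileNotFoundError(f"no input files matched {config.inputs}")
    models: dict[str, StructureModel] = {}
    for path in paths:
        try:
            model = parse_structure(path.read_text(), pdb_id=None)
        except StructureParseError as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        if model.pdb_id == "XXXX":
            model.pdb_id = path.stem[:4].upper()
        models[model.pdb_id] = model
    if not models:
        raise FileNotFoundError("no parseable structures among the inputs")
    result = scan_corpus(models, config)
    compute_tables(result, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, text in sorted(result.outputs.items()):
        (outdir / name).write_text(text)
    return result


def run_asite(
    msa_path: str | Path,
    anchors: asite_mod.AnchorSpec = asite_mod.YIIP_ANCHORS,
    output_dir: str | Path = "metalsites_out",
    exclude_reference: bool = True,
    fmt: str | None = None,
) -> tuple[asite_mod.SignatureMatrix, asite_mod.ConsensusQuartet]:
    """A-site signature analysis of one clade MSA; writes TSV + JSON outputs."""
    msa = asite_mod.read_msa(msa_path, fmt)
    columns = asite_mod.map_anchor_columns(msa, anchors)
    blocks = asite_mod.extract_blocks(msa, columns, reference_id=anchors.reference_id)
    matrix = asite_mod.signature(
        blocks, exclude_reference=exclude_reference,
        quartet_positions=anchors.quartet_positions(),
    )
    consensus = asite_mod.consensus_quartet(matrix)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "asite_signature.tsv").write_text(matrix.to_tsv())
    (outdir / "asite_consensus.json").write_text(
        json.dumps(
            {
                "consensus_quartet": consensus.quartet,
                "tie_positions": list(consensus.tie_positions),
                "n_sequences_profiled": int(matrix.n_effective.max()) if matrix.n_positions else 0,
                "reference_excluded": exclude_reference,
            },
            indent=1,
        )
    )
    return matrix, consensus
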