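"""Coordination-geometry classification by least-RMSD template superposition.

Each metal site (the metal plus its CN ligating atoms, waters included) is
compared against every ideal geometry of the same coordination number from a
library of 36 templates spanning CN 2-9, compiled after the geometry set used
by the FindGeo tool (Andreini et al., J Biol Inorg Chem 2012).  The template
is translated so the metal sits at the origin, scaled to the observed mean
metal-ligand distance, and superposed by an optimal proper rotation (Kabsch)
minimised over the vertex-to-ligand assignment.  The lowest-RMSD template of
matching CN wins; sites whose best normalized RMSD exceeds the distortion
threshold are "irregular" and drop out of geometry statistics (they stay in
coordination-number statistics).

The assignment search seeds an iterative closest-point loop from rotations
that align pairs of template vertices onto pairs of observed ligands, uses
Hungarian assignment within each iteration and finishes with local 2-swap
refinement; it reproduces the exhaustive CN! search at low CN.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from math import cos, pi, radians, sin, sqrt

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "GeometryTemplate",
    "GeometryAssignment",
    "load_template_library",
    "superpose_rmsd",
    "assign_geometry",
    "REGULAR_MAX_RMSD",
    "DISTORTED_MAX_RMSD",
]

# Normalized-RMSD thresholds (coordinates scaled to mean bond length 1).
REGULAR_MAX_RMSD = 0.4
DISTORTED_MAX_RMSD = 0.7


@dataclass(frozen=True)
class GeometryTemplate:
    code: str
    description: str
    coordination_number: int
    ideal_coordinates: np.ndarray  # (CN+1, 3); row 0 = metal at origin

    @property
    def vertices(self) -> np.ndarray:
        return self.ideal_coordinates[1:]


@dataclass(frozen=True)
class GeometryAssignment:
    site_id: str
    coordination_number: int
    best_code: str | None
    rmsd: float  # Angstrom, at the observed scale
    rmsd_normalized: float
    regularity: str  # "regular" | "distorted" | "irregular"


# --- ideal geometry definitions ----------------------------------------------


def _sph(theta_deg: float, phi_deg: float) -> list[float]:
    t, p = radians(theta_deg), radians(phi_deg)
    return [sin(t) * cos(p), sin(t) * sin(p), cos(t)]


def _ring(n: int, theta_deg: float, phi0_deg: float = 0.0) -> list[list[float]]:
    return [_sph(theta_deg, phi0_deg + 360.0 * k / n) for k in range(n)]


# Trigonal prism with square side faces: polar angle of the two triangle rings.
_PRISM_THETA = 49.107  # degrees; cos(theta) = 1/2 / sqrt(7/12)
# Ideal square antiprism (all edges equal): polar angle of the two square rings.
_SQA_THETA = 59.26

_TETRA = [
    [1, 1, 1],
    [1, -1, -1],
    [-1, 1, -1],
    [-1, -1, 1],
]
_TETRA = (np.array(_TETRA) / sqrt(3.0)).tolist()


def _prism() -> list[list[float]]:
    return _ring(3, _PRISM_THETA) + _ring(3, 180 - _PRISM_THETA)


def _prism_cap(phi_deg: float) -> list[float]:
    return _sph(90.0, phi_deg)


def _dodecahedron() -> list[list[float]]:
    # Triangular (D2d) dodecahedron, hard-sphere ideal angles.
    ta, tb = 36.85, 69.46
    return [
        _sph(ta, 0), _sph(ta, 180), _sph(180 - ta, 90), _sph(180 - ta, 270),
        _sph(tb, 90), _sph(tb, 270), _sph(180 - tb, 0), _sph(180 - tb, 180),
    ]


def _octahedron() -> list[list[float]]:
    return [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]


def _oct_cap(sign: int = 1) -> list[float]:
    v = sign / sqrt(3.0)
    return [v, v, v]


def _antiprism() -> list[list[float]]:
    return _ring(4, _SQA_THETA) + _ring(4, 180 - _SQA_THETA, 45.0)


def _ideal_geometries() -> list[tuple[str, str, list[list[float]]]]:
    """(code, description, unit vertex list) for the 36-template library."""
    geoms: list[tuple[str, str, list[list[float]]]] = [
        # CN 2
        ("lin", "linear", [_sph(0, 0), _sph(180, 0)]),
        ("ben", "bent (tetrahedral angle)", [_sph(0, 0), _sph(109.471, 0)]),
        # CN 3
        ("tri", "trigonal plane", _ring(3, 90)),
        ("trp", "trigonal pyramid (vacant tetrahedron)", _ring(3, 109.471)),
        ("tsh", "T-shape (vacant square plane)", [_sph(90, 0), _sph(90, 180), _sph(90, 90)]),
        ("fac", "fac-trivacant octahedron", [[1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        # CN 4
        ("tet", "tetrahedron", _TETRA),
        ("spl", "square plane", _ring(4, 90)),
        ("see", "seesaw (equatorially vacant trigonal bipyramid)",
         [_sph(0, 0), _sph(180, 0), _sph(90, 0), _sph(90, 120)]),
        ("vtb", "axially vacant trigonal bipyramid", [_sph(0, 0)] + _ring(3, 90)),
        # CN 5
        ("tbp", "trigonal bipyramid", [_sph(0, 0), _sph(180, 0)] + _ring(3, 90)),
        ("spy", "square pyramid (vacant octahedron)", [_sph(0, 0)] + _ring(4, 90)),
        ("vtp", "vacant trigonal prism", _prism()[:5]),
        ("dpb", "divacant pentagonal bipyramid", [_sph(0, 0)] + _ring(5, 90)[:4]),
        ("ppl", "pentagonal plane", _ring(5, 90)),
        # CN 6
        ("oct", "octahedron", _octahedron()),
        ("tpr", "trigonal prism", _prism()),
        ("ppy", "pentagonal pyramid (axially vacant pentagonal bipyramid)",
         [_sph(0, 0)] + _ring(5, 90)),
        ("pvp", "equatorially vacant pentagonal bipyramid",
         [_sph(0, 0), _sph(180, 0)] + _ring(5, 90)[:4]),
        ("vct", "vacant capped trigonal prism", (_prism() + [_prism_cap(60)])[1:]),
        # CN 7
        ("pbp", "pentagonal bipyramid", [_sph(0, 0), _sph(180, 0)] + _ring(5, 90)),
        ("coc", "face-monocapped octahedron", _octahedron() + [_oct_cap()]),
        ("ctp", "square-face monocapped trigonal prism", _prism() + [_prism_cap(60)]),
        ("hpy", "hexagonal pyramid (axially vacant hexagonal bipyramid)",
         [_sph(0, 0)] + _ring(6, 90)),
        ("sav", "vacant square antiprism", _antiprism()[:7]),
        # CN 8
        ("cub", "cube", _cube()),
        ("sqa", "square antiprism", _antiprism()),
        ("hbp", "hexagonal bipyramid", [_sph(0, 0), _sph(180, 0)] + _ring(6, 90)),
        ("dod", "triangular dodecahedron", _dodecahedron()),
        ("boc", "trans-bicapped octahedron", _octahedron() + [_oct_cap(1), _oct_cap(-1)]),
        ("btp", "square-face bicapped trigonal prism",
         _prism() + [_prism_cap(60), _prism_cap(180)]),
        ("hps", "heptagonal pyramid", [_sph(0, 0)] + _ring(7, 90)),
        # CN 9
        ("ttp", "square-face tricapped trigonal prism",
         _prism() + [_prism_cap(60), _prism_cap(180), _prism_cap(300)]),
        ("csa", "capped square antiprism", _antiprism() + [_sph(0, 0)]),
        ("hbn", "heptagonal bipyramid", [_sph(0, 0), _sph(180, 0)] + _ring(7, 90)),
        ("ccu", "face-monocapped cube", _cube() + [_sph(0, 0)]),
    ]
    return geoms


def _cube() -> list[list[float]]:
    s = 1.0 / sqrt(3.0)
    return [[sx * s, sy * s, sz * s] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]


def build_template_library() -> list[GeometryTemplate]:
    """Construct the 36-template library from its analytic definitions."""
    out = []
    for code, desc, verts in _ideal_geometries():
        v = np.asarray(verts, dtype=float)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), v])
        out.append(GeometryTemplate(code, desc, len(v), coords))
    return out


def load_template_library() -> list[GeometryTemplate]:
    """Load the packaged template library (data/geometry_templates.json)."""
    text = resources.files("metalsites").joinpath("data/geometry_templates.json").read_text()
    raw = json.loads(text)
    out = []
    for entry in raw["templates"]:
        coords = np.asarray(entry["coordinates"], dtype=float)
        out.append(
            GeometryTemplate(entry["code"], entry["description"], entry["coordination_number"], coords)
        )
    return out


def export_library_json() -> str:
    """Serialise the analytic library to the packaged-JSON form."""
    lib = build_template_library()
    payload = {
        "provenance": (
            "Ideal coordination geometries (36 templates, CN 2-9) compiled from "
            "standard polyhedra and their vacancy derivatives, after the geometry "
            "set of the FindGeo tool (Andreini, Cavallaro & Lorenzini, "
            "J Biol Inorg Chem 17:539, 2012). Coordinates: metal at origin, "
            "unit-length vertices."
        ),
        "templates": [
            {
                "code": t.code,
                "description": t.description,
                "coordination_number": t.coordination_number,
                "coordinates": np.round(t.ideal_coordinates, 12).tolist(),
            }
            for t in lib
        ],
    }
    return json.dumps(payload, indent=1)


# --- superposition -----------------------------------------------------------


def _kabsch_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||a @ R.T - b||_F (rows are points)."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def _rmsd_for_assignment(tmpl: np.ndarray, obs: np.ndarray, perm: np.ndarray) -> float:
    """RMSD over CN+1 points (metal at origin included) for a fixed assignment."""
    matched = tmpl[perm]
    rot = _kabsch_rotation(matched, obs)
    diff = matched @ rot.T - obs
    n_pts = len(obs) + 1  # + metal, which contributes zero to the sum
    return float(np.sqrt((diff * diff).sum() / n_pts))


def _anchor_pair(tmpl: np.ndarray) -> tuple[int, int]:
    """Template vertex pair closest to perpendicular (non-degenerate Kabsch)."""
    n = len(tmpl)
    best, best_score = (0, 1), np.inf
    for i in range(n):
        for j in range(i + 1, n):
            cosang = abs(float(tmpl[i] @ tmpl[j]))
            if cosang < best_score:
                best_score, best = cosang, (i, j)
    return best


def _pair_seed_rotations(tmpl: np.ndarray, obs: np.ndarray) -> list[np.ndarray]:
    """Rotations aligning a non-collinear template vertex pair onto observed pairs."""
    seeds = [np.eye(3)]
    n = len(obs)
    obs_unit = obs / np.linalg.norm(obs, axis=1, keepdims=True)
    i0, i1 = _anchor_pair(tmpl)
    base = tmpl[[i0, i1]]
    for j in range(n):
        for l in range(n):
            if l == j:
                continue
            rot = _kabsch_rotation(base, obs_unit[[j, l]])
            seeds.append(rot)
    return seeds


def _icp_best_assignment(tmpl: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, float]:
    """Best vertex-to-ligand assignment via seeded ICP + 2-swap refinement."""
    n = len(obs)
    best_perm: np.ndarray | None = None
    best_rmsd = np.inf
    for rot0 in _pair_seed_rotations(tmpl, obs):
        rotated = tmpl @ rot0.T
        prev_perm = None
        for _ in range(12):
            cost = ((rotated[:, None, :] - obs[None, :, :]) ** 2).sum(axis=2)
            rows, cols = linear_sum_assignment(cost)
            perm = np.empty(n, dtype=int)
            perm[cols] = rows  # perm[k] = template vertex matched to obs k
            if prev_perm is not None and np.array_equal(perm, prev_perm):
                break
            prev_perm = perm
            rot = _kabsch_rotation(tmpl[perm], obs)
            rotated = tmpl @ rot.T
        rmsd = _rmsd_for_assignment(tmpl, obs, prev_perm)
        if rmsd < best_rmsd - 1e-15:
            best_rmsd = rmsd
            best_perm = prev_perm
    # local 2-swap refinement
    improved = True
    while improved:
        improved = False
        for i, j in itertools.combinations(range(n), 2):
            perm = best_perm.copy()
            perm[i], perm[j] = perm[j], perm[i]
            rmsd = _rmsd_for_assignment(tmpl, obs, perm)
            if rmsd < best_rmsd - 1e-12:
                best_rmsd, best_perm = rmsd, perm
                improved = True
    return best_perm, best_rmsd


def superpose_rmsd(observed: np.ndarray, template: GeometryTemplate) -> float:
    """Least RMSD (Angstrom) of *observed* against *template*.

    *observed* is a (CN+1, 3) array with the metal in row 0.  The metal is
    translated to the origin, the template is scaled to the observed mean
    metal-ligand distance, and the RMSD is minimised over proper rotations
    and vertex-to-ligand assignments.  The metal counts as one of the CN+1
    points of the RMSD.
    """
    observed = np.asarray(observed, dtype=float)
    cn = len(observed) - 1
    if cn != template.coordination_number:
        raise ValueError(
            f"coordination number mismatch: observed {cn}, "
            f"template {template.code} is CN {template.coordination_number}"
        )
    ligands = observed[1:] - observed[0]
    dists = np.linalg.norm(ligands, axis=1)
    if np.any(dists == 0.0):
        raise ValueError("ligand coincides with the metal")
    scale = float(dists.mean())
    norm_obs = ligands / scale
    _, rmsd_norm = _icp_best_assignment(template.vertices, norm_obs)
    return rmsd_norm * scale


def normalized_superpose_rmsd(observed: np.ndarray, template: GeometryTemplate) -> float:
    """As :func:`superpose_rmsd` but on coordinates scaled to mean bond 1."""
    observed = np.asarray(observed, dtype=float)
    ligands = observed[1:] - observed[0]
    scale = float(np.linalg.norm(ligands, axis=1).mean())
    return superpose_rmsd(observed, template) / scale


def assign_geometry(
    site,
    library: list[GeometryTemplate] | None = None,
    thresholds: tuple[float, float] = (REGULAR_MAX_RMSD, DISTORTED_MAX_RMSD),
) -> GeometryAssignment:
    """Assign the best-matching ideal geometry (or "irregular") to a site.

    *site* may be a :class:`~metalsites.site_extraction.MetalSite` or a bare
    (CN+1, 3) coordinate array with the metal in row 0.  All templates of the
    site's CN are evaluated; regularity follows the normalized-RMSD
    thresholds ``(regular_max, distorted_max)``.  Sites with CN outside the
    library range [2, 9] come back irregular with no code.
    """
    if library is None:
        library = load_template_library()
    if hasattr(site, "site_coordinates"):
        observed = site.site_coordinates()
        site_id = site.site_id
    else:
        observed = np.asarray(site, dtype=float)
        site_id = "site"
    cn = len(observed) - 1
    candidates = [t for t in library if t.coordination_number == cn]
    if not candidates:
        return GeometryAssignment(site_id, cn, None, float("nan"), float("nan"), "irregular")
    ligands = observed[1:] - observed[0]
    scale = float(np.linalg.norm(ligands, axis=1).mean())
    best_code, best_norm = None, np.inf
    for tmpl in candidates:
        r = superpose_rmsd(observed, tmpl) / scale
        if r < best_norm:
            best_norm, best_code = r, tmpl.code
    regular_max, distorted_max = thresholds
    if best_norm <= regular_max:
        regularity = "regular"
    elif best_norm <= distorted_max:
        regularity = "distorted"
    else:
        regularity = "irregular"
    code = best_code if regularity != "irregular" else None
    return GeometryAssignment(site_id, cn, code, best_norm * scale, best_norm, regularity)
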