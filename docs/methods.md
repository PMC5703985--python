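# Methods

## Scope and data model

`metalsites` computes descriptive binding statistics for metal ions in
protein crystal structures. The unit of analysis is the **metal site**: one
metal ion plus the set of atoms bonded to it according to the structure's
LINK records. Coordination is taken from LINK records *only*; no
distance-based bond inference is performed, so a metal without usable LINKs
contributes nothing. This is a deliberate methodological stance — LINK
records encode the depositor's own assignment of coordination — and it is
the main axis along which surveys of this kind differ from distance-cutoff
surveys.

Metal species are identified by atom label within a free-ion residue (MN,
ZN, NI, CO, CU, CD; FE is read as ferric) or by residue component (FE2 for
ferrous iron), so the two iron oxidation states are tracked as distinct
species. The DDDD-variant configuration adds CA and MG.

## Filtration cascade

Sites pass through ordered stages; each stage logs input, survivors and the
dropped site ids:

1. **Redundancy** (structure level). Entries sharing > 90% sequence identity
   are collapsed to one representative *before* site extraction. Identity is
   computed on the longest polymer chain by an end-gap-free global alignment
   (match = 1, mismatch = 0, gap = −1) as identical positions / alignment
   length. Because several alignments can attain the optimal score, the
   implementation optimises the lexicographic objective (score, matches,
   −length); all three terms are additive per alignment column, so the
   dynamic program remains exact, and the identity value is well defined and
   symmetric. Clustering is greedy in the CD-HIT style: entries sorted by
   (length descending, id ascending) join the first founder they match above
   the threshold, else found a new cluster. Applying redundancy globally
   (rather than per metal) is a design choice recorded in the run report.
2. **Symmetry-equivalent sites** (per structure). Sites are equivalent when
   they share the metal species and a residue-offset fingerprint: the sorted
   multiset of (residue name, ligating atom name, residue-number offset from
   the site's first ligating residue in that chain), plus water/other
   counts. This catches NCS copies in homo-oligomers and LINK-duplicated
   sites without crystallographic symmetry math. The representative is the
   lexicographically first (chain, residue number) metal.
3. **Resolution** — keep sites from X-ray structures with REMARK 2
   resolution ≤ `max_resolution` (default 2.0 Å; disabled in the DDDD
   variant).
4. **Co-ligands** — drop any site with a ligand that is neither a standard
   amino acid (modified residues map to their parents, e.g. MSE → Met) nor
   water ({HOH, WAT, DOD}). Metal–metal bridges therefore drop both sites.
5. **Protein ligation** — keep sites with ≥ 2 protein-ligating atoms
   (main-chain O/N count as protein atoms; the analysis does not separate
   backbone from side-chain ligation).
6. **Required component** (DDDD variant only) — keep sites with at least one
   ligating Asp.

## Statistics

All tables are per metal species and purely descriptive (no hypothesis
tests). Fractions are count / per-metal denominator and sum to 1 within
1e-9 by construction.

* **By-atom propensity**: every metal–(protein atom) bond counts once, so a
  bidentate Asp counts twice. **By-residue** counts each distinct ligating
  residue once; the two modes coincide exactly on chelation-free data.
* **CN distribution**: CN = all ligating atoms including waters; every
  surviving site contributes once.
* **Geometry distribution**: denominator is the pool of sites with a
  *defined* geometry (regular or distorted), so per metal the CN pool is
  always ≥ the geometry pool.
* **pH stratification**: crystallisation pH from REMARK 200, bins
  pH ≤ 6 (acidic), 6 < pH < 7 (mild acidic), 7 ≤ pH < 8 (neutral),
  pH ≥ 8 (basic). The source phrasing is ambiguous at the endpoints of 7
  and 8; this package fixes the half-open convention above and asserts the
  partition property in tests. Sites without a recorded pH are excluded
  from the pH analysis only. REMARK 200 pH values like "7.0-8.0" are read
  as the midpoint; "NULL" as absent.
* **Quartets**: sites whose distinct ligating protein residues number
  exactly four (any atom count ≥ 4, waters permitted, no CN cap), keyed by
  the alphabetically sorted one-letter composition (e.g. DDHH).
  Cysteine-containing keys are flagged separately because such sites are
  predominantly structural rather than catalytic.

## Coordination geometry

Geometry is assigned by least-RMSD superposition against a library of 36
ideal templates spanning CN 2–9, compiled after the geometry set of the
FindGeo tool (Andreini, Cavallaro & Lorenzini, J Biol Inorg Chem 17:539,
2012) from standard polyhedra and their vacancy derivatives. The library
ships as packaged JSON (`data/geometry_templates.json`, metal at origin,
unit vertices) and is regenerated analytically; a test pins the two
representations together. Shapes were chosen so that templates of equal CN
stay mutually separated (pairwise ideal-shape RMSD ≳ 0.16–0.6 on unit
coordinates), which the noise-recovery test quantifies.

For a site with CN ligands the observed coordinates are translated so the
metal sits at the origin and scaled so the mean metal–ligand distance is 1;
template vertices are unit length. The reported RMSD is over CN + 1 points
— the metal is included and contributes zero to the numerator but one to the
denominator — minimised over proper rotations (Kabsch, SVD with determinant
correction) and over vertex-to-ligand assignments. The assignment search
seeds an iterative-closest-point loop from rotations aligning a
near-perpendicular template vertex pair onto every ordered observed pair
(degenerate, antipodal anchor pairs are avoided — with them the two-point
Kabsch under-determines the rotation and the search can stall in local
minima), uses Hungarian assignment per iteration, and finishes with local
2-swap refinement. On CN ≤ 6 the search reproduces the exhaustive CN!
enumeration to < 1e-9 (tested on random noisy sites).

Regularity thresholds apply to the normalized RMSD: **regular** ≤ 0.4,
**distorted** ≤ 0.7, else **irregular** (no geometry code; excluded from
geometry statistics, retained for CN statistics). The values mirror the
spirit of FindGeo's defaults and are configurable. Sites with CN outside
2–9 are irregular by definition. Sub-template matching (vacant coordination
positions, partial occupancy) is not attempted: a site competes only against
templates of its own CN.

## A-site profiling

Input is a clade MSA (aligned FASTA or Clustal) containing a reference
sequence with known quartet residue numbers; the default anchor set is YiiP
D45, D49 (TM2 duet), H153, D157 (TM5 duet) with a 5-residue flank. Anchor
residues are verified against the reference before any extraction — a
mismatch aborts with the position and the residue found, guarding against
numbering drift. Each duet yields a 15-column block in the reference frame
(columns of reference residues a₁−5 … a₂+5), so insertions relative to the
reference make blocks non-consecutive in alignment coordinates but never
change what the reference itself reads. Re-anchoring through a combined
all-clade MSA (for clades whose own MSA fails to place the second duet) is
supported by running a second pass with another `AnchorSpec`, not by
automated tree logic.

Per column, frequencies are computed over non-gap residues (`n_effective`
reported) and information content is `log₂20 − H` bits with no small-sample
correction by default — clade sizes vary widely and the profile is used
qualitatively; the WebLogo-style `(s−1)/(2 ln2 · n)` correction is available
as an option. The reference row is excluded from frequencies by default
(flag available). The consensus quartet takes the majority residue at block
positions 6, 10, 21, 25; ties break alphabetically and are flagged.

## Synthetic data: what it emulates and what it does not

The generator exists so that every stage has an enumerable ground truth.

A generated structure contains: a scaffold chain of Cα atoms with SEQRES, a
metal HETATM, ligating atoms placed on the chosen template's vertices scaled
to a 2.1 Å mean bond length (typical DDMC–O/N bond; configurable) plus
optional Gaussian coordinate noise, one LINK per bond, optional waters and a
non-water decoy ligand, REMARK 2 resolution and REMARK 200 pH. Scaffold
sequences are random per structure — a constant scaffold would collapse the
whole corpus into one redundancy cluster — and planted redundancy families
reuse one sequence with < 10% point mutations outside ligand positions.
Emission goes through the package's own PDB writer; an independent reader
(gemmi) cross-checks the column layout in the tests.

The corpus manifest computes expected stage counts, the surviving site set
and all expected tables by direct integer arithmetic over the planted site
specifications; a test verifies by AST inspection that this enumeration
calls no pipeline code.

Deliberately **not** emulated: realistic side-chain rotamers and packing
(only ligating-atom positions matter to any implemented statistic),
crystallographic symmetry records (equivalence detection is
fingerprint-based), altloc disorder in generated files, mmCIF, and any
correlation structure between pH, resolution and site composition. Passing
tests therefore demonstrate correctness of counting, filtering, clustering,
superposition and profiling logic — not robustness to every pathology of
real depositions (those are covered only to the extent of the parser's
tolerance tests: pH ranges, NULL fields, missing element columns, malformed
lines, dangling and symmetry-operator LINKs).

## Numerical and design choices

* Altlocs: only blank or 'A' conformers are kept; a LINK naming a discarded
  altloc stays unresolved. LINK endpoints under a non-identity symmetry
  operator are dropped (logged): symmetry mates are never constructed.
* Element inference when columns 77–78 are blank: two-letter symbols are
  trusted only outside standard residues ("CD" in residue CD is cadmium;
  "CD1" in LEU is carbon; "SE" in MSE is selenium).
* Coordinates are fixed-point with three decimals in PDB text; round-trip
  identity holds for models at that precision, and σ = 0 generated sites
  carry only rounding error (RMSD ≲ 1e-3 Å).
* The quartet rule imposes no CN cap: a 4-residue site with many waters
  still contributes.
* Protein–protein interface sites (ligands from several chains) count once
  after symmetry dedup.
* Structures lacking any parseable ATOM/HETATM record are skipped with a
  log message; a scan only fails when no input parses at all.
* Determinism: all randomness flows through seeded `numpy` generators;
  identical (inputs, config, seed) give byte-identical outputs, and output
  files are written in sorted order.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use a 200-structure corpus
(60 clean survivors, 40 resolution failures, 40 co-ligand failures, 20
under-ligated sites, 8 redundancy families × 3 copies, 16 symmetric-duplicate
structures), 100 noise trials per geometry template at σ = 0.1, 50
random sites for the exhaustive-search comparison, 6 × 4 redundancy
families, and clade MSAs of 50–500 sequences. These sizes exercise every
code path and keep the full verification run in the low minutes on one core.

## Known limitations

* mmCIF is not read; the pipeline is defined on the legacy PDB dialect and
  its LINK records.
* Identity clustering is quadratic in corpus size (with a cheap
  composition-based rejection bound); it is meant for desk-scale corpora,
  not the full PDB.
* Geometry assignment treats all ligating atoms identically (no element- or
  charge-weighted superposition) and does not attempt vacancy/sub-template
  matching.
* The pH analysis inherits the well-known caveat that REMARK 200 reports
  crystallisation-solution pH, not the pH at the binding event.
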