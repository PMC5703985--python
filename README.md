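# metalsites

Statistics of divalent d-block metal cation (DDMC) binding sites in protein
crystal structures, computed from legacy-PDB coordinate files, plus signature
profiling of the A-site of cation diffusion facilitator (CDF) transporters.

## The problem

Zn²⁺, Mn²⁺, Fe²⁺, Co²⁺, Ni²⁺, Cu²⁺ and Cd²⁺ drive catalysis, structure and
transport, and each metal prefers particular ligating residues and
coordination polyhedra. Database-wide surveys of metalloprotein structures
quantify those preferences: which amino acids ligate each metal (and how
often), at what coordination number (CN), in which ideal geometry, and — for
transporter work — which four-residue "quartets" form tight binding sites
like the CDF A-site (two residues on TM helix 2, two on TM helix 5; the
XX-XX motif, DD-HD in *E. coli* YiiP at D45/D49/H153/D157).

`metalsites` is a tested, reusable implementation of such a survey for
structural bioinformaticians: it takes a local directory of PDB files and a
choice of metal species, applies a defined filtration cascade, and emits
every table the analysis needs. A synthetic-corpus generator with fully
enumerable ground truth makes every stage verifiable without downloading a
single structure.

## What it computes

Given structures with metal ions and LINK records, the pipeline:

1. **Redundancy reduction** — one representative per cluster of entries with
   pairwise sequence identity > 90% (end-gap-free global alignment on the
   longest chain; greedy CD-HIT-style clustering).
2. **Site extraction** — one site per metal ion, ligating atoms taken from
   LINK records only (never by distance); partners classed protein / water /
   other; one representative per group of symmetry-equivalent sites.
3. **Filtration** — X-ray resolution ≤ 2.0 Å, no co-ligands other than
   water, ≥ 2 protein-ligating atoms (the `standard-2016` preset); or no
   resolution limit with a required Asp component and Ca²⁺/Mg²⁺ added (the
   `dddd-variant` preset). Per-stage counts are reported.
4. **Statistics** — per metal *M* and residue *r*, the by-atom propensity

   `P_M(r) = (metal–atom bonds to residues of type r) / (all metal–protein-atom bonds of M)`

   (a residue chelating through two atoms counts twice), plus a by-residue
   variant; CN distributions (waters count as ligands); coordination-geometry
   distributions from least-RMSD superposition against 36 ideal templates
   (CN 2–9, Kabsch rotation minimised over vertex assignments; sites beyond
   the distortion threshold are "irregular" and excluded from geometry — but
   not CN — statistics); crystallisation-pH-stratified tables over the bins
   pH ≤ 6, (6,7), [7,8), ≥ 8; and quartet profiles over sites ligated by
   exactly four distinct residues, cysteine-containing quartets flagged.
5. **A-site profiling** — from a clade MSA containing the YiiP reference,
   extract two 15-residue blocks (each duet ± 5 flanking residues; quartet at
   block positions 6, 10, 21, 25), compute per-column residue frequencies and
   information content `IC = log₂20 − H` in bits (the LOGO stack height), and
   call the consensus quartet.

## Worked example

Generate a synthetic corpus with known ground truth, then scan it:

```sh
$ metalsites simulate --out corpus --seed 7 --survivors 12 --resolution-fails 4 \
      --coligand-fails 4 --protein-min-fails 2 --families 2 --copies-per-family 3 \
      --symmetric-dups 2
30 structures written to corpus/

$ metalsites scan corpus --out out
redundancy: 30 -> 26
resolution: 26 -> 22
coligand: 22 -> 18
protein_atoms: 18 -> 16
surviving sites: 16
outputs in out/
```

The cascade dropped 4 redundant family copies, 4 low-resolution structures,
4 sites with a non-water co-ligand and 2 sites with fewer than two
protein-ligating atoms; the 2 symmetric duplicates were merged before
filtering. `out/quartets.tsv` then holds the quartet profile of the 16
surviving sites:

```
metal	quartet	count	fraction
CO	DEEH	1	1
FE2	EEEH	2	1
NI	DHHH	1	1
ZN	CCHH	4	1
```

i.e. every surviving Zn quartet site in this corpus is the planted
Cys₂His₂ composition. A-site profiling of a synthetic clade alignment
recovers its planted consensus:

```sh
$ metalsites asite clade.fasta --out asite_out
consensus quartet: HD-HD
```

with the full 30-position frequency/bits matrix in
`asite_out/asite_signature.tsv`. Profiling the YiiP reference row alone
yields `DD-HD`, its documented A-site motif.

## Layout

| module | role |
| --- | --- |
| `metalsites.pdb_io` | legacy-PDB parsing/writing (ATOM/HETATM, LINK, REMARK 2, REMARK 200 pH, SEQRES) |
| `metalsites.redundancy` | pairwise identity + greedy >90% clustering |
| `metalsites.site_extraction` | LINK-record site building, filtration cascade, symmetry dedup |
| `metalsites.geometry` | 36-template library, Kabsch/assignment superposition, regularity calls |
| `metalsites.propensity` | propensity, CN, geometry, pH-bin and quartet tables |
| `metalsites.asite` | A-site block extraction, LOGO matrix, consensus quartet |
| `metalsites.synthetic` | ground-truth PDB corpus and MSA generators |
| `metalsites.pipeline` / `metalsites.cli` | orchestration and the `metalsites` command |

See `docs/methods.md` for the full methods description and design choices.
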