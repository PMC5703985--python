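"""CDF A-site signature profiling from a clade multiple sequence alignment.

The A-site of cation diffusion facilitator (CDF) transporters is a quartet of
metal-ligating residues, two on TM helix 2 and two on TM helix 5 (the XX-XX
motif; DD-HD in E. coli YiiP: D45, D49, H153, D157).  Given a clade MSA that
includes a reference sequence with known quartet residue numbers, this module
extracts two 15-residue blocks per sequence (each duet plus five residues of
flank on either side, 30 positions total, quartet at positions 6, 10, 21 and
25), computes per-position residue frequencies and information content in
bits (the LOGO letter-stack height), and calls the consensus quartet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from ._residues import AA3_TO_1

__all__ = [
    "AnchorSpec",
    "YIIP_ANCHORS",
    "SiteBlock",
    "SignatureMatrix",
    "ConsensusQuartet",
    "AnchorMismatchError",
    "read_msa",
    "map_anchor_columns",
    "extract_blocks",
    "signature",
    "consensus_quartet",
]

GAP_CHARS = {"-", ".", "~"}
AA_CODES = sorted(AA3_TO_1.values())  # 20 one-letter codes
MAX_BITS = math.log2(20.0)


class AnchorMismatchError(ValueError):
    """The reference residue at an anchor position is not the expected one."""


@dataclass(frozen=True)
class AnchorSpec:
    """Reference-frame definition of the A-site quartet.

    ``anchors`` are four (reference residue number, expected one-letter code)
    pairs; the first two form the TM2 duet, the last two the TM5 duet.
    ``flank`` residues on both sides of each duet complete the blocks.
    """

    reference_id: str
    anchors: tuple[tuple[int, str], ...]
    flank: int = 5

    def __post_init__(self):
        if len(self.anchors) != 4:
            raise ValueError("an AnchorSpec needs exactly four anchors")
        nums = [a[0] for a in self.anchors]
        if nums != sorted(nums) or len(set(nums)) != 4:
            raise ValueError("anchor residue numbers must be strictly increasing")

    @property
    def duets(self) -> tuple[tuple, tuple]:
        return (self.anchors[0], self.anchors[1]), (self.anchors[2], self.anchors[3])

    def quartet_positions(self) -> tuple[int, int, int, int]:
        """1-based positions of the four anchors within the concatenated blocks."""
        (a1, a2), (b1, b2) = self.duets
        len_block1 = (a2[0] + self.flank) - (a1[0] - self.flank) + 1
        p1 = self.flank + 1
        p2 = self.flank + 1 + (a2[0] - a1[0])
        p3 = len_block1 + self.flank + 1
        p4 = len_block1 + self.flank + 1 + (b2[0] - b1[0])
        return (p1, p2, p3, p4)


# E. coli YiiP (PDB 3H90), the reference CDF with a structure of the occupied
# A-site: DD-HD quartet at D45, D49, H153, D157.
YIIP_ANCHORS = AnchorSpec(
    reference_id="YiiP",
    anchors=((45, "D"), (49, "D"), (153, "H"), (157, "D")),
    flank=5,
)


@dataclass(frozen=True)
class SiteBlock:
    sequence_id: str
    text: str  # 30 characters (two 15-position blocks), gaps preserved
    is_reference: bool = False


@dataclass
class SignatureMatrix:
    """Per-position residue frequencies and information content (bits)."""

    frequencies: np.ndarray  # (n_positions, 20), rows sum to 1 where n_effective > 0
    information: np.ndarray  # (n_positions,), in [0, log2(20)]
    n_effective: np.ndarray  # (n_positions,), ungapped sequence count
    quartet_positions: tuple[int, int, int, int] = (6, 10, 21, 25)
    codes: tuple[str, ...] = tuple(AA_CODES)

    @property
    def n_positions(self) -> int:
        return len(self.information)

    def to_tsv(self) -> str:
        header = "position\t" + "\t".join(self.codes) + "\tbits\tn_effective"
        lines = [header]
        for i in range(self.n_positions):
            freqs = "\t".join(f"{f:.6g}" for f in self.frequencies[i])
            lines.append(f"{i + 1}\t{freqs}\t{self.information[i]:.6g}\t{int(self.n_effective[i])}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConsensusQuartet:
    quartet: str  # "XX-XX" form
    tie_positions: tuple[int, ...] = ()

    def __str__(self) -> str:
        return self.quartet


def read_msa(path: str | Path, fmt: str | None = None):
    """Read an aligned FASTA or Clustal file into a Biopython alignment."""
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:7].upper()
        fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
    return AlignIO.read(str(path), fmt)


def _reference_row(msa, reference_id: str) -> str:
    for record in msa:
        if record.id == reference_id or record.id.split("|")[0] == reference_id:
            return str(record.seq)
    raise KeyError(f"reference sequence {reference_id!r} not found in the alignment")


def map_anchor_columns(msa, spec: AnchorSpec = YIIP_ANCHORS) -> list[int]:
    """Alignment columns (0-based) of the 30 block positions, reference frame.

    For each duet the block covers reference residues from ``flank`` before
    the first anchor to ``flank`` after the second; insertions relative to
    the reference make the returned columns non-consecutive.  The reference's
    residues at the anchor numbers must match the expected codes.
    """
    ref = _reference_row(msa, spec.reference_id)
    # residue number (1-based, ungapped) -> alignment column
    res2col: dict[int, int] = {}
    n = 0
    for col, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            n += 1
            res2col[n] = col
    for resnum, expected in spec.anchors:
        if resnum not in res2col:
            raise AnchorMismatchError(
                f"reference has only {n} residues; anchor {resnum} out of range"
            )
        found = ref[res2col[resnum]].upper()
        if found != expected.upper():
            raise AnchorMismatchError(
                f"anchor mismatch at reference residue {resnum}: expected "
                f"{expected}, found {found}"
            )
    columns: list[int] = []
    for duet in spec.duets:
        (first, _), (second, _) = duet
        for resnum in range(first - spec.flank, second + spec.flank + 1):
            if resnum not in res2col:
                raise AnchorMismatchError(
                    f"block residue {resnum} outside the reference sequence"
                )
            columns.append(res2col[resnum])
    return columns


def extract_blocks(msa, columns: list[int], reference_id: str | None = None) -> list[SiteBlock]:
    """One :class:`SiteBlock` per MSA sequence, gaps preserved."""
    blocks = []
    for record in msa:
        seq = str(record.seq)
        text = "".join(seq[c].upper() if seq[c] not in GAP_CHARS else "-" for c in columns)
        blocks.append(SiteBlock(record.id, text, is_reference=(record.id == reference_id)))
    return blocks


def signature(
    blocks: list[SiteBlock],
    exclude_reference: bool = True,
    quartet_positions: tuple[int, int, int, int] = (6, 10, 21, 25),
    small_sample_correction: bool = False,
) -> SignatureMatrix:
    """Per-position frequency vectors and information content in bits.

    Frequencies are over non-gap characters; information content is
    log2(20) minus the Shannon entropy of the column (0 for all-gap
    columns).  The optional small-sample correction subtracts the
    (s-1)/(2 ln2 n) bias term and floors at zero.
    """
    rows = [b for b in blocks if not (exclude_reference and b.is_reference)]
    if not rows:
        raise ValueError("no blocks to profile")
    length = len(rows[0].text)
    if any(len(b.text) != length for b in rows):
        raise ValueError("blocks have inconsistent lengths")
    idx = {c: i for i, c in enumerate(AA_CODES)}
    freqs = np.zeros((length, 20))
    n_eff = np.zeros(length)
    for block in rows:
        for pos, ch in enumerate(block.text):
            if ch in idx:
                freqs[pos, idx[ch]] += 1
                n_eff[pos] += 1
    info = np.zeros(length)
    for pos in range(length):
        if n_eff[pos] == 0:
            continue
        p = freqs[pos] / n_eff[pos]
        freqs[pos] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        bits = MAX_BITS - entropy
        if small_sample_correction:
            bits -= 19.0 / (2.0 * math.log(2.0) * n_eff[pos])
        info[pos] = max(bits, 0.0)
    return SignatureMatrix(freqs, info, n_eff, quartet_positions)


def consensus_quartet(matrix: SignatureMatrix) -> ConsensusQuartet:
    """Majority residue at the quartet positions, formatted as "XX-XX".

    Ties are broken alphabetically and reported in ``tie_positions``.
    """
    letters = []
    ties = []
    for pos in matrix.quartet_positions:
        p = matrix.frequencies[pos - 1]
        best = float(p.max())
        if best <= 0.0:
            letters.append("-")
            continue
        winners = [matrix.codes[i] for i in range(20) if p[i] == best]
        letters.append(winners[0])
        if len(winners) > 1:
            ties.append(pos)
    quartet = f"{letters[0]}{letters[1]}-{letters[2]}{letters[3]}"
    return ConsensusQuartet(quartet, tuple(ties))
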