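"""Sequence-redundancy reduction: one representative per >threshold-identity cluster.

Identity between two protein sequences is computed from an end-gap-free
global alignment (match=1, mismatch=0, gap=-1) as the number of identical
aligned positions divided by the alignment length.  Because several
alignments can attain the optimal score, the alignment is chosen by the
lexicographic objective (score, matches, -length), which makes the identity
value well-defined and symmetric.

Clustering is greedy in the CD-HIT style: entries sorted by (length
descending, id ascending) each join the first cluster whose founder they
match above the threshold, otherwise they found a new cluster.  Founders are
the representatives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = [
    "StructureSeq",
    "pairwise_identity",
    "cluster_representatives",
    "longest_chain_seq",
]


@dataclass(frozen=True)
class StructureSeq:
    pdb_id: str
    representative_sequence: str

    @property
    def length(self) -> int:
        return len(self.representative_sequence)


def longest_chain_seq(model) -> StructureSeq:
    """The longest polymer chain of a structure, the clustering proxy entity."""
    from .pdb_io import chain_sequence

    best = ""
    for chain in model.chains():
        try:
            seq = chain_sequence(model, chain)
        except KeyError:
            continue
        if len(seq) > len(best):
            best = seq
    return StructureSeq(model.pdb_id, best)


_NEG = float("-inf")


def _align(a: str, b: str) -> tuple[int, int, int]:
    """End-gap-free global alignment maximising (score, matches, -length).

    Returns (score, matches, alignment_length).  Score uses match=1,
    mismatch=0, internal/leading/trailing gap=-1 except that end gaps are
    free.  All three objectives are additive per alignment column, so the
    lexicographic optimum satisfies the DP optimality principle.
    """
    n, m = len(a), len(b)
    # cell value: (score, matches, -length); end-gap-free handled by free
    # first-row/column initialisation and a final max over the last row/column.
    prev = [(0, 0, -j) for j in range(m + 1)]  # free leading gaps in a
    best_last = None
    for i in range(1, n + 1):
        cur = [(0, 0, -i)]  # free leading gaps in b
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = ai == b[j - 1]
            ps, pm, pl = prev[j - 1]
            diag = (ps + (1 if match else 0), pm + (1 if match else 0), pl - 1)
            us, um, ul = prev[j]
            up = (us - 1, um, ul - 1)
            ls, lm, ll = cur[j - 1]
            left = (ls - 1, lm, ll - 1)
            cur.append(max(diag, up, left))
        prev = cur
        # free trailing gaps in b: candidate ending at (i, m)
        s, mt, nl = prev[m]
        cand = (s, mt, nl - (n - i))
        if best_last is None or cand > best_last:
            best_last = cand
    # free trailing gaps in a: candidates ending at (n, j)
    for j in range(m + 1):
        s, mt, nl = prev[j]
        cand = (s, mt, nl - (m - j))
        if best_last is None or cand > best_last:
            best_last = cand
    score, matches, neg_len = best_last
    return score, matches, -neg_len


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions over the alignment length, in [0, 1]."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    _, matches, length = _align(a, b)
    return matches / length


def cluster_representatives(entries: list[StructureSeq], threshold: float = 0.9) -> list[str]:
    """Greedy founder clustering; returns representative pdb_ids.

    An entry joins the first founder it matches with identity strictly above
    *threshold* (ties in the sort broken by pdb_id ascending).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(entries, key=lambda e: (-e.length, e.pdb_id))
    founders: list[StructureSeq] = []
    counters: list[Counter] = []
    for entry in order:
        if not entry.representative_sequence:
            founders.append(entry)  # sequence-free entries stand alone
            counters.append(Counter())
            continue
        ec = Counter(entry.representative_sequence)
        for founder, fc in zip(founders, counters):
            if not founder.representative_sequence:
                continue
            # cheap upper bound: matches <= shared letter counts and the
            # alignment is at least as long as the longer sequence
            shared = sum((ec & fc).values())
            if shared / max(entry.length, founder.length) <= threshold:
                continue
            if pairwise_identity(entry.representative_sequence, founder.representative_sequence) > threshold:
                break
        else:
            founders.append(entry)
            counters.append(ec)
    return [f.pdb_id for f in founders]
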