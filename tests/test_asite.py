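"""A-site block extraction, LOGO signature and consensus calling."""

import math

import numpy as np
import pytest
from Bio import AlignIO

from metalsites.asite import (
    AnchorMismatchError,
    AnchorSpec,
    SiteBlock,
    YIIP_ANCHORS,
    consensus_quartet,
    extract_blocks,
    map_anchor_columns,
    read_msa,
    signature,
)
from metalsites.synthetic import MsaProfileSpec, generate_msa, hdhd_clade_spec

LOG2_20 = math.log2(20)


@pytest.fixture(scope="module")
def hdhd_msa(tmp_path_factory):
    fasta, truth = generate_msa(hdhd_clade_spec(80), seed=21)
    path = tmp_path_factory.mktemp("msa") / "clade.fasta"
    path.write_text(fasta)
    return read_msa(path), truth


def test_gap_free_reference_gives_consecutive_columns(hdhd_msa):
    msa, truth = hdhd_msa
    cols = map_anchor_columns(msa, YIIP_ANCHORS)
    assert cols == truth["planted_columns"]
    assert cols[:15] == list(range(cols[0], cols[0] + 15))
    assert cols[15:] == list(range(cols[15], cols[15] + 15))


def test_insertions_shift_columns_but_not_reference_frame():
    spec = hdhd_clade_spec(40)
    with_ins = MsaProfileSpec(
        n_sequences=40,
        position_distributions=spec.position_distributions,
        insertion_columns=(46, 150),  # inside both blocks
    )
    fasta1, truth1 = generate_msa(spec, seed=4)
    fasta2, truth2 = generate_msa(with_ins, seed=4)
    import io

    msa1 = AlignIO.read(io.StringIO(fasta1), "fasta")
    msa2 = AlignIO.read(io.StringIO(fasta2), "fasta")
    cols1 = map_anchor_columns(msa1, YIIP_ANCHORS)
    cols2 = map_anchor_columns(msa2, YIIP_ANCHORS)
    assert cols2 == truth2["planted_columns"]
    assert cols2[5:15] != list(range(cols2[5], cols2[5] + 10))  # non-consecutive
    ref1 = next(b for b in extract_blocks(msa1, cols1, "YiiP") if b.is_reference)
    ref2 = next(b for b in extract_blocks(msa2, cols2, "YiiP") if b.is_reference)
    assert ref1.text == ref2.text  # the reference block reads its own sequence


def test_reference_absent_is_an_error(hdhd_msa):
    msa, _ = hdhd_msa
    with pytest.raises(KeyError, match="reference"):
        map_anchor_columns(msa, AnchorSpec("NOPE", ((45, "D"), (49, "D"), (153, "H"), (157, "D"))))


def test_anchor_mismatch_names_position_and_found_code(hdhd_msa):
    msa, _ = hdhd_msa
    bad = AnchorSpec("YiiP", ((45, "D"), (49, "D"), (153, "W"), (157, "D")))
    with pytest.raises(AnchorMismatchError, match=r"153.*expected W.*found H"):
        map_anchor_columns(msa, bad)


def test_blocks_have_30_columns_for_every_sequence(hdhd_msa):
    msa, _ = hdhd_msa
    cols = map_anchor_columns(msa, YIIP_ANCHORS)
    blocks = extract_blocks(msa, cols, reference_id="YiiP")
    assert len(blocks) == len(msa)
    assert all(len(b.text) == 30 for b in blocks)
    assert sum(b.is_reference for b in blocks) == 1


def _blocks(rows):
    return [SiteBlock(f"s{i}", text) for i, text in enumerate(rows)]


def test_conserved_column_hits_max_bits():
    mat = signature(_blocks(["H"] * 40), exclude_reference=False, quartet_positions=(1, 1, 1, 1))
    assert mat.information[0] == pytest.approx(LOG2_20, abs=1e-12)


def test_uniform_column_has_zero_bits():
    mat = signature(
        _blocks(list("ACDEFGHIKLMNPQRSTVWY")),
        exclude_reference=False,
        quartet_positions=(1, 1, 1, 1),
    )
    assert mat.information[0] == pytest.approx(0.0, abs=1e-12)


def test_half_split_column_loses_exactly_one_bit():
    mat = signature(
        _blocks(["H"] * 20 + ["D"] * 20),
        exclude_reference=False,
        quartet_positions=(1, 1, 1, 1),
    )
    assert mat.information[0] == pytest.approx(LOG2_20 - 1.0, abs=1e-12)


def test_all_gap_column_reports_zero_bits_and_zero_n():
    mat = signature(_blocks(["-"] * 10), exclude_reference=False, quartet_positions=(1, 1, 1, 1))
    assert mat.information[0] == 0.0
    assert mat.n_effective[0] == 0


def test_all_gap_rows_change_nothing(hdhd_msa):
    msa, _ = hdhd_msa
    cols = map_anchor_columns(msa, YIIP_ANCHORS)
    blocks = extract_blocks(msa, cols, reference_id="YiiP")
    padded = blocks + [SiteBlock(f"gap{i}", "-" * 30) for i in range(5)]
    a = signature(blocks)
    b = signature(padded)
    assert np.array_equal(a.frequencies, b.frequencies)
    assert np.array_equal(a.information, b.information)


def test_planted_hdhd_consensus(hdhd_msa):
    msa, _ = hdhd_msa
    cols = map_anchor_columns(msa, YIIP_ANCHORS)
    blocks = extract_blocks(msa, cols, reference_id="YiiP")
    consensus = consensus_quartet(signature(blocks))
    assert consensus.quartet == "HD-HD"
    assert consensus.tie_positions == ()


def test_yiip_alone_reads_ddhd(hdhd_msa):
    msa, _ = hdhd_msa
    cols = map_anchor_columns(msa, YIIP_ANCHORS)
    blocks = [b for b in extract_blocks(msa, cols, "YiiP") if b.is_reference]
    mat = signature(blocks, exclude_reference=False)
    assert consensus_quartet(mat).quartet == "DD-HD"


def test_ties_break_alphabetically_and_are_flagged():
    rows = ["H" * 30] * 10
    # position 10: half D, half E
    for i in range(5):
        rows[i] = rows[i][:9] + "D" + rows[i][10:]
    for i in range(5, 10):
        rows[i] = rows[i][:9] + "E" + rows[i][10:]
    consensus = consensus_quartet(signature(_blocks(rows), exclude_reference=False))
    assert consensus.quartet == "HD-HH"
    assert consensus.tie_positions == (10,)


def test_clustal_and_fasta_inputs_agree(tmp_path):
    fasta, _ = generate_msa(hdhd_clade_spec(30), seed=6)
    import io

    msa = AlignIO.read(io.StringIO(fasta), "fasta")
    fpath = tmp_path / "clade.fasta"
    cpath = tmp_path / "clade.aln"
    fpath.write_text(fasta)
    with open(cpath, "w") as fh:
        AlignIO.write(msa, fh, "clustal")
    from metalsites.pipeline import run_asite

    mat_f, cons_f = run_asite(fpath, output_dir=tmp_path / "of")
    mat_c, cons_c = run_asite(cpath, output_dir=tmp_path / "oc")
    assert cons_f == cons_c
    assert np.array_equal(mat_f.frequencies, mat_c.frequencies)
    assert (tmp_path / "of" / "asite_signature.tsv").read_text() == (
        tmp_path / "oc" / "asite_signature.tsv"
    ).read_text()


def test_estimated_frequencies_match_planted_distributions():
    """n=500 sampling: every position within 3 binomial SEs of its truth."""
    spec = hdhd_clade_spec(500, conservation=0.7)
    fasta, truth = generate_msa(spec, seed=13)
    import io

    msa = AlignIO.read(io.StringIO(fasta), "fasta")
    cols = map_anchor_columns(msa, YIIP_ANCHORS)
    blocks = extract_blocks(msa, cols, reference_id="YiiP")
    mat = signature(blocks)
    n = 500
    for pos, letter in zip((6, 10, 21, 25), "HDHD"):
        p = 0.7
        se = math.sqrt(p * (1 - p) / n)
        idx = mat.codes.index(letter)
        assert abs(mat.frequencies[pos - 1, idx] - p) <= 3 * se
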