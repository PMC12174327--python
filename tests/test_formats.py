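"""PAT/BETA/blocks round trips, parsing contracts, and counting identities."""

import gzip

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cfmeth.formats import (
    BetaVector,
    Block,
    CpGIndexMap,
    FormatError,
    FragmentRecord,
    block_from_cpg_interval,
    fragments_to_beta,
    read_blocks,
    read_pat,
    write_blocks,
    write_pat,
)


# -- fragment records -------------------------------------------------------


def test_pat_line_maps_to_record(tmp_path, cpg_map):
    path = tmp_path / "a.pat"
    path.write_text("chr1\t17\tCCT\t3\n")
    (rec,) = read_pat(path, cpg_map)
    assert rec == FragmentRecord("chr1", 17, "CCT", 3)
    assert rec.end_cpg == 20


@pytest.mark.parametrize(
    "line, message",
    [
        ("chr1\t17\tCGT\t1", "pattern"),  # 'G' is not in the alphabet
        ("chr1\t17\tCCT\t0", "count"),
        ("chr1\t17\t...\t2", "observed"),
        ("chr1\t99\tCCT\t1", "range"),  # runs past chr1's 100 CpGs
        ("chr3\t1\tC\t1", "chromosome"),
        ("chr1\t17\tCCT", "fields"),
    ],
)
def test_pat_parse_errors_name_the_line(tmp_path, cpg_map, line, message):
    path = tmp_path / "bad.pat"
    path.write_text("chr1\t1\tTT\t1\n" + line + "\n")
    with pytest.raises(FormatError, match="line 2") as err:
        read_pat(path, cpg_map)
    assert message in str(err.value).lower()


def test_pat_requires_sorted_records(tmp_path, cpg_map):
    path = tmp_path / "unsorted.pat"
    path.write_text("chr1\t10\tCC\t1\nchr1\t5\tTT\t1\n")
    with pytest.raises(FormatError, match="sorted"):
        read_pat(path, cpg_map)
    with pytest.raises(ValueError, match="order"):
        write_pat(
            [FragmentRecord("chr1", 10, "CC"), FragmentRecord("chr1", 5, "TT")],
            tmp_path / "out.pat",
        )


def test_write_pat_exact_serialization(tmp_path):
    path = tmp_path / "one.pat"
    write_pat([FragmentRecord("chr1", 5, "TT", 2)], path)
    assert path.read_text() == "chr1\t5\tTT\t2\n"
    write_pat([], tmp_path / "empty.pat")
    assert (tmp_path / "empty.pat").read_text() == ""


@st.composite
def record_collections(draw):
    n = draw(st.integers(0, 30))
    recs = []
    start = 1
    for _ in range(n):
        start = draw(st.integers(start, 90))
        pattern = draw(
            st.text(alphabet="CT.", min_size=1, max_size=min(8, 100 - start + 1)).filter(
                lambda p: set(p) != {"."}
            )
        )
        recs.append(FragmentRecord("chr1", start, pattern, draw(st.integers(1, 5))))
    return recs


@given(record_collections())
def test_pat_round_trip_identity(tmp_path_factory, records):
    cpg_map = CpGIndexMap.from_positions({"chr1": (101 + 10 * np.arange(100)).tolist()})
    path = tmp_path_factory.mktemp("rt") / "x.pat"
    write_pat(records, path)
    assert read_pat(path, cpg_map) == records


def test_pat_gzip_round_trip(tmp_path, cpg_map):
    recs = [FragmentRecord("chr1", 3, "CT.C", 2), FragmentRecord("chr2", 101, "TT", 1)]
    path = tmp_path / "x.pat.gz"
    write_pat(recs, path)
    with gzip.open(path, "rt") as fh:  # really gzip on disk
        assert fh.readline().startswith("chr1\t3")
    assert read_pat(path, cpg_map) == recs


# -- beta conversion --------------------------------------------------------


def test_fragments_to_beta_counts(cpg_map):
    recs = [
        FragmentRecord("chr1", 5, "C"),
        FragmentRecord("chr1", 5, "C"),
        FragmentRecord("chr1", 5, "T"),
    ]
    beta = fragments_to_beta(recs, cpg_map)
    assert beta.counts_at(5) == (2, 3)


def test_fragments_to_beta_skips_unobserved_and_weights_counts(cpg_map):
    beta = fragments_to_beta([FragmentRecord("chr1", 5, "C.C", 2)], cpg_map)
    assert beta.counts_at(5) == (2, 2)
    assert beta.counts_at(6) == (0, 0)
    assert beta.counts_at(7) == (2, 2)


def test_fragments_to_beta_empty(cpg_map):
    beta = fragments_to_beta([], cpg_map)
    assert beta.n_total.sum() == 0 and len(beta) == cpg_map.n_cpgs


def _beta_reference(records, cpg_map):
    """Independent per-record oracle for the vectorized conversion."""
    meth = np.zeros(cpg_map.n_cpgs, dtype=np.int64)
    total = np.zeros(cpg_map.n_cpgs, dtype=np.int64)
    for rec in records:
        for off, ch in enumerate(rec.pattern):
            if ch in "CT":
                total[rec.start_cpg - 1 + off] += rec.count
                if ch == "C":
                    meth[rec.start_cpg - 1 + off] += rec.count
    return BetaVector(meth, total)


@given(record_collections())
def test_beta_additivity_and_symbol_conservation(records):
    cpg_map = CpGIndexMap.from_positions({"chr1": (101 + 10 * np.arange(100)).tolist()})
    beta = fragments_to_beta(records, cpg_map)
    assert beta == _beta_reference(records, cpg_map)
    half = len(records) // 2
    summed = fragments_to_beta(records[:half], cpg_map) + fragments_to_beta(records[half:], cpg_map)
    assert summed == beta
    n_symbols = sum(r.count * (len(r.pattern) - r.pattern.count(".")) for r in records)
    assert int(beta.n_total.sum()) == n_symbols


# -- blocks -----------------------------------------------------------------


def test_blocks_read_example(tmp_path, cpg_map):
    path = tmp_path / "b.bed"
    path.write_text("chr1\t1000\t1600\t17\t25\n")
    (blk,) = read_blocks(path, cpg_map)
    assert blk == Block("chr1", 1000, 1600, 17, 25)
    assert blk.n_cpgs == 8


def test_blocks_round_trip(tmp_path, cpg_map):
    blocks = [
        Block("chr1", 100, 180, 1, 9),
        Block("chr1", 200, 300, 11, 21),
        Block("chr2", 500, 530, 101, 103),
    ]
    path = tmp_path / "blocks.bed"
    write_blocks(blocks, path)
    assert read_blocks(path, cpg_map) == blocks


def test_blocks_reject_inverted_and_overlapping(tmp_path, cpg_map):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t1600\t1000\t17\t25\n")
    with pytest.raises(FormatError):
        read_blocks(path, cpg_map)
    path.write_text("chr1\t100\t200\t1\t9\nchr1\t150\t300\t5\t15\n")
    with pytest.raises(FormatError, match="overlap"):
        read_blocks(path, cpg_map)


def test_block_from_cpg_interval_covers_its_sites(cpg_map):
    blk = block_from_cpg_interval(cpg_map, "chr1", 5, 13)
    # CpGs 5..12 sit at 1-based positions 141..211
    assert (blk.start_bp, blk.end_bp) == (140, 212)
    assert blk.n_cpgs == 8
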