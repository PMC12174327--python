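"""U/X/M fragment classification and atlas construction."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cfmeth.formats import Block, FragmentRecord
from cfmeth.markers import MarkerBlock
from cfmeth.uxm import (
    ClassifierParams,
    block_uxm_proportions,
    build_atlas,
    classify_fragment,
    read_atlas,
    tally_uxm,
    write_atlas,
)

BLOCK = Block("chr1", 0, 400, 1, 21)


def frag(pattern, start=1, count=1):
    return FragmentRecord("chr1", start, pattern, count)


@pytest.mark.parametrize(
    "pattern, expected",
    [
        ("TTTT", "U"),
        ("CCC", "M"),
        ("TCCT", "X"),
        ("T.T", None),  # 2 observed CpGs < rlen 3
        ("TTC", "U"),  # 1/3 methylated: the boundary is inclusive
        ("CCT", "M"),  # 2/3 methylated: inclusive on the M side too
        ("..C..", None),
        ("TTTC", "U"),  # 1/4 <= 1/3
        ("TCTCT", "X"),  # 2/5 strictly between the thresholds
    ],
)
def test_classify_thresholds(pattern, expected):
    assert classify_fragment(frag(pattern), BLOCK) == expected


def test_classify_restricts_to_in_block_cpgs():
    block = Block("chr1", 0, 100, 1, 5)  # CpGs 1..4
    # full pattern is half methylated, but the in-block part "TTT" is U
    rec = frag("TTTCCC", start=2)
    assert classify_fragment(rec, block) == "U"
    outside = frag("CCC", start=30)
    assert classify_fragment(outside, block) is None


@given(st.text(alphabet="CT", min_size=1, max_size=8), st.integers(0, 3), st.integers(0, 3))
def test_dot_padding_never_changes_the_class(core, left, right):
    padded = "." * left + core + "." * right
    a = classify_fragment(frag(core, start=5), BLOCK)
    b = classify_fragment(frag(padded, start=5 - left + 0), BLOCK)
    # shift start so observed CpGs land on the same sites
    assert a == b


@given(st.text(alphabet="CT.", min_size=1, max_size=10).filter(lambda p: set(p) != {"."}))
def test_inversion_swaps_u_and_m(pattern):
    inverted = pattern.translate(str.maketrans("CT", "TC"))
    swap = {"U": "M", "M": "U", "X": "X", None: None}
    assert classify_fragment(frag(inverted), BLOCK) == swap[classify_fragment(frag(pattern), BLOCK)]


def test_block_proportions_examples():
    frags = [frag("TTT")] * 6 + [frag("TCCT")] + [frag("CCC")] * 3
    c = block_uxm_proportions(frags, BLOCK)
    assert (c.u, c.x, c.m, c.n) == (Fraction(3, 5), Fraction(1, 10), Fraction(3, 10), 10)
    weighted = block_uxm_proportions([frag("TTT", count=4), frag("CCC", count=1)], BLOCK)
    assert (weighted.u, weighted.x, weighted.m, weighted.n) == (
        Fraction(4, 5), 0, Fraction(1, 5), 5,
    )
    empty = block_uxm_proportions([frag("T.", start=1)], BLOCK)
    assert empty.n == 0


@given(st.lists(st.text(alphabet="CT.", min_size=3, max_size=8).filter(lambda p: p.count(".") < len(p)), max_size=20))
def test_proportions_sum_to_one_exactly(patterns):
    c = block_uxm_proportions([frag(p) for p in patterns], BLOCK)
    if c.n:
        assert c.u + c.x + c.m == 1


def test_rlen_parameter():
    assert classify_fragment(frag("TT"), BLOCK, ClassifierParams(rlen=2)) == "U"
    assert classify_fragment(frag("TT"), BLOCK) is None


def test_invalid_params():
    with pytest.raises(ValueError):
        ClassifierParams(u_threshold=Fraction(2, 3), m_threshold=Fraction(1, 3))
    with pytest.raises(ValueError):
        ClassifierParams(rlen=0)


# -- tallies over many blocks -----------------------------------------------


def test_tally_matches_per_block_classification_with_straddling_fragments():
    blocks = [Block("chr1", 0, 100, 1, 11), Block("chr1", 100, 200, 11, 21)]
    recs = [
        frag("TTTT", 1),
        frag("CCCC", 13),
        frag("TTTCCC", 8),  # straddles: TTT in block 1, CCC in block 2
        frag("TTTT", 40),  # outside both blocks
        frag("T.TC", 9),
    ]
    fast = tally_uxm(recs * 200, blocks)  # force the vectorized path
    slow = np.array(
        [[c.n_u, c.n_x, c.n_m] for c in (block_uxm_proportions(recs * 200, b) for b in blocks)]
    )
    assert np.array_equal(fast, slow)
    single = tally_uxm(recs, blocks)
    assert np.array_equal(single * 200, fast)


# -- atlas ------------------------------------------------------------------


def _markers(n_cpgs=10):
    b1 = Block("chr1", 0, 100, 1, 11)
    b2 = Block("chr1", 100, 200, 11, 21)
    return [
        MarkerBlock(b1, "alpha", "hypo", 0.9, 1),
        MarkerBlock(b2, "beta", "hyper", 0.9, 1),
    ]


def test_perfect_references_give_unit_contrast():
    markers = _markers()
    refs = {
        "alpha": [frag("TTTT", 2)] * 5 + [frag("TTTT", 12)] * 5,
        "beta": [frag("CCCC", 2)] * 5 + [frag("CCCC", 12)] * 5,
    }
    atlas = build_atlas(refs, markers)
    # hypo marker: U proportion; hyper marker: M proportion
    assert atlas.values[0].tolist() == [1.0, 0.0]
    assert atlas.values[1].tolist() == [0.0, 1.0]
    assert atlas.coverage.tolist() == [[5, 5], [5, 5]]


def test_partial_methylation_gives_fractional_atlas_value():
    markers = [_markers()[1]]  # hyper marker on block 2
    refs = {"beta": [frag("CCCC", 12)] * 9 + [frag("TTTT", 12)]}
    atlas = build_atlas(refs, markers)
    assert atlas.values[0, 0] == pytest.approx(0.9)


def test_empty_marker_list_rejected():
    with pytest.raises(ValueError):
        build_atlas({"alpha": []}, [])


def test_missing_target_coverage_warns_and_keeps_nan():
    markers = _markers()
    refs = {"alpha": [frag("TTTT", 2)] * 5, "beta": [frag("CCCC", 2)] * 5}
    with pytest.warns(UserWarning, match="no coverage"):
        atlas = build_atlas(refs, markers)
    assert np.isnan(atlas.values[1, 1])  # beta's hyper marker unseen in beta
    assert atlas.coverage[1, 1] == 0


def test_atlas_round_trip(tmp_path):
    markers = _markers()
    refs = {
        "alpha": [frag("TTTT", 2), frag("CTCC", 12)],
        "beta": [frag("CCCC", 2), frag("CCCC", 12)],
    }
    atlas = build_atlas(refs, markers)
    write_atlas(atlas, tmp_path / "atlas.tsv", tmp_path / "cov.tsv")
    back = read_atlas(tmp_path / "atlas.tsv", tmp_path / "cov.tsv")
    assert back.cell_types == atlas.cell_types
    np.testing.assert_allclose(back.values, atlas.values)
    assert np.array_equal(back.coverage, atlas.coverage)
    assert [m.block for m in back.markers] == [m.block for m in atlas.markers]
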