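"""Fragment-level U/X/M classification and the deconvolution atlas.

Each fragment overlapping a marker block is restricted to its observed
in-block CpGs and classed by the methylated fraction m/k: U (mostly
unmethylated) when m/k <= 1/3, M (mostly methylated) when m/k >= 2/3, X
otherwise; fragments with fewer than ``rlen`` observed in-block CpGs are
excluded. The printed thresholds "<=33%" / ">=66%" are taken as the exact
thirds, compared in integer arithmetic (m*q <= p*k), so boundary fragments
such as a 3-CpG read with one methylated site classify as U without float
artefacts.

The atlas is the marker x cell-type matrix of U proportions (hypomethylated
markers) or M proportions (hypermethylated markers) computed from pooled
reference fragments per cell type — the design matrix of the NNLS
deconvolution.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import Block, FragmentRecord, _open_text
from .markers import MarkerBlock

_C_BYTE, _T_BYTE = ord("C"), ord("T")


@dataclass(frozen=True)
class ClassifierParams:
    """U/X/M thresholds (exact rationals) and the minimum observed in-block
    CpGs per fragment (``rlen``, default 3)."""

    u_threshold: Fraction = Fraction(1, 3)
    m_threshold: Fraction = Fraction(2, 3)
    rlen: int = 3

    def __post_init__(self):
        u = Fraction(self.u_threshold).limit_denominator(10**6)
        m = Fraction(self.m_threshold).limit_denominator(10**6)
        object.__setattr__(self, "u_threshold", u)
        object.__setattr__(self, "m_threshold", m)
        if not 0 < u < m < 1:
            raise ValueError("thresholds must satisfy 0 < u_threshold < m_threshold < 1")
        if self.rlen < 1:
            raise ValueError("rlen must be >= 1")


@dataclass
class UXMCounts:
    """Count-weighted U/X/M tallies over one block; proportions are exact."""

    n_u: int = 0
    n_x: int = 0
    n_m: int = 0

    @property
    def n(self) -> int:
        return self.n_u + self.n_x + self.n_m

    @property
    def u(self) -> Fraction:
        return Fraction(self.n_u, self.n)

    @property
    def x(self) -> Fraction:
        return Fraction(self.n_x, self.n)

    @property
    def m(self) -> Fraction:
        return Fraction(self.n_m, self.n)


def _classify_counts(n_meth: int, n_obs: int, params: ClassifierParams) -> str | None:
    if n_obs < params.rlen:
        return None
    u, m = params.u_threshold, params.m_threshold
    if n_meth * u.denominator <= u.numerator * n_obs:
        return "U"
    if n_meth * m.denominator >= m.numerator * n_obs:
        return "M"
    return "X"


def classify_fragment(
    record: FragmentRecord, block: Block, params: ClassifierParams = ClassifierParams()
) -> str | None:
    """Class of one fragment over one block: 'U', 'X', 'M', or None (excluded)."""
    if record.chrom != block.chrom or record.start_cpg >= block.end_cpg or record.end_cpg <= block.start_cpg:
        return None
    lo = max(record.start_cpg, block.start_cpg) - record.start_cpg
    hi = min(record.end_cpg, block.end_cpg) - record.start_cpg
    sub = record.pattern[lo:hi]
    n_meth = sub.count("C")
    n_obs = n_meth + sub.count("T")
    return _classify_counts(n_meth, n_obs, params)


def block_uxm_proportions(
    records: Iterable[FragmentRecord], block: Block, params: ClassifierParams = ClassifierParams()
) -> UXMCounts:
    """Count-weighted U/X/M tallies of all fragments overlapping the block."""
    counts = UXMCounts()
    for rec in records:
        cls = classify_fragment(rec, block, params)
        if cls == "U":
            counts.n_u += rec.count
        elif cls == "X":
            counts.n_x += rec.count
        elif cls == "M":
            counts.n_m += rec.count
    return counts


def tally_uxm(
    records: Iterable[FragmentRecord],
    blocks: Sequence[Block],
    params: ClassifierParams = ClassifierParams(),
) -> np.ndarray:
    """U/X/M tallies over many non-overlapping blocks in one pass.

    Returns an ``(n_blocks, 3)`` integer array of count-weighted (U, X, M)
    tallies. Blocks must be sorted and non-overlapping (within a chromosome);
    a fragment straddling two blocks contributes to each block it overlaps,
    classified on that block's in-block CpGs only.
    """
    records = list(records)
    out = np.zeros((len(blocks), 3), dtype=np.int64)
    grouped: dict[str, list[tuple[int, int, int]]] = {}
    for j, b in enumerate(blocks):
        grouped.setdefault(b.chrom, []).append((b.start_cpg, b.end_cpg, j))
    by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
    vectorizable = True
    for chrom, triples in grouped.items():
        triples.sort()
        starts_c = [t[0] for t in triples]
        ends_c = [t[1] for t in triples]
        by_chrom[chrom] = (starts_c, ends_c, [t[2] for t in triples])
        if any(ends_c[i] > starts_c[i + 1] for i in range(len(starts_c) - 1)):
            vectorizable = False  # overlapping blocks: take the general path
    if vectorizable and len(records) > 512:
        records = _tally_uxm_vectorized(records, by_chrom, out, params)
    rlen = params.rlen
    un, ud = params.u_threshold.numerator, params.u_threshold.denominator
    mn, md = params.m_threshold.numerator, params.m_threshold.denominator
    for rec in records:
        entry = by_chrom.get(rec.chrom)
        if entry is None:
            continue
        starts, ends, idx = entry
        f_start, f_end = rec.start_cpg, rec.end_cpg
        i = bisect_right(starts, f_start) - 1
        # step back over same-start duplicates / rare overlaps, then forward
        while i > 0 and ends[i - 1] > f_start:
            i -= 1
        if i < 0 or ends[i] <= f_start:
            i += 1
        pattern, cnt = rec.pattern, rec.count
        while i < len(starts) and starts[i] < f_end:
            b_start, b_end = starts[i], ends[i]
            if b_start <= f_start and f_end <= b_end:
                sub = pattern
            else:
                sub = pattern[max(f_start, b_start) - f_start : min(f_end, b_end) - f_start]
            n_meth = sub.count("C")
            n_obs = n_meth + sub.count("T")
            if n_obs >= rlen:
                if n_meth * ud <= un * n_obs:
                    col = 0
                elif n_meth * md >= mn * n_obs:
                    col = 2
                else:
                    col = 1
                out[idx[i], col] += cnt
            i += 1
    return out


def _tally_uxm_vectorized(
    records: list[FragmentRecord],
    by_chrom: Mapping[str, tuple[list[int], list[int], list[int]]],
    out: np.ndarray,
    params: ClassifierParams,
) -> list[FragmentRecord]:
    """Tally fragments wholly inside one block; return the remainder.

    Fragments fully contained in a single block (the overwhelming case for
    short cfDNA reads over kb-scale blocks) classify on their whole pattern,
    which vectorizes; straddling or unmatched fragments are handed back for
    the general per-record path.
    """
    from .formats import group_records_by_length

    un, ud = params.u_threshold.numerator, params.u_threshold.denominator
    mn, md = params.m_threshold.numerator, params.m_threshold.denominator
    leftovers: list[FragmentRecord] = []
    by_rec_chrom: dict[str, list[FragmentRecord]] = {}
    for rec in records:
        by_rec_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom, recs in by_rec_chrom.items():
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        bstarts = np.asarray(entry[0], dtype=np.int64)
        bends = np.asarray(entry[1], dtype=np.int64)
        bidx = np.asarray(entry[2], dtype=np.int64)
        for ids, starts, counts, codes in group_records_by_length(recs):
            k = codes.shape[1]
            pos = np.searchsorted(bstarts, starts, side="right") - 1
            pc = np.clip(pos, 0, None)
            contained = (pos >= 0) & (starts >= bstarts[pc]) & (starts + k <= bends[pc])
            if not contained.all():
                leftovers.extend(recs[i] for i in ids[~contained])
            if not contained.any():
                continue
            sel = contained
            n_meth = (codes[sel] == _C_BYTE).sum(axis=1)
            n_obs = n_meth + (codes[sel] == _T_BYTE).sum(axis=1)
            cls = np.full(n_meth.shape, 1, dtype=np.int64)  # X
            cls[n_meth * ud <= un * n_obs] = 0  # U
            cls[n_meth * md >= mn * n_obs] = 2  # M
            keep = n_obs >= params.rlen
            flat = bidx[pc[sel][keep]] * 3 + cls[keep]
            np.add.at(out.reshape(-1), flat, counts[sel][keep])
    return leftovers


@dataclass
class AtlasMatrix:
    """Marker x cell-type design matrix of U/M fragment proportions.

    ``values[i, j]`` is the U (hypo marker i) or M (hyper marker i) fragment
    proportion in cell type j, NaN where ``coverage[i, j] == 0``.
    """

    markers: list[MarkerBlock]
    cell_types: list[str]
    values: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        shape = (len(self.markers), len(self.cell_types))
        if self.values.shape != shape or self.coverage.shape != shape:
            raise ValueError("atlas values/coverage must be (n_markers, n_cell_types)")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("atlas values must lie in [0, 1]")


def build_atlas(
    reference_sets: Mapping[str, Sequence[FragmentRecord]],
    markers: Sequence[MarkerBlock],
    params: ClassifierParams = ClassifierParams(),
) -> AtlasMatrix:
    """Compute the atlas from pooled per-cell-type reference fragments.

    ``reference_sets`` maps each cell type to its pooled fragment records
    (reference samples of a type are pooled by concatenation — equivalently,
    by summing fragment counts). A marker with zero coverage in its own
    target type is kept with a missing value and a warning.
    """
    if len(markers) == 0:
        raise ValueError("cannot build an atlas from an empty marker list")
    cell_types = list(reference_sets)
    blocks = [mk.block for mk in markers]
    values = np.full((len(markers), len(cell_types)), np.nan)
    coverage = np.zeros((len(markers), len(cell_types)), dtype=np.int64)
    for j, ct in enumerate(cell_types):
        tallies = tally_uxm(reference_sets[ct], blocks, params)
        n = tallies.sum(axis=1)
        coverage[:, j] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            u_prop = tallies[:, 0] / n
            m_prop = tallies[:, 2] / n
        for i, mk in enumerate(markers):
            if n[i] > 0:
                values[i, j] = u_prop[i] if mk.direction == "hypo" else m_prop[i]
    for i, mk in enumerate(markers):
        if mk.group in reference_sets and coverage[i, cell_types.index(mk.group)] == 0:
            warnings.warn(
                f"marker {i} ({mk.block.chrom}:{mk.block.start_bp}-{mk.block.end_bp}) "
                f"has no coverage in its target type {mk.group}",
                stacklevel=2,
            )
    if (coverage.sum(axis=1) == 0).any():
        warnings.warn("some markers have no coverage in any cell type", stacklevel=2)
    return AtlasMatrix(list(markers), cell_types, values, coverage)


# ---------------------------------------------------------------------------
# Atlas serialization
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ["chrom", "start_bp", "end_bp", "start_cpg", "end_cpg", "group", "direction"]


def _atlas_frame(atlas: AtlasMatrix, matrix: np.ndarray) -> pd.DataFrame:
    rows = []
    for mk, vals in zip(atlas.markers, matrix):
        b = mk.block
        rows.append([b.chrom, b.start_bp, b.end_bp, b.start_cpg, b.end_cpg, mk.group, mk.direction, *vals])
    return pd.DataFrame(rows, columns=_KEY_COLUMNS + atlas.cell_types)


def write_atlas(atlas: AtlasMatrix, path: str | Path, coverage_path: str | Path | None = None) -> None:
    _atlas_frame(atlas, atlas.values).to_csv(path, sep="\t", index=False, float_format="%.10g")
    if coverage_path is not None:
        _atlas_frame(atlas, atlas.coverage).to_csv(coverage_path, sep="\t", index=False)


def read_atlas(path: str | Path, coverage_path: str | Path | None = None) -> AtlasMatrix:
    df = pd.read_csv(path, sep="\t")
    cell_types = [c for c in df.columns if c not in _KEY_COLUMNS]
    markers = [
        MarkerBlock(
            Block(r.chrom, int(r.start_bp), int(r.end_bp), int(r.start_cpg), int(r.end_cpg)),
            str(r.group), str(r.direction), score=1.0, rank=i + 1,
        )
        for i, r in enumerate(df.itertuples())
    ]
    values = df[cell_types].to_numpy(dtype=float)
    if coverage_path is not None:
        coverage = pd.read_csv(coverage_path, sep="\t")[cell_types].to_numpy(dtype=np.int64)
    else:
        coverage = np.where(np.isnan(values), 0, 1).astype(np.int64)
    return AtlasMatrix(markers, cell_types, values, coverage)
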