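"""Fragment-level (PAT-like), per-CpG (BETA-like), and block (BED-like) formats.

The coordinate system is a genome-wide CpG index: every CpG site gets a global,
1-based index assigned in chromosome order (:class:`CpGIndexMap`). Fragment
records anchor a methylation pattern string (``C`` methylated, ``T``
unmethylated, ``.`` unobserved) at the index of its first covered CpG. Blocks
are half-open runs of consecutive CpG indices ``[start_cpg, end_cpg)`` with
genomic bp coordinates kept in the BED convention (0-based, half-open) both in
memory and on disk.

All files are plain TSV; a ``.gz`` extension triggers transparent gzip.
"""

from __future__ import annotations

import gzip
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

_PATTERN_ALPHABET = frozenset("CT.")


class FormatError(ValueError):
    """Raised for malformed PAT/BETA/blocks files; carries the line number."""

    def __init__(self, message: str, path: object = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.line = line


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------------------
# CpG index map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGIndexMap:
    """Global 1-based CpG numbering over ordered chromosomes.

    ``cpg_positions[chrom]`` holds the sorted 1-based bp positions of the C of
    each CpG site; ``index_offset[chrom]`` is the global index of the first
    CpG on that chromosome.
    """

    chrom_names: tuple[str, ...]
    cpg_positions: dict[str, np.ndarray]
    index_offset: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        offsets: dict[str, int] = {}
        nxt = 1
        for chrom in self.chrom_names:
            pos = np.asarray(self.cpg_positions[chrom], dtype=np.int64)
            if pos.ndim != 1 or pos.size == 0:
                raise ValueError(f"chromosome {chrom} has no CpG positions")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"CpG positions not strictly increasing on {chrom}")
            if pos[0] < 1:
                raise ValueError("CpG positions are 1-based and must be >= 1")
            object.__setattr__(self, "cpg_positions", {**self.cpg_positions, chrom: pos})
            offsets[chrom] = nxt
            nxt += pos.size
        object.__setattr__(self, "index_offset", offsets)
        object.__setattr__(self, "_n_cpgs", nxt - 1)

    @classmethod
    def from_positions(cls, positions: dict[str, Sequence[int]]) -> "CpGIndexMap":
        return cls(tuple(positions), {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()})

    @property
    def n_cpgs(self) -> int:
        return self._n_cpgs  # type: ignore[attr-defined]

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global index range ``[first, last+1)`` of a chromosome."""
        off = self.index_offset[chrom]
        return off, off + self.cpg_positions[chrom].size

    def locate(self, index: int) -> tuple[str, int]:
        """Map a global CpG index to its (chromosome, 1-based bp position)."""
        if not 1 <= index <= self.n_cpgs:
            raise IndexError(f"CpG index {index} outside [1, {self.n_cpgs}]")
        for chrom in self.chrom_names:
            lo, hi = self.chrom_range(chrom)
            if index < hi:
                return chrom, int(self.cpg_positions[chrom][index - lo])
        raise AssertionError("unreachable")

    def global_index(self, chrom: str, position: int) -> int:
        pos = self.cpg_positions[chrom]
        i = bisect_left(pos.tolist(), position)
        if i == len(pos) or pos[i] != position:
            raise KeyError(f"no CpG at {chrom}:{position}")
        return self.index_offset[chrom] + i


def write_cpg_map(cpg_map: CpGIndexMap, path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for chrom in cpg_map.chrom_names:
            for pos in cpg_map.cpg_positions[chrom]:
                fh.write(f"{chrom}\t{pos}\n")


def read_cpg_map(path: str | Path) -> CpGIndexMap:
    positions: dict[str, list[int]] = {}
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                chrom, pos = line.rstrip("\n").split("\t")
                positions.setdefault(chrom, []).append(int(pos))
            except ValueError as exc:
                raise FormatError(f"malformed CpG map line: {exc}", path, lineno) from None
    return CpGIndexMap.from_positions(positions)


# ---------------------------------------------------------------------------
# Fragment records (PAT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One sequenced fragment: CpG-index anchor, C/T/. pattern, multiplicity."""

    chrom: str
    start_cpg: int
    pattern: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        p = self.pattern
        if not p or not _PATTERN_ALPHABET.issuperset(p):
            raise ValueError(f"invalid methylation pattern {p!r}")
        if len(p) == p.count("."):
            raise ValueError("pattern must contain at least one observed CpG")

    @property
    def end_cpg(self) -> int:
        """Half-open end of the covered CpG-index interval."""
        return self.start_cpg + len(self.pattern)


def read_pat(path: str | Path, cpg_map: CpGIndexMap) -> list[FragmentRecord]:
    """Parse a PAT-like TSV, validating indices against ``cpg_map``.

    Records must be sorted by (chromosome in map order, start_cpg); ordering
    is preserved in the returned list.
    """
    records: list[FragmentRecord] = []
    chrom_order = {c: i for i, c in enumerate(cpg_map.chrom_names)}
    prev = (-1, -1)
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"expected 4 tab-separated fields, got {len(fields)}", path, lineno)
            chrom, start_s, pattern, count_s = fields
            if chrom not in chrom_order:
                raise FormatError(f"unknown chromosome {chrom!r}", path, lineno)
            try:
                start, count = int(start_s), int(count_s)
            except ValueError:
                raise FormatError("start_cpg and count must be integers", path, lineno) from None
            try:
                rec = FragmentRecord(chrom, start, pattern, count)
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from None
            lo, hi = cpg_map.chrom_range(chrom)
            if not (lo <= start and rec.end_cpg <= hi):
                raise FormatError(
                    f"CpG indices [{start}, {rec.end_cpg}) outside {chrom} range [{lo}, {hi})",
                    path, lineno,
                )
            key = (chrom_order[chrom], start)
            if key < prev:
                raise FormatError("records not sorted by (chrom, start_cpg)", path, lineno)
            prev = key
            records.append(rec)
    return records


def write_pat(records: Iterable[FragmentRecord], path: str | Path) -> None:
    """Serialize records as PAT-like TSV; input must already be sorted."""
    prev: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    with _open_text(path, "w") as fh:
        for rec in records:
            if prev is not None:
                if rec.chrom == prev[0]:
                    if rec.start_cpg < prev[1]:
                        raise ValueError("records out of order: start_cpg decreases within chromosome")
                elif rec.chrom in seen_chroms:
                    raise ValueError(f"records out of order: chromosome {rec.chrom} repeats")
            seen_chroms.add(rec.chrom)
            prev = (rec.chrom, rec.start_cpg)
            fh.write(f"{rec.chrom}\t{rec.start_cpg}\t{rec.pattern}\t{rec.count}\n")


# ---------------------------------------------------------------------------
# Beta vectors
# ---------------------------------------------------------------------------


class BetaVector:
    """Per-CpG (n_methylated, n_total) counts indexed by global CpG index."""

    __slots__ = ("n_meth", "n_total")

    def __init__(self, n_meth: np.ndarray, n_total: np.ndarray):
        n_meth = np.asarray(n_meth, dtype=np.int64)
        n_total = np.asarray(n_total, dtype=np.int64)
        if n_meth.shape != n_total.shape or n_meth.ndim != 1:
            raise ValueError("n_meth and n_total must be 1-D arrays of equal length")
        if np.any(n_meth < 0) or np.any(n_meth > n_total):
            raise ValueError("requires 0 <= n_methylated <= n_total at every site")
        self.n_meth = n_meth
        self.n_total = n_total

    @classmethod
    def zeros(cls, n_cpgs: int) -> "BetaVector":
        return cls(np.zeros(n_cpgs, dtype=np.int64), np.zeros(n_cpgs, dtype=np.int64))

    def __len__(self) -> int:
        return self.n_meth.size

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BetaVector)
            and np.array_equal(self.n_meth, other.n_meth)
            and np.array_equal(self.n_total, other.n_total)
        )

    def __add__(self, other: "BetaVector") -> "BetaVector":
        return BetaVector(self.n_meth + other.n_meth, self.n_total + other.n_total)

    def counts_at(self, index: int) -> tuple[int, int]:
        """(n_methylated, n_total) at a global 1-based CpG index."""
        return int(self.n_meth[index - 1]), int(self.n_total[index - 1])

    def slice_cpgs(self, start_cpg: int, end_cpg: int) -> tuple[np.ndarray, np.ndarray]:
        """Count arrays over the half-open global index interval."""
        return self.n_meth[start_cpg - 1 : end_cpg - 1], self.n_total[start_cpg - 1 : end_cpg - 1]


def group_records_by_length(
    records: Sequence[FragmentRecord],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Group records by pattern length into (index, start, count, codes) tuples.

    ``codes`` is a ``(n, k)`` uint8 matrix of ASCII pattern bytes — the shared
    vectorization backbone for beta conversion and U/X/M tallying.
    """
    buckets: dict[int, tuple[list[int], list[str]]] = {}
    for i, rec in enumerate(records):
        idx, pats = buckets.setdefault(len(rec.pattern), ([], []))
        idx.append(i)
        pats.append(rec.pattern)
    out = []
    for k, (idx, pats) in buckets.items():
        codes = np.frombuffer("".join(pats).encode("ascii"), dtype=np.uint8).reshape(-1, k)
        ids = np.asarray(idx, dtype=np.int64)
        starts = np.fromiter((records[i].start_cpg for i in idx), dtype=np.int64, count=len(idx))
        counts = np.fromiter((records[i].count for i in idx), dtype=np.int64, count=len(idx))
        out.append((ids, starts, counts, codes))
    return out


_C, _T = ord("C"), ord("T")


def fragments_to_beta(records: Iterable[FragmentRecord], cpg_map: CpGIndexMap) -> BetaVector:
    """Collapse fragment patterns to per-CpG counts ('.' contributes nothing)."""
    records = list(records)
    meth = np.zeros(cpg_map.n_cpgs, dtype=np.int64)
    total = np.zeros(cpg_map.n_cpgs, dtype=np.int64)
    for _, starts, counts, codes in group_records_by_length(records):
        k = codes.shape[1]
        base = starts - 1
        for off in range(k):
            col = codes[:, off]
            is_c = col == _C
            is_t = col == _T
            if is_c.any():
                np.add.at(meth, base[is_c] + off, counts[is_c])
                np.add.at(total, base[is_c] + off, counts[is_c])
            if is_t.any():
                np.add.at(total, base[is_t] + off, counts[is_t])
    return BetaVector(meth, total)


def write_beta(beta: BetaVector, path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for i in range(len(beta)):
            fh.write(f"{i + 1}\t{beta.n_meth[i]}\t{beta.n_total[i]}\n")


def read_beta(path: str | Path, cpg_map: CpGIndexMap) -> BetaVector:
    meth = np.zeros(cpg_map.n_cpgs, dtype=np.int64)
    total = np.zeros(cpg_map.n_cpgs, dtype=np.int64)
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                idx_s, m_s, t_s = line.rstrip("\n").split("\t")
                idx, m, t = int(idx_s), int(m_s), int(t_s)
            except ValueError:
                raise FormatError("malformed BETA line", path, lineno) from None
            if not 1 <= idx <= cpg_map.n_cpgs:
                raise FormatError(f"CpG index {idx} out of range", path, lineno)
            meth[idx - 1], total[idx - 1] = m, t
    return BetaVector(meth, total)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Block:
    """A run of consecutive CpG sites.

    ``[start_bp, end_bp)`` is 0-based half-open (BED); ``[start_cpg, end_cpg)``
    is global 1-based half-open.
    """

    chrom: str
    start_bp: int
    end_bp: int
    start_cpg: int
    end_cpg: int

    def __post_init__(self):
        if self.end_cpg <= self.start_cpg:
            raise ValueError(f"empty CpG interval [{self.start_cpg}, {self.end_cpg})")
        if self.end_bp <= self.start_bp:
            raise ValueError(f"empty bp interval [{self.start_bp}, {self.end_bp})")

    @property
    def n_cpgs(self) -> int:
        return self.end_cpg - self.start_cpg

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def overlaps_cpgs(self, start_cpg: int, end_cpg: int) -> bool:
        return self.start_cpg < end_cpg and start_cpg < self.end_cpg


def block_from_cpg_interval(cpg_map: CpGIndexMap, chrom: str, start_cpg: int, end_cpg: int) -> Block:
    """Construct a block whose bp interval tightly covers its CpG sites."""
    lo, _ = cpg_map.chrom_range(chrom)
    pos = cpg_map.cpg_positions[chrom]
    first = int(pos[start_cpg - lo])
    last = int(pos[end_cpg - 1 - lo])
    # C at 1-based position p occupies 0-based [p-1, p); +1 covers the G.
    return Block(chrom, first - 1, last + 1, start_cpg, end_cpg)


def _check_block_order(blocks: Sequence[Block]) -> None:
    """Blocks must come in chromosome runs, sorted and non-overlapping within each."""
    seen: set[str] = set()
    prev: Block | None = None
    for b in blocks:
        if prev is None or b.chrom != prev.chrom:
            if b.chrom in seen:
                raise ValueError(f"blocks out of order: chromosome {b.chrom} repeats")
            seen.add(b.chrom)
        else:
            if b.start_cpg < prev.start_cpg:
                raise ValueError("blocks not sorted by start_cpg within chromosome")
            if b.start_cpg < prev.end_cpg or b.start_bp < prev.end_bp:
                raise ValueError(
                    f"overlapping blocks on {b.chrom}: [{prev.start_cpg}, {prev.end_cpg}) "
                    f"and [{b.start_cpg}, {b.end_cpg})"
                )
        prev = b


def read_blocks(path: str | Path, cpg_map: CpGIndexMap | None = None) -> list[Block]:
    """Read a BED-like blocks file (chrom, start_bp, end_bp, start_cpg, end_cpg)."""
    blocks: list[Block] = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError("expected >= 5 columns", path, lineno)
            try:
                blk = Block(fields[0], int(fields[1]), int(fields[2]), int(fields[3]), int(fields[4]))
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from None
            if cpg_map is not None:
                lo, hi = cpg_map.chrom_range(blk.chrom)
                if not (lo <= blk.start_cpg and blk.end_cpg <= hi):
                    raise FormatError("block CpG interval outside chromosome range", path, lineno)
            blocks.append(blk)
    try:
        _check_block_order(blocks)
    except ValueError as exc:
        raise FormatError(str(exc), path) from None
    return blocks


def write_blocks(blocks: Sequence[Block], path: str | Path) -> None:
    _check_block_order(blocks)
    with _open_text(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.start_cpg}\t{b.end_cpg}\n")


def iter_in_block(records: Iterable[FragmentRecord], block: Block) -> Iterator[FragmentRecord]:
    """Fragments whose covered CpG interval overlaps the block."""
    for rec in records:
        if rec.chrom == block.chrom and rec.start_cpg < block.end_cpg and block.start_cpg < rec.end_cpg:
            yield rec
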