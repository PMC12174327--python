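"""One-vs-all discovery of differentially methylated blocks (DMBs).

For each candidate block and each cell-type group the separation between the
target group's block-mean methylation and everyone else's is scored with
quantile slack: with T the target means, B the background means,

    hypo  score  s- = Q(B, bg_quant) - Q(T, 1 - tg_quant)
    hyper score  s+ = Q(T, tg_quant) - Q(B, 1 - bg_quant)

and the block becomes a marker in the direction of the larger score when that
score clears the margin. Quantiles interpolate linearly between order
statistics, so scores are reproducible bit for bit. Per group, candidates of
both directions are ranked together (score desc, then shorter block, then
genomic order) and truncated to ``top_k`` — the "top 100 blocks per group"
rule.

Also here: the per-block methylation score used for atlas heatmaps (fraction
of fragments whose observed in-block CpGs are uniformly unmethylated or
methylated — the strict, zero-discordance reading, distinct from the
thresholded U/X/M classifier), and the variable-block hierarchical clustering
used to define reference groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, isnan
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .formats import Block, BetaVector, FragmentRecord, _open_text


@dataclass(frozen=True)
class MarkerParams:
    """Quantile slacks, margin, and per-group marker cap."""

    tg_quant: float = 0.2
    bg_quant: float = 0.1
    margin: float = 0.4
    top_k: int = 100

    def __post_init__(self):
        if not (0 <= self.tg_quant < 0.5 and 0 <= self.bg_quant < 0.5):
            raise ValueError("quantile slacks must lie in [0, 0.5)")
        if not 0 < self.margin <= 1:
            raise ValueError("margin must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class MarkerBlock:
    """A cell-type-specific marker: block, target group, direction, score."""

    block: Block
    group: str
    direction: str  # "hypo" | "hyper"
    score: float
    rank: int = 0

    def __post_init__(self):
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"direction must be 'hypo' or 'hyper', got {self.direction!r}")


def block_mean_methylation(beta: BetaVector, block: Block) -> float:
    """Pooled methylated fraction over the block; NaN when uncovered."""
    meth, total = beta.slice_cpgs(block.start_cpg, block.end_cpg)
    t = int(total.sum())
    if t == 0:
        return float("nan")
    return int(meth.sum()) / t


def block_means_matrix(
    betas: Mapping[str, BetaVector], blocks: Sequence[Block]
) -> pd.DataFrame:
    """Block x sample matrix of mean methylation (rows align with ``blocks``)."""
    data = {}
    for sample, beta in betas.items():
        cm = np.concatenate([[0], np.cumsum(beta.n_meth)])
        ct = np.concatenate([[0], np.cumsum(beta.n_total)])
        m = np.array([cm[b.end_cpg - 1] - cm[b.start_cpg - 1] for b in blocks], dtype=float)
        t = np.array([ct[b.end_cpg - 1] - ct[b.start_cpg - 1] for b in blocks], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            data[sample] = np.where(t > 0, m / np.maximum(t, 1), np.nan)
    return pd.DataFrame(data, index=pd.RangeIndex(len(blocks), name="block"))


def find_markers(
    group_labels: Mapping[str, str],
    block_means: pd.DataFrame,
    blocks: Sequence[Block],
    params: MarkerParams = MarkerParams(),
) -> list[MarkerBlock]:
    """One-vs-all DMB discovery over a block x sample mean-methylation matrix.

    ``group_labels`` maps sample names (columns of ``block_means``) to group
    labels; rows of ``block_means`` align with ``blocks``. Returns markers for
    every group, each ranked 1..top_k within its group.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) < 2:
        raise ValueError("marker discovery requires at least two groups")
    if len(block_means) != len(blocks):
        raise ValueError("block_means rows must align with blocks")
    values = block_means.to_numpy(dtype=float)
    samples = list(block_means.columns)
    markers: list[MarkerBlock] = []
    for group in groups:
        in_group = np.array([group_labels[s] == group for s in samples])
        T = values[:, in_group]
        B = values[:, ~in_group]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
            q_t_hi = np.nanquantile(T, 1 - params.tg_quant, axis=1)
            q_t_lo = np.nanquantile(T, params.tg_quant, axis=1)
            q_b_lo = np.nanquantile(B, params.bg_quant, axis=1)
            q_b_hi = np.nanquantile(B, 1 - params.bg_quant, axis=1)
        s_hypo = q_b_lo - q_t_hi
        s_hyper = q_t_lo - q_b_hi
        cand: list[tuple[float, int, int, int, str]] = []
        for i in range(len(blocks)):
            sm, sp = s_hypo[i], s_hyper[i]
            if isnan(sm) or isnan(sp):
                continue  # group or background has no defined mean for this block
            score, direction = (sm, "hypo") if sm >= sp else (sp, "hyper")
            if score >= params.margin:
                cand.append((score, blocks[i].length_bp, i, i, direction))
        cand.sort(key=lambda c: (-c[0], c[1], c[2]))
        for rank, (score, _, i, _, direction) in enumerate(cand[: params.top_k], 1):
            markers.append(MarkerBlock(blocks[i], group, direction, float(score), rank))
    return markers


def methylation_score(
    records: Iterable[FragmentRecord], block: Block, direction: str
) -> float:
    """Fraction of overlapping fragments that are uniformly T (hypo) or C
    (hyper) over their observed in-block CpGs; NaN when no fragment has an
    observed in-block CpG."""
    if direction not in ("hypo", "hyper"):
        raise ValueError("direction must be 'hypo' or 'hyper'")
    want = "T" if direction == "hypo" else "C"
    other = "C" if direction == "hypo" else "T"
    num = den = 0
    for rec in records:
        if rec.chrom != block.chrom or rec.start_cpg >= block.end_cpg or rec.end_cpg <= block.start_cpg:
            continue
        lo = max(rec.start_cpg, block.start_cpg) - rec.start_cpg
        hi = min(rec.end_cpg, block.end_cpg) - rec.start_cpg
        sub = rec.pattern[lo:hi]
        n_want = sub.count(want)
        n_other = sub.count(other)
        if n_want + n_other == 0:
            continue
        den += rec.count
        if n_other == 0:
            num += rec.count
    return num / den if den else float("nan")


def methylation_score_matrix(
    records_by_sample: Mapping[str, Sequence[FragmentRecord]],
    markers: Sequence[MarkerBlock],
) -> pd.DataFrame:
    """Marker x sample methylation-score matrix (heatmap export)."""
    rows = {}
    for j, mk in enumerate(markers):
        rows[j] = {
            s: methylation_score(recs, mk.block, mk.direction)
            for s, recs in records_by_sample.items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "marker"
    return df


def cluster_reference_samples(
    block_means: pd.DataFrame,
    top_frac: float = 0.1,
    n_clusters: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average-linkage clustering of samples over the most variable blocks.

    Blocks are ranked by across-sample variance of mean methylation and the
    top ``ceil(top_frac * n_blocks)`` retained (all of them, with a warning,
    when fewer than ``1/top_frac`` exist). Returns the scipy linkage matrix
    and, when ``n_clusters`` is given, flat labels at that cut.
    """
    if block_means.shape[1] < 3:
        raise ValueError("clustering requires at least 3 samples")
    n_blocks = len(block_means)
    n_keep = ceil(top_frac * n_blocks)
    if n_blocks < 1 / top_frac:
        warnings.warn("fewer blocks than 1/top_frac; using all blocks", stacklevel=2)
        n_keep = n_blocks
    var = block_means.var(axis=1, ddof=1).fillna(-np.inf)
    top = var.sort_values(ascending=False, kind="stable").index[:n_keep]
    data = block_means.loc[top].T  # samples x blocks
    data = data.fillna(data.mean(axis=0)).fillna(0.0)
    Z = linkage(data.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(Z, n_clusters, criterion="maxclust") if n_clusters else None
    return Z, labels


# ---------------------------------------------------------------------------
# Marker table serialization
# ---------------------------------------------------------------------------

_MARKER_COLUMNS = ["chrom", "start_bp", "end_bp", "start_cpg", "end_cpg", "group", "direction", "score", "rank"]


def write_markers(markers: Sequence[MarkerBlock], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        fh.write("\t".join(_MARKER_COLUMNS) + "\n")
        for mk in markers:
            b = mk.block
            fh.write(
                f"{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.start_cpg}\t{b.end_cpg}\t"
                f"{mk.group}\t{mk.direction}\t{mk.score:.10g}\t{mk.rank}\n"
            )


def read_markers(path: str | Path) -> list[MarkerBlock]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return [
        MarkerBlock(
            Block(r.chrom, int(r.start_bp), int(r.end_bp), int(r.start_cpg), int(r.end_cpg)),
            str(r.group), str(r.direction), float(r.score), int(r.rank),
        )
        for r in df.itertuples()
    ]
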