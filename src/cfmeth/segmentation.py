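"""Segmentation of multi-sample reference methylomes into homogeneous blocks.

A block is a maximal run of consecutive covered CpGs over which every
reference sample's per-CpG methylation fraction stays within a fixed range
(the homogeneity tolerance) and whose genomic span stays under a length cap.
The greedy left-to-right rule below is deterministic: extend the current block
one CpG at a time while the constraints hold, otherwise start a new block.
Eligibility filtering (CpG count, length, minimum per-sample observations,
capture-panel restriction) is a separate pass so that discovery and filtering
can be tested independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats import Block, BetaVector, CpGIndexMap


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the greedy segmentation.

    max_block_bp
        Cap on the genomic span of a block (default 2000 bp).
    homogeneity_tol
        Maximum allowed within-block range (max - min) of per-CpG methylation
        fractions, enforced per sample (default 0.25).
    min_sites_per_estimate
        Minimum per-CpG total count for that CpG's fraction to constrain
        homogeneity; shallower CpGs still join blocks (default 5).
    """

    max_block_bp: int = 2000
    homogeneity_tol: float = 0.25
    min_sites_per_estimate: int = 5

    def __post_init__(self):
        if not 0 < self.homogeneity_tol < 1:
            raise ValueError("homogeneity_tol must lie in (0, 1)")
        if self.max_block_bp <= 0:
            raise ValueError("max_block_bp must be positive")


@dataclass(frozen=True)
class BlockFilterParams:
    """Block eligibility: >= min_cpgs CpG sites, span < max_len_bp, at least
    min_observations pooled CpG counts in every sample, and overlap with the
    capture panel (``panel=None`` disables the panel restriction)."""

    min_cpgs: int = 3
    max_len_bp: int = 2000
    min_observations: int = 10
    panel: Sequence[Block] | None = None

    def __post_init__(self):
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")


def segment_methylomes(
    betas: Sequence[BetaVector],
    cpg_map: CpGIndexMap,
    params: SegmentationParams = SegmentationParams(),
) -> list[Block]:
    """Partition the covered CpG space into homogeneously methylated blocks.

    Covered means nonzero total count in at least one sample; maximal runs of
    covered CpGs are segmented independently, so blocks never bridge coverage
    gaps. Output blocks are non-overlapping and exhaust the covered CpGs.
    """
    if len(betas) == 0:
        raise ValueError("segmentation requires at least one reference sample")
    meth = np.stack([b.n_meth for b in betas])
    total = np.stack([b.n_total for b in betas])
    if meth.shape[1] != cpg_map.n_cpgs:
        raise ValueError("beta vectors do not match the CpG map")

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total >= params.min_sites_per_estimate, meth / np.maximum(total, 1), np.nan)
    covered = (total > 0).any(axis=0)

    blocks: list[Block] = []
    for chrom in cpg_map.chrom_names:
        lo, hi = cpg_map.chrom_range(chrom)
        pos = cpg_map.cpg_positions[chrom]
        idx = np.flatnonzero(covered[lo - 1 : hi - 1]) + (lo - 1)  # 0-based global
        if idx.size == 0:
            continue
        # split covered CpGs into maximal consecutive runs
        run_breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, run_breaks):
            blocks.extend(_segment_run(run, frac, pos, lo, chrom, params))
    return blocks


def _segment_run(
    run: np.ndarray,
    frac: np.ndarray,
    pos: np.ndarray,
    chrom_offset: int,
    chrom: str,
    params: SegmentationParams,
) -> list[Block]:
    n_samples = frac.shape[0]
    out: list[Block] = []
    i0 = 0
    cur_min = np.full(n_samples, np.inf)
    cur_max = np.full(n_samples, -np.inf)

    def close(i_last: int) -> None:
        g0, g1 = int(run[i0]), int(run[i_last])
        p0 = int(pos[g0 - (chrom_offset - 1)])
        p1 = int(pos[g1 - (chrom_offset - 1)])
        out.append(Block(chrom, p0 - 1, p1 + 1, g0 + 1, g1 + 2))

    for i in range(run.size):
        g = int(run[i])
        f = frac[:, g]
        new_min = np.fmin(cur_min, f)
        new_max = np.fmax(cur_max, f)
        if i > i0:
            p_start = pos[int(run[i0]) - (chrom_offset - 1)]
            span = (pos[g - (chrom_offset - 1)] + 1) - (p_start - 1)
            homogeneous = bool(np.all((new_max - new_min) <= params.homogeneity_tol + 1e-12))
            if span > params.max_block_bp or not homogeneous:
                close(i - 1)
                i0 = i
                new_min = np.where(np.isnan(f), np.inf, f)
                new_max = np.where(np.isnan(f), -np.inf, f)
        else:
            new_min = np.where(np.isnan(f), np.inf, f)
            new_max = np.where(np.isnan(f), -np.inf, f)
        cur_min, cur_max = new_min, new_max
    close(run.size - 1)
    return out


def filter_blocks(
    blocks: Sequence[Block],
    betas: Sequence[BetaVector],
    params: BlockFilterParams = BlockFilterParams(),
) -> list[Block]:
    """Retain blocks meeting the eligibility rules (see BlockFilterParams).

    The observation floor is enforced per sample: the pooled CpG count total
    inside the block must reach ``min_observations`` in every sample.
    """
    kept: list[Block] = []
    panel = list(params.panel) if params.panel is not None else None
    for blk in blocks:
        if blk.n_cpgs < params.min_cpgs:
            continue
        if blk.length_bp >= params.max_len_bp:
            continue
        ok = True
        for beta in betas:
            _, tot = beta.slice_cpgs(blk.start_cpg, blk.end_cpg)
            if int(tot.sum()) < params.min_observations:
                ok = False
                break
        if not ok:
            continue
        if panel is not None and not any(
            p.chrom == blk.chrom and blk.overlaps_cpgs(p.start_cpg, p.end_cpg) for p in panel
        ):
            continue
        kept.append(blk)
    return kept
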