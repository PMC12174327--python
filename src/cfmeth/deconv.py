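"""NNLS deconvolution of cfDNA samples against a U/X/M atlas, and Geq/mL.

The sample's per-marker U/M proportion vector b is fitted against the atlas
design matrix A by non-negative least squares, min ||Ax - b|| s.t. x >= 0, and
the solution renormalized to sum to one — cell-type fractions of the cfDNA
mixture. Markers without sample coverage, or with a missing atlas value in
any cell type, are dropped from the fit (row-wise complete case). Fractions
convert to absolute genome equivalents per mL of serum by

    Geq/mL = fraction * [cfDNA ng/mL] / (3.3e-12 g * 1e9 ng/g)

i.e. dividing by the 3.3 pg mass of one haploid human genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize

from .formats import FragmentRecord
from .uxm import AtlasMatrix, ClassifierParams, tally_uxm


@dataclass(frozen=True)
class GeqParams:
    """Mass of one haploid human genome, in grams (3.3 pg)."""

    genome_mass_g: float = 3.3e-12

    def __post_init__(self):
        if not self.genome_mass_g > 0:
            raise ValueError("genome_mass_g must be positive")


@dataclass
class DeconvolutionResult:
    """Normalized cell-type fractions with fit diagnostics."""

    cell_types: list[str]
    fractions: np.ndarray
    raw_coefficients: np.ndarray
    residual_norm: float
    used_markers: np.ndarray  # boolean mask over atlas markers

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")

    @property
    def n_used_markers(self) -> int:
        return int(self.used_markers.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.cell_types, self.fractions.tolist()))


def sample_marker_vector(
    records: Sequence[FragmentRecord],
    markers: Sequence,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker U (hypo) / M (hyper) proportions of a sample's fragments.

    Returns ``(b, mask)``: ``b[i]`` is the proportion over included fragments
    in marker i (NaN where none), ``mask[i]`` is True where the marker has at
    least one included fragment. Raises when no marker is covered.
    """
    if len(markers) == 0:
        raise ValueError("markers must be non-empty")
    blocks = [mk.block for mk in markers]
    tallies = tally_uxm(records, blocks, params)
    n = tallies.sum(axis=1)
    mask = n > 0
    if not mask.any():
        raise ValueError("sample has no informative coverage on any marker")
    b = np.full(len(markers), np.nan)
    hypo = np.array([mk.direction == "hypo" for mk in markers])
    with np.errstate(invalid="ignore", divide="ignore"):
        u_prop = tallies[:, 0] / n
        m_prop = tallies[:, 2] / n
    b[mask] = np.where(hypo[mask], u_prop[mask], m_prop[mask])
    return b, mask


def nnls_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x >= 0 minimizing ||Ax - b||_2 (active-set NNLS)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.size:
        raise ValueError("A must be 2-D with rows aligned to b")
    if not (np.isfinite(A).all() and np.isfinite(b).all()):
        raise ValueError("A and b must be finite")
    if A.shape[1] == 0 or np.any(~A.any(axis=0)):
        raise ValueError("A has an all-zero column; the fit is unidentifiable")
    x, _ = scipy.optimize.nnls(A, b)
    return x


def deconvolve(
    atlas: AtlasMatrix,
    records: Sequence[FragmentRecord],
    params: ClassifierParams = ClassifierParams(),
) -> DeconvolutionResult:
    """Estimate a sample's cell-type fractions against the atlas."""
    if len(atlas.markers) == 0:
        raise ValueError("empty atlas")
    b, covered = sample_marker_vector(records, atlas.markers, params)
    complete = ~np.isnan(atlas.values).any(axis=1)
    use = covered & complete
    if not use.any():
        raise ValueError("no marker is both sample-covered and atlas-complete")
    A = atlas.values[use]
    x = nnls_solve(A, b[use])
    total = x.sum()
    if total == 0:
        raise ValueError("NNLS solution is identically zero; cannot normalize")
    residual = float(np.linalg.norm(A @ x - b[use]))
    return DeconvolutionResult(
        cell_types=list(atlas.cell_types),
        fractions=x / total,
        raw_coefficients=x,
        residual_norm=residual,
        used_markers=use,
    )


def to_genome_equivalents(
    fraction: float,
    cfdna_conc_ng_per_ml: float,
    params: GeqParams = GeqParams(),
) -> float:
    """Convert a cell-type fraction and cfDNA concentration to Geq/mL."""
    if not (np.isfinite(fraction) and np.isfinite(cfdna_conc_ng_per_ml)):
        raise ValueError("inputs must be finite")
    if fraction < 0 or cfdna_conc_ng_per_ml < 0:
        raise ValueError("inputs must be non-negative")
    genome_mass_ng = params.genome_mass_g * 1e9
    return fraction * cfdna_conc_ng_per_ml / genome_mass_ng
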