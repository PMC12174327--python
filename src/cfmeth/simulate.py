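"""Synthetic data with known ground truth for the whole pipeline.

Three generators:

* reference methylomes — a synthetic genome of CpG blocks, each block carrying
  a per-cell-type latent methylation propensity theta. Marker blocks planted
  for one target type are hypomethylated there (theta = marker_low) and
  methylated everywhere else (theta = marker_high), or the reverse for
  hypermethylated markers; non-marker blocks share one propensity across all
  types. Fragment methylation is bimodal at the fragment level: a fragment is
  drawn fully methylated with probability theta, else fully unmethylated, and
  each CpG symbol is then flipped independently with the bisulfite error rate
  epsilon. This fragment-level concordance, not independent per-CpG noise, is
  what makes the U/X/M classes informative.
* cfDNA mixtures — fragments whose source cell type is multinomial with the
  requested true proportions, generated from that type's block propensities;
  plus a spike-in series of two-component mixtures at a ladder of minor-
  component levels.
* longitudinal cohorts — per patient x timepoint cell-type fraction profiles
  following injury / no-injury trajectory means (both arms spike at POD0; the
  no-injury arm decays toward baseline by POD7 while the injury arm stays
  elevated through POD30), with lognormal biological noise, cfDNA
  concentrations, and AST/ALT liver enzymes linked to hepatocyte Geq/mL by a
  noisy power law.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .deconv import GeqParams, to_genome_equivalents
from .formats import Block, CpGIndexMap, FragmentRecord
from .markers import MarkerBlock
from .uxm import ClassifierParams

DEFAULT_CELL_TYPES = (
    "hepatocyte",
    "biliary",
    "hepatic_stellate",
    "endothelial",
    "lymphoid",
    "myeloid",
    "neuron",
    "cardiomyocyte",
    "kidney_epithelial",
    "gastric_epithelial",
)


def _cell_type_names(n: int, names: Sequence[str] | None) -> list[str]:
    if names is not None:
        if len(names) != n:
            raise ValueError("cell_type_names length must equal n_cell_types")
        return list(names)
    base = list(DEFAULT_CELL_TYPES[:n])
    base += [f"cell_type_{i:02d}" for i in range(len(base) + 1, n + 1)]
    return base


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSimConfig:
    """Synthetic reference-methylome conditions.

    The defaults mirror the reference design the analysis assumes: 20
    cell-type groups, 100 planted markers per group, marker propensities
    0.05/0.95, 3-10 CpGs observed per fragment, and a 3% per-CpG symbol flip
    emulating bisulfite conversion/sequencing error.
    """

    n_cell_types: int = 20
    samples_per_type: int = 3
    n_blocks: int = 3000
    planted_markers_per_type: int = 100
    marker_low: float = 0.05
    marker_high: float = 0.95
    hyper_fraction: float = 0.2
    background_beta_a: float = 0.3
    background_beta_b: float = 0.3
    cpgs_per_block: int = 15
    cpg_spacing_bp: int = 60
    block_gap_bp: int = 500
    fragments_per_block: int = 100
    cpgs_per_fragment: tuple[int, int] = (3, 10)
    bisulfite_error: float = 0.03
    seed: int = 0
    cell_type_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0 <= self.bisulfite_error < 0.5:
            raise ValueError("bisulfite_error must lie in [0, 0.5)")
        for p in (self.marker_low, self.marker_high):
            if not 0 <= p <= 1:
                raise ValueError("propensities must lie in [0, 1]")
        if self.n_cell_types * self.planted_markers_per_type > self.n_blocks:
            raise ValueError("planted markers exceed the number of blocks")
        kmin, kmax = self.cpgs_per_fragment
        if not 1 <= kmin <= kmax <= self.cpgs_per_block:
            raise ValueError("cpgs_per_fragment range must fit inside a block")


@dataclass(frozen=True)
class MixtureSimConfig:
    """A cfDNA mixture with known cell-type proportions."""

    true_proportions: tuple[float, ...]
    total_fragments: int
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.true_proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("true_proportions must be non-negative and sum to 1")
        if self.total_fragments < 0:
            raise ValueError("total_fragments must be >= 0")


@dataclass(frozen=True)
class CohortSimConfig:
    """Longitudinal cohort conditions emulating the peri-transplant design.

    Trajectory means are cell-type fractions per timepoint; both arms spike
    at POD0 (surgical damage), the no-injury arm recovers by POD7, and the
    injury arm stays elevated through POD30. AST/ALT follow
    ``coef * hepatocyte_geq**gamma * exp(noise)``.
    """

    n_patients: int = 20
    injury_fraction: float = 0.55
    timepoints: tuple[str, ...] = ("PRE", "POD0", "POD7", "POD30")
    hepatocyte_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "no_injury": {"PRE": 0.02, "POD0": 0.25, "POD7": 0.04, "POD30": 0.03},
            "injury": {"PRE": 0.02, "POD0": 0.25, "POD7": 0.15, "POD30": 0.12},
        }
    )
    biliary_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "no_injury": {"PRE": 0.005, "POD0": 0.05, "POD7": 0.01, "POD30": 0.008},
            "injury": {"PRE": 0.005, "POD0": 0.05, "POD7": 0.04, "POD30": 0.035},
        }
    )
    background_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "myeloid": 0.55,
            "lymphoid": 0.25,
            "endothelial": 0.08,
            "hepatic_stellate": 0.05,
            "neuron": 0.02,
            "megakaryocyte": 0.05,
        }
    )
    conc_means_ng_per_ml: Mapping[str, float] = field(
        default_factory=lambda: {"PRE": 25.0, "POD0": 125.0, "POD7": 40.0, "POD30": 30.0}
    )
    noise_sigma: float = 0.35
    conc_sigma: float = 0.4
    ast_coef: float = 0.1
    ast_gamma: float = 0.9
    enzyme_sigma: float = 0.3
    injury_etiologies: tuple[str, ...] = ("hepatocellular", "biliary", "mixed")
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.injury_fraction <= 1:
            raise ValueError("injury_fraction must lie in [0, 1]")
        if self.noise_sigma < 0 or self.conc_sigma < 0 or self.enzyme_sigma < 0:
            raise ValueError("noise scales must be non-negative")


# ---------------------------------------------------------------------------
# Reference methylomes
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSimResult:
    """Synthetic reference set: fragments per (type, sample), planted truth."""

    config: ReferenceSimConfig
    cpg_map: CpGIndexMap
    blocks: list[Block]
    truth_markers: list[MarkerBlock]
    theta: np.ndarray  # (n_blocks, n_cell_types) latent methylation propensity
    cell_types: list[str]
    fragments: dict[str, list[list[FragmentRecord]]]  # type -> per-sample lists

    def pooled_fragments(self, cell_type: str) -> list[FragmentRecord]:
        out: list[FragmentRecord] = []
        for sample in self.fragments[cell_type]:
            out.extend(sample)
        return out


def _build_layout(config: ReferenceSimConfig) -> tuple[CpGIndexMap, list[Block]]:
    """One synthetic chromosome of equally sized, regularly spaced CpG blocks."""
    npb, spacing, gap = config.cpgs_per_block, config.cpg_spacing_bp, config.block_gap_bp
    within = np.arange(npb) * spacing
    starts = 1000 + np.arange(config.n_blocks) * ((npb - 1) * spacing + gap)
    positions = (starts[:, None] + within[None, :]).ravel()
    cpg_map = CpGIndexMap.from_positions({"chr1": positions})
    blocks = [
        Block(
            "chr1",
            int(positions[i * npb]) - 1,
            int(positions[i * npb + npb - 1]) + 1,
            i * npb + 1,
            (i + 1) * npb + 1,
        )
        for i in range(config.n_blocks)
    ]
    return cpg_map, blocks


def _plant_markers(
    config: ReferenceSimConfig, blocks: list[Block], cell_types: list[str], rng: np.random.Generator
) -> tuple[np.ndarray, list[MarkerBlock]]:
    n_types = config.n_cell_types
    theta_bg = rng.beta(config.background_beta_a, config.background_beta_b, size=config.n_blocks)
    theta = np.tile(theta_bg[:, None], (1, n_types))
    n_markers = n_types * config.planted_markers_per_type
    marker_blocks = rng.choice(config.n_blocks, size=n_markers, replace=False)
    truth: list[MarkerBlock] = []
    separation = config.marker_high - config.marker_low
    for t in range(n_types):
        chosen = marker_blocks[t * config.planted_markers_per_type : (t + 1) * config.planted_markers_per_type]
        for bi in chosen:
            hyper = rng.random() < config.hyper_fraction
            if hyper:
                theta[bi, :] = config.marker_low
                theta[bi, t] = config.marker_high
            else:
                theta[bi, :] = config.marker_high
                theta[bi, t] = config.marker_low
            truth.append(
                MarkerBlock(blocks[bi], cell_types[t], "hyper" if hyper else "hypo", abs(separation))
            )
    truth.sort(key=lambda mk: (mk.group, mk.block.start_cpg))
    return theta, truth


def _emit_fragments(
    block_ids: np.ndarray,
    theta_per_fragment: np.ndarray,
    blocks: Sequence[Block],
    config: ReferenceSimConfig,
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    """Vectorized fragment generation given each fragment's block and theta.

    Returns records sorted by start CpG (single synthetic chromosome).
    """
    n = block_ids.size
    if n == 0:
        return []
    kmin, kmax = config.cpgs_per_fragment
    ks = rng.integers(kmin, kmax + 1, size=n)
    npb = config.cpgs_per_block
    offsets = rng.integers(0, npb - ks + 1)
    block_start = np.array([b.start_cpg for b in blocks], dtype=np.int64)
    starts = block_start[block_ids] + offsets
    latent_meth = rng.random(n) < theta_per_fragment
    flips = rng.random((n, kmax)) < config.bisulfite_error
    meth = latent_meth[:, None] ^ flips  # per-CpG observed methylation
    codes = np.where(meth, np.uint8(ord("C")), np.uint8(ord("T")))
    patterns: np.ndarray = np.empty(n, dtype=object)
    for k in range(kmin, kmax + 1):
        rows = np.flatnonzero(ks == k)
        if rows.size == 0:
            continue
        chunk = np.ascontiguousarray(codes[rows, :k]).view(f"S{k}").ravel()
        patterns[rows] = chunk
    order = np.argsort(starts, kind="stable")
    return [
        FragmentRecord("chr1", int(starts[i]), patterns[i].decode("ascii"), 1)
        for i in order
    ]


def simulate_reference_set(config: ReferenceSimConfig = ReferenceSimConfig()) -> ReferenceSimResult:
    """Generate per-type reference WGBS fragment sets with planted markers."""
    rng = np.random.default_rng(config.seed)
    cell_types = _cell_type_names(config.n_cell_types, config.cell_type_names)
    cpg_map, blocks = _build_layout(config)
    theta, truth = _plant_markers(config, blocks, cell_types, rng)
    fragments: dict[str, list[list[FragmentRecord]]] = {}
    f = config.fragments_per_block
    all_blocks = np.repeat(np.arange(config.n_blocks), f)
    for t, ct in enumerate(cell_types):
        per_sample = []
        for _ in range(config.samples_per_type):
            theta_frag = theta[all_blocks, t]
            per_sample.append(_emit_fragments(all_blocks, theta_frag, blocks, config, rng))
        fragments[ct] = per_sample
    return ReferenceSimResult(config, cpg_map, blocks, truth, theta, cell_types, fragments)


# ---------------------------------------------------------------------------
# Mixtures and spike-ins
# ---------------------------------------------------------------------------


def simulate_mixture(reference: ReferenceSimResult, config: MixtureSimConfig) -> list[FragmentRecord]:
    """Draw a cfDNA mixture from the reference truth propensities."""
    n_types = len(reference.cell_types)
    props = np.asarray(config.true_proportions, dtype=float)
    if props.size != n_types:
        raise ValueError("true_proportions length must match the reference cell types")
    rng = np.random.default_rng(config.seed)
    n = config.total_fragments
    if n == 0:
        return []
    type_ids = rng.choice(n_types, size=n, p=props)
    block_ids = rng.integers(0, len(reference.blocks), size=n)
    theta_frag = reference.theta[block_ids, type_ids]
    return _emit_fragments(block_ids, theta_frag, reference.blocks, reference.config, rng)


@dataclass
class SpikeInMixture:
    """One labelled spike-in mixture: truth level, replicate id, fragments."""

    level: float
    replicate: int
    seed: int
    records: list[FragmentRecord]


def spike_in_series(
    reference: ReferenceSimResult,
    background_type: str,
    spike_type: str,
    levels: Sequence[float] = (0.0, 0.001, 0.01, 0.05),
    replicates: int = 3,
    depth_per_block: int = 200,
    seed: int = 0,
) -> list[SpikeInMixture]:
    """Two-component mixtures with the spike type at each ladder level."""
    for lv in levels:
        if not 0 <= lv <= 1:
            raise ValueError("spike levels must lie in [0, 1]")
    bg = reference.cell_types.index(background_type)
    sp = reference.cell_types.index(spike_type)
    total = depth_per_block * len(reference.blocks)
    out: list[SpikeInMixture] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(len(levels) * replicates) % (2**31)
    i = 0
    for level in levels:
        props = np.zeros(len(reference.cell_types))
        props[bg] = 1.0 - level
        props[sp] = level
        for rep in range(replicates):
            child = int(child_seeds[i])
            i += 1
            cfg = MixtureSimConfig(tuple(props), total, seed=child)
            out.append(SpikeInMixture(level, rep, child, simulate_mixture(reference, cfg)))
    return out


# ---------------------------------------------------------------------------
# Analytic U/X/M probabilities (oracle for convergence checks)
# ---------------------------------------------------------------------------


def uxm_probabilities(
    theta: float, epsilon: float, k: int, params: ClassifierParams = ClassifierParams()
) -> tuple[float, float, float]:
    """Closed-form P(U), P(X), P(M) for a fragment with k observed CpGs.

    The fragment is latently fully methylated with probability theta, and
    each observed symbol flips with probability epsilon; the class thresholds
    are the classifier's exact rationals.
    """
    if k < params.rlen:
        raise ValueError("fragment below rlen is excluded, not classified")
    m_u = max((m for m in range(k + 1) if Fraction(m, k) <= params.u_threshold), default=-1)
    m_m = min((m for m in range(k + 1) if Fraction(m, k) >= params.m_threshold), default=k + 1)
    # observed methylated count ~ Binom(k, 1-eps) when latently methylated
    p_u = theta * binom.cdf(m_u, k, 1 - epsilon) + (1 - theta) * binom.cdf(m_u, k, epsilon)
    p_m = theta * binom.sf(m_m - 1, k, 1 - epsilon) + (1 - theta) * binom.sf(m_m - 1, k, epsilon)
    return float(p_u), float(1 - p_u - p_m), float(p_m)


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortSimConfig = CohortSimConfig()) -> pd.DataFrame:
    """Long-format cohort table with per-row truth labels.

    Columns: patient_id, timepoint, cell_type, fraction, conc_ng_per_ml,
    geq_per_ml, outcome, AST, ALT. Fractions sum to 1 over cell types within
    each (patient, timepoint); outcome is 'no_injury' or an injury etiology.
    """
    rng = np.random.default_rng(config.seed)
    n_injury = int(round(config.n_patients * config.injury_fraction))
    geq = GeqParams()
    bg_types = list(config.background_weights)
    bg_w = np.asarray([config.background_weights[c] for c in bg_types], dtype=float)
    bg_w = bg_w / bg_w.sum()
    rows = []
    for p in range(config.n_patients):
        injured = p < n_injury
        arm = "injury" if injured else "no_injury"
        outcome = (
            config.injury_etiologies[p % len(config.injury_etiologies)] if injured else "no_injury"
        )
        pid = f"P{p + 1:02d}"
        for tp in config.timepoints:
            hep = config.hepatocyte_means[arm][tp] * _lognormal(rng, config.noise_sigma)
            bil = config.biliary_means[arm][tp] * _lognormal(rng, config.noise_sigma)
            hep, bil = min(hep, 0.85), min(bil, 0.85)
            if hep + bil > 0.9:  # keep room for the hematopoietic background
                scale = 0.9 / (hep + bil)
                hep, bil = hep * scale, bil * scale
            rest = 1.0 - hep - bil
            bg_noise = bg_w * _lognormal_vec(rng, config.noise_sigma, bg_w.size)
            bg_frac = rest * bg_noise / bg_noise.sum()
            conc = config.conc_means_ng_per_ml[tp] * _lognormal(rng, config.conc_sigma)
            fractions = {"hepatocyte": hep, "biliary": bil}
            fractions.update(dict(zip(bg_types, bg_frac)))
            hep_geq = to_genome_equivalents(hep, conc, geq)
            ast = config.ast_coef * hep_geq**config.ast_gamma * _lognormal(rng, config.enzyme_sigma)
            alt = 0.8 * config.ast_coef * hep_geq**config.ast_gamma * _lognormal(rng, config.enzyme_sigma)
            for ct, frac in fractions.items():
                rows.append(
                    {
                        "patient_id": pid,
                        "timepoint": tp,
                        "cell_type": ct,
                        "fraction": frac,
                        "conc_ng_per_ml": conc,
                        "geq_per_ml": to_genome_equivalents(frac, conc, geq),
                        "outcome": outcome,
                        "AST": ast,
                        "ALT": alt,
                    }
                )
    return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def _lognormal_vec(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)


def scaled_reference_config(**overrides) -> ReferenceSimConfig:
    """A desk-scale reference configuration for quick end-to-end runs."""
    base = ReferenceSimConfig(
        n_cell_types=4,
        samples_per_type=2,
        n_blocks=160,
        planted_markers_per_type=20,
        fragments_per_block=60,
    )
    return replace(base, **overrides)
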