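"""End-to-end orchestration: simulate -> segment -> filter -> markers ->
atlas -> deconvolve -> Geq -> cohort statistics.

``run_pipeline`` executes the stages into a run directory with a
machine-readable manifest (parameter hashes, seed, package version) and a
log. Stages are re-entrant: a stage whose outputs exist under an unchanged
parameter hash is skipped, and a changed hash refuses to overwrite unless
``force=True``. One global seed fans out to per-stage seeds by stable
derivation, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconv import GeqParams, deconvolve, to_genome_equivalents
from .formats import fragments_to_beta, write_blocks, write_cpg_map, write_pat
from .markers import MarkerParams, block_means_matrix, find_markers, write_markers
from .segmentation import BlockFilterParams, SegmentationParams, filter_blocks, segment_methylomes
from .simulate import (
    CohortSimConfig,
    MixtureSimConfig,
    ReferenceSimConfig,
    simulate_cohort,
    simulate_mixture,
    simulate_reference_set,
)
from .stats import bh_adjust, enzyme_correlation, injury_contrast, pre_post_contrast
from .uxm import ClassifierParams, build_atlas, write_atlas

logger = logging.getLogger("cfmeth.pipeline")

STAGES = ("reference", "segment", "markers", "atlas", "deconv", "cohort")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the global seed."""

    reference: ReferenceSimConfig = ReferenceSimConfig(
        n_cell_types=4, samples_per_type=2, n_blocks=160, planted_markers_per_type=20,
        fragments_per_block=60,
    )
    segmentation: SegmentationParams = SegmentationParams()
    block_filter: BlockFilterParams = BlockFilterParams()
    marker: MarkerParams = MarkerParams(top_k=20)
    classifier: ClassifierParams = ClassifierParams()
    geq: GeqParams = GeqParams()
    cohort: CohortSimConfig = CohortSimConfig()
    mixtures: tuple[tuple[float, ...], ...] = ((0.6, 0.2, 0.1, 0.1), (0.0, 0.0, 0.5, 0.5))
    mixture_depth_per_block: int = 120
    mixture_conc_ng_per_ml: float = 50.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        sub = {
            "reference": ReferenceSimConfig,
            "segmentation": SegmentationParams,
            "block_filter": BlockFilterParams,
            "marker": MarkerParams,
            "classifier": ClassifierParams,
            "geq": GeqParams,
            "cohort": CohortSimConfig,
        }
        for key, val in raw.items():
            if key in sub:
                if key == "reference" and "cpgs_per_fragment" in val:
                    val["cpgs_per_fragment"] = tuple(val["cpgs_per_fragment"])
                kwargs[key] = sub[key](**val)
            elif key == "mixtures":
                kwargs[key] = tuple(tuple(m) for m in val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def _params_hash(obj: Any) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = json.dumps(default(obj) if dataclasses.is_dataclass(obj) else obj,
                         default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, Any] = {"version": __version__, "stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, stage: str, phash: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        return (
            entry is not None
            and entry["params_hash"] == phash
            and all(Path(p).exists() for p in entry["outputs"])
            and {str(p) for p in outputs} <= set(entry["outputs"])
        )

    def stage_conflicts(self, stage: str, phash: str) -> bool:
        entry = self.data["stages"].get(stage)
        return entry is not None and entry["params_hash"] != phash

    def record(self, stage: str, phash: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {"params_hash": phash, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Run all stages into ``out_dir``; returns the run directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["seed"] = config.seed
    try:
        hashes = {stage: _params_hash({"config": config, "stage": stage}) for stage in STAGES}
        for stage in STAGES:
            if manifest.stage_conflicts(stage, hashes[stage]) and not force:
                raise RuntimeError(
                    f"stage {stage!r}: outputs exist under a different parameter hash; "
                    "pass force=True to overwrite"
                )
        if not force and all(
            manifest.stage_done(stage, hashes[stage], _stage_outputs(stage, out))
            for stage in STAGES
        ):
            logger.info("all stages up to date under the current parameter hash; skipped")
            return out
        state: dict[str, Any] = {}
        for stage in STAGES:
            logger.info("stage %s: running", stage)
            _run_stage(stage, config, out, state)
            manifest.record(stage, hashes[stage], _stage_outputs(stage, out))
            logger.info("stage %s: done", stage)
    except Exception:
        logger.exception("pipeline halted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _stage_outputs(stage: str, out: Path) -> list[Path]:
    table = {
        "reference": [out / "cpg_map.tsv", out / "blocks_truth.tsv"],
        "segment": [out / "blocks.tsv", out / "blocks_filtered.tsv"],
        "markers": [out / "markers.tsv"],
        "atlas": [out / "atlas.tsv", out / "atlas_coverage.tsv"],
        "deconv": [out / "fractions.csv", out / "geq.csv"],
        "cohort": [out / "cohort.csv", out / "cohort_stats.csv"],
    }
    return table[stage]


def _run_stage(stage: str, config: PipelineConfig, out: Path, state: dict[str, Any]) -> None:
    if stage == "reference":
        ref_cfg = dataclasses.replace(config.reference, seed=config.stage_seed("reference"))
        ref = simulate_reference_set(ref_cfg)
        state["ref"] = ref
        write_cpg_map(ref.cpg_map, out / "cpg_map.tsv")
        write_blocks(ref.blocks, out / "blocks_truth.tsv")
        write_markers(ref.truth_markers, out / "markers_truth.tsv")
        refs_dir = out / "refs"
        refs_dir.mkdir(exist_ok=True)
        for ct, samples in ref.fragments.items():
            for i, recs in enumerate(samples):
                write_pat(recs, refs_dir / f"{ct}_{i + 1}.pat.gz")
    elif stage == "segment":
        ref = state["ref"]
        betas = {
            f"{ct}_{i + 1}": fragments_to_beta(recs, ref.cpg_map)
            for ct, samples in ref.fragments.items()
            for i, recs in enumerate(samples)
        }
        state["betas"] = betas
        blocks = segment_methylomes(list(betas.values()), ref.cpg_map, config.segmentation)
        write_blocks(blocks, out / "blocks.tsv")
        filtered = filter_blocks(blocks, list(betas.values()), config.block_filter)
        state["blocks"] = filtered
        write_blocks(filtered, out / "blocks_filtered.tsv")
    elif stage == "markers":
        ref, betas, blocks = state["ref"], state["betas"], state["blocks"]
        means = block_means_matrix(betas, blocks)
        groups = {name: name.rsplit("_", 1)[0] for name in betas}
        markers = find_markers(groups, means, blocks, config.marker)
        state["markers"] = markers
        write_markers(markers, out / "markers.tsv")
    elif stage == "atlas":
        ref, markers = state["ref"], state["markers"]
        pooled = {ct: ref.pooled_fragments(ct) for ct in ref.cell_types}
        atlas = build_atlas(pooled, markers, config.classifier)
        state["atlas"] = atlas
        write_atlas(atlas, out / "atlas.tsv", out / "atlas_coverage.tsv")
    elif stage == "deconv":
        ref, atlas = state["ref"], state["atlas"]
        rows = []
        total = config.mixture_depth_per_block * len(ref.blocks)
        for mi, props in enumerate(config.mixtures):
            cfg = MixtureSimConfig(
                tuple(props), total, seed=(config.stage_seed("deconv") + mi) % 2**31
            )
            records = simulate_mixture(ref, cfg)
            result = deconvolve(atlas, records, config.classifier)
            for ct, frac, true in zip(result.cell_types, result.fractions, props):
                rows.append(
                    {
                        "mixture": f"mix{mi + 1}",
                        "cell_type": ct,
                        "fraction": frac,
                        "true_fraction": true,
                        "geq_per_ml": to_genome_equivalents(
                            float(frac), config.mixture_conc_ng_per_ml, config.geq
                        ),
                        "residual_norm": result.residual_norm,
                        "n_used_markers": result.n_used_markers,
                    }
                )
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "fractions.csv", index=False)
        frame[["mixture", "cell_type", "geq_per_ml"]].to_csv(out / "geq.csv", index=False)
    elif stage == "cohort":
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed("cohort"))
        table = simulate_cohort(cohort_cfg)
        table.to_csv(out / "cohort.csv", index=False)
        stats_rows = []
        for ct in ("hepatocyte", "biliary"):
            res, med_fc = pre_post_contrast(table, ct)
            stats_rows.append(
                {"contrast": "pre_vs_pod0", "cell_type": ct, "statistic": res.statistic,
                 "p_value": res.p_value, "n": res.n, "median_fold_change": med_fc}
            )
            res2 = injury_contrast(table, ct)
            stats_rows.append(
                {"contrast": "injury_vs_no_injury_pod7_30", "cell_type": ct,
                 "statistic": res2.statistic, "p_value": res2.p_value, "n": res2.n,
                 "median_fold_change": np.nan}
            )
        corr = enzyme_correlation(table, "hepatocyte", "AST", "POD0")
        stats_rows.append(
            {"contrast": "spearman_AST_hepatocyte_geq_POD0", "cell_type": "hepatocyte",
             "statistic": corr.statistic, "p_value": corr.p_value, "n": corr.n,
             "median_fold_change": np.nan}
        )
        frame = pd.DataFrame(stats_rows)
        frame["q_value"] = bh_adjust(frame["p_value"].fillna(1.0).to_numpy())
        frame.to_csv(out / "cohort_stats.csv", index=False)
    else:  # pragma: no cover
        raise AssertionError(stage)
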