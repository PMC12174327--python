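#!/usr/bin/env python
"""Cell-type fraction recovery on random multi-type cfDNA mixtures.

Random Dirichlet mixtures over a 10-cell-type synthetic atlas are
deconvolved at 200 fragments per marker block; the mean absolute error of
the recovered fractions summarizes the fidelity of the U/X/M + NNLS pipeline
under realistic marker contrast and 3% per-CpG bisulfite error.
"""

import argparse
from pathlib import Path

from cfmeth.experiments import build_reference_atlas, mixture_recovery_experiment
from cfmeth.simulate import ReferenceSimConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--mixtures", type=int, default=25)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = ReferenceSimConfig(
        n_cell_types=10, samples_per_type=3, n_blocks=1100,
        planted_markers_per_type=100, fragments_per_block=300, seed=args.seed,
    )
    print("building 10-type reference atlas ...")
    ref, atlas = build_reference_atlas(cfg)
    print(f"deconvolving {args.mixtures} random mixtures ...")
    results = mixture_recovery_experiment(
        ref, atlas, n_mixtures=args.mixtures, depth_per_block=200, seed=args.seed + 1
    )
    results.to_csv(args.out / "mixture_recovery.tsv", sep="\t", index=False)

    err = (results["estimate"] - results["true"]).abs()
    by_type = results.assign(abs_err=err).groupby("cell_type")["abs_err"].mean()
    print(f"mean absolute fraction error: {err.mean():.4f} (max {err.max():.4f})")
    print(by_type.round(4).to_string())
    print(f"table -> {args.out}/mixture_recovery.tsv")


if __name__ == "__main__":
    main()
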