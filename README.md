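# cfmeth

Fragment-level cell-free DNA (cfDNA) methylation deconvolution for
tissue-of-origin monitoring — built around the liquid-biopsy design used to
track cellular damage after solid-organ (e.g. liver) transplant from serial
blood samples.

Dying cells shed DNA fragments into the circulation. Because DNA methylation
is highly cell-type-specific and stable across individuals, the CpG
methylation pattern carried by a single sequenced cfDNA fragment identifies
the cell type that released it. `cfmeth` implements the full analysis chain
on top of fragment-level bisulfite data:

1. **Reference atlas construction** — segment multi-sample reference
   methylomes into homogeneously methylated blocks, filter blocks (≥3 CpGs,
   <2 kb, ≥10 observations per sample, capture-panel overlap), and discover
   cell-type-specific differentially methylated blocks (DMBs) one-vs-all
   with quantile slack: a block is a hypomethylated marker for group *G*
   when `Q_{bg}(B, 0.1) − Q_{1−tg}(T, 0.8) ≥ margin` (defaults
   `tg.quant = 0.2`, `bg.quant = 0.1`, `margin = 0.4`), keeping the top 100
   blocks per group.
2. **U/X/M classification** — each fragment overlapping a marker, restricted
   to its observed in-block CpGs (≥ `rlen = 3`), is **U** (mostly
   unmethylated, methylated fraction ≤ 1/3), **M** (≥ 2/3) or **X** (mixed);
   thresholds are compared in exact rational arithmetic. The atlas records
   each marker's U (hypo) or M (hyper) fragment proportion per cell type.
3. **NNLS deconvolution** — a cfDNA sample's per-marker U/M proportion
   vector *b* is fitted against the atlas *A* by non-negative least squares,
   `min ‖Ax − b‖₂ s.t. x ≥ 0`, and normalized to cell-type fractions.
   Fractions convert to absolute genome equivalents per mL:
   `Geq/mL = fraction × [cfDNA ng/mL] / 3.3×10⁻³ ng`, using the 3.3 pg mass
   of a haploid human genome.
4. **Cohort statistics** — paired Wilcoxon signed-rank tests (pre-transplant
   vs post-reperfusion), Mann–Whitney outcome contrasts of combined
   POD7/POD30 signal, Spearman correlation with liver enzymes (AST/ALT),
   fold changes, and Benjamini–Hochberg / Benjamini–Krieger–Yekutieli FDR
   control — with exact small-sample p-values by enumeration.
5. **Synthetic data** — generators for reference methylomes with planted
   markers (bimodal fragment-level methylation + bisulfite error), cfDNA
   mixtures with known proportions, spike-in ladders, and longitudinal
   injury/no-injury cohorts, so every pipeline stage can be validated
   against ground truth.

Real PAT/BETA data from controlled-access repositories is *not* required:
the package reads and writes plain-TSV PAT-like (chrom, CpG index, `C/T/.`
pattern, count), BETA-like, and BED-like block formats.

## Worked example

The numbered drivers under `analysis/` run the studies end to end. The
cohort analysis:

```bash
python analysis/04_cohort_analysis.py --seed 1 --power-seeds 20
```

prints (abridged):

```
                                  contrast  cell_type  statistic      p  n  median_fold_change      q
                    PRE vs POD0 (Wilcoxon) hepatocyte   210.0000 0.0000 20             13.5875 0.0000
injury vs no-injury POD7/30 (Mann-Whitney) hepatocyte    99.0000 0.0002 20                 NaN 0.0002
    Spearman AST ~ hepatocyte Geq/mL @POD0 hepatocyte     0.8541 0.0000 20                 NaN 0.0000

significant (p < 0.05) in 20/20 cohorts (100%)
```

Reading: across 20 simulated patients the hepatocyte cfDNA fraction rises
sharply from pre-transplant to post-reperfusion (Wilcoxon statistic 210 =
every patient increased; median ~13.6-fold), hepatocyte Geq/mL tracks AST
(Spearman ρ ≈ 0.85), and the combined post-operative day 7/30 hepatocyte
signal separates patients with allograft injury from those without
(Mann–Whitney, q < 0.001) — reproducibly so across independent cohort
simulations.

`analysis/02_spike_in_lod.py` measures the deconvolution detection limit
with spike-in ladders, `analysis/03_mixture_recovery.py` the fraction
recovery error on random 10-type mixtures, and
`analysis/05_full_pipeline_demo.py` runs every stage into a single run
directory with a manifest (`cfmeth.pipeline.run_pipeline`).

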