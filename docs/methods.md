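# Methods

## The measurement model

A bisulfite-sequenced cfDNA fragment reports the methylation state of each
CpG it covers: `C` (methylated), `T` (unmethylated), or `.` (unobserved).
Fragments are anchored in a genome-wide CpG coordinate system: every CpG
site receives a global, 1-based index in chromosome order, and all
block/marker arithmetic happens on half-open CpG-index intervals
`[start, end)`, so a block's site count is simply `end − start`. Base-pair
coordinates follow the BED convention (0-based, half-open) both in memory
and on disk, which makes the serialized block format (`chrom, start_bp,
end_bp, start_cpg, end_cpg`) a plain identity round trip.

Within a cell type, neighbouring CpGs are strongly co-methylated, so a
fragment drawn from one cell type tends to be concordantly methylated or
unmethylated across a marker block. That concordance is the signal the
U/X/M classifier exploits; it is lost in per-CpG averages, which is why the
pipeline works at fragment level.

## Segmentation

Reference methylomes are segmented into homogeneously methylated blocks by
a deterministic greedy scan: walk the covered CpGs left to right, extending
the current block while (a) every sample's within-block range of per-CpG
methylation fractions stays within `homogeneity_tol` (default 0.25), and
(b) the genomic span stays ≤ `max_block_bp` (default 2000 bp). CpGs with
fewer than `min_sites_per_estimate` (default 5) observations contribute no
homogeneity constraint but still belong to blocks; runs of entirely
uncovered CpGs break blocks. The output partitions the covered CpG space:
blocks never overlap and jointly exhaust it. On noise-free
piecewise-constant methylomes the recovered boundaries equal the planted
change points whenever adjacent levels differ by more than the tolerance
(tested). Block eligibility is a separate pass: ≥3 CpG sites, span < 2 kb,
pooled CpG observations ≥ 10 *in every reference sample* (the per-sample
reading guarantees every group mean used downstream is estimable), and
overlap with the capture panel when one is supplied.

## Marker discovery

For each cell-type group `G` and block `b`, with `T` the block-mean
methylation of `G`'s samples and `B` everyone else's:

    s⁻ = Q(B, bg_quant) − Q(T, 1 − tg_quant)      (hypomethylated in G)
    s⁺ = Q(T, tg_quant) − Q(B, 1 − bg_quant)      (hypermethylated in G)

Quantiles interpolate linearly between order statistics, so scores are
bit-reproducible. The block becomes a candidate in the direction of the
larger score when that score reaches `margin` (default 0.4); per group,
candidates of both directions are ranked together — score descending, then
shorter span, then genomic order — and truncated to `top_k` (default 100).
The quantile slack (defaults `tg_quant 0.2`, `bg_quant 0.1`) tolerates
outlying reference samples on either side. Block means are pooled ratios
(Σ methylated / Σ total over the block), undefined (missing, never zero)
when the block is uncovered; a block is skipped for a group whose samples
have no defined mean there. Scores are antisymmetric under methylation
inversion (m → 1−m swaps hypo and hyper exactly; property-tested).

Two fragment-level summaries coexist deliberately: the *methylation score*
used for atlas heatmaps counts fragments whose observed in-block CpGs are
strictly uniform (zero discordant sites), while the *U/X/M classifier* uses
the 1/3 and 2/3 thresholds below. Both definitions appear in the source
design; they differ on e.g. a 4-CpG fragment with one methylated site.

Reference grouping itself can be audited with
`cluster_reference_samples`: average-linkage hierarchical clustering on
Euclidean distance over the top 10% most variable blocks.

## U/X/M classification and the atlas

A fragment overlapping a marker is restricted to its observed in-block
CpGs; with `k` observed sites and `m` methylated it is excluded when
`k < rlen` (default 3), **U** when `m/k ≤ 1/3`, **M** when `m/k ≥ 2/3`,
else **X**. The printed thresholds "≤33%" / "≥66%" are implemented as the
exact thirds with inclusive comparison in integer arithmetic
(`m·q ≤ p·k`): percentages are rounded renderings of thirds, and exact
rational comparison avoids float boundary artefacts — this matters for
3-CpG fragments, where one methylated site is U, two are M. Out-of-block
CpGs on the same fragment are ignored (per-marker semantics); '.'-padding
never changes a class, and C↔T inversion swaps U and M exactly (both
property-tested). U/X/M proportions are count-weighted and sum to exactly 1
as rationals.

The atlas pools each cell type's reference samples (summing fragment
counts), and stores per marker the U proportion for hypomethylated markers
or the M proportion for hypermethylated ones, with a parallel coverage
matrix; a marker uncovered in its own target type is kept as missing with a
warning.

## Deconvolution and genome equivalents

The sample's marker vector `b` holds its U/M proportion per covered marker;
markers without sample coverage, or with a missing atlas entry in any cell
type (row-wise complete case, no imputation), are dropped. The fit is
unweighted non-negative least squares (`scipy.optimize.nnls`, an active-set
method), then the solution is rescaled to sum to one — solve-then-normalize
rather than a sum-constrained fit. An all-zero solution or a sample with no
informative coverage is an error, never a silent 0/0. The result carries
the raw coefficients, residual norm, and used-marker mask.

Fractions convert to absolute concentrations as

    Geq/mL = fraction × conc_ng_per_mL / (3.3×10⁻¹² g × 10⁹ ng/g)

i.e. division by 3.3×10⁻³ ng per haploid genome. A literal reading of the
usual description ("multiplying the fraction times the concentration by the
genome mass") is dimensionally inconsistent — multiplying by grams per
genome cannot yield genomes per mL — so the division form is implemented;
it reproduces the standard worked value 0.1 × 33 ng/mL → 1000 Geq/mL.

## Cohort statistics

All tests are two-sided with fixed, documented exact/approximate switches
so results are machine-independent:

* **Wilcoxon signed rank**: zero differences dropped (Wilcoxon's original
  convention — software differs here); exact null distribution by
  enumeration of sign assignments (subset-sum convolution, identical to
  brute force) for n ≤ 25 without ties in |d|; otherwise normal
  approximation with tie correction and no continuity correction.
* **Mann–Whitney U**: midranks; exact by enumeration of group assignments
  for combined n ≤ 12 without ties; otherwise normal approximation with
  tie correction. Degenerate zero-variance inputs give p = 1.
* **Spearman**: Pearson correlation of midranks; exact permutation p for
  n ≤ 8; otherwise the t approximation on n − 2 degrees of freedom.
* Exact two-sided p = min(1, 2 × smaller tail including the observed
  statistic).
* **BH** step-up adjustment preserves input order and enforces
  monotonicity. **BKY two-stage**: stage 1 BH at α′ = α/(1+α) estimates
  m₀; stage 2 BH at α′·m/m₀ (all rejected when m₀ = 0) — the original
  two-stage definition, matching `statsmodels` `fdr_tsbky`, which the
  tests use as an independent cross-check.

Derived quantities: fold change = post/pre (undefined, never infinite, at
zero baseline; computed on fractions by default, optionally on Geq/mL) and
the combined POD7/POD30 average (mean of the timepoints present). The
injury contrast compares combined POD7/POD30 levels between outcome arms by
Mann–Whitney; any outcome label other than `no_injury` counts as injury.

## Synthetic data: what it emulates, and what it does not

Reference methylomes live on one synthetic chromosome of equally sized CpG
blocks (15 CpGs every 60 bp, blocks 500 bp apart — comfortably inside the
eligibility filters). Each block carries a latent methylation propensity θ
per cell type: non-marker blocks share a common θ ~ Beta(0.3, 0.3) (a
bimodal methylome, mostly strongly methylated or unmethylated); planted
marker blocks set θ to `marker_low` (default 0.05) in the target type and
`marker_high` (default 0.95) elsewhere for hypomethylated markers, reversed
for the ~20% hypermethylated ones (cell-type-specific hypermethylation is
the rarer direction in real atlases). Fragment methylation is **bimodal at
the fragment level**: a fragment is drawn fully methylated with probability
θ, else fully unmethylated, and each observed symbol then flips
independently with the bisulfite error rate ε (default 0.03). This latent
concordance — not independent per-CpG noise — is what makes U/X/M
informative, mirroring the co-methylation structure of real reads.
Fragments observe 3–10 CpGs uniformly at random within one block. The
implied class probabilities have the closed form

    P(U | θ, ε, k) = θ·P(Bin(k, 1−ε) ≤ u·k) + (1−θ)·P(Bin(k, ε) ≤ u·k)

(`uxm_probabilities`), against which the generator is verified. Mixtures
draw each fragment's source type from the stated proportions and its block
uniformly; spike-in ladders are two-component mixtures with recorded truth.

The longitudinal cohort generator works directly at the fraction level
(deconvolution noise is studied separately): both outcome arms spike at
POD0 (hepatocyte mean fraction 0.02 → 0.25, mimicking surgical damage);
the no-injury arm decays to near baseline by POD7 (0.04 → 0.03) while the
injury arm stays elevated (0.15 → 0.12), with the biliary fraction
following the same shape at lower levels. Multiplicative lognormal noise
(σ = 0.35) perturbs the liver signals; the remaining mass is split among
background cell types with a myeloid-dominated weight profile and
renormalized so fractions sum to one. cfDNA concentration means are
(PRE, POD0, POD7, POD30) = (25, 125, 40, 30) ng/mL — a 5-fold
post-reperfusion surge over an already elevated end-stage-liver-disease
baseline — and AST/ALT follow a noisy power law of hepatocyte Geq/mL,
`AST = 0.1 · Geq^0.9 · exp(N(0, 0.3))`, which induces the strong rank
correlation the enzyme-correlation analysis expects.

What the generator does **not** emulate: real genomic coordinates and CpG
density variation, fragment length/end-motif biology, within-type
propensity heterogeneity across reference donors, capture efficiency
variation across markers, and partially methylated (X-rich) biology.
Passing tests therefore demonstrate correctness and statistical behaviour
of the algorithms under the stated generative conditions, not performance
on patient data.

## Experiment scales and the measured detection limit

The spike-in study uses a five-cell-type liver panel (hepatocyte, biliary,
hepatic stellate, endothelial, myeloid) with 100 planted markers per type,
reference depth 3 samples × 2000 fragments/block (so atlas sampling error
is subdominant to the cfDNA sample's counting noise), and mixtures at 200
fragments per marker block with ε = 3%. A two-cell-type reference was
rejected deliberately: with only two groups every marker block separates
*both* groups in opposite directions, so top-k selection picks winners
among ~2× near-tied candidates scored on the same fragments used to build
the atlas, inflating the atlas contrast (a winner's-curse selection bias
that manifested as 60–100% false "detection" of an absent spike). The
five-type panel removes the degeneracy; at level 0 the spike is estimated
positive in ~half the replicates, as an unbiased truncated estimator
should be.

Under these conditions the minor-component estimator has standard
deviation ≈ 1.7×10⁻³: the background carries ~5% opposite-latent-state
fragments at every marker (a direct consequence of the 0.05/0.95
propensities), giving per-marker binomial noise sd ≈ √(0.05·0.95/200) over
~200 informative markers. A 0.1% spike is therefore estimated without bias
(median within a factor of two of truth) but crosses zero too often —
detection ≈ 72–74% of replicates — while 0.2% reaches the ≥90% detection
bar. The reported operating detection limit at these scales is
accordingly 0.2%. Detecting 0.1% at ≥90% would require roughly 4× the
markers-×-depth product or near-perfect marker contrast (background
propensities near 0/1), not a different algorithm; the deeper-sequenced,
cleaner-marker regime of real capture panels is exactly where the
fragment-level design claims that resolution.

Problem sizes elsewhere (10-type recovery at 100 mixtures, 100-seed cohort
power, 50-replicate ladders) were chosen to give stable estimates at
desk scale; the acceptance script and test suite regenerate everything
from seeds at run time.

## Pipeline orchestration

`run_pipeline` executes simulate → segment → filter → markers → atlas →
deconvolve → Geq → cohort stats into a run directory with a manifest
recording the package version, global seed, and a parameter hash per stage.
One global seed fans out to per-stage seeds by SHA-256 derivation, so
stages are individually reproducible. Re-runs under an unchanged
configuration are skipped whole (the manifest hash and outputs are
checked); a changed configuration refuses to overwrite without `force` —
re-entrancy is at whole-run granularity, since later stages are cheap
relative to simulation. Stage failures halt with the failing stage named
and partial outputs retained for inspection.

## Known limitations

* Segmentation is a greedy single-resolution scan; it reproduces planted
  change points under the stated conditions but is not the multi-sample
  likelihood segmentation of production block callers, and boundary
  placement on noisy data differs from planted truth when adjacent levels
  are within the tolerance.
* NNLS rows are unweighted; coverage weighting is plumbed but off by
  default, matching the reference design.
* The deconvolution reports point estimates only (no bootstrap intervals).
* Exact-test thresholds (n ≤ 25 / ≤ 12 / ≤ 8) are fixed constants chosen
  for reproducibility, not adaptive performance limits.
* The cohort generator ties AST/ALT to hepatocyte Geq/mL only; cholestatic
  enzyme dynamics (ALP, bilirubin) are not modelled.
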