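# Methods

## Study design the package models

A mouse diet-intervention experiment: C57BL/6 mice on chow (CD) or high-fat
diet (HFD); after four weeks of HFD feeding, mice with fasting blood
glucose above 9.5 mmol/L constitute the diabetic model, which is split into
an untreated arm (HFD+SPSS, saline) and two supplement arms (HFD+PA,
HFD+Rutin; 200 mg/kg/day oral gavage for six weeks). Body weight (g) and
fasting glucose (mmol/L) are measured weekly; fecal genus-level amplicon
count tables are obtained at the reference week (4) and endpoint week (10);
glucose- and insulin-tolerance curves are measured near the endpoint.

## Phenotype deltas

Per group, `group_delta` averages BW and FBG over mice at each week and
reports end-minus-reference differences:

ΔBW = B̄W_end − B̄W_ref,  ΔFBG = F̄BG_end − F̄BG_ref.

A positive ΔBW is weight gain. `delta_contrast(a, b)` reports Δa − Δb and
100·(Δa − Δb)/Δa; the first argument's delta is the denominator, the
convention under which the worked group-mean table yields an excess of
2.17 g = 39.3% (the alternative denominator would give 64.8% and is
rejected — an explicit unit test pins this). Tolerance-test curves are
summarized by the trapezoidal AUC over (minutes, glucose); the default is
total AUC, with an incremental (baseline-subtracted, floored at zero)
variant by flag.

## Beta diversity and the centroid offset

Bray–Curtis dissimilarity is computed on relative abundances (counts are
row-normalized first, so library size never enters). Classical PCoA
double-centers the squared dissimilarities, B = −½ J D∘D J, and
eigendecomposes B; axis k is the unit eigenvector times √λₖ, with a
deterministic sign convention (largest-magnitude loading positive) so runs
are byte-reproducible. Because Bray–Curtis is a semimetric, B has negative
eigenvalues; the default policy retains positive axes only and logs the
negative-eigenvalue mass fraction (typically ~2% on the synthetic
communities), with Lingoes and Cailliez additive-constant corrections
available. `proportion_explained` divides by Σ|λ| so retained proportions
sum to at most 1. A PCA fidelity mode (`pca_relabund`, SVD of
column-centered relative abundances) is provided because some published
toolchains run a principal-component routine where PCoA is described; both
modes flow into the same downstream statistic, and neither is asserted as
canonical.

GM_offset(g₁, g₂) is the Euclidean distance between group-mean coordinates
on the first n_axes axes (default 2, matching the statistic's published
form; more axes can only increase it, so the 2-axis value is a lower bound
on separation — a documented caveat). The statistic is provably invariant
to per-axis sign flips, rotations of the retained subspace, and group
exchange; tests verify this numerically at 1e-10.

### Inference

The ordination is a function of the distance matrix alone, so the
permutation null permutes group labels among the two groups' samples on the
fixed coordinates — exact, and O(B·n) instead of O(B·n³). p-values use the
add-one estimator (1 + #{null ≥ obs})/(1 + B), bounded below by 1/(B+1).
The 95% bootstrap interval resamples mice (not samples) with replacement
within each group, respecting the repeated-measures structure. ANOSIM
follows Clarke: R = (r̄_between − r̄_within)/(n(n−1)/4) on tie-averaged
ranks of the dissimilarities, permutation p as above. The n(n−1)/4 divisor
is the one under which perfect separation gives exactly R = 1;
implementation is cross-checked against scikit-bio on shared inputs.

## Alpha diversity and composition summaries

Shannon entropy uses natural log (base configurable); "Simpson" is the
Gini–Simpson form 1 − Σp² throughout, stated prominently because the bare
name is ambiguous. Indices are computed on proportions of raw counts
without rarefaction (an optional rarefaction helper exists for sensitivity
analyses). The F/B ratio divides summed Firmicutes fractions by summed
Bacteroidota fractions, per sample or on group-mean fractions; a zero
denominator yields a flagged undefined value rather than an exception.

## Differential genera and networks

Per-genus two-sample tests on relative abundances: Welch's unequal-variance
t-test by default ("t-test" alone underdetermines the variant; Welch is the
safer default), Student's and Kruskal–Wallis by flag. Retention is raw
p < 0.05 by default for both differential genera and network edges — the
convention of the analysis this package systematizes — with
Benjamini–Hochberg adjustment available and recommended. Key microbes are
the intersection of the significant sets of the two treatment pre/post
contrasts. Core genera are those whose group-mean abundance exceeds a
presence threshold (default 0, i.e. any nonzero mean — the threshold is a
documented choice, not a published value) in every group; specific genera
in exactly one. Correlation networks join samples to per-mouse body
features, compute all genus–genus and genus–feature Pearson (or Spearman)
correlations with t-distribution p-values, and export each retained
unordered pair once as a Cytoscape-compatible edge table.

## Synthetic data generator

The generator defines the study conditions for every test:

- **Community model.** 66 genera across 9 phyla (Firmicutes 30,
  Bacteroidota 15, the remainder spread over 7 minor phyla), interleaved
  across a geometric rank-abundance curve spanning 4 natural-log units.
  Each (group, week) cell has expected composition softmax(base + effect);
  samples are Dirichlet(θ·p) with θ = 50 and multinomial counts at
  log-normal library size (ln-mean 10.8 ≈ 49k reads, ln-sd 0.3). θ and the
  library parameters are stated configuration, not published facts.
- **Effects.** HFD raises five mid-to-high-rank Firmicutes key taxa and
  depresses five Bacteroidota key taxa by one log-fold at both weeks —
  producing the F/B-ratio seesaw — while the treatments partially revert
  this at the endpoint and add small distinct signatures; rutin reverts
  more (retention 0.2) than PA (0.6), so the rutin endpoint sits farther
  from untreated HFD, reproducing the qualitative ordering of the published
  offsets. Effects are additive in log space, so shifts renormalize the
  rest of the community automatically.
- **Phenotypes.** Per mouse: baseline ~ N(group mean, group sd), plus group
  slope × (week − w₀), plus κ·shift·(week − w₀)/(w_end − w₀), plus
  N(0, σ) measurement noise; FBG floored at 0.1 mmol/L. Baselines and
  slopes default to the published group means and deltas (e.g. BW at week 4:
  22.65/29.68/26.12/25.39 g; six-week ΔBW 3.35/5.52/−3.116/−0.594 g; ΔFBG
  0.66/−0.2/−4.54/−4.56 mmol/L; HFD baselines above the 9.5 mmol/L model
  threshold). `shift` is the mouse's realized Bray–Curtis displacement
  between its two sampled compositions. The coupling term grows linearly
  from zero at the reference week to κ·shift at the endpoint — the reading
  under which κ actually moves the end-minus-reference delta (a constant
  offset would cancel); κ defaults to 0.
- **Ground truth** records expected per-cell compositions, pairwise
  latent-effect displacements (zero iff two cells share an effect vector),
  the set of truly shifted genera, and per-mouse realized shifts.

What the generator does *not* emulate: sequencing error and chimeras,
taxonomic misassignment, zero-inflation beyond what the DM model induces,
cage effects and coprophagy-driven correlation between cage-mates,
longitudinal autocorrelation of the microbiome beyond two time points, and
compositional correlation structure among non-key taxa. Passing tests
therefore certify the statistical machinery under a DM world, not the
biology of any particular real dataset.

## Numerical choices and problem sizes

- Eigenvalues within 1e-10 of zero (relative to the spectral radius) are
  treated as null; an all-non-positive spectrum is a degenerate-input
  error. Coordinates are re-centered after scaling to remove float drift.
- Dissimilarity matrices must be symmetric within 1e-12 with zero
  diagonal; simplex vectors within 1e-9 of unit sum.
- Permutations default to 999 (199 in Monte-Carlo loops); p-values can
  never be 0 by construction.
- Calibration checks use 2,000 null datasets (n = 5/group, 199
  permutations) for the offset test, 30 null datasets × 66 genera
  (n = 20/group, θ = 200 on a 2-log-unit community, where the t-test's
  normal approximation is comfortably valid) for the differential rule, and
  64 independent Gaussian feature columns (2,016 pairs, n = 20) for network
  retention. On the default steep community the Welch test is mildly
  *conservative* for rare genera at small n — a known property of t-tests
  on skewed near-zero abundances, documented here rather than hidden by the
  calibration fixture.
- Recovery checks use a δ ∈ {0, 0.25, 0.5, 1.0} effect grid at n = 5/group
  with 200 replicates per level (100 in the acceptance script) and a
  sensitivity check at n = 20/group, δ = 1.
- The pipeline derives per-stage seeds from the top-level seed by hashing
  the stage name (SHA-256, reduced below 2³¹), so stages re-run in
  isolation reproduce their slice of a full run; `report.json` is a pure
  function of (inputs, config, seed).

## Known limitations

- The published offset values from the real study (6.68, 1.79, 7.39, 6.20,
  6.54) and its offset–ΔFBG correlation (R = 0.92) are not reproducible
  from this package alone: they require the deposited raw reads processed
  through an external denoising/classification pipeline, and the original
  ordination mode and correlation inputs are under-specified. The package
  reproduces the statistic's definition, its invariances, and the
  qualitative ordering (rutin shift > PA shift) on synthetic data.
- GM_offset on two axes discards separation in higher axes; use
  `n_axes="all positive"` semantics (pass a larger n_axes) when the first
  two axes explain little variance.
- Raw-p edge retention without adjustment inflates network false
  discoveries when many pairs are tested; prefer `adjust="bh"`.
- The bootstrap CI is percentile-based and can be narrow at n = 5 mice per
  group; it quantifies resampling variability, not ordination uncertainty.
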