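# Methods

## The model

`overlayde` calls differentially expressed (DE) genes between two
conditions with two replicates each, without a fold-change threshold.
The idea: plot every gene as a dot in a 2D log10-TPM scatter and ask
whether the between-condition scatter is *covered* by the
between-replicate scatter. Replicate scatter is what two measurements
of the same biology look like; anything it cannot cover is attributed
to differential expression.

Concretely, for a comparison of conditions 1 and 2:

- **Replicate clouds.** For each condition, the scatter of replicate 1
  vs replicate 2 log10-TPM values (one point per gene). The union of
  the two clouds is the null cloud.
- **Condition combinations.** The four pairings (rep *a* of condition 1
  vs rep *b* of condition 2, *a, b* ∈ {1, 2}) give four
  between-condition scatters.
- **Overlap predicate.** A dot has radius *s* (the *dot size*, in
  log10-TPM data units). Two dots overlap when their center distance is
  ≤ 2*s* (touching counts). Euclidean distance by default; Chebyshev
  optional. Overlap queries run through a KD-tree whose results are
  contract-identical to brute force (tested).
- **DE rule.** A gene is DE iff in *all four* combinations its point
  overlaps no point of the null cloud. Genes are not excluded from the
  null cloud when their own points are tested, matching how overlaid
  scatter plots behave.

Because overlap is monotone in *s*, DE sets are nested: growing the dot
size can only remove calls.

## Expression noise and the dot-size calibration

Per-gene pairwise noise is the squared coefficient of variation of the
two values,

    eta²_i = 2 (x_ij − x_ik)² / (x_ij + x_ik)²,

computed on linear TPM. It is dimensionless, symmetric and bounded by
2 (attained when one value is zero). Transcriptome noise is the mean of
eta² over genes (a sum is available as an option; the mean is the
default because the replicate-noise levels worth comparing across
datasets are per-gene averages).

The *replicate-noise baseline* is the mean of the two within-condition
replicate-pair noises. The dot size is swept over a grid (default
0.001–0.009 step 0.001, plus 0.015) and the selected size is the
smallest whose non-DE between-condition noise is at or below the
baseline; if none reaches it, the largest size is returned with a
warning flag (`DotSizeSelection.qualified = False`).

**Known limitation of the calibration.** The baseline averages over the
whole retained transcriptome while the non-DE noise averages over the
covered subset, and coverage preferentially excludes noisy genes. On
data whose non-DE genes scatter exactly like replicates, the non-DE
noise therefore sits *below* the baseline at every dot size and the
rule selects the smallest grid size, where isolated null genes (the
sparse tails of the scatter band) dominate the call set. The examples
and acceptance script compute this behaviour explicitly
(`fdr_at_selected_size`). On real data the rule behaves better because
between-condition background variation keeps non-DE noise above the
baseline at small sizes; the conservative choice is the largest swept
size whenever `qualified` is false, and the KDE p-value refinement
(below) is the principled way to trim false calls at small sizes.

## Low-expression filtering

Weakly expressed genes are noise-dominated and are removed before the
overlay. The transcriptome-wide TPM distribution (pooled non-zero
values across samples) is fitted by maximum likelihood to five
candidate families — lognormal, Pareto (location pinned at the sample
minimum), Burr XII, log-logistic, Weibull — and the best is chosen by
AIC (ties: fewer parameters, then name). Locations are pinned at zero
so the fits are deterministic; the lognormal and Pareto estimators are
closed-form, the rest start from fixed moment-style guesses.

The cutoff is the lowest point below the fitted mode where the
empirical density (Gaussian KDE of log10 values, Silverman bandwidth)
crosses the fitted density, mapped back to TPM; with no sub-mode
crossing the minimum value is returned and nothing is filtered. On
pure-family data the first crossing is a noise-level fluctuation in the
lower tail (anywhere from the ~0.1% to ~6% quantile); it becomes
meaningful when a genuine low-expression excess exists. The filter rule
defaults to *mean* (gene kept when its mean TPM across all samples
exceeds the cutoff); *all*/*any* variants and a manual threshold are
available.

A gene that is zero in both samples of any pair the comparison uses has
undefined eta² and no usable position in that scatter; the pipeline
drops such genes after filtering (the mean rule alone does not
guarantee positivity).

## KDE p-values

The null cloud (2*m* points: the union of both replicate clouds, built
by concatenating the replicate-1 and replicate-2 log10-TPM vectors of
the two conditions) defines an equal-weight 2D Gaussian mixture with
diagonal bandwidth. Bandwidths default to the per-dimension Silverman
rule for d = 2, h_d = sd_d · n^(−1/6); a univariate Sheather–Jones
solve-the-equation plug-in per dimension is available
(`method="plugin"`; the bandwidth matrix stays diagonal, recorded in
the output metadata).

Three p-value readings are provided, evaluated at the gene's
between-condition point (replicate-1 pairing by default; an option
takes the maximum over all four pairings):

- `cdf` (default): the lower-orthant mass F(x₁, x₂) of the mixture —
  the literal integral of the null density up to the point. Note it
  flags only the lower-left tail, i.e. down-shifted genes.
- `two_sided`: 2·min(F, 1 − F).
- `hdr`: the probability that a draw from the fitted mixture has
  density at most the density at the point (Monte-Carlo, seeded) —
  near 1 deep inside the cloud, near 0 for outliers in any direction.
  This is the recommended reading for refinement.

Final calls: `de_final = de_overlay ∧ (p < p_cutoff) ∧ (|log2 FC| ≥
log2(fold_cutoff))`, each cutoff optional; fold change is the ratio of
per-condition mean TPM (positivity guaranteed by the filter, no
pseudocount). Cutoffs can only shrink the DE set. No multiple-testing
correction is applied; the p-values are descriptive scores against an
estimated null, not calibrated tail probabilities.

## Response metrics

For time-series designs, two validation views computed per gene subset
(all / DE / non-DE): (1) Pearson correlation of log10 expression
between the anchor condition and each time point, replicates matched by
label and averaged, so the anchor correlates with itself at exactly 1;
(2) PCA with samples as observations and subset genes as variables
(mean-centered, unscaled, full decomposition), per-condition scores
averaged over replicates, each component's sign fixed so the anchor
scores ≤ 0. The PCA is refit per subset rather than projected from the
all-gene fit.

## The synthetic generator

`SynthConfig`/`generate_counts` emulate the input this caller expects:

| parameter | default | meaning |
|---|---|---|
| `m` | 2000 | genes |
| `baseline` | (2.0, 1.5) | bulk lognormal (mu, sigma), natural-log TPM-like units |
| `replicate_cv` | 0.15 | CV of multiplicative lognormal replicate noise |
| `condition_cv` | 0.05 | sub-threshold biological drift per condition, coherent across its replicates |
| `n_de` | 200 | injected DE genes |
| `fold_range` | (4, 8) | injected fold-change interval |
| `direction_prob` | 0.5 | probability a DE gene goes up |
| `spike_frac` | 0.0 | fraction of weakly expressed noise genes (off by default) |
| `library_size` | 8·10⁶ | multinomial read depth per sample |
| `lengths_range` | (500, 5000) | gene lengths, bp |

Counts are drawn multinomially with probabilities proportional to
expression × gene length, so TPM recovery is unbiased and low counts
carry realistic Poisson-like noise. The depth gives a few thousand
reads per gene, in line with bacterial bulk RNA-seq. All randomness
comes from one seeded generator; identical configs are bit-identical.

Two deliberate design choices:

- **DE genes come from the lower three quartiles of baseline
  expression.** TPM is compositional: injecting multiplicative fold
  changes into high-mass genes changes each sample's total mass and
  shifts *every* other gene's TPM between conditions, making nominally
  non-DE genes differentially expressed by construction. Restricting
  the injected mass keeps the composition comparable (residual shift
  ≪ replicate noise). When `n_de` exceeds the pool, all non-spike genes
  become eligible.
- **`condition_cv` exists and is small but nonzero.** Real conditions
  perturb most of the transcriptome a little; a generator whose null
  genes scatter exactly like replicates is an idealization that makes
  the between-condition non-DE noise indistinguishable from the
  baseline.

What the generator does not emulate: gene–gene correlation, batch
effects, expression-dependent replicate CV beyond counting noise,
isoform structure, and a fold-change continuum (injected effects are
well-separated from the null). Tests passing on this generator
demonstrate the algorithmic contracts (overlap exactness, monotonicity,
calibration mechanics, recovery of well-separated effects), not
performance on real transcriptomes.

## Numerical choices

- TPM floor for log10 transforms: 10⁻³ (keeps zeros finite in scatter
  space; such genes are typically filtered first).
- Replicate-pair selection: maximal Pearson correlation of log10(TPM +
  floor) over all genes, ties to the lexicographically smallest pair;
  constant columns are skipped.
- Overlap ties: touching (distance exactly 2s) counts as overlap.
- AIC ties: fewer free parameters, then lexicographic family name.
- Degenerate fits: all-equal samples, non-positive values and
  non-finite likelihoods raise immediately rather than returning
  garbage parameters.
- Empty DE or non-DE subsets yield NaN noise entries in the sweep; NaN
  never satisfies the baseline comparison.
- HDR p-values use 4000 Monte-Carlo draws by default, seeded.

## Limitations

- Exactly two replicates per condition enter a comparison; with more,
  the best-correlated pair is used (run other pairs explicitly to
  mirror multi-replicate overlays).
- The calibration-rule bias discussed above: on clean data prefer the
  `qualified` flag plus HDR-p refinement over trusting the smallest
  selected size.
- The `cdf` p-value reading is directional (lower-left tail only); it
  is kept as the default literal definition, with `hdr` recommended.
- Overlap geometry treats dots as disks in data units; rendered glyph
  sizes in other tools will not match exactly.
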