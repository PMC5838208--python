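# Methods

## Model and procedure

The pipeline compares two groups of samples (reference vs case) over a
matrix of β values (CpG sites × samples, β ∈ [0, 1], missing allowed).

**Per-site statistics.** The between-group shift at a site is the
Hodges–Lehmann estimate, the median of all n_case × n_ref pairwise
differences (case − reference), computed pairwise-complete under
missingness. Direction-specific significance uses one-sided Mann–Whitney
rank-sum tests; a location-shifted variant tests H1: the case distribution
exceeds the reference by more than a given offset (case values are reduced
by the offset before ranking, so offset 0 is the plain test). Per-group
low/medium/high methylation status uses one-sided Wilcoxon signed-rank
tests against β = 0.5: *low* iff p(location < 0.5) < 0.025, *high* iff
p(location > 0.5) < 0.025, *medium* otherwise.

Rank tests are exact — full enumeration of the rank-statistic null
distribution — whenever the total sample size is ≤ 25 and the data carry no
ties; otherwise a tie-corrected normal approximation with continuity
correction is used. The exact null distributions are computed once per
sample-size configuration and cached, so the vectorised genome-wide scan
and a single-site call produce identical p-values. Note an inherent
property of the exact tests at tiny n: with 5 observations the smallest
attainable one-sided signed-rank p is 1/32 = 0.03125, so a 5-sample group
can never be called low/high at α = 0.025 under the nonparametric family.
A parametric family (`test_family="t"`: one-sample t against 0.5, Welch
two-sample) is available for that regime; the nonparametric family is the
default because it needs no normality assumption at n as small as 5 vs 14.

**Mixture model.** The genome-wide distribution of HL shifts is modelled as
a univariate Gaussian mixture fitted by EM. The component count K is chosen
by scanning K = 1…10 and minimising BIC = −2·ll + ν·ln(n) with ν = 3K − 1
free parameters (K means + K standard deviations + K−1 free weights).
σ values are floored at 10⁻⁴ Δβ (HL values are medians of β differences on
a [−1, 1] scale; narrower components are numerical artifacts) and component
weights below 10⁻⁴ trigger a restart from a jittered initialisation.

**Maximum-probability cutoffs.** The real line is partitioned by
argmaxₖ wₖ φ(x; μₖ, σₖ). Boundaries are located by a dense grid scan
(step 10⁻⁵ over [min μ − 6σ, max μ + 6σ]) refined by bisection on the two
swapping components' weighted-density difference to |Δdensity| < 10⁻¹².
The first three boundaries at x > 0 are the up-methylation tier cutoffs
(everything beyond the third merges into the extreme tier); the same rule on
the negative side yields down cutoffs when at least three negative
boundaries exist (reported separately; the down tiers are less settled
because the down-methylation signal in the motivating data is weak).
A boundary within one grid step of zero is the up/down split itself (exactly
symmetric mixtures) and is assigned to neither side.

**Tier calls.** A site's direction is up iff p_up < α (one-sided α = 0.025;
optionally the Storey q). Its tier is the deepest cutoff c at which the
shifted test rejects *and* the HL point estimate exceeds c; the "at least"
tiers nest by construction because the shifted-test p-value is monotone in
the shift. An alternative reading — thresholding the HL estimate of sites
significant at shift 0 — is available as `tier_rule="hl_filter"`.

**Region integration.** Site p-values are combined per (gene, TSS/Body
region) and per interval feature by Stouffer's method,
Z = Σ Φ⁻¹(1 − pᵢ)/√k, unweighted; up and down are combined strictly
separately, and Storey correction is applied across regions within one
(region kind, direction) stratum. A site annotated to several genes
contributes to each; region tiers combine the shifted-test p-values per
cutoff and take the deepest one significant at α. p-values are clipped to
[10⁻¹⁵, 1 − 10⁻¹⁵] before any normal-quantile transform (one shared
constant), keeping every Z finite.

**Storey q-values.** π₀(λ) = #{p > λ}/(m(1 − λ)) on the grid
λ = 0.05, …, 0.95 is smoothed with a cubic least-squares fit (a 4-parameter
smoother standing in for the usual df = 3 smoothing spline, which no
installed dependency exposes with a df parameter), evaluated at λ = 0.95
and clipped into (0, 1]; then q_(i) = π₀·m·p_(i)/i with running-minimum
monotonisation. With fewer than 20 p-values π₀ is fixed at 1 (the estimate
is too unstable), which reduces to Benjamini–Hochberg.

## Region classes and coordinates

Manifest RefGene groups TSS1500/TSS200/5′UTR map to the TSS class and
1stExon/Body/3′UTR to the gene-Body class (both can hold for one site
because genes overlap); a site with no gene annotation is Intergenic, and
Intergenic never co-occurs with the other classes. Both ASCII (5'UTR) and
Unicode (5′UTR) manifest spellings are accepted. Manifest positions are
1-based; all interval work is 0-based half-open (BED convention), converted
in exactly one place: a site at 1-based position p lies in [start, end) iff
start ≤ p − 1 < end. Strand is ignored; chromosome labels are matched after
stripping an optional `chr` prefix.

## EM initialisation and the genome-scale fitting strategy

EM on this kind of shift distribution — a sharp near-zero peak flanked by
heavy, low-weight, strongly overlapping tails — is highly multimodal in its
starting point. The production fitter (`fit_mixture`, used by the model
scan) therefore runs a family of starts: uniform quantile spacing,
normal-score quantile spacings (which place components deep in the tails),
and seeded random quantile levels; each start runs to convergence on a
histogram-weighted version of the sample (2,000 equal-width bins once
n > 10,000 — weighted EM is still an exact ascent on the weighted
likelihood), and the best start by likelihood is polished on the full
sample (tol 10⁻⁸ relative log-likelihood, ≤ 1,000 iterations). Everything
is deterministic given the seed. The single-start quantile initialisation
remains available as `initialize_components` and is deliberately isolated
behind its own interface.

A known identifiability limit, established while validating the fitter: on
485,512 draws from the published 8-component HSC/AML mixture, the converged
maximum-likelihood solution has *higher* likelihood than the generating
parameters, with the means of the broad low-weight tail components
(w ≈ 0.01–0.06, σ ≈ 0.11–0.19) displaced by up to ~0.1 Δβ, while the four
dominant central components (87.8% of the weight) are recovered to ±0.003.
Tail-component locations at this sample size are therefore reported as
descriptive, not as sharply estimated quantities. The tier cutoffs are
essentially unaffected, because they live in the central region where the
dominant components rule.

## Synthetic data generator

`SimulationSpec` emulates the motivating study's shape: 5 reference vs 14
case samples by default; per-site baselines drawn from a two-mode beta
distribution (modes 0.1 and 0.9, weights 0.55/0.45, concentration 30 —
matching the characteristic bimodal 450K β histogram); per-sample noise
beta-distributed with concentration 100 (replicate SD ≈ 0.05 at β = 0.5),
respecting the [0, 1] support where Gaussian noise would not. Genes are
tiled along chromosomes with 3 TSS and 4 Body sites each; a configurable
fraction of genes receives a coherent planted case shift (default scenario:
5% of genes at Δβ = +0.1), and background shifts may be drawn from any
mixture (default: none, i.e. a flat null). The truth table records every
site's true shift and tier.

What the generator does **not** emulate: Infinium I/II probe-chemistry
differences, batch effects, spatial correlation between neighbouring CpGs,
copy-number artifacts, or cell-composition heterogeneity. Passing tests on
this generator therefore demonstrate the statistical machinery under clean
two-group sampling, not robustness to array artifacts.

## Validation scale and calibration

The test suite validates: the HL estimator against exhaustive pairwise
enumeration; exact rank-test p-values against full enumeration for group
sizes ≤ 8; the MAP boundaries against an independent dense-grid argmax
oracle on random mixtures; EM against a closed form at K = 1 and an
independent mixture implementation on separated components; and the
published desk-scale values (Cramér's V of the status tables, the top-four
component weight share, the three positive tier boundaries). End-to-end
recovery uses 20 replicates of 4,000-site studies (5% planted genes,
Δβ = 0.1): sensitivity and false-discovery proportion are aggregated over
replicates. Null calibration uses one 20,000-site δ ≡ 0 study; note that
the exact 5-vs-14 rank-sum test is discrete, with attainable one-sided
levels 0.0218 and 0.0279 bracketing 0.025 — the realised rejection rate
under the null sits at the conservative attainable level 0.0218, not at
the nominal 0.025.

## Known limitations

- Down-methylation cutoffs depend on the fitted model having three negative
  MAP boundaries; they are reported as experimental.
- The mixture scan can select a K whose MAP partition is too coarse for
  four tiers; the pipeline then falls back to the next-best K by BIC that
  supports them (recorded in the run manifest).
- Storey's π₀ smoother is a cubic polynomial fit, not a smoothing spline;
  on typical p-value ensembles the difference is well below the Monte-Carlo
  noise of the estimate.
- Gene-level results treat sites within a region as independent when
  combining (Stouffer); correlated neighbouring CpGs make the combined
  p-values optimistic, which is the standard caveat for this integration
  rule.
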