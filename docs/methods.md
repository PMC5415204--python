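# Methods

## The two-state thermodynamic model

Each missense variant is treated as a two-state folding equilibrium. The
mutant's folding free energy is the wild type's plus the predicted change,
ΔG_mut = ΔG_WT + ΔΔG, and the equilibrium folded fraction is the logistic

    f(ΔΔG) = 1 / (1 + exp((ΔG_WT + ΔΔG) / RT)).

Sign convention: ΔG = RT·ln([Unf]/[Fold]), so negative ΔG means mostly
folded. (The alternative sign convention, with ΔG = −RT·ln([Unf]/[Fold]),
would make a *positive* ΔG_WT describe a stable protein; we use the
convention under which a stable wild type has ΔG_WT < 0, which is the one
consistent with an effective stability of about −3 kcal/mol producing a
drop in protein levels at ΔΔG ≳ 3 kcal/mol.)

Two observables hang off the folded fraction:

- **Relative steady-state abundance** (wild type = 1): level(ΔΔG) =
  f(ΔΔG)/f(0). The assumption is that the protein quality-control system
  degrades the unfolded population, so cellular abundance is proportional
  to the folded fraction.
- **Residual function**, measured as % survival of cells under a
  genotoxic drug to which the functional protein confers *sensitivity*:
  survival(ΔΔG) = s_unf + (s_fold − s_unf)·level(ΔΔG), where s_fold and
  s_unf are pinned to the observed survival of two anchor variants — the
  wild type (assumed fully folded) and a strongly destabilized variant
  (assumed fully unfolded). Anchors with equal survival are rejected as
  degenerate.

Constants: R = 1.987×10⁻³ kcal/(mol·K); T = 310.15 K (37 °C, the culture
temperature), with 302.15 K (29 °C) available. Both overridable.

### Fitting and uncertainty

ΔG_WT is the only free parameter. It is estimated by ordinary least squares
on the linear abundance (or survival) scale, minimized by bounded scalar
optimization over [−15, +5] kcal/mol at 10⁻⁷ tolerance; tests verify
equality with an exhaustive 10⁻³-resolution grid search. Linear-scale OLS
is used because abundance ratios come from densitometry, whose error is
roughly additive on that scale. A fit that lands at a search bound is
flagged in the result.

Uncertainty is a nonparametric bootstrap: the variant set is resampled with
replacement at full size, the fit repeated (default 5,000 refits, seeded,
bit-reproducible), and the result reports the bootstrap standard deviation
as the quoted error plus 25–75% and 2.5–97.5% percentile bands. A
without-replacement subsampling mode (fraction 0.8) is available but not
default. The wild type enters the fit only if it is present in the input
table; it is never injected silently.

`degradation_threshold` converts a fitted ΔG_WT into the ΔΔG at which the
predicted relative level drops to one half, available in closed form:
ΔΔG½ = RT·ln(1/(0.5·f(0)) − 1) − ΔG_WT. For a stable wild type this is
≈ −ΔG_WT, the practical boundary between tolerated and degraded variants;
bootstrap bands are propagated through the same formula.

**Known coverage behaviour.** With ~24 variants, the 2.5–97.5 percentile
bootstrap band covers a known true ΔG_WT in about 89–90% of replicate
experiments rather than the nominal 95% — the familiar small-sample
undercoverage of percentile intervals. The quoted bands should be read with
that in mind.

## ΔΔG data handling

Variants are keyed by `<wt><position><mut>` strings with 1-based positions
in the numbering of the input table; no renumbering is attempted, and
positions absent from the input (e.g. unresolved in the crystal structure)
return "no prediction", never 0. Two aggregation schemes reduce raw
replicate tables to one value per variant: arithmetic mean over replicates
within each chain then over chains (the convention of FoldX-style
calculators run per monomer; with balanced data this equals the grand mean,
but the order is fixed for unbalanced input), and the mean of the k lowest
of exactly n values (the Rosetta-protocol convention, k = 3, n = 15).
Group summaries report mean ± SEM with the n−1 sample standard deviation.
Heat-map export clips rendered values at +7 kcal/mol by default — a display
convention only; stored values are untouched.

## Co-variation model

A pairwise maximum-entropy (Potts) model over a 21-state alphabet (20 amino
acids + gap) scores a sequence by E(σ) = Σᵢ hᵢ(σᵢ) + Σᵢ<ⱼ Jᵢⱼ(σᵢ, σⱼ),
interpreted as log-likelihood up to a constant. A mutation's score is the
wild-type-minus-mutant energy with all other positions fixed to the query
sequence; positive = disfavoured by the family (more damaging). Scores are
gauge-invariant; models are reported in the zero-sum gauge. Variants are
scored only at non-gap query columns; positions outside the alignment map
return "no prediction".

Sequences are down-weighted by 1/(number of neighbours at ≥ θ identity),
identity counted over all columns including gaps; θ = 0.8 by default, the
standard choice for phylogenetically redundant real alignments.

Fitting maximizes the weighted, L2-regularized pseudolikelihood — the
product over columns of conditional likelihoods p(σᵢ | σ₋ᵢ) — with L-BFGS
and an analytic gradient, couplings parameterized as one symmetric block
per column pair. The likelihood term is normalized by total sequence
weight, so the convergence tolerance (10⁻⁵ on the gradient) and the
penalties (λ_h = 0.01, λ_J = 0.01 per coupling block) are independent of
alignment depth. A heavier coupling penalty scaled with L was tried and
rejected: it visibly shrinks strong couplings at desk scales. The
independent-site model (fields = log of pseudocount-smoothed weighted
column frequencies, J = 0) is the conservation baseline.

The Gibbs sampler draws synthetic alignments from a model by single-chain
systematic-scan sampling, emitting one sequence every `thin` sweeps after
`burn_in` sweeps. Strong couplings slow single-site mixing — moving a
coupled state pair requires crossing an energy barrier one column at a
time — so the defaults (burn_in = 500, thin = 20) are deliberately
conservative; with short thinning the autocorrelation at coupled column
pairs measurably biases refitted couplings.

**Recovery experiments** refit a known truth model (L = 8, 4-letter
alphabet, random N(0,1) fields, one coupled column pair with a ±1.6
matched-state block) from 2,000 sampled sequences and compare all 24
single-substitution scores. These experiments use θ = 1.0 (duplicate
collapsing only): the samples are i.i.d., and at L = 8 the θ = 0.8 rule
clusters unrelated sequences (7/8 identity arises by chance), collapsing
the effective sample size and degrading recovery for no statistical reason.
Typical recovery is Spearman ρ ≈ 0.93–0.99, with the coupled pair always
carrying the largest coupling norm. Because the depth, identity filtering
and construction of real protein-family alignments vary, recovery on
synthetic alignments is the testable claim here; the scorer applied to a
real MSH2 alignment inherits whatever limitations that alignment has.

## Evaluation statistics

- **ROC/AUC** over pathogenic vs non-pathogenic variants, ties credited
  0.5, so the AUC equals the Mann-Whitney U statistic normalized by
  n₁·n₂ (verified against brute-force pair counting). Per-predictor
  orientation flags make "higher = damaging" uniform; missing scores are
  excluded with a count.
- **Leave-one-out accuracy**: for each held-out variant, the threshold
  maximizing balanced accuracy on the rest classifies it. Candidate
  thresholds are midpoints between consecutive unique training scores
  (plus ±∞), so the cut sits between classes rather than on a training
  point; among ties the smallest threshold wins, pushing borderline
  variants to the pathogenic side — the conservative choice for a
  screening context.
- **Bootstrap group test** (one-sided): each group resampled with
  replacement at its own size; p = fraction of resamples contradicting the
  stated direction. Used for the half-life comparison between variants
  destabilized by less vs more than 3 kcal/mol, one-sided because the
  hypothesis is directional; variants at exactly 3.0 kcal/mol go to the
  high group.
- **Permutation group test** (two-sided by default, mean or median
  difference): exhaustive enumeration when C(n, n_a) ≤ 10⁵, Monte-Carlo
  with the add-one correction otherwise.
- **Correlation**: squared Pearson r with the two-sided t-transform p.
- **Frequency binning**: per allele-frequency bin, the 25/50/75% ΔΔG
  quartiles; empty bins are reported with n = 0.

## Synthetic data generators

All generators are pure functions of a `SyntheticConfig` whose seed is
mandatory; each generator draws from its own deterministic substream. The
defaults describe the study conditions, not values fitted to any real
dataset:

- **ΔΔG matrix**: full saturation (19 substitutions × n positions, default
  120; 855 gives the full-chain grid of 16,245). Per variant, a
  two-component mixture — near-zero bulk N(0.5, 0.8²) kcal/mol and a
  destabilizing tail 2 + Gamma(shape 2, scale 3) — with tail probability
  0.35 at buried positions (default 35% of positions) and 0.08 at exposed
  ones, plus +2 kcal/mol for substitutions to proline. This reproduces the
  qualitative shape of real saturation datasets: a dominant near-zero mode,
  overall mean ~2 kcal/mol, and a right-skewed destabilizing tail.
- **Phenotypes**: levels = two-state prediction at ΔG_WT = −3.0 kcal/mol ×
  lognormal noise (σ = 0.15, roughly densitometry-level scatter); survival
  = anchored interpolation (folded anchor 0%, unfolded 100%) + Gaussian
  noise (sd 5 points) clipped to [0, 100]; half-life = 19 h ×
  (0.15 + 0.85·level) × lognormal noise (σ = 0.1) — an invented monotone
  map used only to exercise the group tests, since no quantitative
  half-life model is assumed. MSH6-interaction categories are thresholded
  at 8 and 15 kcal/mol.
- **Labels**: pathogenic iff true ΔΔG > 3 kcal/mol, then flipped
  independently with probability 0.1.
- **Frequencies**: E[log₁₀ f] = −2.5 − 0.6·max(ΔΔG, 0) with N(0, 0.5²)
  noise, clipped to [0, 1] — common variants are the stable ones.

What the generators deliberately do *not* emulate: correlated prediction
errors between neighbouring positions, position-specific quality-control
recognition (real cells degrade some near-neutral variants), measurement
error on ΔΔG itself, and phylogenetic structure in alignments. Passing
recovery tests therefore demonstrates the estimators are correct and well
calibrated under the model's own assumptions — not that the two-state
model is a complete description of any particular protein.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 50 replicate datasets for
each ΔG_WT recovery experiment (24 variants, 200 bootstrap refits each for
the abundance fit; 8 variants for the survival fit); 2,000 sequences for
the co-variation recovery; 10⁴ resamples for bootstrap tests and 2×10⁴ for
Monte-Carlo permutation tests; 855 positions for the full-saturation
enumeration and summary checks. Grid-search oracles run at 10⁻³ kcal/mol
resolution. These sizes give stable statistics at interactive runtimes.

Degenerate inputs are errors, not warnings: fits require ≥ 3 variants and
non-constant observations; anchored survival requires distinct anchors;
group tests require ≥ 2 values per group; single-class label sets are
rejected. Ties are resolved by documented fixed rules (AUC half-credit;
3.0 kcal/mol to the high group; LOO ties to the pathogenic side).

## Known limitations

- ΔΔG inputs are consumed as given; the typical ~0.8 kcal/mol error of the
  underlying energy functions propagates directly into every downstream
  quantity.
- The two-state model ignores local unfolding, partner-dependent
  stabilization and quality-control specificity; the fitted ΔG_WT is an
  *effective* cellular stability, not an in-vitro folding free energy.
- Bootstrap percentile bands slightly undercover at n ≈ 24 (see above).
- The pseudolikelihood fitter is dense and desk-scale (L up to a few
  hundred columns); it is not a GPU-scale DCA implementation.
- Homolog search and alignment construction are out of scope: the MSA is
  an input.
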