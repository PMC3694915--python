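# Methods

This note documents the models implemented in `platydate`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that matter.

## Rate model

The core assumption is the generation-time effect: germ-line mutations
accumulate mainly at DNA replication, so a lineage's substitution rate per
year is its per-generation rate divided by its generation time,
r = μ_gen/ḡ.  μ_gen is taken as an *interval*, the broadest published
human pedigree range [9.70×10⁻⁹, 1.36×10⁻⁸] subs/site/generation
(`rates.HUMAN_PEDIGREE_INTERVAL`), and is never point-estimated: all
downstream ages are intervals whose old/young ratio is exactly
1.36/0.970 ≈ 1.402.  Two identities follow and are asserted throughout:
r·ḡ returns the per-generation bound exactly, and for any dated node
t_fast·r_fast = t_slow·r_slow = h, the node's molecular depth.

Per-node generation times are configuration, not inference.  The packaged
`rate_config.json` carries the effective values
{Platyrrhini 16, Atelidae branching 16, Cebidae 15, Anthropoidea 16,
Catarrhini 19.5, Homo/Pan 27} yr, which reproduce the published per-node
rate pairs at 3 significant figures.  Only the Homo/Pan value is a simple
mean of tabulated extant genera (29 and 25 yr); the others are not
derivable from any obvious subset mean of the trait table (e.g. the
extant Cebus/Saimiri mean is 11.5 yr, not 15), so the averaging scheme
behind them is treated as unknown and exposed as explicit per-node
configuration rather than guessed.

## Trait allometry and imputation

Generation time is regressed on adult body mass on the **raw scale**
(grams, years): the raw-scale Pearson correlation reproduces the reported
0.89 on the 15 extant platyrrhine genera, whereas log-scale does not.
Three fitters are provided:

- `fit_quadratic` (default downstream): least squares g = a + bm + cm².
- `fit_linear`: the c = 0 restriction; its residual sum of squares is
  never smaller than the quadratic's (property-tested).
- `em_impute`: bivariate-normal missing-data EM on (mass, generation
  time), deterministic initialization from complete-case moments,
  convergence when the relative observed-data log-likelihood change is
  below 1e-8 (max 500 iterations); the log-likelihood trajectory is
  retained and asserted monotone.

The fit trains on the extant platyrrhines by default.  Under that
quadratic fit every tabulated fossil generation time at ≤ 3000 g is
reproduced within ±1.5 yr, and the 2700 g *Dolichocebus* prediction
(10.29 yr) rounds to the tabulated 10 yr.  The heaviest fossils
(*Stirtonia* 10 kg, *Protopithecus*/*Caipora* ~24 kg) sit outside the
extant platyrrhine mass range; their tabulated values (20–22 yr) exceed
the curve's extrapolation by ~2 yr and exact reproduction there is not
claimed.  Imputed values are rounded to the nearest year by default
(the reference table prints integers for fossils); rounding is
configurable.  A fit predicting a nonpositive generation time raises,
naming the genus.

A note on the "all primates" correlation: the extant table contains 19
genera, but the published value 0.907 corresponds exactly (0.9069) to the
18-genus set without *Gorilla*, whose 19-yr generation time at 71 kg
breaks the monotone trend; with *Gorilla* the raw-scale correlation is
0.74.  `select_subset(..., "study")` names that 18-genus set, alongside
`"platyrrhini"` (15) and `"all_extant"` (19).

## Relative rate screen

Tajima's 1-df test: for ingroup taxa A, B and outgroup C, m_A counts
sites with A≠B, B=C (uniquely derived on A), symmetrically m_B;
(m_A−m_B)²/(m_A+m_B) ~ χ²₁ under a clock, with (0,0) defined as a perfect
clock (p = 1).  Columns containing a gap or any non-ACGT symbol in any of
the three sequences are excluded (strictest reading).  P-values are
reported uncorrected and a taxon is flagged when it appears in any
significant comparison; flagged taxa are excluded before distance
computation (overridable).  Pair choice matters: all-pairs testing is
only meaningful among lineages expected to share a generation time —
under the model, cross-clade comparisons *should* fail the clock — so the
pipeline accepts an explicit pair list and the analysis scripts compare
within clades.  Empirical calibration (simulated clocklike 10 kb
triplets): type-I error ≈ 0.044–0.06 at α = 0.05 over 1000 replicates;
power ≈ 1.0 against a lineage with doubled rate.

## Clock dating

Distances: closed-form JC69, K2P and TN93 (default TN93) with pairwise
deletion of non-ACGT sites (complete deletion available); base
frequencies for TN93 are empirical per pair.  Saturated pairs (any log
argument ≤ 0, e.g. JC p ≥ 0.75) raise an error naming the pair.  The
implementation agrees with `ape::dist.dna` to ~10⁻⁴ relative.  Corrected
pairwise distances stand in for maximum-likelihood branch-length
re-estimation deliberately: the contribution being implemented is the
dating arithmetic, not the substitution-model machinery, and TN93 is the
richest model with a closed form.

Node heights: on a fixed rooted topology, minimizing
Σ_{i<j} (d_ij − 2h_lca(i,j))² is separable — each internal node's
unconstrained optimum is half the mean distance over the tip pairs whose
LCA it is.  Ultrametric monotonicity (child ≤ parent) is restored by
isotonic regression in the tree order: a violating child block is pooled
into its parent block with pair-count weights, always resolving the
violation whose child block is *highest* first.  Arbitrary merge order is
not exact (a premature merge can drag a parent block below a later
sibling); highest-first pooling matches an exhaustive active-set
enumeration oracle to 10⁻⁹ on hundreds of random ≤ 6-tip instances.
Pooled heights are clamped at zero (they are convex combinations of
nonnegative pair means, so this is a formality).

Ages: t_fast = h/r_fast, t_slow = h/r_slow, in Ma at 2 d.p.; displayed
rates at 3 significant figures.  Each node uses its own configured ḡ;
with mixed ḡ across nodes parent/child age order is not guaranteed and is
reported rather than enforced.  `reproduce_interval_table` audits any
published rate/age table via the t·r conservation identity; on the
packaged six-node table the identity holds within 0.03% and every upper
endpoint is recovered at 2 d.p.

## Calibration priors

A fossil calibration is T = offset + X with ln X ~ N(μ_log, σ_log²): the
offset (the fossil's age) is a hard floor, so "95% of mass between the
bounds" is operationalized as the 0.975 quantile sitting near the soft
maximum.  The table's "mean" and "standard deviation" are read in log
space (the BEAUti lognormal convention): under that reading all nine
packaged calibrations put the 0.975 quantile within 7.4% of the printed
soft maximum (Hominini 10.09 vs 10.00 Ma; root 65.58 vs 65.80 Ma),
whereas the real-space reading (provided via
`CalibrationPrior.from_real_space` and reported by the audit script)
misses by up to 44%.  Quantile and coverage are exact inverses
(round-trip tested to 1e-10).  No MCMC is run; the priors are audited as
the Bayesian analysis's inputs only.

## Synthetic data

`simulate_traits` draws masses uniformly on a range (default 300–10000 g,
the extant platyrrhine span) and adds Gaussian noise to the allometric
prediction, floored at 1 yr; a noise SD of ~1.7 yr matches the observed
allometric correlation of ~0.89 at the packaged quadratic fit's
signal variance.  `simulate_alignment` evolves sequences under HKY
(default κ = 2, equal frequencies) along a chronogram in which each
branch's expected length is duration×10⁶ × μ_gen/ḡ_branch.  Site
evolution is exact per-site exponential-waiting-time simulation,
vectorized per branch with branches visited in preorder, so output is
byte-reproducible for a given seed.  The default "true" per-generation
rate is the geometric midpoint of the human interval
(√(9.70×10⁻⁹·1.36×10⁻⁸) ≈ 1.149×10⁻⁸), chosen so the published interval
brackets truth symmetrically on the log scale.  The bundled study-like
chronogram places nodes at the midpoints of the published age intervals
(platyrrhine crown 24.4 Ma, anthropoid root 44.3 Ma, outgroup split
60 Ma) with ḡ = 16 yr on platyrrhine branches and 19.5–27 yr on
catarrhine ones.

What the generator does **not** emulate: among-site rate heterogeneity
(no Γ), indels and alignment error, GTR-level exchangeability asymmetry,
within-lineage generation-time change along a branch, and fossil
mass-estimation error.  Passing recovery tests therefore demonstrate the
correctness of the dating arithmetic under the model's own assumptions,
not robustness to their violation on real data.

Problem sizes: recovery uses 50 replicates of 20 kb ten-taxon alignments
(the nuclear-matrix scale), the rate-test calibration 1000 replicates of
10 kb triplets; both complete in seconds.  When generation time varies
along root-to-tip paths no single ḡ is "the" clade value;
`SyntheticTruth.effective_generation_times` returns the path-averaged
value consistent with the least-squares depth, and recovery experiments
configure nodes with it.  Coverage of the true age by [t_fast, t_slow]
is ~96–97% for nodes deeper than 5 Ma.

## Known limitations

- Topology is an input; no tree search, no bootstrap, no posterior.
- Distance-based depths lose efficiency relative to ML branch lengths at
  high divergence; saturation raises rather than down-weights.
- The per-node ḡ values that reproduce the published rates are shipped as
  data because the original averaging rule is underdetermined.
- The Tajima screen's default all-pairs mode flags both members of a
  significant pair; identifying *which* lineage deviates needs either the
  pair structure (as in the analysis scripts) or external information.
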