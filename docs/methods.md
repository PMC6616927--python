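# Methods

This note documents the models and procedures implemented in `beeftradeoff`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not establish.

## The synthetic herd generator

The generator emulates a finishing-cattle study in which ~30 animals carry 62
measurements across four parameters of interest: 3 Animal-Performance
variables (slaughter weight, ADG, FCR), 20 Carcass-Property variables
(weights, proportions, EUROP-style scores, pH, CIELAB colour), 28
Nutritional-Quality variables (lipid content plus 27 fatty-acid amounts,
proportions and ratios) and 11 Organoleptic-Quality variables (panel scores
0–100 for texture and flavour descriptors).

**Model.** Variables are grouped into planted blocks, each driven by a latent
factor. Variable *j* of block *c* is

    x_j = s_j * (lam_j * f_c + sqrt(1 - lam_j^2) * noise_sd * eps_j),

scaled and shifted into native units. Default loadings are 0.75–0.9 (within-
block correlations ≈ 0.55–0.8, which at n = 30 reproduces the 60–75% cluster
cohesiveness range typical of such data). `noise_sd` defaults to 1, so every
variable has unit variance before the native-unit transform.

**Structure across blocks** comes from two mechanisms:

* *Group composites.* Each NQ and OQ block loads (coupling 0.5 by default,
  i.e. half the factor variance) on a group-level composite, with an
  *orientation*: blocks whose high values mean better quality load
  positively, "higher is worse" axes (n-6/n-3, C16:0/C18:0, trans FA,
  bitter, rancid-fish, fatty-vs-metal, blood-acid) load negatively. The
  latent correlation between the NQ and OQ composites is the parameter
  `rho_nq_oq` (default −0.3): it is the single dial for how much nutritional
  and sensory quality truly co-vary. A coupling of 0.5 keeps the composite a
  meaningful driver of its group while leaving half of every block's variance
  block-specific.
* *Cross links.* An acyclic coefficient map between block factors encodes
  the structural narrative the models are supposed to rediscover: fatter
  carcasses carry more intramuscular lipid (+0.5), a lower PUFA/MUFA balance
  (−0.35) and more flavour intensity (+0.35); heavy fat depots penalize
  tenderness (−0.25); a high PUFA/MUFA balance promotes rancid-fish notes
  (+0.3); slaughter weight tracks carcass weight (+0.8). The coefficients
  bridging NQ and OQ are deliberately modest so that `rho_nq_oq` remains the
  governing dial for the NQ–OQ association (at ρ = 0 the links alone leave a
  data-level index correlation of about −0.05 at large n).

Factors are represented exactly as coefficient vectors over an iid-normal
basis, so every factor has population variance 1 after link propagation and
regeneration with one seed is bit-identical. Chroma and hue are computed from
the sampled a\*, b\* (convention: hue = ±π/2 when a\* = 0, with a warning).

**What the generator does not emulate:** measurement error structure
(instrument drift, panelist effects), missing data, diet or pen effects,
non-Gaussian tails, and the exact identities of the real 62-variable panel
(the default names are a plausible reconstruction; counts per group are
fixed at 3/20/28/11). Passing tests on synthetic herds therefore demonstrate
that the *pipeline* behaves as specified, not that any biological conclusion
transfers to real cattle.

## Pre-treatment

Standardization uses sample SDs (ddof = 1); zero-variance columns are
refused by name. Clustering of variables is hierarchical ascending
clustering around latent components: starting from singletons, the merge
chosen at each step minimizes the loss in total homogeneity
Σ<sub>clusters</sub> λ₁(R<sub>C</sub>) (λ₁ = leading eigenvalue of the
members' correlation matrix); ties break on the lowest variable index. The
cut at k is followed by a consolidation pass that moves single variables
between clusters while the criterion strictly increases — the standard
partitioning refinement of this literature, guaranteed to terminate.
Correlation (not covariance) matrices are used throughout, consistent with
standardized inputs; homogeneity is reported as a percentage of the variable
count. Each cluster latent is the first principal component of its members,
re-standardized and oriented to correlate positively with its
highest-loading member.

Summarization follows a declarative plan: AP variables pass through
unclustered; CP is clustered at k = 6 with carcass weight and pH kept as
representatives of their cluster (the rest absorbed); lipid content bypasses
the NQ clustering (k = 6 on the 27 fatty-acid variables) with n-6/n-3 kept
as a representative; tenderness and juiciness bypass the OQ clustering
(k = 5 on the 9 flavour variables). The result is always 24 standardized
indicators. If two latent seed variables land in one data-driven cluster,
the second indicator falls back to the seed variable itself (warned), which
keeps the layout intact on unlucky samples.

## Model selection

Per indicator, candidates are all indicators of the other three groups.
Families: OLS (pseudoinverse on singular designs, with a warning), ridge
(penalty by efficient leave-one-out CV over 25 log-spaced values 1e-3–1e3),
random forest (500 trees by default, seeded), PLS (components ≤ min(10, p)
by inner 5-fold CV; the CV costs one fit per fold because truncating the
rotation matrix yields every smaller component count), and SIR (5 quantile
slices ≈ 6 animals per slice at n = 30, first direction of the generalized
eigenproblem with a 1e-8 ridge, then a univariate linear link).

The race uses shared seeded 2/3–1/3 splits (50 by default; a conventional
ratio for n = 30), median test MSE as the champion criterion (robust to
occasional fit failures; a family failing > 20% of splits is disqualified),
and candidates in canonical table order so the champion is invariant to how
candidates are listed. Permutation importance permutes each candidate's test
column once per split (one seeded permutation per split, shared across
columns — a constant column therefore has importance exactly 0); a random
standard-normal probe processed identically provides the selection
threshold, with a top-1 fallback so no model is ever empty. The optimism
correction refits the champion family with the selected subset on B
bootstrap resamples (optimism_b = adjR² on the resample − adjR² of that
refit on the original data; corrected = apparent − mean optimism);
re-running family and predictor selection inside the bootstrap is not done
by default (tractability at B = 100), which makes the correction slightly
optimistic about the selection step itself.

## Sensitivity

First-order Sobol indices use the pick-freeze (Saltelli) estimator with two
independent standard-normal base matrices (default n_base = 10⁴ per model;
the linear-model oracle S₁ = 0.8 is recovered to ±0.02 at 10⁵). Inputs are
treated as independent, matching the standardized scale and the ±2σ OAT
range; the real indicators are correlated, so these indices describe the
fitted response surface, not a correlation-aware attribution — a documented
caveat. Negative Monte-Carlo estimates are clipped to 0 (logged); Σ Sᵢ is
reported as computed, since interaction effects legitimately push it below
1. One-at-a-time profiles evaluate the model on a 41-point grid over
[−2, 2] with the other predictors at 0; a predictor can combine a small Sᵢ
with a visibly sloped profile when interactions are present (a regression
test constructs f = 0.3x₁ + x₂x₃ to pin this behaviour down).

## Virtual animals

The anchor group defaults to Carcass Properties (the richest group, 7
indicators); it is selectable. Anchor coordinates are drawn independently
and uniformly from the 41-point grid and accepted only if every ordered pair
lies inside the 95% *prediction* interval of its pairwise regression fitted
on the real standardized indicators — a prediction interval, not a mean
confidence band, because candidates are individuals (the mean band is
available behind a flag and is much stricter). Rejection sampling is capped
(default 10⁵ draws per requested anchor) with an error suggesting a wider
level. Non-anchor indicators start at 0 and are updated for exactly 10
rounds; one random update order is drawn per round and shared by the whole
population, which makes the update a well-defined population map and allows
batched model predictions. Early stopping is deliberately not used; instead
the maximum absolute change in the last round is reported as a convergence
diagnostic (for linear models the iterate provably approaches the solution
of the induced linear system; tests check agreement to 1e-6 on constructed
contractions).

A structural consequence worth knowing: the procedure adds no residual
noise, so every virtual animal is a deterministic function of its anchor
vector. Correlations measured on a virtual population are therefore
*amplified* relative to the data — common-cause structure through the anchor
group survives undiluted, and with ~30 training animals the index
correlation of a single virtual population scatters widely (typically
|r| ≈ 0.2–0.4) around its structural value even when the generator's NQ–OQ
dial is zero. Aggregating over independent replicates (pooling populations
from several seeds) recovers the underlying association; single-population
correlations should be read with this in mind.

## Trade-off

Indexes are weighted sums of the standardized indicators (weights fixed by
expertise, |w| summing to 1 per index) and are re-standardized over the
population by default: the targets (±2, ±2) are meant in index standard
deviations, and raw weighted sums have SD well below 1, so without
re-standardization no animal would approach the targets (raw mode is a
flag). Correlation is Pearson with a two-sided t-test. Nearest-profile
selection is Euclidean in the (NQ, OQ) plane with ties broken by animal id;
the worst set is drawn from the population excluding the best set, so the
two are disjoint by construction. Wilcoxon rank-sum comparisons use the
exact null when both groups have ≤ 12 observations without ties and the
tie-corrected normal approximation otherwise; significance codes are ns,
\*\* (< 0.01), \*\*\* (< 0.001), \*\*\*\* (< 0.0001). No multiple-testing
correction is applied across the 24 indicators — a documented limitation;
with 30-vs-30 deterministic virtual animals the tests should be read as
descriptive contrast strength, not literal inference.

## Orchestration and reproducibility

A single master seed drives everything; each stage derives a named substream
(SHA-256 of `"{master}:{stage}"`, reduced below 2³¹), so stages can be
re-run in isolation with unchanged randomness. All interchange is CSV
(written at full repr precision, read with round-trip float parsing, so
write→read is bit-exact); fitted models are bundled in a versioned pickle
container. Two runs with one master seed produce byte-identical numeric
outputs.

## Problem sizes used by the test suite and acceptance script

The package defaults follow the analysis design (50 splits, B = 100, 500
trees, n_base = 10⁴, 500 virtual animals). The automated suites exercise the
same code paths at desk scale, chosen as the package's own test conditions:
the structural 24-model check and the recovery suite use 10 splits, B = 20,
30–60 trees and 200 virtual animals; the optimism suite uses B = 40 and 150
trees; determinism runs use 4 splits, B = 3, 25 virtual animals;
`scripts/acceptance.py` runs one full pipeline at 10 splits, B = 20, 150
trees, n_base = 4000 and 300 virtual animals. None of the asserted
properties (layout counts, oracle agreement, sign recoveries, optimism gaps,
byte-level determinism) depends on the full-scale settings.

## Known limitations

* Correlated-input sensitivity (Shapley-style attribution) is out of scope.
* The optimism correction does not bootstrap the model/predictor selection.
* The pairwise realism filter constrains pairs only; higher-order anchor
  combinations are not filtered.
* Virtual-population correlations are amplification-dominated at n = 30
  training animals (see above); replicate pooling is recommended.
* The clustering consolidation finds a local optimum of the homogeneity
  criterion (verified against exhaustive search on small planted cases).
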