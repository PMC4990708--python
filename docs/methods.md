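# Methods

This note documents the models, numerical choices and limitations behind
`bitelever`, in the package's own terms. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Trees and units

A `TimeTree` is a rooted tree with branch durations in millions of years
(Myr). Fossil tips simply end earlier than extant tips; no ultrametric
assumption is made anywhere. Branch lengths must be strictly positive:
under any Brownian-type model the variance contributed by a branch is
rate × duration, so a zero-duration branch makes its rate
unidentifiable, and we reject it at read time rather than degrade
silently.

Node ids are assigned in preorder after sorting every node's children by
the lexicographically smallest tip label in their subtree. Internal
nodes often carry no label, so "sort children by label" is implemented
through this subtree key; it makes node ids a pure function of the
topology, and posterior tables keyed by node id are therefore comparable
across runs, machines and (re)reads of the same Newick string.

Pruning to the taxa with data collapses degree-2 internal nodes by
summing durations. The original root is retained even if it is left
with a single child: re-rooting at the MRCA of the kept taxa would
shorten root-to-tip paths, and we treat "root-to-tip durations of kept
tips are preserved exactly" as the defining contract of pruning.

Trait measurements are in millimetres and are natural-logged at load.
The heterochrony ratio ln(RAP)/ln(HW) is a quotient of logarithms, so
its *level* depends on the unit convention (a regression test pins mm);
the shape of the trajectories and the inversion diagnostic do not.

## Single-trait models (BM, OU, EB)

The BM log-likelihood is computed by the pruning (contrasts) algorithm:
one post-order pass yields the GLS root estimate, its variance, the log
determinant of the unit-rate tip covariance and the contrast sum of
squares, from which the density at any (σ², root) follows. The ML rate
uses divisor n (true ML, comparable with AIC); the REML value (divisor
n − 1) is reported alongside. When all tips are identical the rate sits
on the σ² = 0 boundary; the fit is flagged degenerate instead of
returning a spurious interior optimum.

OU is parameterised with the root state fixed and equal to the optimum,
using the Hansen covariance
cov(i, j) = σ²/(2α) · e^(−α·(dᵢ+dⱼ−2tₐ)) · (1 − e^(−2α·tₐ)),
where tₐ is the shared path duration and dᵢ tip depths. On
non-ultrametric trees the familiar stationary form is invalid (fossil
tips have not "forgotten" the root), hence the fixed-root form and a
dense-matrix evaluation; trees here are small (tens to a couple hundred
tips), so the O(n³) profile evaluations are negligible. EB rescales each
branch by ∫ e^(g·t) dt over the branch's time interval and reuses the BM
machinery. Both shape parameters are profiled by bounded scalar
optimisation (α ∈ [1e−8, 50/T], g ∈ [ln(1e−6)/T, 0], T = tree height);
the α → 0 and g → 0 limits reproduce the BM likelihood, which the tests
check. AIC is the headline criterion and AICc is emitted alongside,
since the choice between them is not fixed by the problem.

## The mvBM model and sampler

Generative model, per branch b with duration t_b:

    x_child | x_parent ~ Normal(x_parent, σ² · r_b · t_b)
    ln r_b ~ Normal(0, ν²)  independently per branch
    σ² ~ Inverse-Gamma(shape a₀, scale b₀),  flat prior on the root.

Defaults: ν = 1 (multipliers typically within e^±2 of 1), a₀ = b₀ = 0.5
(weak; with dozens of branches the likelihood dominates), 100 000
iterations, 20% burn-in, thinning 10, proposal sd 1.5 on ln r. The
iteration count is a config value: production analyses raise it,
desk-scale runs complete in seconds. The proposal sd was set so the
multiplier acceptance fraction sits mid-band (~0.5) on trees of this
scale; acceptance outside [0.1, 0.6] triggers a diagnostic warning, not
an error. ν = 0 pins every multiplier at 1, giving single-rate BM
exactly.

The sampler is Metropolis-within-Gibbs:

* **Node states** have normal full conditionals assembled from the
  precisions 1/(σ²·r·t) of their incident branches. Because a parent and
  child always differ in depth parity, the tree is two-colorable and all
  nodes of one color are conditionally independent given the other; each
  sweep therefore updates the two color classes as two vectorised
  draws — mathematically identical to one-at-a-time Gibbs, but it keeps
  a 100k-sweep chain in numpy rather than Python loops. Tips are data
  and are never touched.
* **σ²** is conjugate inverse-gamma given states and multipliers.
* **ln r_b** uses vectorised random-walk Metropolis: conditional on the
  states, each branch's likelihood involves only its own increment, so
  all branches propose and accept independently in one step.

Initialisation: internal states by post-order child averages, r ≡ 1,
σ² at the BM ML estimate — a point well inside the typical set, so short
chains are usable. All randomness flows through a single seeded
generator; identical config yields bit-identical output, which the CLI
manifest relies on. The log joint density is checked finite at every
retained sample. Effective sample sizes (arviz) are reported for the
root-state and σ² chains.

In the ν → 0 limit the posterior over node states is the single-rate BM
conditional, and the tests verify the posterior means against the dense
joint-normal conditional means (with an effectively flat root prior) on
small trees, within Monte-Carlo error.

### What branch-rate inference can and cannot resolve

Each branch contributes exactly one Gaussian increment, so the evidence
about r_b is one standardized deviation s = Δx²/(σ²·t). A branch
simulated at 25× the base (variance) rate yields s = 25·z² with
z ~ N(0,1); ranking branches by the *true* s (states known) top-ranks
that branch only ~57% of the time on a 64-tip tree, because a quarter of
the time |z| < 0.32 and the fast branch simply left no footprint. The
sampler, which must also integrate over latent ancestral states, sits
somewhat below that ceiling (40–55% in the acceptance runs). Single-
branch detection is therefore reported as a measured fraction, not
presumed reliable; multipliers are well calibrated in aggregate
(credible-interval coverage of r = 1 on single-rate data is checked at
≥ 90%), and group-level separation of fast versus slow branches is what
the recovery tests assert.

## Rate space and scenario classification

Per-branch signed rates are (child − parent posterior mean)/duration,
in ln-units per Myr, for each trait; signs matter because the scenarios
distinguish increase from decrease, which absolute rates cannot. The
isometry reference is the reduced-major-axis line through the
(HW-rate, RAP-rate) cloud — slope sign(r)·sd(y)/sd(x), intercept through
the means — and a branch's residual is its vertical offset from that
line. Classification (u = HW rate, v = RAP rate, resid):

| condition | label |
|---|---|
| u > 0, v > 0, resid > +tol | AI (accelerated increase) |
| u > 0, v > 0, resid < −tol | DI (decelerated increase) |
| u ≤ 0, v > 0 | SEP_POS (lever elongates, body shrinks/holds) |
| u < 0, v < 0, resid > +tol | DD (decelerated decrease) |
| u < 0, v < 0, resid < −tol | AD (accelerated decrease) |
| u ≥ 0, v < 0 | SEP_NEG |
| otherwise (on the line, or v = 0) | ISO |

The tolerance defaults to 1e−9 ln-units/Myr; exact ties occur only in
constructed fixtures. The labels are exhaustive and exclusive, and
negating both rate vectors (and refitting the line) swaps AI↔AD, DI↔DD
and SEP_POS↔SEP_NEG, which the tests exercise on random clouds. Point
estimates use posterior means; `scenario_probabilities` propagates
paired posterior draws instead, refitting the RMA line per draw, when
per-branch label uncertainty is wanted. Branch painting emits annotated
Newick, a scenario census, and the longest contiguous root-ward AI run
ending at each tip — the "continuous accelerated-increase trend"
diagnostic for lineages leading to living taxa.

Whether residuals should be taken about the RMA line of the rates
themselves or about a separate prior regression is genuinely open; the
RMA-of-rates construction is the simplest one consistent with the
six-scenario geometry and is the package's definition.

## Heterochrony trajectories

Ontogenetic stages are equal-width bins of ln(HW) between the series
minimum and maximum (equal-count quantile bins are a config option);
"progressive stages of body size" reads most naturally as equal spans of
log size. Evolutionary stages map ancestor-chain entry k of m
(root-first, 1-based) to stage ⌈10·k/m⌉, so the earliest ancestors fall
in stage 1 and the focal tip in stage 10 regardless of chain length.
The stage value is the mean of ln(RAP)/ln(HW) over members; ln(RAP/HW)
is available behind the `ratio` switch, since the quotient-of-logs
convention, while the package default, is not the only defensible one.

The inflection of a trajectory is the interior stage (2..9) with the
largest absolute second difference of stage means, ties to the earliest
stage, undefined where a neighbour bin is empty, and suppressed entirely
when the largest second difference is below 1e−6 (flat or linear
trajectories have no inflection). Inversion = ontogenetic inflection
strictly earlier than the evolutionary one. A visual judgement in the
source material becomes, here, a reproducible operator; the maximum-
curvature definition is the package's choice.

## Synthetic data

`simulate_tree` is a Yule process (default 0.02 speciations/lineage/Myr,
giving ~200-Myr-deep trees at 36 taxa); a fossilisation switch truncates
a chosen fraction of terminal branches at uniform random heights,
mimicking a fossil-rich, non-ultrametric phylogeny. `simulate_mvbm`
walks the tree in preorder with Normal(0, σ²·r·t) increments and records
every node state and multiplier as truth.

`simulate_ontogeny` emulates a 34-specimen developmental series as a
biphasic log-log allometry: ln(rap) = ln(a₁) + b₁·ln(hw) up to a
breakpoint, continuing with slope b₂ (continuous at the break), with
multiplicative noise on RAP only. Defaults: HW 20–300 mm (hatchling to
large adult; total length back-computed at ~12× head width, spanning
roughly 24–360 cm), a₁ = 0.08, b₁ = 1.4, b₂ = 0.9 (early positive
allometry, then deceleration), breakpoint 40 mm — about a quarter of the
way through the ln(HW) range, i.e. in stage 3 of 10, roughly where a
young crocodylian first accesses robust prey — and noise sd 0.05.
Specimens are placed evenly in ln(HW): a developmental series is a
deliberately size-structured sample, not a random draw, and even
placement makes the noise-free trajectory deterministic. What this
generator does *not* emulate: measurement error on HW, heteroscedastic
growth noise, sampling gaps, or individual growth-curve variation — so
passing tests demonstrate correctness of the pipeline on idealised
allometries, not robustness to all features of field data.

`simulate_evolution_chain` produces an ancestor chain whose
ln(RAP)/ln(HW) ratio is constant until a relative depth (default 0.8)
and then rises linearly to a higher ratio at the tip — the "late
evolutionary acceleration" pattern, with 15 entries by default so the
stage mapping matches a 15-node ancestor chain.

## Problem sizes and determinism

Default test and acceptance sizes: trees of 8–200 tips, mvBM chains of
20k–100k iterations, 20–50 replicates per stochastic property — sizes at
which every statement above is checked in about a minute each while
remaining at the scale of the study system. Every stochastic routine
takes an explicit seed, and the pipeline writes a manifest (config,
seed, version) sufficient to reproduce its outputs byte-for-byte.

## Known limitations

* Traits are modelled independently; there is no correlated-trait mvBM,
  so rate-space geometry inherits any dependence between the two chains
  only through the data.
* The mvBM model has no explicit optima ("adaptive peaks"); rate
  heterogeneity is the only non-BM ingredient. Shift-point or
  multi-optimum OU analyses are out of scope.
* Scenario labels from posterior means understate uncertainty; use
  `scenario_probabilities` when label confidence matters.
* Single-branch rate detection is information-limited (see above);
  treat per-branch multipliers as screening statistics, not verdicts.
* Stage binning conventions (equal-width vs equal-count, quotient vs
  difference of logs) change trajectory levels; both are exposed as
  options and the defaults are stated above.
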