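# Methods

This note documents the models implemented in `chronodiv`, the
conventions they rely on, the synthetic-data generators used to test
them, and the limitations of both.

## Time conventions

Two clocks are used consistently:

* **age** — Myr before present; tips are at age 0, the root at
  `root_age`.  User-facing thresholds, breakpoints, and sea-level
  intervals are ages, matching the Ma axis of dated phylogenies.
* **t** — Myr since the root, `t = root_age − age`.  All likelihood
  integrals run forward in t.

Lineage counts are right-continuous: a branching event at time t counts
toward N(t) from t onward.  This makes ∫N(t)dt equal the sum of edge
lengths exactly, which the test suite verifies to 1e-9.  A
multifurcation of out-degree m contributes m−1 branching events at the
same age.  Divergence between two species is the age of their most
recent common ancestor (not twice it).

Ultrametricity is validated on input with a relative tolerance
(default 1e-6, configurable) because chronograms from dating software
carry rounding noise.

## Pure-birth likelihood

For a reconstructed chronogram with n tips and speciation rate λ(t):

    log L = Σᵢ log λ(tᵢ) − ∫₀ᵀ N(t) λ(t) dt + log((n−1)!)

over the n−2 non-root branching times; the root split is conditioned on
and contributes no rate factor, and no survival conditioning is needed
because an extinction-free process always survives.  The log((n−1)!)
labelled-histories constant is included so absolute values match the
classic LTT-likelihood convention; every AIC comparison is invariant to
it.  If any event falls where λ=0 the log-likelihood is −∞.

Rate families and their free-parameter counts k:

| family | λ(t) | k | fit |
|---|---|---|---|
| constant | λ | 1 | closed form λ̂=(n−2)/X, SE λ̂/√(n−2) |
| piecewise, m epochs | λⱼ between breakpoint ages | 2m−1 | analytic per-epoch MLE, breakpoints profiled on a grid |
| logistic | 1/(1+e^{−(at+b)}) | 2 | Nelder–Mead multi-start, observed-information SEs |
| sea-level step | λ_high in high-stand ages, λ_low elsewhere | 2 | analytic pooled MLE per state |

Epochs are half-open: an event exactly at a boundary age belongs to the
**younger** epoch — a deterministic tie-break that only matters on
measure-zero configurations of real data.

The logistic form uses t (time since root), so a < 0 means a rate
declining toward the present — the direction of a diversification
slowdown.  Its integral against N(t) has an exact primitive
(softplus/a per inter-event interval); when |a|·Δt < 1e-6 the primitive
difference cancels catastrophically in floating point, so a midpoint
evaluation (error O((aΔt)²)) is substituted.  The implementation is
cross-checked against adaptive quadrature in the tests.

### Breakpoint profiling and trimming

The profile likelihood in a breakpoint age is continuous but kinked at
branching ages, so breakpoints are profiled by exhaustive search over
the midpoints between consecutive distinct branching ages plus a
uniform grid (default 0.1 Myr), deduplicated.  The search is
**trimmed**: each epoch must contain at least `min_epoch_frac`
(default 0.15) of the non-root events, floored at one event and capped
so a feasible partition always exists.  Without trimming the supremum
is dominated by spurious spikes from near-empty epochs at the very
edges of the tree — the same pathology that motivates the 15% trimming
convention in structural-break testing — which inflates the apparent
support for rate shifts on constant-rate trees.  `min_epoch_frac=0`
restores the raw supremum.  Epoch rates are indexed oldest-first.

Rate SEs in multi-rate models are Poisson (λ̂ⱼ/√eventsⱼ).  Breakpoint
ages get no SE: the profile has zero curvature between branching ages,
so an observed-information SE is not defined for them.

### Birth–death

The constant-rate birth–death fit maximises the reconstructed-process
likelihood conditioned on the root split and survival of both root
lineages, parameterised as (r, a) = (λ−μ, μ/λ) with bounds r > 0,
0 ≤ a < 1.  At a = 0 it equals the constant Yule likelihood, so the
models nest.  The implementation reproduces `ape::birthdeath` exactly
(verified against it on fixture trees).  On data generated without
extinction, μ̂ sits on its zero boundary roughly half the time — the
expected behaviour for a boundary-true parameter, whose estimator is
asymptotically normal around 0 with the negative half clipped.  μ gets
no SE when the estimate is on the boundary.

### LTT curves, envelopes, window rates

The LTT curve steps from 2 (the root split) to n.  Envelopes simulate
the fitted model conditioned on the observed (n, root_age) by rejection
sampling and take pointwise 2.5/97.5% quantiles of the lineage count on
a shared time grid (default 101 points, ≥100 replicates).  Window rates
partition [0, root_age] into fixed-width age windows (default 10 Myr),
half-open toward the past with the youngest window touching the
present; each window reports (non-root events)/(lineage-time), and a
window with zero lineage-time reports a missing rate, never 0.

Model comparison uses raw AIC = −2 log L + 2k; the best model is the
minimum, ties broken toward fewer parameters.  Models that are
infeasible on a given tree (e.g. more epochs than events) are skipped
with a warning rather than aborting the table.

## Community structure

Δ^P_S pools all (site, co-occurring pair) instances with equal weight
per instance; Δ^P_T averages over all distinct pairs in the pooled
species set of the analysis (species present in at least one site).
Both restrict to pairs with divergence strictly below the threshold T.
An alternative Δ^P_T over cross-site pair instances is available via
`delta_t_mode="between_sites"`; the default is the pooled definition.
The per-instance (rather than per-site-mean) weighting of Δ^P_S is a
choice; the worked-example arithmetic is insensitive to it.

The partial-randomization null permutes species identities uniformly
within each maximal clade whose crown age is below T, leaving deeper
structure fixed — cross-block divergences are invariant because, on an
ultrametric tree, every member of a block is equidistant from every
tip outside it (a property the tests check).  `null_mode=
"truncate_only"` instead shuffles the whole tip set and relies only on
the pair-set truncation.  Defaults: R = 999 replicates, add-one
permutation p-values ((#{null ≥ obs}+1)/(R+1), ties counted as
extreme), empirical 2.5/97.5 percentile CIs with linear interpolation.
A threshold below every divergence leaves the statistic undefined; the
direct test raises, and the profile reports the row as untestable.
Report tables round to 3 decimals, half away from zero, so worked
examples recomputed from rounded published inputs can differ by ±0.001.

Default threshold grids: every 5 Myr (5–50) at the regional scale,
every 10 Myr (10–50) at the local scale.

Community summaries report, per island × habitat group: site counts,
total and mean ± SD richness, mean ± SD pairwise Sørensen similarity
2c/(A+B) within the group (missing for single-site groups), and the
island-level mean over cross-habitat site pairs.

## Synthetic data

Trees are grown forward from the two root lineages.  Waiting times are
exponential at the total rate N·λ; time-varying families use Ogata
thinning with the family supremum over the simulated span as bound,
which is exact because N is constant between events.  Stopping is
either at fixed duration, or at a tip count (allowed only for
t-indexed families, i.e. constant and logistic, since age-indexed
rates are undefined without a known depth); tip-count stopping
completes the final inter-event interval, under which convention
λ̂ = (n−2)/X is exactly unbiased (λX is then Gamma(n−1, 1)).
Conditioned simulation (exact n and root age) rejection-samples
fixed-duration runs and errors out, with advice, if the acceptance
probability is too low within the attempt cap.

Community assembly modes and what they emulate:

* **neutral** — uniform sampling without replacement; the
  random-sorting null of community assembly.
* **filtered** — inclusion weights exp(−strength·|trait − optimum|)
  with a unit-rate, root-zero Brownian trait (only relative distances
  matter); produces phylogenetic clustering, as under habitat
  filtering.
* **dispersed** — sequential draws rejecting species within `strength`
  Myr of any resident; produces dispersion, as under limiting
  similarity.  Sites that cannot reach target richness are left
  partial with a warning.
* **recent_allopatry** — both members of every cherry younger than
  `strength` Myr are placed in different sites and the remaining
  richness filled neutrally from non-cherry species, so no site holds
  both members of a young pair.  This reproduces the signature of
  recent allopatric speciation: Π_ST strongly negative at small
  divergence thresholds, near zero at the full-tree threshold.

The sea-level fixtures provide a fixed two-interval toy table and a
seeded random alternation of high/low stands over ages 0–30 Ma; older
ages stay low-stand because so few lineages exist there that the
covariate is uninformative.

What the generators deliberately do not emulate: extinction (no
birth–death simulation), biogeographic range evolution, abundance
structure (presence/absence only), detection error, and spatial
autocorrelation among sites.  Passing tests therefore demonstrate
internal consistency of estimators and tests under the stated
processes, not robustness to these real-data complications.

## Experiment sizes used in the test suite

The consistency and calibration experiments use sizes chosen to give
comfortable statistical resolution: constant-rate recovery over 500
100-tip trees (3-SE check, exactly unbiased by construction);
breakpoint recovery over 50 trees of ~140 tips with a 0.15→0.05 shift
at 10 Ma (median |τ̂−τ| ≤ 3 Myr; observed ≈ 0.2 Myr); sea-level-rate
recovery over 50 trees (≤15% mean error); permutation-null calibration
over 200 neutral datasets at R=199 (two-sided 5% rejection within
[1%, 11%]); the allopatry signature over 100 replicates (sign test
p < 0.01); and model-selection sanity over 50 single-rate and 50
strong-shift trees.

## Known limitations

* Free-breakpoint search supports up to three epochs (two breakpoints);
  more epochs require fixed breakpoints.  The two-breakpoint grid is
  O(candidates²) in memory.
* No extinction-through-time estimation and no dating: chronograms are
  inputs, taken as correct.
* Conditioned tree simulation is rejection-based and becomes expensive
  when the rate model is a poor match for the requested (n, root_age).
* The Π_ST machinery treats samples as species lists; abundance-based
  variants are out of scope.
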