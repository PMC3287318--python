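# chronodiv

Diversification rates and phylogenetic community structure on ultrametric
chronograms.

`chronodiv` is aimed at evolutionary ecologists who have (a) a dated,
ultrametric phylogeny of a species pool — for example Indo-Pacific
coral-reef fish families on a ~50-Myr chronogram — and (b) binary
species × site occurrence records from surveys of that pool.  It answers
two linked questions:

1. **How did the pool diversify through time?**  Time-dependent
   pure-birth (Yule) models with constant, piecewise (rate-shift),
   logistic, and sea-level-covariate speciation rates λ(t) are fitted by
   maximum likelihood and compared by AIC, alongside a constant-rate
   birth–death fit, lineage-through-time (LTT) curves with simulation
   envelopes, and per-window rate estimates.
2. **Is community membership structured by phylogeny?**  The Π_ST
   statistic partitions mean phylogenetic divergence into a within-site
   component Δ^P_S and a total-pool component Δ^P_T,

   Π_ST = (Δ^P_T − Δ^P_S) / Δ^P_T,

   with Π_ST > 0 indicating phylogenetic clustering within sites and
   Π_ST < 0 dispersion.  Computing Π_ST only over species pairs that
   diverged less than T Myr ago, and permuting species identities only
   within clades younger than T ("partial randomization"), profiles the
   community structure through time.

## The models

For a chronogram with n tips, root age T and lineage count N(t), the
time-dependent pure-birth log-likelihood conditioned on the root split is

    log L = Σᵢ log λ(tᵢ) − ∫₀ᵀ N(t) λ(t) dt + log((n−1)!)

summed over the n−2 non-root branching times tᵢ.  A constant rate has the
closed-form MLE λ̂ = (n−2)/X with X the total branch length; piecewise and
sea-level models have analytic per-epoch MLEs (events / lineage-time) with
breakpoints profiled over an exhaustive, trimmed grid; the logistic family
λ(t) = 1/(1+e^{−(at+b)}) is fitted numerically.  The birth–death model uses
the standard reconstructed-process likelihood conditioned on the survival of
both root lineages (it reproduces `ape::birthdeath` exactly).

## Worked example

```python
import chronodiv as cd

# a 2-epoch pure-birth tree: rate drops 0.15 -> 0.05 at 10 Ma
truth = cd.PiecewiseRate((0.15, 0.05), (10.0,))
tree  = cd.simulate_yule_tree(truth, duration=35.0, seed=7)   # 83 tips

table, fits = cd.compare_models(tree, intervals=cd.sea_level_fixture("toy"), seed=0)
print(table[["model", "logL", "k", "AIC", "best"]].to_string(index=False))
```

```
          model      logL  k        AIC  best
           yule  3.348623  1  -4.697246 False
    birth_death  3.348623  2  -2.697246 False
      sea_level  3.623649  2  -3.247298 False
       logistic  6.380342  2  -8.760684 False
 one_breakpoint 11.981753  3 -17.963506  True
two_breakpoints 13.946030  5 -17.892061 False
```

AIC selects the one-breakpoint model, whose fit recovers the generating
regime — old rate 0.146 ± 0.022, young rate 0.058 ± 0.010, shift at
10.4 Ma against a truth of 0.15 / 0.05 / 10 Ma:

```python
print(fits["one_breakpoint"].summary())
```

```
Diversification fit: piecewise_2_epochs
  n tips: 83   root age: 35 Myr
  log L = 11.9818   k = 3   AIC = -17.9635
  converged: True
  parameters:
    lambda_1 = 0.145698 +/- 0.02172
    lambda_2 = 0.0575037 +/- 0.009584
    tau_1 = 10.4
```

Communities assembled under recent allopatry (young sister species split
across sites) show the expected threshold-dependent signature — strong
dispersion among recent divergences, none at the full-tree scale:

```python
occ = cd.simulate_communities(tree, n_sites=3, richness_per_site=20,
                              mode="recent_allopatry", strength=5.0, seed=8)
print(cd.PiStTest(occ, tree, threshold=35.0).fit(reps=999, seed=10).summary())
```

```
Pi_ST at threshold 35 Myr
  obs: Delta_S = 25.511  Delta_T = 25.072  Pi_ST = -0.018
  null (R=999): mean = 0.003  SD = 0.010  CI = [-0.014, 0.023]
  one-sided p: obs<exp 0.010   obs>exp 0.991
```

At threshold 5 Myr the same data give Π_ST = −0.377 (within-site pairs
are far more divergent than the recently diverged pool pairs, because
young sisters never co-occur).

## Command line

The `chronodiv` command orchestrates the full pipeline:

```sh
chronodiv simulate --mode recent_allopatry --out-dir data/
chronodiv run --tree data/tree.nwk --occurrence data/occurrence.csv \
              --metadata data/metadata.csv --intervals data/sea_levels.csv \
              --seed 1 --out-dir report/
```

`run` writes the model-comparison table, LTT + envelope, window rates,
regional (among-island) and local (inner-reef vs outer-slope) Π_ST
profiles, community summaries (richness and Sørensen similarity
2c/(A+B)), and a JSON manifest that makes every table reproducible.
Individual stages are available as `fit-diversification`, `ltt`,
`pist-profile`, `summarize`.

## Documentation

See `docs/methods.md` for the model definitions, conventions (time
directions, epoch boundary rules, likelihood constants), the synthetic
data generators, and known limitations.
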