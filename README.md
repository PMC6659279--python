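# fadesat

Fatty-acid desaturation indices and phylogenetic model selection for
comparative analyses of mammalian adipose tissue.

Mammals store most fat as triacylglycerols whose fatty-acid (FA) makeup sets
how cold the tissue can get before it stiffens. Species that cannot rely on
fur — seals, otters and other semi-aquatic mammals above all — are expected
to shift their superficial fat toward unsaturated FAs at colder (higher)
latitudes. Testing that idea across species requires (i) summary indices of
desaturation computed from published FA composition tables and (ii)
regression models that respect the non-independence of related species.
`fadesat` provides both, plus a synthetic-data generator so the entire
pipeline can be exercised and validated without any external data.

## What it computes

**Desaturation indices.** From a per-species wt% composition profile:

- Δ9-desaturation index, the ratio of the five Δ9-pathway monounsaturates to
  their three saturated precursors (a proxy for endogenous Δ9-desaturase
  activity; dietary polyunsaturates are excluded):

      Δ9-DI = (wt%14:1ω5 + wt%16:1ω7 + wt%16:1ω9 + wt%18:1ω9 + wt%18:1ω7)
              / (wt%14:0 + wt%16:0 + wt%18:0)

- double-bond index over *all* FAs, which also reflects dietary PUFAs:

      DBI = Σ xᵢ · wt%ᵢ / 100        (xᵢ = number of double bonds of FA i)

FA labels are parsed from the common dialects (`16:1ω7`, `16:1w7`,
`16:1n-7`, `16:1(n-7)`) and canonicalised.

**Phylogenetic GLS with Pagel's λ.** The regression y = Xβ + ε assumes
ε ~ N(0, σ²·V(λ)), where V is the Brownian-motion covariance implied by the
tree (shared root-to-MRCA branch length) and λ ∈ [0, 1] scales its
off-diagonal — λ = 0 is phylogenetic independence, λ = 1 full Brownian
covariance. β and σ² are profiled analytically through Cholesky whitening;
λ is estimated by bounded maximum likelihood. Models are compared by AICc
(small-sample-corrected AIC) and Akaike weights, with evidence ratios
w_a/w_b = exp((ΔAICc_b − ΔAICc_a)/2). Because published supertrees contain
polytomies, every fit can be repeated across many random (zero-branch-length)
polytomy resolutions and aggregated.

**The study designs.** Ready-made model suites compare environment
(terrestrial / semi-aquatic / fully-aquatic), latitude, their interaction and
a null model against either index; a second suite tests latitude versus
(log) hair density in semi-aquatic species. Helpers extract per-environment
latitude slopes with 95% CIs (significance = CI excludes 0), per-environment
means ± SD, a pinniped blubber-section (outer layer vs whole core)
subanalysis, and plain OLS regressions of individual FAs on latitude.

## Worked example

```python
from fadesat import MAIN_SUITE, run_model_suite
from fadesat.simulate import SimulationConfig, simulate_traits, simulate_tree

cfg = SimulationConfig(seed=7, n_tips=54, true_lambda=0.5, polytomy_fraction=0.25)
tree = simulate_tree(cfg)                       # ultrametric, with polytomies
records, truth = simulate_traits(tree.resolve_polytomies(7), cfg)

result = run_model_suite(records, tree, "delta9_di", MAIN_SUITE, n_iter=50, seed=1)
print(result.table().to_string(index=False))
print(result.env_slopes.to_string(index=False))
```

prints (model ranking first, then per-environment latitude slopes):

```
           model  delta_AICc  PGLS_lambda  effect_size_r  weighted_AICc
     interaction    0.000000     0.200150       0.875387   9.999999e-01
        additive   33.259395     0.000000       0.739888   5.995344e-08
   latitude_only   37.675442     0.696880       0.399851   6.589945e-09
environment_only   39.061396     0.000000       0.686920   3.295533e-09
            null   50.595141     0.601489            NaN   1.031347e-11

  environment     slope    ci_low  ci_high  significant
  terrestrial -0.018038 -0.038020 0.001943        False
 semi_aquatic  0.070923  0.053858 0.087988         True
fully_aquatic -0.001525 -0.025246 0.022196        False
```

The data were generated under the interaction model (true semi-aquatic slope
0.06, true λ = 0.5) and the suite recovers exactly that structure: the
interaction model takes essentially all the Akaike weight and
only the semi-aquatic slope's CI excludes zero. The scripts in `examples/`
walk through each capability (indices, λ estimation, model selection, the
full simulate → reproduce round trip); the `fadesat` command exposes the
same pipeline from a shell (`indices`, `pgls`, `reproduce`, `simulate`).

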