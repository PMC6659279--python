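# Methods

## Desaturation indices

Two summaries are computed from per-species FA composition profiles
(percent by weight):

- **Δ9-desaturation index.** Ratio of the five Δ9-pathway monounsaturates
  (14:1ω5, 16:1ω7, 16:1ω9, 18:1ω9, 18:1ω7) to the three saturated
  precursors (14:0, 16:0, 18:0). These MUFAs can be produced endogenously
  by Δ9-desaturation of the corresponding SFAs, so the ratio proxies
  desaturase activity rather than diet. Polyunsaturates never enter.
- **Double-bond index.** Σ (double bonds × wt%)/100 over every FA in the
  profile, saturates contributing zero. Because dietary PUFAs carry most
  double bonds, DBI moves with diet in a way Δ9-DI does not; the contrast
  between the two indices is what separates endogenous desaturation from
  dietary signal.

Numerical choices: FAs named in the Δ9-DI formula but absent from a profile
count as zero wt% with a logged warning (published composition tables omit
trace FAs inconsistently); a zero saturated denominator is an error, not an
infinity. Profiles are *not* renormalised to a 100% total before index
computation — both indices are ratios or weighted sums of the reported wt%
values, so renormalisation would only matter for DBI, and source tables are
used as printed; a `renormalize` option exists for callers who want it.
wt% totals outside 100 ± 5 (configurable) raise warnings, never silent
changes. Branched-chain FAs (iso/anteiso) parse as saturated and are
excluded from Δ9-DI by construction. The ω-dialect table (`ω`, `w`, `n-`,
`(n-)`) is module-level and extensible; unknown dialects fail loudly.

## PGLS with Pagel's λ

The regression model is y = Xβ + ε with ε ~ N(0, σ²·V(λ)). V is the
Brownian covariance of the tree (V[i,j] = root-to-MRCA shared path length);
Pagel's λ multiplies its off-diagonal, interpolating between a star phylogeny
(λ=0) and full Brownian covariance (λ=1). Estimation:

- β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, computed by whitening with the Cholesky factor of
  V and solving the whitened least-squares problem by QR — no explicit
  inverse is ever formed (the explicit-inverse formula serves as the test
  oracle instead).
- σ̂² = rᵀV⁻¹r/n (ML profile); lnL = −n/2·ln(2πσ̂²) − ½ln|V| − n/2.
- λ̂ maximises the profile likelihood on [0,1] by bounded Brent search
  (tolerance 1e-6) with explicit endpoint checks at 0 and 1. λ is capped at
  1 by definition of the transform used, not at the larger
  positive-definiteness bound.
- Standard errors scale σ̂² by n/(n−p) (the unbiased adjustment); CIs are
  t-based with n−p degrees of freedom. "Significant" always means the 95%
  CI excludes zero.
- Degenerate inputs: rank-deficient designs raise an error naming the
  collinear columns (QR with pivoting); a saturated model (n = p) is refused
  because σ̂² = 0 exactly; non-positive-definite V is an error.

**Model selection.** AICc = −2lnL + 2k + 2k(k+1)/(n−k−1). The parameter
count is k = p + 2 when λ is estimated (p regression coefficients, σ², λ)
and p + 1 at fixed λ — a convention choice, logged in each fit, matching
common practice for λ-PGLS model selection. Akaike weights are normalised
exp(−ΔAICc/2); the evidence ratio of two models is the ratio of their
weights. Ties in ΔAICc rank deterministically by fewer parameters, then
model name. Effect size r = √(1 − RSS_model/RSS_null) with each RSS taken
in that model's own V(λ̂)-whitened space, clipped to [0,1]; the intercept-only
model is refitted with its own λ̂ on the same data.

**Polytomy handling.** Supertrees contain unresolved nodes. Each
multifurcation is resolved by repeatedly joining a uniformly chosen pair of
children under a new zero-length internal edge until binary — zero-length
edges leave every pairwise tip distance, and hence V, exactly unchanged, so
the randomisation explores topology labellings without perturbing the
covariance; for a trichotomy the three rooted shapes are equiprobable.
Per-iteration seeds derive from (master seed, iteration counter) via a seed
sequence and are recorded in the per-iteration table, making any run
reproducible from the master seed. Across iterations both the mean
(headline, used for ΔAICc ranking) and the median of AICc, λ̂, β̂ and CI
bounds are reported, since an aggregation rule is not uniquely canonical.
A fully binary tree short-circuits to a single fit. Trees are not rescaled
to unit height; the GLS is invariant to a global scale up to the σ²
parameterisation.

## Study model suites

Main suite (both indices, all species): interaction
(β₀ + β_lat·β_env structure, i.e. latitude, two environment dummies and
their products), additive, latitude-only, environment-only, null. Hair
suite (semi-aquatic species with hair-density data): latitude ×
log hair density, the additive pair, each alone, null. Environment is
dummy-coded against **fully-aquatic** by default so intercept contrasts read
directly as "versus fully-aquatic". All models within one suite run share
the same resolved trees, so per-iteration comparisons are like-with-like.
Per-environment latitude slopes come from the interaction fit: the reference
level's slope is β_latitude, other levels add their interaction coefficient,
with the variance combined from the coefficient covariance.

Other analysis choices:

- **Latitude** is folded to absolute value by default (it is a thermal
  proxy and the sources mix hemispheres); a `signed` mode is available.
- **Hair density** uses primary + secondary densities summed when both are
  reported, log-transformed. Species lacking hair density are dropped only
  from the hair suite, never from the main suites.
- **Blubber-section subanalysis**: latitude-only PGLS run separately for
  pinnipeds measured on the outer blubber layer versus the whole core
  (blubber is stratified — the outer layer is MUFA-enriched — so the section
  used can bias Δ9-DI). Groups under three species are refused.
- **Per-FA regressions** are ordinary, non-phylogenetic OLS of wt% on
  latitude with two-sided t-tests at α = 0.01, run on the species set the
  caller supplies (the pipeline passes pinnipeds, where the Δ9-DI–latitude
  correlation concentrates). Whether this should be restricted further to
  outer-layer animals is left to the caller.

## Synthetic data

The generator produces what the analysis consumes, with the statistical
structure the model assumes:

- **Trees.** Yule (pure-birth) process run to the target tip count, with one
  extra waiting interval so tips have positive terminal branches; exactly
  ultrametric. A configurable fraction of internal edges can be collapsed
  into polytomies (lengths absorbed downward, tip depths unchanged).
- **Traits.** Environments are assigned in contiguous blocks of the leaf
  order by default ("clade-biased"), because phylogenetically clustered
  predictors are precisely the confounding PGLS exists to handle — i.i.d.
  assignment (available via a flag) would understate it. Latitudes are
  uniform on the configured band; hair densities log-normal for semi-aquatic
  species. The response is y = Xβ + ε with ε drawn through the Cholesky
  factor of σ²·V(λ) — the exact PGLS generative model — and the generating
  (β, λ, σ²) are returned in a truth sidecar for recovery tests.
- **Defaults are the emulated study conditions**: 54 tips split 15
  terrestrial / 25 semi-aquatic / 14 fully-aquatic; latitude 0–80°;
  λ = 0.5; interaction-model coefficients giving per-environment lines
  2.27 + 0.02·lat (fully-aquatic), −1.34 + 0.06·lat (semi-aquatic),
  1.62 − 0.01·lat (terrestrial); σ² = 0.3, which on a Yule tree of height
  ≈ ln 54 yields a tip-level residual SD near 1.1, comparable to the
  within-group spread of real desaturation indices; hair density
  log-normal(meanlog 4.0, sdlog 1.5) hairs/mm², spanning sparse pinniped
  fur to dense otter/rodent coats.
- **FA profiles.** A fixed 12-FA panel (the 8 index FAs plus 18:2ω6,
  20:4ω6, 20:5ω3, 22:6ω3). Total mass (100 wt%) is split into SFA, MUFA and
  PUFA blocks: the MUFA/SFA ratio fixes Δ9-DI exactly; Dirichlet noise
  within the SFA and MUFA blocks adds realism without touching either index
  (all index MUFAs carry one double bond); the PUFA block is apportioned
  between 18:2ω6 and 22:6ω3 to land the DBI exactly. Index targets outside
  the panel's feasible region raise an error stating the region. Profiles
  therefore round-trip through the index formulas to ~1e-9.

What the generator does **not** emulate: diet-driven covariance among FAs,
measurement error in published tables, non-ultrametric trees, body-mass or
sex structure. Passing tests demonstrate the estimators' correctness under
the assumed model and their behaviour under realistic sample sizes and
confounding — not robustness to violations of the Brownian/λ model itself.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to what the
estimators need, not more: λ recovery uses 50 replicates at 200 tips per
true λ (sampling spread of λ̂ at the 54-species scale would swamp the check);
model-selection and slope-coverage checks use 20–50 replicates at 54–100
tips; polytomy-resolution aggregation is exercised at tens of iterations,
with the 1000-iteration default reserved for real analyses (on a binary
tree the run short-circuits, so the default costs nothing there).

## Known limitations

- Only Pagel's λ is implemented as a branch-length transform — no OU, κ or
  δ — and estimation is ML, not REML, so σ̂² and λ̂ carry the usual small-n
  ML bias; CIs on λ itself are not produced.
- Aggregation across polytomy resolutions reports mean and median but no
  across-tree uncertainty for the coefficients (the per-iteration table is
  exposed for callers who want more).
- Per-FA regressions ignore phylogeny by design; treat their p-values as
  descriptive.
- The λ transform requires positive tip depths; degenerate zero-length
  trees are rejected rather than regularised.
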