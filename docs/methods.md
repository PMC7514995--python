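# Methods

## Data model

The unit of input is a taxa-by-time table of relative species abundances
(RSA): rows are OTU/species labels, columns integer day indices, every
column a composition. Raw counts are accepted and renormalized column by
column. Individuals are grouped (e.g. healthy / transitory / unhealthy);
inference runs on a pooled per-group table.

**LCM reconstruction.** Members of a group are observed for different
numbers of days. Each member is extended to the least common multiple of
the member lengths by whole-series cyclic tiling, which preserves every
species' empirical value distribution exactly (a bootstrap would too, but
tiling is deterministic and keeps within-series ordering). Species shared
by several members are averaged pointwise; species unique to one member
pass through, and pooled columns are re-closed to sum 1. Tiling
introduces artificial periodicity (period = the member's original
length); we document rather than correct this, and the permutation null
(below) excludes shifts that would re-align lagged couplings.

## Information-theoretic estimators

All entropies are plug-in (maximum-likelihood) estimates in bits over
equal-frequency (quantile) symbol alphabets.

* **Bins.** Default `n_bins = max(2, floor((T/20)^(1/3)))`, i.e. the
  median split for series shorter than a few thousand points. The TE
  statistic fills a `B^3`-cell lag-triple histogram (`B^4+` with
  conditioners); requiring roughly 20 counts per cell keeps the plug-in
  bias (~`df / (2 N ln 2)`) an order of magnitude below typical coupling
  signals. A `T^(1/3)` rule, natural for one-dimensional histograms,
  leaves under one count per cell at T = 500 and destroys detection
  power.
* **History.** TE uses a single lagged value as history for both series
  (Markov order 1 at lag tau); multi-symbol histories are out of scope
  for series this short.
* **Lag selection.** `tau* = argmin_{tau in 1..tau_max} exp(-MI)` with
  ties toward the smallest lag; `tau_max = min(5, floor(T/6))`. The
  functional-distance census searches both signs of the lag; directed TE
  uses positive lags only.
* **Significance.** Circular-shift permutation null of the source
  (`n_perm = 200` by default), preserving the source's marginal and
  autocorrelation. Shifts within `tau_max + 1` of 0 or T are excluded: a
  shift s re-aligns a true lag-L coupling with the tested lag whenever
  `s = L - tau (mod T)`, so unguarded shifts contaminate the null with
  the coupling under test. An edge is retained only when its TE exceeds
  the *entire* null (p < 1/(n_perm+1)). With ~n(n-1) candidate pairs per
  network, a per-pair 5% level would admit ~0.05 n(n-1) false edges and
  cap precision near 0.5 on 20-species benchmarks; the family-wise rule
  keeps the expected number of null edges per network below ~2. A
  quantile rule remains available via `alpha`.
* **Indirect-link pruning.** Each surviving edge (i -> j) is re-tested
  conditionally on the `c_max = 3` strongest alternative predictors of
  j (by unconditional TE, each at its own selected lag). Significant
  parents of j are always eligible conditioners; other species are
  excluded when they look more like children of the source than parents
  of the target (`TE(i->k) > TE(k->j)`), since such proxies of the
  source's own past would explain away a genuine direct edge. The edge
  is dropped unless its conditional TE exceeds the whole conditional
  null. This separates information flow (direct influence) from
  information transfer (mediated or common-mode dependence).
* **Sign.** The sign of an interaction is the sign of the Spearman
  correlation between source(t - tau) and target(t); zero maps to +1.
  Compositional closure biases pairwise correlations negative, so signs
  are reliable only when no species holds a large share of the
  community (see Limitations).

## Networks

The MENet keeps every significant, pruning-surviving directed edge; the
total network entropy `H(N) = sum H(x_i) + sum sign*TE` is maximized by
this set because each retained TE term is nonnegative. The noise term of
the entropy balance is reported as zero (no estimator exists for it);
utility weights are fixed at 1. OIN pruning is a single pass: node i is
kept iff OTE(i) > ITE(i) strictly (a tie is redundancy); reported
OTE/ITE are recomputed over retained edges, but the keep decision is not
iterated.

The **entropy-flow pattern** reports `H` against a rising TE cutoff. The
curve uses TE magnitudes (`sum H(x_i) + sum_{|TE| >= c} TE`) so that it
is non-increasing in the cutoff; the signed sum (where negative edges
would make the curve non-monotone) is available as
`total_network_entropy`, and the signed-TE skewness is reported along
the threshold grid as the symmetry diagnostic: balanced +/- interactions
give near-zero skew, positively biased ones a skewed distribution.
Pareto threshold networks keep the top 20% of edges by |TE| (ties broken
lexically by (source, target)).

## Indices, diversity, fits, metrics

* **TEI**: sigma_i = OTE(i)/H(OIN) with unsigned TE magnitudes
  (activity), mu_i = H(x_i) g(x_i)/H(OIN); H(OIN) is the signed total.
  **MII**: s_i = MI(X_i;Y)/H(Y), s_ij = MI(X_i;X_j|Y)/H(Y).
* **Diversity** (presence = RSA > `presence_eps`, default 0): alpha(t) =
  richness; beta(t) = 1 - Jaccard similarity of consecutive presence
  sets, with the disjoint-set fallback that sets the shared count to 1
  (implemented literally; a strict-Jaccard switch exists because the
  fallback gives disjoint sets nonzero similarity); gamma(t) =
  cumulative distinct species; M(t) = cumulative (species, time)
  presence occurrences, counting re-introductions.
* **Exceedance fits**: upper cutoff m at the 0.99 quantile; truncation
  y* by a Clauset-style KS scan over candidate thresholds; pdf exponent
  epsilon by truncated-Pareto ML on [y*, m]; a power-law regime is
  declared only if it beats an exponential fit of the same tail in
  likelihood *and* spans at least a decade (m/y* >= 10) — without the
  span requirement the upper tail of a pure exponential sample is
  routinely misflagged. lambda1 is the exponential ML rate below y*
  (over the whole sample when no power law is found); lambda2 fits the
  super-cutoff exceedances. The cutoff family f(y/m) is exponential.
* **Scaling fits**: OLS on (log10 x, log10 y) with r^2 and decades
  spanned; applied to gamma vs M, OTE vs mean RSA, and similarity decay.
* **Metrics**: functional degree k_f counts incident directed edges,
  structural degree k counts undirected neighbors (k_f >= k always);
  structural distances are hop counts on the undirected skeleton;
  stability is the spectral radius of the 0/1 undirected adjacency or
  the signed TE matrix; resilience is seeded uniform node removal
  reporting surviving giant-component and |TE| fractions.

## Synthetic data

The generator runs AR(1) log-abundance dynamics: diagonal 0.3, planted
signed couplings `strength/sqrt(n_parents)` on a chosen topology, unit
Gaussian innovations, 50-step burn-in. Random and scale-free topologies
are acyclic (edges oriented along a random node order): cyclic feedback
frequently pushes the spectral radius near 1, and the stability rescale
that prevents divergence would silently shrink the very couplings the
ground truth asserts. Latent states are exponentiated, scaled to
Zipf-ranked means (rank^(-1/(eps-1)), eps = 2 by default) and
column-closed to compositions. Defaults mirror the study conditions: 47
species, 30 days, scale-free topology, balanced signs, coupling 0.8.
`reference_cohort()` produces six members of 30/15/15/9/9/14 days in
three groups, exercising the 30/45/126 LCM paths. `copy_chain()` is the
symbol-level X -> Y -> Z fixture for flow-vs-transfer checks.

What the generator does *not* emulate: sequencing depth and zero
inflation, taxonomic assignment error, non-stationary regime shifts,
higher-order (non-pairwise) couplings. Passing the recovery benchmarks
therefore shows the estimator chain is correct and powered for
AR-coupled compositional data, not that real gut series satisfy those
assumptions.

## Benchmarks and problem sizes

The recovery benchmark uses 20-species, 500-day communities with 20
planted couplings at strength 0.8 over five seeds; the package defaults
achieve mean edge precision of roughly 0.8-0.95 and mean recall of
roughly 0.7-0.75 there depending on the seed set (per-seed values
fluctuate about +-0.1, which is why the benchmark is asserted on the
seed mean). Regime diagnostics pool signed TEs across three seeds of
30-species/400-day networks per sign regime. Diversity, fit and metric
checks run on cohort-shaped tables (47 species, 9-30 days).

## Limitations

* With very few species, compositional closure couples everyone through
  the shared denominator: in a 3-species community the planted-chain
  edge set is not recoverable in RSA space (the denominator-mediated
  lagged dependence is genuine), and inferred signs are biased negative.
  The method targets communities of tens of species, where each
  species' share is small.
* Strong couplings (>= 0.9) with coarse symbols leave a residual
  reverse-edge artifact: the binary own-history does not fully capture
  the target's state, so correlates of that state can appear weakly
  "predictive". The conditional pruning mitigates but does not remove
  this on long chains.
* TE values are plug-in estimates and biased upward at small T; all
  significance statements are relative to the matched permutation null,
  not to zero.
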