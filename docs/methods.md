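# Methods

This note documents the models, numerical choices and known limitations
of `estuarch`, in the order of the analysis pipeline.

## Feature-table preparation

The canonical container is a samples-in-rows count matrix with a
normalization state flag (`raw`, `rarefied`, `css`, `clr`).  Preprocessing
rules:

* **Depth filter** — samples with fewer than `min_reads` (default 100)
  focal-domain reads are discarded before normalization; the boundary is
  strict (`< min_reads` removed).
* **Network pre-filter** — a feature enters network inference only with
  total abundance >= 100 reads *and* presence in >= 15% of samples
  (`ceil(0.15 n)`, both boundaries inclusive).  The abundance threshold is
  interpreted as total reads across the samples of the table being
  filtered; since networks are built per estuary x season stratum, it
  applies per sub-table (configurable).
* **Domain flags** — archaeal / bacterial / phytoplankton flags are
  derived from the taxonomy; chloroplast lineages mark eukaryotic
  phytoplankton and are excluded from the bacterial flag, so the three
  flags partition the classified features.
* **Rarefaction** — multivariate hypergeometric subsampling (without
  replacement) to a fixed depth, default 10,600 reads; rows then sum to
  the depth exactly and stay integer.  Samples below depth are dropped
  with a warning.
* **CSS (cumulative sum scaling)** — per sample *j*, the scaling factor
  s_j is the sum of counts <= the l-th quantile of the sample's *nonzero*
  counts (linear interpolation between order statistics, pinned for
  reproducibility); normalized values are c_ij / s_j x 1000.  l is fixed
  at 0.5; the adaptive instability search of the original CSS method is
  deliberately not implemented — on tables this small it adds a
  data-dependent discontinuity for little benefit.  CSS output is exactly
  invariant to per-sample multiplicative depth and monotone within a
  sample.  No log transform is applied before ordination by default
  (flag available).

## Sloan neutral community model

Model: a taxon with source-pool relative abundance p has stationary local
relative abundance x ~ Beta(Nm p, Nm (1-p)); with a detection limit of d
reads out of N, the classic detection probability is
F(p) = 1 - I_{d/N}(Nm p, Nm (1-p)).

* **Fitting** — Nm is the single free parameter, fitted by least squares
  of observed occurrence frequencies on the detection curve (coarse
  log-grid bracket + bounded scalar minimization; deterministic).  Only
  taxa with p > 0 and freq_obs > 0 enter the objective.  N defaults to
  the rounded mean local sample depth and d to 1 read; both are exposed
  because the analysis is only self-consistent when the simulator and
  the fit agree on them.
* **Detection model** — the default objective uses the *exact*
  beta-binomial detection probability P(count >= d) = BetaBin.sf(d-1; N,
  Nm p, Nm (1-p)).  The classic threshold form F(p) above is its
  continuum approximation (thresholding x at d/N) and is available via
  `detection="threshold"`.  On genuinely discrete counts the threshold
  form is biased: against the package's own generator the fitted m was
  ~20-35% too high (median relative error 23.7% over twenty simulations
  at S=500, N=10^4, n=100), while the exact form recovers m with ~1%
  median error.  Both forms are exposed; `expected_frequency` computes
  the threshold curve, `expected_frequency_exact` the beta-binomial one.
* **R^2** — 1 - SSE/SST with SST about the mean observed frequency.
  Negative values (model fits worse than the mean) are reported as-is,
  never truncated.
* **Envelope and classification** — each taxon is classified against a
  95% envelope around the fitted curve at its p: above / neutral / below,
  with boundary ties neutral.  The default envelope is the central
  binomial acceptance region [binom.ppf(.025; n, f_pred),
  binom.ppf(.975; n, f_pred)]/n with n the number of local samples: it
  is the calibrated region for the *observed* frequency, and reaches 0
  and 1 at extreme predictions — where a taxon detected in every sample
  is exactly what neutrality predicts.  The Wilson score interval used
  by the classic workflow is available (`envelope="wilson"`) but is a
  confidence interval for a proportion, not an acceptance region: its
  upper bound is < 1 by construction, so with ~100 samples it flags
  ~10% of truly neutral high-abundance taxa as "above"; the binomial
  region brings that to ~1% while keeping 95% sensitivity for planted
  selected-for taxa at effect 3.
* **Source pool** — p comes from pooled relative abundances of a source
  table: either the regional (all-estuary) pool or each estuary's own
  pooled counts; both modes are exposed, and explicit p vectors are
  accepted for simulation studies.
* **Abundance partition** — cumulative relative abundance of focal
  (e.g. archaeal) taxa per category; the three shares sum to 1.

## Distance-based statistics

All implemented from their matrix definitions (validated against
scikit-bio and brute-force enumeration in the tests):

* **Bray-Curtis** d(x,y) = sum|x_i - y_i| / sum(x_i + y_i); all-zero
  samples are rejected by name.
* **PCoA** — eigendecomposition of the Gower-centered matrix
  -1/2 J D^2 J.  Negative eigenvalues (non-Euclidean dissimilarities)
  are reported, not corrected; proportion explained uses positive
  eigenvalues only.
* **PERMANOVA** — sequential (Type I) sums of squares via nested
  projection matrices on the Gower-centered matrix, terms in the order
  given (main effects before interactions, `a:b` syntax).  Term order
  matters for unbalanced designs — exactly the situation after dropping
  low-count samples — so the order is part of the reported result; total
  SS is order-invariant.  Pseudo-F = (SS_t/df_t)/(SS_r/df_r); p-values
  by free (unrestricted) permutation of sample labels with the add-one
  rule, or exhaustive enumeration of all n! relabelings on small
  designs.  Free permutation is a documented limitation for nested
  designs.  A numerically zero residual (perfect separation) reports
  F = +inf rather than an error.
* **Mantel / partial Mantel** — Spearman by default (Pearson available)
  on the off-diagonal vectors; p by simultaneous row/column permutation
  of the second matrix (one-sided, add-one).  The partial test
  correlates rank-vector residuals after regressing both on the control
  matrix's ranks, re-residualizing each permuted vector.
* **Environmental screen** — Spearman rho and two-sided p per
  (taxon group, covariate) pair with pairwise deletion of missing
  values; pairs with < 4 complete observations or a constant vector
  report missing.

## Direct association networks

Inference follows the local-to-global, constraint-based contract: an edge
survives only if no measured variable set renders the pair conditionally
independent.

* Taxa are clr-transformed (log over geometric mean, pseudocount 1);
  environmental covariates are z-scored and enter as ordinary nodes.
  Missing environmental values are rejected outright.
* Candidate edges: pairwise correlation with two-sided Fisher-z test at
  alpha (default 0.001).  A taxon-taxon pair is only testable with
  >= n_obs_min (default 10) co-nonzero samples — the package's reading
  of the upstream tool's `n_obs_min`.
* Pruning: PC-stable schedule for conditioning sizes k = 1..max_k
  (default 3).  At each level the adjacency is frozen; for each edge
  (i,j) every size-k subset of either endpoint's frozen neighborhood is
  tested (partial correlation from the inverse of the corresponding
  correlation submatrix, Fisher-z with n - k - 3 df); one insignificant
  test removes the edge.  Freezing per level makes the result
  independent of edge visiting order; a separating set found from either
  endpoint removes the edge (AND rule; OR available).
* Edge weight and sign come from the pairwise clr correlation, not the
  final partial correlation — partial coefficients shrink with the
  conditioning set and their sign is less stable.
* Modules: greedy modularity maximization on absolute edge weights
  (networkx implementation), communities relabelled by lowest node id;
  isolated nodes become singleton modules.  Chosen over stochastic
  (Louvain/Leiden) methods for bit-reproducibility of downstream
  Zi/Pi/roles.
* Zi/Pi on unweighted degrees: Zi = within-module degree standardized
  over the module's members (population sd; Zi := 0 when sd = 0);
  Pi = 1 - sum_s (k_is/k_i)^2 (0 for isolated nodes).  Roles:
  peripheral (Zi <= 2.5, Pi <= 0.62), connector (Zi <= 2.5, Pi > 0.62),
  module hub (Zi > 2.5, Pi <= 0.62), network hub (both above); the
  peripheral side is boundary-inclusive.  Weighted degree is exposed as
  an alternative but unweighted is the default.
* Cross-domain summary: edge counts and percent-positive per class
  (archaea-archaea, archaea-bacteria, archaea-phytoplankton, taxon-env,
  other) plus per-archaeal-genus total and cross-domain degree.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes,
not sequences:

* **Design** — 4 estuaries x 2 seasons x 2 stations (low ~10 /
  medium ~25 psu) x 5 replicates = 80 samples, with cruise-style sample
  ids (`WYE_L_1`); environmental covariates (temperature, salinity, pH,
  DO, nutrients, COD) track season/station/latitude with replicate
  noise.
* **Source pool** — lognormal relative abundances (sigma = 2, the
  typical amplicon rank-abundance shape), 800 taxa split 70% bacteria /
  20% archaea / 10% phytoplankton (chloroplast) by default.
* **Neutral communities** — direct sampling of the stationary
  Beta(Nm p, Nm(1-p)) per taxon and sample followed by Binomial(N, x)
  read counts.  This is the exact generative counterpart of the fitted
  model (O(S n), no birth-death dynamics needed).  Counts are drawn per
  taxon independently, matching the independent-taxon approximation of
  the fit, so row sums vary around N ~ 30,000 rather than equalling it.
  Default migration rates differ by estuary (0.4 for the strongly mixed
  northernmost estuary, 0.12-0.2 elsewhere) to create recoverable
  between-estuary contrasts.
* **Selection** — planted "for"/"against" taxa have their occurrence
  frequency multiplied/divided by a known factor (default effect 3, 15
  for / 10 against per stratum) by flipping zero cells to resampled
  nonzero counts or zeroing detections.  Planting edits frequency, not
  mean abundance, because the neutral partition is defined on frequency.
* **Association graphs** — latent Gaussian with unit-diagonal precision
  matrix whose only nonzero off-diagonals are the planted edges (so
  latent partial correlations equal the edge strengths), optional
  environmental parents, then softmax-to-proportions and multinomial
  reads.  clr(counts) tracks the latent field up to centering, matching
  the network module's assumptions; rows sum to the sequencing depth
  exactly.  Positive-definiteness is checked and violated edge sets are
  reported.

Not emulated: sequence errors and chimeras, taxon-taxon interactions in
the *neutral* communities (the two generators are separate models),
spatial autocorrelation beyond the factor structure, and realistic
environmental driving of community composition (covariates track the
design, not the taxa, except where explicitly planted in graph data).
Consequently, passing tests demonstrate correctness of the estimators on
data satisfying their assumptions — not robustness to real-data
violations such as overdispersion beyond beta-binomial, taxon
correlations in neutral fits, or nonlinear environmental responses.

## Validation experiment sizes

The validation experiments (`estuarch.benchmarks`, asserted in
`tests/test_acceptance.py`) use problem sizes chosen to make Monte-Carlo
error small relative to the tolerances while keeping the whole suite
around a minute: 10^6 draws per cell on a 5x5 (p, Nm) grid; twenty
neutral simulations at S=500, N=10^4, n=100; 200 null PERMANOVA datasets
at 999 permutations (n=16); exhaustive enumeration at n=6 (720
relabelings) and n=5 (120); a 50-taxon/40-edge planted graph at n=200,
depth 50,000; forty chain runs (lengths 3-5, embedded among 30 taxa,
n=500).  Chains are embedded in a larger taxon background because clr
closure on very small compositions (3-6 taxa) induces strong artificial
correlations — a compositional fact, not an inference failure.

## Known limitations

* Conditional-independence tests assume approximately Gaussian clr
  values; heavy zero-inflation (beyond the n_obs_min guard) violates
  this.
* `max_k` = 3 bounds the conditioning search; denser true graphs can
  leave indirect edges in place.
* Free permutation in PERMANOVA is anti-conservative for nested/repeated
  designs.
* The neutral fit treats taxa as independent observations; phylogenetic
  or interaction structure is ignored (by design — matching the model).
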