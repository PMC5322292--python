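# Methods

## Indices

All eleven indices are formulated as similarities S on [0, 1]; ordinations
and tests use D = max(0, 1 − S).  Notation: n_Ai counts of taxon i in sample
A, n_A = Σ_i n_Ai, N_A = #{i : n_Ai > 0}, p_Ai = n_Ai / n_A.

Count-based: classical Jaccard JCI = |shared| / |union| (incidence only);
weighted Jaccard JCW = ½(Σ_{shared} p_Ai + Σ_{shared} p_Bi); Chao's
abundance-based Jaccard JCC = ÛV̂/(Û + V̂ − ÛV̂) with Û, V̂ the Chao et al.
(2004) formula-9 estimators of the fraction of individuals in shared taxa
(observed fraction plus a rare-taxon correction driven by shared taxa that
are singletons in the partner sample; when the doubleton count f_{+2} is 0 it
is replaced by 1, and each estimator is capped at 1 before combination);
Bray–Curtis BC = 2Σ min(n_Ai, n_Bi)/(n_A + n_B); Morisita–Horn
MH = 2Σ p_Ai p_Bi / (Σ p_Ai² + Σ p_Bi²).  "Observed" means count > 0, with
no minimum-abundance threshold.

Phylogenetic: unweighted UniFrac similarity is shared over union branch
length, where a branch counts as shared when its subtree contains observed
taxa of both samples.  Weighted UniFrac uses the normalised variant
D = Σ_e l_e |p_A(e) − p_B(e)| / Σ_i φ_i (p_Ai + p_Bi) (φ_i = root-to-leaf
path length), so that D ∈ [0, 1] and all indices are comparable on the same
scale.  Both are computed on a branch-incidence matrix, which also gives the
vectorised all-pairs forms; the implementation is cross-checked against
scikit-bio's `unweighted_unifrac` / `weighted_unifrac` in the test suite.

Interaction-adjusted: TU is the plain average association between the taxa
observed in A and in B, TU = (1/N_A N_B) ΣΣ C_ij; TW is the bilinear form
p_Aᵀ C p_B scaled by the geometric mean of the within-sample strengths,
TW = p_Aᵀ C p_B / √((p_Aᵀ C p_A)(p_Bᵀ C p_B)).  TU carries no normalisation
term, so TU(A, A) < 1 in general (it equals the mean within-sample
association); the "identical communities give 1" property holds exactly for
TW and is asserted there.  PU/PW substitute the phylogenetic association
matrix Φ.  TW/PW stay within [0, 1] because canonical association matrices
are positive semi-definite.

## The association transform

Raw interaction matrices live on method-specific scales (correlations on
[−1, 1], taxa-wise similarities on [0, 1], cophenetic similarities).  The
canonical transform correlates the full rows of the raw matrix — including
the diagonal and the focal columns — and maps r to C = (1 + r)/2.  Excluding
the focal columns is available as `exclude_focal=True` (default off).  The
two choices differ in degenerate cases: on a star tree with equal tip
lengths, excluded-focal profiles are constant and all associations are
neutral (0.5), while full-row profiles are indicator vectors with Pearson
correlation −1/(n−1).  Zero-variance profiles map to neutral 0.5 with a
warning.  Cophenetic similarity uses global max-distance normalisation,
I_φ = 1 − d_coph/max d_coph, chosen so that the most distant leaf pair
anchors the scale at 0.

A caveat verified empirically: the transform preserves association ranks on
*structured* networks (block-correlated data), but for pure-noise symmetric
matrices the profile correlation is unrelated to the individual raw entries,
so rank preservation should not be expected of arbitrary matrices.

## Network inference

SparCC follows Friedman & Alm's estimator for compositional data: per
resample, taxon fractions are drawn from Dirichlet(counts + 1) per sample;
the log-ratio variation matrix T_ij = Var(log x_i − log x_j) is computed
across samples; basis variances ω solve the sparse approximation
(diag(d) + W) ω = t (W the included-pair indicator, t the corresponding row
sums of T); correlations ρ_ij = (ω_i + ω_j − T_ij)/(2√(ω_i ω_j)) are clipped
to [−1, 1]; and the most strongly correlated pair above the exclusion
threshold (0.1) is iteratively removed from the basis estimation, up to 10
exclusions.  Estimates are averaged over 20 Dirichlet resamples.  Defaults
(10 exclusion iterations, threshold 0.1, 20 resamples) follow the reference
estimator's conventions; the resample average is the only averaging loop.
Spearman, taxa-wise Bray–Curtis similarity and taxa-wise weighted Jaccard
(Ruzicka form, Σ min / Σ max across samples) are provided as alternative
inference methods; all-zero taxa are excluded before inference.

## PERMANOVA, PCoA, gradient correlations

PERMANOVA uses Anderson's (2001) partition: G = −½ J D² J, with sums of
squares allocated sequentially (Type-I, adonis convention) across model
terms via hat-matrix projections, per-term F against the full-model residual
mean square, and free permutations of sample labels.  p = (1 + #{F_perm ≥
F_obs})/(1 + n_perm), so p is never 0; the default n_perm is 999.  Aliased
terms (rank increment 0) raise an error.  PCoA is classical scaling (via
scikit-bio); negative eigenvalues are reported but not corrected, and
coordinates are returned for positive axes only, since the first-axis
correlation is the downstream use case.  Gradient correlations are Spearman
correlations of the distance-matrix upper triangle against absolute pairwise
covariate differences.

## Simulation engines

The GLV integrator is a discrete-time Ricker-type update,

    x_i ← x_i · exp(Δt (r_i (1 − Σ_k x_k / K) + (A x)_i / K)),

with Δt = 0.1 and 100 steps by default: it preserves non-negativity without
an ODE solver, carrying capacity enters as a shared logistic brake on total
abundance, and interactions are scaled by 1/K to keep dynamics bounded.
Final states are stochastically rounded (floor plus Bernoulli remainder) to
integer counts.  Carrying capacities are set to the per-sample totals of the
source table and starting counts rescaled to 10% of capacity.

Interaction matrices place within-group interactions on Barabási–Albert
edges (m = 2) with magnitudes Uniform(0, 0.5) and random signs, and set all
between-group entries competitive, Uniform(−0.5, −0.1) plus
Uniform(−0.05, 0.05) noise — strictly negative.  These magnitudes are the
package's choice; only the structure (scale-free within, competitive
between) is prescribed by the design.

Four benchmark scenarios compose the generators; the base table is a
two-component Dirichlet-multinomial (25 + 25 samples, 200 taxa, depth 2000;
preferred-taxon Dirichlet weights lognormal(0, 1), non-preferred 0.02),
giving strong habitat preference and within-habitat co-abundance:

* `negative_control` — abundances shuffled per taxon across all samples,
  interaction-neutral GLV: no habitat, co-abundance or interaction signal.
* `habitat_only` — shuffling within habitat groups keeps preference but
  breaks co-abundance; neutral GLV.
* `interaction_only` — Poisson(5) starting counts, invariant growth rates
  (0.5), the two-group interaction matrix; habitat labels assigned *post
  hoc* by the dominant taxa group.  Capacity is set to 10× the Poisson
  start total so samples begin at 10% of capacity and interactions shape the
  growth phase.
* `habitat_plus_interaction` — within-group shuffled starts plus the
  interaction matrix.

When TINA is computed "from the known interaction matrix", the (directed)
GLV matrix is symmetrised before the canonical transform, which requires a
symmetric input.

What the generators emulate — habitat preference, co-abundance, explicit
pairwise interactions, compositional sampling, rarefaction — covers the
signals the indices are designed to detect.  What they do not emulate:
sequencing error and chimeras, phylogenetically correlated habitat
preference (scenario trees are random), overdispersion beyond the
Dirichlet-multinomial, and temporal dynamics.  Passing benchmarks therefore
demonstrate correct behaviour of the indices under controlled signals, not
performance on any particular real survey.

## Numerical and design notes

* Distances are clamped to [0, 1]; matrices are symmetrised and diagonals
  forced exact after vectorised computation.
* TSV output uses 10 significant digits, making read→write→read round trips
  the identity at that precision.
* Unrooted Newick input is midpoint-rooted, since root-to-leaf lengths φ_i
  require a root.
* Taxa absent from an association matrix are tolerated only when unobserved
  (all-zero) — they cannot contribute to TINA/PINA sums; observed missing
  taxa raise an error (harmonise first).
* Vectorised all-pairs index computation agrees with per-pair scalar calls
  to 1e−12 (asserted in tests); index sums iterate over taxa intersections
  and are order-independent.
* Workflow seeds are split per stage from one master seed; feeding the *same*
  integer seed to two different generators would correlate their streams, so
  derived seeds are always drawn from the master stream.
* Benchmark problem sizes (50 samples × 200 taxa, 20 replicates, 999
  permutations) were chosen as the package's standard desk-scale
  configuration for the scenario studies.

## Known limitations

* SparCC assumes many taxa with sparse correlation structure; with very few
  taxa (< 4) the basis-variance system is unidentifiable and an error is
  raised.  Compositional invariance holds only within resampling noise.
* TU's plain-average form makes its self-similarity context-dependent;
  rankings, not absolute TU values, are comparable across datasets.
* Interaction-adjusted indices are not context-invariant in general: their
  values change when the network is re-inferred on a different sample set.
  Workflows therefore always re-infer the network on the exact subset under
  analysis.
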