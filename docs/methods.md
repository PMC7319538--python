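# Methods

This note documents the models, algorithms, and numerical choices behind
`causalmix`, and what its simulation-based validation does and does not
establish.

## The model

`causalmix` targets tabular biomedical data that mix continuous
measurements (expression, clinical scores) with categorical ones
(diagnosis, sex, smoking status).  The underlying model is the pairwise
mixed graphical model: a Markov random field in which each continuous
variable x_s has a Gaussian conditional

    x_s | rest  ~  N( α_s + Σ_t β_st x_t + Σ_j ρ_sj(y_j), 1 ),

and each categorical variable y_j has a multinomial-logistic conditional
with level-ℓ score

    α_j(ℓ) + Σ_s ρ_sj(ℓ) x_s + Σ_r φ_rj(y_r, ℓ).

An edge between two variables means exactly that the corresponding pairwise
block (β_st scalar, ρ_sj vector, or φ_rj matrix) is nonzero — the two
variables are conditionally dependent given all the others.

**Conditional variances are fixed at 1** for continuous nodes, and all
continuous columns are standardized before fitting.  This keeps the
pseudo-likelihood convex, makes the three penalties comparable across edge
types, and matches the simulator.  Variance estimation is deliberately out
of scope.

**Identifiability.**  Adding a constant to a ρ vector or a row/column of a
φ block can be absorbed by the intercepts, so those blocks are only
identified up to centering.  We mean-center ρ vectors and doubly center φ
blocks after every proximal step and absorb the shifts into the
intercepts.  Both centerings are orthogonal projections, so the smooth loss
is exactly unchanged and the group norms never increase — the monotone
objective guarantee survives.

## Undirected learning (penalized pseudo-likelihood)

The fit minimizes the average negative log pseudo-likelihood (the sum of
node-conditional negative log-likelihoods, divided by n) plus

    λ_CC Σ|β_st|  +  λ_CD Σ‖ρ_sj‖₂  +  λ_DD Σ‖φ_rj‖_F .

The ℓ1 / group-ℓ2 / group-Frobenius combination is the natural blockwise
sparsity penalty for the three edge types; group thresholding produces
*exact* zeros, so edge extraction is a support read-out (threshold 1e-8
guards against round-off only).

Optimization is proximal gradient with:

* backtracking line search (step halved until the quadratic majorization
  holds; the step is allowed to grow 1.25× between iterations);
* FISTA momentum with a **monotone restart**: whenever the accelerated
  candidate would raise the penalized objective (or overflow), the step is
  retaken as a plain proximal step from the best iterate and the momentum
  is reset.  The recorded objective trace is therefore non-increasing on
  every run, which the test suite asserts;
* convergence when the relative objective change drops below `tol`
  (default 1e-5, 1e-4 inside the subsampled stability loops where only the
  edge support matters);
* β and φ store each free parameter twice (symmetric matrices).  Inner
  products and distances in the line search weight those arrays by 1/2 so
  the algorithm operates in the free parameter space.

Default penalties are 0.25 for all three types — an arbitrary mid-grid
value; stability selection (below) is the recommended way to set them.
The rank-based Gaussianization (nonparanormal transform, Winsorized ECDF →
normal quantiles, truncation δ = 1/(4 n^¼ √(π log n)), rescaled to the
original sd) is opt-in for continuous columns with non-normal marginals.

## Penalty selection (stability)

Penalties are selected per edge type from subsampling stability.  N = 20
subsamples of size min(⌊10√n⌋, ⌊0.75 n⌋) are drawn without replacement;
for a candidate penalty triple the model is fitted on every subsample and
each edge type's *instability* is the mean over its possible pairs of
2·θ̄(1−θ̄), θ̄ being the fraction of subsample graphs containing the pair
(0 for edges always present or always absent, maximal 0.5 at θ̄ = ½).

Starting with all three types at the smallest grid value (default: 30
log-spaced values in [0.05, 0.9]), any type whose instability exceeds the
bound γ = 0.05 advances one grid step; the loop refits and repeats.
Because the three penalties are coupled through the joint fit, a type that
met the bound at an earlier iteration is **re-certified at the current
triple** whenever another type moves, and advances again if it no longer
qualifies; penalties only ever increase, so the loop terminates.  This
re-certification is what makes the selected triple self-consistent: the
instability of the chosen triple, recomputed on fresh subsamples, stays
within γ + 0.02 (checked by the test suite and the acceptance script).
If the grid is exhausted the largest value is used, with a warning.  The
reported profile includes a sparse-end running maximum (monotonized
instability) to guard interpretation against non-monotone noise.

## Directed refinement (PC-Stable)

The undirected graph seeds an order-independent constraint-based search:

* **Skeleton.**  Depth-wise pruning with start-of-depth adjacency
  snapshots used both for subset enumeration and for the candidate edge
  list — removals within a depth cannot influence that depth, which makes
  the skeleton invariant under variable reordering (verified exhaustively
  over all 720 permutations of a 6-node fixture).  Conditioning subsets
  are enumerated in lexicographic order from both endpoints' snapshot
  neighborhoods; the first separating set found is recorded.
* **Sepsets on demand.**  An unshielded triple X–Z–Y whose endpoint pair
  was nonadjacent from the start (absent from the seed graph) has no
  recorded separating set.  Before orientation we search for one exactly
  as the skeleton phase would; if none is found the triple is left
  unoriented.  Without this step a seeded search either fabricates
  colliders (treating the missing set as empty) or cannot orient true
  colliders whose spouse pair the seed graph already separated.
* **Colliders.**  Arrowhead demands are collected from *all* unshielded
  triples with Z outside the recorded separating set, then applied at
  once; an edge demanded at both ends becomes an explicit arrow–arrow
  ("conflicted") edge rather than being overwritten.  This is stricter
  than overwrite-style PC variants but keeps orientation
  order-independent.
* **Propagation.**  Meek rules R1–R3 to a fixed point (no new colliders,
  no directed cycles).  R4 is omitted: without background-knowledge edges
  it can never fire on collider-initialized graphs.

CI tests: if either variable is continuous it becomes the OLS response
(the lexicographically later name when both are — the partial-correlation
t-test is symmetric, so this only pins floating-point determinism); a
categorical X contributes dummy columns tested jointly by a partial F-test
(identical to the squared t-test for one column).  Two categorical
variables are tested by a multinomial-logistic likelihood-ratio test with
(L_Y−1)·(X columns) degrees of freedom.  The multinomial MLE is a damped
Newton iteration on the mean-scaled objective with the exact Fisher
Hessian, converged at gradient sup-norm 1e-8, with a tiny-ridge (1e-8)
refit under separation.  Aliased design columns are dropped with a
warning (p = 1 if all of X is aliased); pairs with non-positive residual
degrees of freedom are untestable and conservatively keep their edge.

Causal reading of the output assumes acyclicity, the causal Markov
condition, faithfulness, and causal sufficiency (no unobserved confounders
or selection bias).  Arrow–arrow edges flag places where the data violated
these assumptions locally.

## Feature pre-selection

For datasets with many variables, a target-directed pre-selection step
ranks continuous candidates by association (|Pearson r| for a continuous
target; 1 − p from the logistic/multinomial LRT for a categorical one),
then sweeps them best-first, marking candidates whose |r| with an
already-selected variable reaches the redundancy threshold τ.  Marked
candidates are dropped or clustered under the earliest-selected variable
they are redundant with; the working list is refilled until the requested
number of representatives is reached.  Categorical candidates and
user-kept variables always pass through and do not count against the
quota.  τ can be chosen by half-sample stability: the smallest grid value
(0.10–0.90, step 0.05) whose sparse-end-monotonized pair instability is at
most γ = 0.05.

## The simulator

Benchmarks use two generators with all parameters declared here:

* **Undirected truth**: Erdős–Rényi graphs with edge probability
  d/(p−1) (expected degree d, default 2); pairwise effect magnitudes drawn
  uniformly from ±[0.5, 1.0]·effect_scale (default effect_scale 1);
  continuous precisions fixed at 1.  ρ vectors are centered and φ blocks
  doubly centered (the identifiable form), and the drawn magnitude is
  placed on the *centered* component (RMS entry in [0.5, 1]·effect_scale):
  centering a raw same-sign draw can cancel the effect almost entirely,
  which would create graph edges no method could recover.  Because independent draws do not guarantee a valid joint
  Gaussian over the continuous block, β is rescaled once at construction
  whenever the minimum eigenvalue of I − B falls below 0.4.  The floor
  caps every continuous node's conditional-variance inflation at 2.5×
  (node-wise R² ≤ 0.6): relations stay strong but never near-deterministic,
  which is the regime in which sparse support recovery is statistically
  meaningful.  Sampling is by Gibbs sweeps over the node conditionals, run
  as many short parallel chains vectorized across chains (each chain
  burned in 200 sweeps, then one draw per 10 sweeps until n rows are
  collected).  Parallel chains give effectively independent draws and are
  the only way to reach n = 20 000 at realistic cost; the all-continuous
  sampler is validated against the closed-form covariance (I − B)⁻¹.
* **DAG truth** (for scoring orientations): a random topological order
  with Erdős–Rényi earlier→later edges; linear-Gaussian equations for
  continuous children and multinomial-logistic equations for categorical
  children, sampled ancestrally.  Each continuous parent enters its
  children on a standardized scale, so variance does not accumulate along
  the order and every child keeps a bounded signal-to-noise ratio; without
  this, deep nodes become near-deterministic and orientation accuracy
  collapses for reasons unrelated to the algorithm.

What passing these benchmarks shows — and does not.  The simulators match
the fitted model family exactly (no model misspecification), have no
missing data, no measurement error, no latent confounding, and modest
dimensionality.  Success demonstrates correctness of the estimators and
reasonable statistical efficiency under the model's own assumptions; it
does not certify performance on real multi-modal data, where marginals are
non-normal (mitigated but not removed by the rank transform), effects are
weaker, and sufficiency rarely holds.

Problem sizes used in the validation suite: structure recovery at p = 20
(10 continuous + 10 three-level categorical), n = 2000, 10 seeds, with a
5-point log penalty grid; orientation checks on 3-variable motifs at
n = 5000 over 20 seeds; stability selection at p = 10, n = 300; CI-test
calibration with 1000 null replicates at n = 500.

## Known limitations

* Orientation inherits the sepset noise of plain collider orientation:
  with perfect d-separation oracles the implementation recovers the exact
  CPDAG on every benchmark DAG, but with finite-sample tests a single
  marginally wrong separating set can flip a collider and propagate
  through the Meek closure.  Skeletons are far more reliable than
  orientations (benchmark skeleton F1 ≈ 0.96 at p = 10, n = 5000, while
  2–5 endpoint errors per graph are common); conflicted edges are reported
  rather than hidden.
* No missing-data handling (loading fails on missing cells), no latent
  confounder search, no background-knowledge constraints.
* Pseudo-likelihood, not full likelihood: the partition function is never
  computed; parameter estimates are consistent for structure but not
  efficient.
* The stability threshold grid and penalty grid are finite; selected
  values are grid values, not continuous optima.
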