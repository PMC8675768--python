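# Methods

## Model

A genomic region binned at fixed resolution is represented as a chain of
`N` monomers whose effective energy is a sum of harmonic restraints on all
monomer pairs,

    U(r) = sum_{i<j} (k_ij / 2) |r_i - r_j|^2,      [k_B T = 1]

with a symmetric stiffness matrix `K = (k_ij)`, zero on the diagonal.  The
Kirchhoff matrix `KK = D - K` (`D_ii = sum_j k_ij`) defines a Gaussian
ensemble over conformations.  Because `KK` has the uniform-translation null
vector, monomer 0 is pinned at the origin: row/column 0 is removed before
inversion and the covariance `sigma = (KK_0)^{-1}` is zero-padded back, so
`sigma_ij = 0` whenever `i*j = 0`.  Per Cartesian coordinate,
`Cov(x_i, x_j) = sigma_ij`; the pair separation variance is
`a_ij = sigma_ii + sigma_jj - 2 sigma_ij`, and the 3D pair-distance density
is

    P(r) = 4 pi (gamma/pi)^{3/2} r^2 exp(-gamma r^2),
    gamma_ij = 1/(2 a_ij),   <r_ij^2> = 3 a_ij = 3/(2 gamma_ij).

Rescaling by `x = sqrt(gamma) r` collapses every pair onto the universal
curve `f(x) = (4 x^2/sqrt(pi)) exp(-x^2)` (available as
`polymer.master_curve`).

Positive definiteness is enforced on the *pinned* Kirchhoff matrix only, so
individual couplings may be negative.  The validity threshold is
`lambda_min > 1e-10 * lambda_max` of the pinned block; violations raise
`ModelValidityError` reporting the offending eigenvalue.

## Cross-linking and n-body contact probabilities

A contact between two segments at distance `r` is captured with probability
`F(r)`: either the Gaussian form `F0(r) = exp(-3 r^2 / (2 r_c^2))` or the
hard step `F1(r) = 1[r <= r_c]`, with capture radius `r_c`.  Since no
physical value of `r_c` is fixed by the data, `r_c = 1` is the default
length unit and is exposed as a parameter everywhere.

Under `F0` every simultaneous-contact probability is a Gaussian integral:

* pairwise: `p_ij = (1 + 3 a/r_c^2)^{-3/2} = (1 + <r^2>/r_c^2)^{-3/2}`;
* triplet: `p_ijk = [1 + 6(a+b+c)/r_c^2 + 27 z/r_c^4]^{-3/2}` with
  `b = sigma_ij + sigma_jk - sigma_ik - sigma_jj`,
  `c = sigma_jj + sigma_kk - 2 sigma_jk`, `z = ac - b^2`;
* 4-body: `[det(W4) det(W4^{-1} + L4)]^{-3/2}` with the gap covariance
  `W4 = [[a,b,f],[b,c,d],[f,d,e]]` and
  `L4 = (3/r_c^2) [[3,2,1],[2,4,2],[1,2,3]]`;
* generic `n >= 2` over a site set A:
  `p_A = [det(KK_0 + Delta_0)/det(KK_0)]^{-3/2}`, where `Delta` adds
  `3/r_c^2` springs between all pairs of A (`Delta_uu = (n-1)*3/r_c^2`,
  `Delta_uv = -3/r_c^2` for `u != v` in A).

The package also carries an equivalent low-dimensional route: with the
gap vectors `g_u = x_{s_u} - x_{s_{u+1}}` of the sorted site tuple,
`p_A = det(I + W_n L_n)^{-3/2}` where `W_n` is the gap covariance and
`L_n[u,v] = (3/r_c^2) min(u,v) (n - max(u,v))` (1-indexed gaps).  This
generalization is verified against the determinant-ratio route for
`n <= 6` in the tests and is preferred for large `N` since it works in
`(n-1)` dimensions.  Log-determinants go through Cholesky factors to avoid
overflow.

A note on typography: all `r_c` factors enter the polynomial forms as
divisions (`.../r_c^2`, `.../r_c^4`).  This is pinned down by the identity
`p_ij = (1 + <r^2>/r_c^2)^{-3/2}` and by numerically expanding
`det(I + W3 L3)` against the triplet polynomial (asserted to 1e-12 in the
tests).

Triplet and 4-body formulas are evaluated on the index-sorted tuple;
permutation invariance is asserted against the general determinant form
rather than assumed.

Under `F1`, only the pairwise probability has a practical closed form,
`p = erf(x) - (2/sqrt(pi)) x e^{-x^2}` at `x = sqrt(gamma) r_c` (the mass
of `P(r)` inside the capture radius, verified against quadrature).  Step
probabilities of order `n >= 3` are provided only through the Monte-Carlo
ensemble estimator; the closed-form functions refuse the step form
explicitly.

Simultaneous pair events and conditionals: `p_{ij,jk}` (both springs
closed, without requiring the i-k contact) is
`[1 + 3(a+c)/r_c^2 + 9 z/r_c^4]^{-3/2}`, equivalently the determinant form
with the sparse two-spring perturbation Omega.  The conditionals follow as
`p_jk|ij = p_{ij,jk}/p_ij` and `p_jk\ij = (p_jk - p_{ij,jk})/(1 - p_ij)`;
they satisfy the total-probability identity and the cooperativity ordering
`p_jk\ij <= p_jk <= p_jk|ij`, with equalities exactly when `b = 0`.  On an
ideal chain `b = 0` for every ordered triple, so both conditionals equal
the marginal `p_jk` (the package implements this derived identity).

## Monte-Carlo ensemble oracle

`sample_ensemble` draws the three Cartesian coordinate blocks
independently with covariance `sigma` (Cholesky factor times standard
normals), which reproduces `<r_ij^2> = 3/(2 gamma_ij)` exactly — this
identity fixes the per-coordinate calibration and is asserted in tests.
Ensemble contact estimates average the all-pairs cross-link weight
`prod F(r_uv)` over conformations and report the standard error of the
mean.  For probabilities of order 1e-6 and below at `M = 2e5` samples the
estimate is dominated by rare large weights; its Studentized distribution
is then visibly heavier-tailed than normal, which matters when many
estimates are screened at a fixed SE multiple.

## Fitting the stiffness matrix to Hi-C

Raw counts are converted to probabilities by rescaling so the median first
off-diagonal equals a target backbone contact probability (default 0.5, a
convention — the count-to-probability map is not identified by the data);
zero-coverage bins are masked.  Four costs compare model and observed
pairwise probabilities over the mask: squared error on probabilities (L0),
on log10 probabilities (L1), one minus the Pearson correlation of log10
probabilities (L2), and the mean squared relative error of `<r^2>` (L3,
averaged over unmasked pairs; the observed `<r^2>` comes from inverting
the configured cross-link form).  Observed probabilities are floored at
1e-10 for logarithms; model probabilities are never clipped inside the
computation.

Gradients are analytic.  Each cost depends on the couplings only through
the pair variances `a_ij`; with `G` the accumulated sensitivity
`dL/d sigma` and `B = sigma G sigma`, the covariance perturbation identity
`d sigma = -sigma (d KK_0) sigma` gives
`dL/dk_uv = -(B_uu + B_vv - 2 B_uv)` — two matrix products per iteration.
Gradients match central finite differences to better than 1e-8 relative on
random models for all four costs and both cross-link forms.

Optimizers: random sampling (RS: perturb a random 5% of couplings by
Gaussian steps scaled to 10% of magnitude + 1e-3, greedy accept),
steepest descent (GD), RMSprop, and ADAM (beta1 = 0.9, beta2 = 0.999,
eps = 1e-8).  Any proposal that leaves the positive-definite cone is
backtracked by halving up to 30 times, then rejected; GD additionally
backtracks on cost increase (a monotone line search — a fixed GD step is
unstable because the log-cost gradients span orders of magnitude).
Backbone couplings are floored at 1e-6 to keep the chain connected.  The
default learning rate is 0.003: on the reference synthetic problem
(N = 60, 12 loops, depth 1e5) ADAM at 0.003 reaches a final cost ~1e-3 of
the initial and log-probability Pearson > 0.995 vs truth in 5000
iterations, while 0.01 oscillates.  Stopping: relative best-cost
improvement below 1e-6 over 200 iterations, or the iteration cap; 100
consecutive inadmissible steps abort with the best-so-far model.  All
optimizers are deterministic given the seed.  The two recommended profiles
are L1 with the Gaussian cross-link (default) and L3 with the step form.

## Multiway statistics

* Stratum expectation: triplets are grouped by minor/major sections
  `m = min(j-i, k-j)`, `t = k-i`; `p_bar(m,t)` and `sigma(m,t)` are the
  stratum mean and *population* SD (population, so a two-element stratum
  scores symmetrically at z = ±1).
* Specificity Z-score `Z_ijk = (p_ijk - p_bar)/sigma`, with the degenerate-
  stratum rule `Z := 0` when `sigma <= 1e-12 * p_bar`: a homopolymer chain
  has exactly degenerate strata, so the chain is an exact null (max |Z| = 0
  over all 1140 triplets at N = 20 — recomputed by `scripts/acceptance.py`).
* Hub score `H_ijk = 3 p_ijk / (p_ij p_jk + p_ij p_ik + p_jk p_ik)`; not
  constant even on the ideal chain.
* Boost factor `p_ijk/(p_ij p_jk)`: <= 1 under both cross-link forms, with
  the strongest suppression at `m = t/2` for fixed `t`.
* Association Z-score: each sampled conformation is one virtual read; a
  queried site `u` is captured by the read with probability
  `F(r_u,viewpoint)` given the conformation (viewpoint-anchored capture —
  chosen over an all-pairs capture event because only the anchored
  convention makes independently injected contacts score a ≈ 0, the
  natural null).  `C+` counts reads capturing both `i` and `j`; the null
  redraws as many reads as captured `i` from the non-`i` pool and counts
  `j` captures; `A = (C+ - mean(C-))/SD(C-)` over `n_resample` redraws,
  deterministic given seeds.  Degenerate pools yield NaN, not an error.
  The concatemer chemistry of real multi-contact assays is not simulated.
* Class summaries: triplets grouped by the sorted multiset of their three
  bin labels (E/P/S/#); mean and SD of Z per group, SD taken over triplets.
* Map correlations: Pearson of log10 probabilities over the joint mask; a
  stratified Pearson (per-|i-j| correlations averaged with weights
  proportional to stratum size); and a stratum-adjusted approximation with
  weights `n_s * sd_a,s * sd_b,s`.  The latter is a documented
  approximation of the published stratum-adjusted correlation, not its
  exact rank-based weighting.

## Synthetic data

The generator inverts the analysis direction: a backbone chain (`k0`,
default 1) decorated with `n_loops` harmonic loops between random anchors
(span >= 2), strengths log-uniform in `[0.1, 1] * k0` — spanning weak to
strong loops while guaranteeing positive definiteness (with a halving
fallback for exotic ranges).  The observed map is emulated by Poisson
counts with mean `depth * p_ij` (sequencing-like noise; the true noise
structure of real Hi-C is not modelled), optional multiplicative
log-normal distortion, and whole-bin dropout.  Ground truth is returned
with every dataset.  What passing recovery tests show is that the
*inference machinery* is correct and well-conditioned at realistic depths;
they do not certify performance on real Hi-C, which carries coverage,
mappability and balancing artifacts outside this noise model.

Default study sizes: recovery experiments use N = 40-100 bins with 8-20
loops at depth 1e5; oracle sweeps use five models with N = 10-18 and
2e5-sample ensembles. These sizes make every analytic-vs-ensemble
comparison and the full fit reproducible in minutes on a single CPU.

## Numerical choices and edge cases

* Probabilities are clipped only at serialization/for logarithms
  (1e-10 floor in costs), never inside the closed forms.
* `contact_to_gamma` for the step form uses bracketed Brent root-finding
  on the monotone CDF; round-trips hold to 1e-10.
* Degenerate map entries (repeated indices in anchored triplet/4-body
  maps) are filled with the corresponding lower-order contact probability
  so maps stay within (0, 1].
* Row sums of the Kirchhoff matrix are zero by construction; for float
  couplings a residue-subtraction pass reduces them to summation
  round-off (exact zeros for integer-valued couplings).
* Bin indices are 0-based; genomic coordinates 0-based half-open; BED
  labels resolve conflicts by priority S > P > E > #.

## Known limitations

* No excluded volume or bending rigidity (appropriate at coarse-grained
  scales); no polymer dynamics; no ligation/indirect-capture chemistry.
* Step-form probabilities of order n >= 3 are Monte-Carlo only.
* The stratum-adjusted correlation is an approximation (above).
* Hi-C normalization upstream (ICE/KR balancing) is assumed done.
* The fit is a local optimizer on a non-convex landscape; multiple starts
  are the caller's responsibility (seed and initial model are exposed).
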