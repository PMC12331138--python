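# Methods

## Problem and setting

`transferknock` tests conditional-independence hypotheses in a *target*
environment: for each variable X_j, the null H_j says that X_j carries no
information about the outcome Y beyond the remaining variables. The package
controls the false discovery rate (FDR) of the selected set at a nominal
level q via model-X knockoffs, and optionally raises power by transferring
information from *external* environments (other populations, studies, or
phenotypes) whose covariate and outcome laws may differ from the target's.
The motivating application is variant selection in genetic association
studies, where large external cohorts exist for one population and the
analyst cares about a smaller target population; nothing in the code is
specific to genetics, and any numeric design matrices can be supplied.

The key constraint every transfer route must respect: conditional on the
statistic magnitudes, the *signs* of null statistics in the target
environment must remain independent fair coin flips. All three transfer
methods below are designed around that invariance, which is what preserves
the knockoff filter's finite-sample FDR guarantee.

## Gaussian knockoffs

Covariate rows are assumed multivariate Gaussian with known mean and
covariance Sigma (the model-X assumption; in the simulations the truth is
known by construction). Knockoffs are sampled from the exact conditional
law

    X~ | X ~ N( X - (X - mu) Sigma^{-1} S,  2S - S Sigma^{-1} S ),
    S = diag(s),

so that [X, X~] has joint covariance [[Sigma, Sigma - S], [Sigma - S,
Sigma]] and the swap-exchangeability property holds exactly. The knockoff
diagonal uses the equicorrelated rule s = min(1, 2*lambda_min(Sigma)),
shrunk by a relative slack of 1e-6 to keep 2*Sigma - S positive
semidefinite under floating point. The equicorrelated rule is
deterministic and cheap, and for the AR(1) designs used here it is nearly
indistinguishable from the semidefinite-programming alternative; `s_diag`
is an injectable field of `GaussianDesignModel` for users who want to plug
in an SDP solution. Covariance inversion goes through a Cholesky solve and
matrices with condition number above 1e10 are rejected rather than
silently regularized. If no covariance is supplied to the model front end,
a Ledoit-Wolf shrinkage estimate is substituted and the guarantee becomes
approximate — acceptable for exploration, not for confirmatory analysis.

## Importance statistics

The base statistic is the lasso coefficient difference on the standardized
augmented design: W_j = |b_j| - |b_{j+p}| with the penalty tuned by seeded
K-fold cross-validation (10 folds by default; the fold assignment is drawn
once per call and reused across the whole tuning grid so comparisons are
paired). Absolute values make the statistic's sign meaningful when effects
are negative; for nonnegative coefficients this coincides with the plain
coefficient difference. Before fitting, each variable/knockoff pair is
swapped with probability 1/2 (seeded) and the statistic sign is flipped
back afterwards; the mathematical solution is unchanged, but this
symmetrizes any residual bias from the solver's fixed coordinate order, so
null signs are exactly symmetric even at finite solver tolerance. Binary
outcomes are supported through l1-penalized logistic regression behind the
same interface; the simulations use the Gaussian family.

### Prior-weighted (transfer) statistics

External information enters as an inverse-importance weight per pair,

    phi_j = 1 / (0.05 + |b^ext_j| + |b^ext_{j+p}|),

computed from a sparse regression on external data alone, or on the pooled
data of all environments when the null sets can be assumed shared across
environments (the pooled variant). The 0.05 offset caps the weight of
variables the external fit ignores at 20; it is exposed as `phi_eps`. A
variant without the knockoff term is available (`include_knockoffs=False`).
Multiple external coefficient vectors (e.g. several related phenotypes)
are combined by their entrywise mean before the weights are formed.

The weighted lasso applies a per-pair penalty

    lambda_j = lambda * f_j / mean(f),   f_j = (1 - gamma) + gamma * phi_j,

with lambda and gamma in [0, 1] tuned jointly by cross-validation on the
target data. The relative factors f are normalized to unit mean so the
cross-validated lambda path lives on the same scale for every gamma; at
gamma = 0, and likewise for constant phi, the construction reduces exactly
to the unweighted statistic. Without this normalization the raw phi values
(up to 20 on standardized designs) would dwarf any useful lambda, every
gamma > 0 would zero out all coefficients, and cross-validation could
never select a positive gamma — defeating the point of the prior. Ties in
cross-validated error break toward smaller gamma (less reliance on the
prior) and then larger lambda (sparser model). Per-feature penalties are
realized exactly by column rescaling (divide column j by f_j/mean(f), fit
one common-penalty lasso, rescale the coefficient back); agreement with a
direct coordinate-descent solve of the weighted objective is covered by a
unit test. Because the weight is identical within each pair, the flip-sign
property holds exactly and null signs remain symmetric, whether phi comes
from external data alone or from the pooled fit under the shared-null
assumption.

## The knockoff filter

The threshold form selects {j : W_j >= T} with T the smallest t > 0 such
that (offset + #{W_j <= -t}) / max(#{W_j >= t}, 1) <= q. The sequential
form orders the hypotheses, finds the smallest prefix length k whose
complement satisfies the same bound, and rejects the positive statistics
past k; with the ascending-|W| ordering the two coincide exactly (tested
on random vectors against a brute-force scan). Zero statistics — common
with lasso fits — count as neither positive nor negative and are never
rejected. The default offset of 1 carries the finite-sample FDR guarantee;
offset 0 is exposed but logs a warning, since it can fail to control the
FDR when very few discoveries are made. A consequence worth knowing: with
offset 1 nothing can ever be rejected at level q unless at least ceil(1/q)
statistics are positive, so analyses with very few true signals and strict
q legitimately return empty selections. The estimated-FDP path is computed
in one reverse cumulative pass; equality with a per-step recount is a unit
test.

## Transfer by re-ordering

**Linear re-ordering** keeps sign(W0) and sets |W_lro| = (1-theta)|W0| +
theta|Wext|, where Wext are knockoff statistics from the pooled external
environments and theta must be fixed before seeing the data. Null signs
stay fair coins because the external data are independent of the target
environment. theta = 0 recovers the vanilla analysis exactly. An "oracle"
that picks theta per replicate to maximize discoveries exists only in the
experiment harness and is flagged `fdr_guaranteed=false` in every output.

**The adaptive knockoff filter** learns the ordering instead: all signs
start masked, and the procedure repeatedly reveals the hypothesis deemed
most likely to carry a negative sign, so positives accumulate at the end
of the testing sequence where the sequential filter keeps them. Validity
requires only that each reveal decision ignore unrevealed signs, which the
implementation enforces by letting the scoring model see only the
magnitudes |W0|, the prior columns, and the signs already revealed (a
perturbation test flips unrevealed signs and checks reveal decisions are
unchanged). The model refits every `batch` reveals (default 10; batch = 1
is fully sequential) and the first 2*batch reveals use an uninformed
fixed-blend score.

The shipped sign model is a ridge-penalized logistic regression of
P(sign = -1) on (|W0_j|, prior columns). Two safeguards address a
selection pathology specific to this training scheme — the revealed sample
consists precisely of the hypotheses that looked most negative, so early
training sets are small, biased toward small magnitudes, and weakly
identify the magnitude coefficient:

* the coefficient on |W0| is constrained nonpositive, so when the prior
  carries no information the learned ordering degenerates to the
  ascending-magnitude ordering of the standard filter rather than an
  arbitrary (or inverted) one;
* prior columns carry a stronger ridge penalty (10.0) than the magnitude
  column (1.0), so the prior influences the ordering only once the
  revealed signs actually support it; the penalties are fixed while the
  training set grows, letting the shrinkage fade as evidence accumulates.

An effectively unpenalized fit, tried first, produced wildly oscillating
coefficients and orderings worse than vanilla; zero statistics are also
excluded from training, since a masked zero carries no sign information
(labeling zeros "non-negative" taught the model the opposite of the
truth). Degenerate fits — fewer than two informative reveals, or all
revealed signs equal — fall back to the fixed-blend score and are flagged
in the ordering trace. Any other model can be plugged in through the
`score(abs_w0, priors, revealed_idx, revealed_neg)` interface, e.g. a
smoother or a tree ensemble.

## Synthetic data generator

`generate_environments` emulates a multi-environment linear study: E+1
environments (default 3) of n = 800 observations each on p = 500
variables, covariate rows i.i.d. N(0, AR1(rho=0.5)), and outcomes
y = X beta_e + N(0, 1). Each environment has 60 signal coordinates; all
external environments share one signal set, and the fraction it shares
with the target's (the *overlap*) is the control parameter. Supports are
drawn uniformly subject to the overlap constraint, with overlap counts
rounded to the nearest integer and the realized value reported.

Nonzero effects all equal a/sqrt(n) with a = 3.5 (about 0.124 at
n = 800). The amplitude is parameterized per-1/sqrt(n) because that is the
scale on which power neither saturates nor vanishes as n varies: a flat
a/n parameterization (also available via `amplitude_scale="n"`) puts the
per-coordinate effect at 0.004, where every method's power is essentially
zero and the power comparison degenerates. Effects are all positive by
default; `random_signs=True` flips each independently. Seed handling is
counter-based — every draw derives from (master_seed, replicate,
environment, purpose) through `numpy.random.SeedSequence` — so any single
replicate is reproducible in isolation and results are independent of
execution order or worker count.

What the generator does *not* emulate: discrete genotypes, linkage-
disequilibrium block structure, population stratification, differing
sample sizes or covariate laws across environments, non-linear outcome
models, and heavy-tailed noise. Passing tests therefore demonstrate the
statistical mechanics of the methods under a clean Gaussian linear design,
not robustness to realistic genomic data.

## The experiment harness and study scales

`run_experiment` maps replicates over an (overlap, replicate) grid,
computing per replicate: knockoffs per environment, target statistics W0,
pooled-external statistics Wext, pooled-data prior weights phi, and every
requested method's selection at level q, scored against the target support
S0. The pooling benchmark — a single analysis of the concatenated data —
is also scored against S0, which is exactly why it violates FDR at low
overlap: it reports variables that are non-null in *any* environment.

Monte-Carlo scales. The default configuration mirrors the reference design
(p = 500, n = 800, 500 replicates). The test suite and the acceptance
script run a reduced rendition chosen to keep a full run on one CPU in the
tens of minutes: p = 200, n = 400, 60 signals, 100 replicates per overlap
in {0, 0.5, 1}, 5 CV folds, a 30-value lambda path truncated at
alpha_max/100, and a gamma grid of {0, 0.25, 0.5, 0.75, 1}. Since effects
scale with 1/sqrt(n), the reduced design keeps power in the informative
mid-range, and FDR control — the quantity under test — is guaranteed at
any scale. The truncated lambda path was checked against the full
100-value path on spot replicates; the cross-validated selections agree.

## Numerical choices

* Lasso solves use scikit-learn coordinate descent, tolerance 1e-4,
  precomputed Gram matrices, max 10,000 iterations; tests of exact
  contracts (flip-sign, duplicate-row invariance, the coordinate-descent
  oracle) tighten the tolerance to 1e-12 instead of loosening assertions.
* Standardization is population-style (ddof 0); constant columns are
  centered but not scaled.
* Cross-validation folds derive from the seed; pooled fits assign folds
  per environment from (seed, env_id), which makes pooled coefficients
  invariant to the order in which environments are listed.
* Ordering ties (equal scores, equal |W|) break by original index, so runs
  are bit-reproducible.
* The logistic sign model is optimized by L-BFGS-B with an analytic
  gradient; the box constraint on the magnitude coefficient guarantees a
  well-defined ordering even under complete separation.

## Limitations

* The FDR guarantee is exact only when the covariate law is known; the
  estimated-covariance path is a convenience, not a validated
  approximate-knockoffs construction.
* Only lasso-family statistics are provided; the statistic interface
  accepts any flip-sign construction, but trees or neural importance
  measures are out of scope.
* Group-level hypotheses (testing blocks of correlated variables jointly)
  and knockoffs for discrete covariates or hidden-Markov genotype models
  are not implemented.
* The adaptive filter's power depends on the sign model; the shipped
  logistic model is intentionally conservative and a flexible
  nonparametric model may extract more from strong priors.
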