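# Methods

## The model

A gene is a continuous-time Markov chain over a small set of promoter
states coupled to a birth-death process for mRNA copy number. In the
two-state telegraph model the promoter leaves the OFF state at rate `k_on`
(so the mean OFF duration — the inverse burst frequency — is `1/k_on`
minutes) and leaves the ON state at rate `k_off`; mRNA is produced at rate
`k_eject` only while ON and degrades first-order at `k_decay`. The burst
size, the mean number of transcripts made per ON period, is
`k_eject/k_off`. One-state (constitutive, Poisson) and three-state (two
OFF states in a serial reversible chain OFF1 ⇄ OFF2 ⇄ ON, ejection only
from ON) variants are supported; the serial-reversible topology is the
minimal generalized-telegraph extension consistent with "two inactive
states", and is what `burstkit` means by a three-state model. A
forward-biased or irreversible chain needs no separate mode: backward
switching rates may simply be set to zero.

### Steady state by CME truncation

The stationary count distribution solves `A p = 0` for the chemical master
equation generator `A` over the joint (promoter state, count) space,
truncated at a copy number `N` where essentially no mass remains. The
truncation starts from a moment-based guess
`N0 = 4⌈mean⌉ + 10⌈√variance⌉` (exact two-state variance; a slow-switching
upper bound otherwise), never below the largest observed count, and doubles
until the boundary mass is below 1e-8, with a hard cap at 10,000 (an error
beyond that: the distribution is not concentrated).

Two solvers are provided and cross-checked against each other in the test
suite:

* **banded** (default): the generator is banded with bandwidth `n_states`
  in count-major ordering. One well-scaled component — a joint state near
  the stationary mode — is pinned to 1, its redundant balance equation
  dropped, and the remaining banded system solved directly; the vector is
  then renormalized. Pinning a *tail* component instead would require the
  solution to represent ratios like `P(mode)/P(N)`, which overflow once the
  boundary probability underflows; the interior pin keeps the system well
  conditioned at any truncation. Deleting a matching row/column pair never
  widens the band, and the submatrix is column diagonally dominant. A
  compiled (numba) version of the same elimination backs the MCMC loop and
  is asserted to agree with the reference solver.
* **nullspace**: orthogonal-factorization (SVD) null space of the dense
  generator, rejecting inputs whose two smallest singular values are not
  separated by a relative factor of 1e6 (the truncated generator must have
  a simple zero eigenvalue). Slower; used as the reference and for
  degeneracy diagnostics.

### Beta-Poisson cross-check

For two states the stationary law is the Beta-Poisson mixture
`P(n) = ∫ Pois(n; νλ) Beta(λ; α, β) dλ` with decay-scaled parameters
`α = k_on/k_decay`, `β = k_off/k_decay`, `ν = k_eject/k_decay`.
`beta_poisson_pmf` evaluates the *normalized* mixing integral (prefactor
`1/B(α,β)`, so the pmf sums to one) by adaptive quadrature in log space.
It is deliberately kept independent of the CME route: the two must agree
pointwise within 1e-6 across a 50-point grid spanning α, β ∈ [0.05, 20]
and ν ∈ [0.5, 100], and the quadrature itself is pinned to the confluent
hypergeometric closed form in the tests.

### Capture loss and alleles

scRNA-seq observes each molecule with probability `p` (the yield, ~5% for
typical 10x data). Binomial thinning of any generalized-telegraph
stationary law equals the stationary law with `ν → pν`; the suite verifies
this identity numerically to 1e-8 for 1-, 2- and 3-state models. Fitting
therefore never thins explicitly: the inferred `k_eject` is the
yield-scaled rate (an optional division by a user-supplied yield is
offered for reporting), while `k_on`, `k_off` and the OFF time are
yield-free. Burst size inherits the yield scaling and is treated as a
relative quantity. Cells carry `n_alleles` independent gene copies
(default 2); the cellular count distribution is the n-fold discrete
self-convolution of the single-allele law.

## Inference

Counts per cell are assumed independent, so the log-likelihood is the sum
of log model probabilities at the observed counts (n times the negative
cross-entropy against the empirical histogram); it is computed from the
histogram, with probabilities floored at 1e-300. The decay rate is fixed
at `ln 2 / half-life` from an independently measured half-life — the
stationary histogram carries no timescale of its own — and the remaining
1/3/5 free rates get broad log-normal priors: means 0.01 (`k_on`-like),
0.1 (`k_off`-like), 0.05 (`k_eject`) per minute, all with coefficient of
variation 10 (`σ² = ln(1+CV²)`, `μ = ln mean − σ²/2`).

Sampling is adaptive random-walk Metropolis in log-rate space, where the
priors are Gaussian. During the warmup (first 25% of samples, discarded)
a global step size is tuned toward 20–40% acceptance and the proposal
*shape* is adapted to the running covariance of the draws
(Haario-style, step `2.38/√d · chol(Σ̂)`); the posterior is strongly
ridge-shaped in `(log k_off, log k_eject)` for weakly identified genes and
isotropic proposals mix far too slowly there. After warmup the proposal is
frozen, keeping the chain Markovian over the retained draws. Default
budget: 4 chains × 50,000 samples; convergence is monitored with the split
potential scale reduction factor (r-hat) per free rate, and a gene whose
worst r-hat is ≥ 1.05 is automatically rerun once with a doubled budget.
Chains are seeded deterministically; identical seeds give bit-identical
chains.

Summaries are computed on the pooled post-warmup draws: median, unscaled
MAD (median absolute deviation from the median) and 2.5–97.5 percentile
credible intervals. Derived quantities are summarized per draw —
`burst_size = k_eject/k_off` on the paired draws, so its uncertainty
respects the strong k_off–k_eject cross-correlation, and
`off_time = 1/k_on` — never by combining marginal summaries. Multi-start
bounded L-BFGS-B maximum-likelihood estimates are available as a
frequentist comparison; the likelihood at the MLE is also used to refine
the best likelihood fed to AIC.

Proposals whose adaptive truncation would exceed the cap are treated as
zero-likelihood (rejected): with observed counts bounded by a few hundred,
parameter regions implying means in the thousands are astronomically
unlikely anyway, and the cap only prunes numerically hopeless excursions.

## Model comparison

`AIC = 2k − 2 ln L̂` with `k` = 1/3/5 free rates (decay excluded) and
`L̂` the best likelihood across MCMC draws and the MLE refinement.
`WAIC = −2(lppd − p_waic)` from a draws × cells pointwise log-likelihood
matrix, with the variance form of `p_waic` and log-sum-exp stabilization.
Ties break toward fewer states (parsimony).

## Quality control

*Cell stage*: cells are kept when they fall inside the central 90%
quantile band (5th–95th percentile, edges inclusive) of **both** the
feature-count and total-count distributions — the two bands are
intersected — and their mitochondrial read fraction is strictly below 5%
(configurable to 7.5%; mitochondrial genes are recognized by a
configurable name prefix, default `MT-`/`mt-`).

*Gene stage*: a fitted gene passes only if `MAD/median < 0.75` (strict)
for each of `k_on`, `k_off`, `k_eject` and burst size, **and** its mean
observed counts per cell ("expression", computed on the QC-passed matrix)
exceeds 0.01 (strict). The filter is a pure per-row predicate.

## mRNA half-lives

After transcriptional shutoff each transcript follows
`y(t) = Asym + (R0 − Asym) e^(−k_decay t)`; the half-life is
`ln 2 / k_decay` hours. Concentrations come from ERCC spike-in scaling:
each sample's factor is the known spiked total divided by its observed
spike-in counts (total-sum scaling; a per-spike-in log-log regression is a
possible alternative but the total-sum default is exact for the
synthetic courses). The nonlinear fit is self-starting (asymptote from the
late timepoints, rate from a log-linear regression of the decaying
component) and, by default, weights residuals by the observed value —
concentration noise is multiplicative, and relative weighting is the
efficient least-squares choice under log-normal errors; unweighted
("absolute") mode is available for strict parity with classic
linear-space asymptotic-regression fits, and the asymptote may be pinned
to zero. All replicate points are fitted jointly (no pre-averaging); the
synthetic course generator emits three replicate samples per timepoint by
default, matching routine bulk time-course practice. Fits that fail or
return a nonpositive rate are flagged and their half-life reported as
missing.

## Gene-network shift

Counts are depth-normalized per cell — `round(count/cell_total ×
depth_scale)` with the scale set to the mean reads per cell of the
shallowest sample (~30,000 in typical 10x data), keeping the data integer
— and pair coexpression is the Spearman rank correlation (midrank ties)
across cells. Only pairs where both genes are detected (nonzero
normalized count) in at least 10% of cells in both compared samples are
eligible; the filter is applied within each compared sample pair, so the
perturbation and replicate comparisons may cover different pair sets
(both sets are reported). A perturbation's effect is the distribution of
per-pair changes Δρ benchmarked against a replicate-vs-replicate control.
Three spread summaries are emitted: the centered MAD of signed Δρ, the
centered MAD of |Δρ|, and the median |Δρ| (MAD about the no-change point
0). The three agree for null-centered distributions; the about-zero form
is the one that remains sensitive when a subset of pairs shifts
coherently, which is why the shift-detection study uses it on the
monitored pairs — a centered MAD is exactly invariant to a uniform shift,
and over the full pair universe any robust summary ignores a 1%
contamination by construction.

## Cross-cell-type normalization

Sequencing depth sets the capture yield, and by the thinning theorem the
eject rate (hence burst size) scales with it. Comparing expression or
burst size across samples of different depth therefore uses
`value / reads_per_cell × mean(reads_per_cell across cell types)`, with
reads per cell taken from the post-QC matrix (the fits are computed on it).

## Synthetic data: what it emulates, and what it does not

The simulator is an exact Gillespie realization of the same reaction
network (independent of the CME solver, so the two validate each other;
total-variation agreement < 0.02 at 50,000 cells is enforced). Cohorts
are built per gene as sums of independent allele draws followed by
binomial capture thinning; per-cell covariates (total counts, feature
counts, a Beta-distributed mitochondrial fraction) exist so the cell-QC
stage has something realistic to filter. Stationarity is approached by
initializing the promoter from the switching chain's stationary law and
the count near the stationary mean, then burning in for at least ten
decay half-lives and ten cycles of the slowest switching rate.

Rank-correlated gene pairs are induced by a Gaussian copula
(`r = 2 sin(πρ/6)`) pushed through each gene's empirical quantile
function, which preserves marginal histograms exactly (a permutation of
the observed counts); discreteness attenuates the achieved Spearman
correlation for sparse genes, and the achieved value is reported.

Ground-truth rate tables are drawn from the fitting priors, rejection-
sampled to single-allele mean expression in [0.3, 20] counts and ν ≤ 200:
the raw CV-10 priors occasionally imply genes with count support in the
thousands, which no expression-filtered scRNA-seq analysis would retain.
The desk-scale studies therefore demonstrate calibration and recovery
*within the realistic count regime*, not for arbitrarily extreme
parameter combinations.

Deliberately not modelled: UMI sequencing errors, doublets, ambient RNA,
batch effects beyond depth differences, correlated alleles, cell-cycle
structure, and time-dependent rates. Passing studies show the inference
machinery is correct and calibrated on data generated by the model class
itself; they cannot certify robustness to real-data artefacts outside
that class.

## Desk-scale study conditions

The validation studies (also rerun by `scripts/acceptance.py`) use: the
50-point closed-form grid above; 20 prior-drawn genes × 5,000 cells ×
4 chains × 50,000 samples for posterior recovery (coverage of 95%
intervals, rank correlation of true vs estimated log10 k_on, r-hat);
the same genes binomially thinned at p = 0.2 for the yield-rescaling
check; 20 replicates × 5,000 cells per regime for AIC selection power
(Poisson ν = 4 vs bursty α = 0.05, β = 1, ν = 50); 100 genes ×
7 timepoints × 3 replicates with CV 0.1 noise and log-normal half-lives
around 4 h for decay recovery; and 20 seeded runs of 100 genes ×
1,500 cells with 50 coupled pairs (ρ = 0.5 removed under perturbation)
for network-shift detection.

## Known limitations

* The three-state chain's identifiability from stationary histograms is
  poor at realistic yields; its role here is model comparison, not
  routine parameter interpretation.
* The MCMC proposal adaptation is frozen after warmup; pathological
  multimodal posteriors (not observed in the studied regimes) would need
  tempering.
* Burst size from scRNA-seq is yield-scaled; only fold changes and
  depth-normalized comparisons across conditions are meaningful.
* Half-life fits assume shutoff is instantaneous and complete; transcription
  lag after drug treatment is not corrected.
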