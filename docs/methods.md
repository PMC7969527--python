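# Methods

## The model

`qamrm` fits a finite mixture of Rasch measurement models in which the latent
classes are not free: they are the attribute profiles α ∈ {0,1}^K of a
user-supplied Q-matrix, and item difficulties are tied (anchored) across
classes a priori. For person *i*, item *j* and class *g* with profile α_g,

P(Y_ij = 1) = Σ_g π_g · exp(θ_i − b_{j,L(j,g)}) / (1 + exp(θ_i − b_{j,L(j,g)})),

with θ_i | g ~ N(0, σ²) (one shared variance, mean fixed at 0 for
identification) and mixing proportions π (G − 1 free parameters). The level
map L(j, g) is derived from the Q-matrix:

* **non-compensatory** (conjunctive): L = 1 when class g masters *all*
  attributes item j requires, else L = 2 — two levels per item;
* **compensatory** (disjunctive): L = 1 + (number of required attributes g
  has not mastered) — up to (row sum + 1) levels per item.

Classes whose mastery intersects an item's required set identically share
that item's difficulty *literally* (one parameter), which places all classes
on one common logit scale with no post-hoc linking and cuts the parameter
count sharply (for the bundled 14-item, 3-attribute design: 28 anchored
non-compensatory difficulties vs 112 unconstrained; 38 compensatory).

Attribute hierarchies restrict the class space: a linear mastery chain over K
attributes leaves K + 1 monotone profiles; arbitrary restrictions can be
given as explicit profile lists. Under a restricted space only *realized*
levels receive free parameters — unrealized levels are non-identifiable, so
they are never allocated (this is what makes the hierarchical compensatory
layout for the 28-item ECPE design come to 65 difficulties + 3 mixing + 1
variance = 69 free parameters).

Assumptions worth stating: unit discrimination (Rasch restriction — no 2PL
slopes), local independence given (g, θ), one ability variance shared across
classes, ignorable missingness (each person's likelihood multiplies over
observed items only), and a correct Q-matrix. Class-specific variances and
ability means are deliberately not free parameters; requesting them is an
error rather than a silent extension.

## Estimation

Marginal maximum likelihood by EM, integrating θ out with Gauss–Hermite
quadrature rescaled to N(0, σ²) (default 31 nodes; at n = 500 the 31-node
log-likelihood agrees with a 61-node rule to ~1e-5, and 41 nodes to < 1e-6).
The missing data are (class, ability); the E-step computes joint posterior
responsibilities over (class, node) in log space, and the M-step is:

* π_g ← mean posterior class mass (floored at 1e-12 and renormalized);
* each difficulty slot ← root of its one-dimensional weighted Rasch
  likelihood equation — expected correct = expected model probability mass —
  pooled over *all* (item, class) cells anchored to the slot, solved by
  safeguarded Newton (steps clipped at 3 logits, values at ±15; a slot with
  ~zero expected exposure is held and logged rather than updated);
* σ² ← posterior expected second moment of θ.

Because the quadrature grid tracks σ between iterations the monitored
log-likelihood is monotone only up to quadrature error; in practice the paths
are monotone to ~1e-8, which the tests assert.

**Multi-start protocol** (defaults): 20 random starts × 10 burn-in EM
iterations; the best 4 continue until the relative log-likelihood change
falls below 1e-7 or 2,000 iterations. Starts draw slot difficulties from
U(−1, 1) sorted ascending within item (so level order begins monotone),
Dirichlet(5, …, 5) mixing, σ = 1. Label switching is structurally absent —
classes are pinned to profiles by the anchor map — so no relabelling is ever
applied. If no run converges the best solution is returned flagged
`converged=False` with a warning, never silently.

Level monotonicity (level 1 easiest) is *expected* but not enforced during
estimation: hard order constraints would change the MLE, and real data can
tie adjacent levels. `monotonicity_report` flags inversions post fit.

**Standard errors.** The analytic score of the marginal log-likelihood
(via Fisher's identity: slot residuals, class-mass residuals on the
multinomial-logit scale, and the σ second-moment residual) is differenced
centrally (step 1e-4·max(1, |x|)) to form the observed information; SEs are
the square roots of the inverse's diagonal, with mixing proportions mapped
back from the log-ratio scale by the delta method. A singular or indefinite
information matrix yields NaN SEs with a warning. Wald 95% intervals are
estimate ± 1.96·SE.

**Derived quantities.** AIC = −2LL + 2p, BIC = −2LL + p·ln n, and the
sample-size adjusted BIC with the (n + 2)/24 convention,
ABIC = −2LL + p·ln((n + 2)/24). The ABIC convention matters when comparing
against published values and is therefore stated here prominently; it is the
convention that reproduces the published ECPE criterion gaps exactly given
the layouts' parameter counts. Classification is the posterior modal profile
(ties broken toward the lower-mastery profile and counted); abilities are
EAP over the joint (class, node) posterior with posterior SDs.

## The synthetic-data generator

`TruthSpec` encodes the recovery-study conditions: the bundled 14-item,
3-attribute Q-matrix (6 one-, 6 two-, 2 three-attribute items), uniform
mixing 1/8, θ ~ N(0, 1), and level difficulty values (−2, 2) for two-level
items, (−2, 1, 2) for three-level and (−2, −1, 1, 2) for four-level items —
ascending level index receives ascending difficulty, the only assignment
consistent with the intended level ordinality. Generation draws class, then
θ, then Bernoulli responses through the IRF; everything is reproducible from
a single seed, and recovery-study replications get per-replication seeds
spawned deterministically from the master seed (results are independent of
execution order).

What the generator does *not* emulate about real data: misspecified
Q-matrices, class-varying ability variances or means, item slopes ≠ 1,
non-ignorable missingness, and local dependence. Passing recovery tests
therefore show calibration of the estimator *under the model*, not
robustness to these violations (the generator can express non-uniform mixing
and other variances, but those are not default study conditions).

## Study / test problem sizes

The recovery studies run 200 replications per condition (n = 1000 and 2000
non-compensatory, n = 1000 compensatory) with a lightened but equivalent
multi-start protocol (6 starts × 6 burn-in, 2 survivors, 21 quadrature
nodes, tol 1e-7) — local maxima are structurally rare here because classes
are pinned a priori, and a truth-started run is verified in the tests to
never beat the multi-start protocol's optimum by more than stopping error.
1,000-replication runs and the full 20/10/4 protocol are a configuration
change away (`--replications`, `FitConfig`). Monte-Carlo error at 200
replications is roughly ±0.003 on pooled bias and ±0.01 on pooled coverage.

## Numerical choices and degenerate inputs

Log-space likelihoods throughout; log-sum-exp for all mixing; expit/log1p
forms for the IRF. σ is floored at 1e-3 and mixing at 1e-12. A degenerate
single-node quadrature rule is provided for σ → 0 limiting checks. Response
matrices reject non-binary cells and name any person/item with no observed
responses; Q-matrices reject non-binary cells, all-zero item rows and
unmeasured attributes by name. Class-space enumeration is capped at K = 12
attributes (4,096 profiles) to guard against accidental explosion. Ties in
classification go to the lower-mastery (earlier canonical) profile,
deterministically.

## Known limitations

* Marginal ML difficulty estimates carry a small outward finite-sample bias
  for levels with little effective exposure (e.g. the full-mastery level of a
  three-attribute item at n = 1000 rests on ~125 persons); the recovery study
  makes this visible as a pooled signed bias of roughly −0.02 at n = 1000
  that shrinks towards zero as n grows.
* Difficulties are reported in the P = σ(θ − b) convention; analyses using a
  threshold convention differ by sign patterns — compare magnitudes with
  care.
* The Q-matrix is taken as correct; no validation or misspecification
  detection is attempted.
* No 2PL/slope extension, no polytomous responses, no Bayesian/MCMC or
  bootstrap machinery.
* Empty classes are never dropped automatically; inspect `class_mass` and
  refit on an explicit reduced profile list if a profile carries ~no mass.
* Finite-difference observed information can go indefinite near boundary
  mixing estimates; SEs are then reported as undefined rather than patched.
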