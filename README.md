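# qamrm — Q-matrix anchored mixture Rasch models

Mixture item response models let examinees differ both *quantitatively* (a
continuous ability θ) and *qualitatively* (a latent class). The classic
mixture Rasch model leaves every class's item difficulties free, which makes
class scales incomparable without post-hoc anchor-item hunting and burns a
parameter per item per class. `qamrm` implements the Q-matrix anchored
variant used in diagnostic measurement: the latent classes are the 2^K
attribute profiles α of a user-supplied Q-matrix, and item difficulties are
constrained equal across classes *a priori* — two classes whose mastery
intersects an item's required attributes the same way share that item's
difficulty parameter. The model for a correct response is

    P(Y_ij = 1) = Σ_g π_g · exp(θ_i − b_{j,L(j,g)}) / (1 + exp(θ_i − b_{j,L(j,g)}))

with θ | g ~ N(0, σ²) shared across classes and L(j, g) the anchoring level
of item j in class g: **non-compensatory** (level 1 only when *all* required
attributes are mastered, else level 2) or **compensatory** (one level per
unmastered required attribute). Estimation is marginal maximum likelihood
via EM with Gauss–Hermite quadrature, multi-start initialization, observed-
information standard errors, AIC/BIC/ABIC, posterior profile classification
and EAP ability estimates. Attribute hierarchies (e.g. a linear mastery
chain) restrict the profile space and shrink the parameter count further.

The package is aimed at psychometricians who want diagnostic classification
*and* a continuous ability score from one calibrated model: researchers
running parameter-recovery simulations, and analysts fitting real
dichotomous tests with a substantive Q-matrix (the 28-item ECPE grammar-test
Q-matrix and its lexical→cohesive→morphosyntactic hierarchy ship as bundled
fixtures).

## Worked example

```python
import qamrm as qm

truth = qm.recovery_truth("non_compensatory")   # 14 items, 3 attributes
space = qm.enumerate_profiles(3)                # 8 profiles (000) ... (111)
y, true_classes, true_thetas = qm.simulate_dataset(truth, 2000, seed=42)

cfg = qm.FitConfig(n_starts=6, burn_iters=6, n_survivors=2,
                   n_quadrature=21, seed=0)
fit = qm.fit_em(y, truth.q, space, "non_compensatory", cfg=cfg)
print(qm.parameter_table(fit, truth.q.item_labels).head())
```

Running `python examples/fit_synthetic.py` (this exact analysis) prints:

```
converged=True after 43 iterations, loglik=-14469.70, 36 free parameters

 slot item  level  estimate     se  truth
    0    1      1    -1.642 +0.119 -2.000
    1    1      2    +1.992 +0.134 +2.000
    2    2      1    -1.894 +0.126 -2.000
    3    2      2    +1.925 +0.125 +2.000
...
modal-profile accuracy vs generating classes: 0.801 (chance 0.125)
EAP ability vs generating ability: correlation 0.593
```

36 free parameters = 28 anchored difficulties (two levels × 14 items) + 7
mixing proportions + 1 ability variance; the unconstrained mixture Rasch
model would need 120. Each difficulty estimate lands within a couple of
standard errors of its generating value (level 1 ≈ −2 for classes mastering
the item's attributes, level 2 ≈ +2 otherwise), classification recovers the
generating profile for 80% of examinees, and the EAP scores track the
generating abilities as well as 14 Rasch items allow.

Other examples: `examples/anchor_maps.py` (how the Q-matrix ties parameters
and the 28/38/112 count arithmetic), `examples/recovery_study.py` (bias and
95% CI coverage), `examples/hierarchy_and_model_comparison.py` (linear
mastery hierarchy and AIC/BIC/ABIC comparison).

## Command line

```bash
qamrm simulate --mode compensatory --n 2000 --seed 7 --out responses.csv
qamrm fit responses.csv qmatrix.csv --mode compensatory --out fit_out
qamrm classify responses.csv qmatrix.csv --out cls_out
qamrm recover --preset noncomp-n1000 --replications 200 --out rec_out
qamrm compare fit_out/summary.json other_fit/summary.json
```

Every command writes a `manifest.json` that reproduces the run. Fitting the
real ECPE data (2,922 × 28, distributed in the CDM R package) is a two-step
optional workflow: `Rscript scripts/ecpe_export.R ecpe_responses.csv`, then
`qamrm fit` with the bundled `ecpe_qmatrix.csv` and
`--hierarchy "a3<a2<a1" --mode compensatory`.

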