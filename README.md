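# mbdynamics

Longitudinal gut-microbiome dynamics under immune checkpoint blockade
(ICB): a tested, reusable pipeline for asking *how* microbial relative
abundances change over the first months of immunotherapy, and how those
trajectories differ between patients who do and do not reach durable
benefit (progression-free survival of at least 12 months, PFS12) in
different clinical contexts — therapy regimen, ICB-induced colitis and
proton-pump-inhibitor (PPI) use.

It is written for microbiome researchers analysing MetaPhlAn4 / HUMAnN3
relative-abundance profiles with repeated sampling per patient, and for
methodologists who want a transparent, fully seeded implementation to
benchmark against.

## The model

Relative abundances are compositional, so inference happens in log-ratio
coordinates.  With `x` a D-part composition, the additive and centered
log-ratio transforms are

    alr(x)_i = log(x_i / x_ref),        clr(x)_i = log(x_i / g(x)),

`g(x)` the geometric mean.  Each sample's alr vector `eta_j` is modelled
by a Bayesian multivariate logistic-normal regression,

    eta_j ~ N(Lambda X_j, Sigma),
    Lambda ~ MatrixNormal(Theta, Sigma, Gamma),
    Sigma ~ InverseWishart(Xi, nu),

where `X` is a Q x N design matrix whose focal block encodes study visit
X (0-3), outcome Z (PFS12) and three binary moderators W1-3 (combination
therapy, colitis, PPI) with all interactions up to X·Z·W:

    Y = b0 + b1 X + b2 Z + b3 XZ + b4 W1 + ... + b15 XZW3.

Peripheral covariates (center, sex, age, BMI, previous targeted therapy,
antibiotics, other immune-related adverse events, days since first
infusion, patient identifier) are mean-centered or weighted-sum coded, so
the intercept is the observation-weighted grand mean and case-control
contrasts involve only the 16 focal coefficients.  Because the alr data
are observed directly, the posterior is conjugate (matrix-normal
inverse-Wishart) and posterior draws are exact.  Draws are mapped to clr
coordinates — invariant to the alr reference — and projected onto post
hoc contrasts: the case-control difference at visit t is
`delta(t) = delta_intercept + t * delta_slope`, and a feature is called
differentially abundant at Bayesian confidence level (BCL) p when the
equal-tailed p-credible interval of `delta(t)` excludes zero.

On top of the regression, the package provides log-ratio **balances**
`B = mean(log x_{I+}) - mean(log x_{I-})` as per-sample biomarker scores
(evaluated by Wilcoxon tests, repeated cross-validated AUC and
Cox/Kaplan-Meier survival stratification), classical 2x2 cohort
statistics, and a synthetic cohort generator with planted ground truth.

## Worked example

```python
from mbdynamics.simulate import SimConfig, simulate_cohort
from mbdynamics.pipeline import run_longitudinal, run_balance
from mbdynamics.balances import BalanceDef
from mbdynamics.contrasts import differential_ranking

sim = simulate_cohort(SimConfig(seed=42))      # 416 samples, 173 patients
res = run_longitudinal(sim.table, sim.meta, S=2000, seed=42)
print(differential_ranking(res.contrast_tables["pfs12"], visit=3).head())

bdef = BalanceDef(sim.truth["balance_plus"], sim.truth["balance_minus"])
m = run_balance(sim.table, sim.meta, bdef, survival=sim.survival,
                repeats=100, seed=42)
```

The ranking lists features by their posterior mean clr difference between
PFS >= 12 and PFS < 12 at the last visit; for this seed the top entries are
planted effects:

```
 rank  feature_id     mean  sig0.9
    1 t__SGB00000 0.856884    True
    2 t__SGB00019 0.825088    True
    3 t__SGB00017 0.772150    True
```

(`mean` is the log fold change in clr units; `sig0.9` marks a 90%
credible interval excluding zero.)  The balance evaluation prints, per
visit, the Wilcoxon p for discriminating the outcome groups and the
100x-repeated 5-fold CV-AUC (mean 0.99 across visits for the planted
balance), and the stratified survival analysis recovers the planted
hazard structure:

```
stratified Cox: HR=1.637 (95% CI 1.089-2.463), p=0.0179
KM median High: 33.79  Low: 20.69    # months
```

i.e. patients below the median balance die earlier, with a hazard ratio
close to the generating value exp(0.5) = 1.65.

The same stages are scriptable from the shell:

```bash
mbdyn simulate --seed 42 --out fixture/
mbdyn fit --profile fixture/profile_sgb.tsv --metadata fixture/metadata.tsv \
          --contrast pfs12 --seed 42 --out model/
mbdyn contrasts --model-dir model/ --contrast pfs12_mono --out extra/
```

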