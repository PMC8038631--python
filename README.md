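# muacglm

Joint mean–dispersion Gaussian GLMs for child MUAC anthropometry.

The mid upper arm circumference (MUAC) is a cheap, fast screen for acute
malnutrition in children under five. A regression of MUAC on a child's
age, weight, height, hemoglobin, total protein and albumen tells you which
measurements drive the *predicted* MUAC — but a plain GLM assumes every
child's MUAC is equally noisy around that prediction. When the residual
spread itself varies with the child's clinical profile, MUAC is less
reliable for some children than others, and a constant-variance model
cannot see that. `muacglm` is built for epidemiologists and
biostatisticians who want both questions answered at once: what determines
the MUAC level, and what determines its reliability.

## The model

Two interlinked generalized linear models are fitted to the same data —
one for the conditional mean, one for the dispersion of the per-child
deviance components *d*ᵢ:

```
E(yᵢ) = μᵢ,   g(μᵢ) = xᵢᵗβ,        var(yᵢ) = φᵢ V(μᵢ)     (mean model)
E(dᵢ) = φᵢ,   h(φᵢ) = gᵢᵗγ,        var(dᵢ) = 2 φᵢ²        (dispersion model)
```

with Gaussian response (identity link *g*, V ≡ 1, dᵢ = (yᵢ − μᵢ)²) and a
gamma dispersion family with log link *h*. Fitting alternates between the
two submodels: the mean model is a weighted least-squares fit with prior
weights 1/φᵢ, the dispersion model is a quasi-likelihood IWLS fit to the
deviance components (REML weighting replaces dᵢ by dᵢ/(1−qᵢ) with prior
weights (1−qᵢ)/2, where qᵢ are leverages), and the loop repeats until the
h-likelihood and coefficients stabilize. Under ML weighting the fixed
point maximizes the extended quasi-likelihood

```
−2h = Σᵢ [ (yᵢ − μᵢ)²/φᵢ + log(2π φᵢ) ].
```

Model choice uses −2ML, the REML-adjusted −2RL = −2h + log det(XᵗWX/2π),
cAIC = −2h + 2·p_mean, AIC and BIC, with lowest AIC as tie-breaker.

Both design matrices use the same ten-coefficient term list by default:
intercept, the six main effects, and the anthropometric interactions
weight:height, age:weight, age:height (raw products, no centering).

Because the hospital cohort this model family was developed on is not
publicly available, the package includes a first-class synthetic cohort
generator: a Gaussian copula with truncated-normal marginals calibrated so
the delivered covariates reproduce the published descriptive moments,
observed ranges and pairwise correlations, plus the published mean and
log-linear dispersion coefficient patterns as ground truth.

## Worked example

```sh
muacglm simulate --n 163 --seed 42 --out cohort.csv
muacglm fit --data cohort.csv --method reml
```

prints (abridged):

```
Mean model
term                estimate          se         t  stars
(Intercept)         3.494497    0.515028    6.7851  ***
age                -2.510144    0.390654   -6.4255  ***
weight              1.328363    0.097514   13.6222  ***
...
Dispersion model
term                estimate          se         t  stars
(Intercept)        -3.570209    1.373014   -2.6003  **
hemoglobin          0.254099    0.071748    3.5415  ***
...
-2ML (-2 h) = 388.9574
cAIC = 408.9574
AIC = 428.9574
converged = True in 14 iterations
```

Read it as: in this synthetic cohort of 163 children, weight is the
dominant positive determinant of the MUAC level (1.33 cm per kg at fixed
interactions), while the positive hemoglobin coefficient in the dispersion
model says children with atypical hemoglobin have noisier MUAC values —
exactly the kind of covariate-driven unreliability a constant-dispersion
GLM hides. Comparing both models on the same cohort
(`muacglm report --n 163 --seed 42`):

```
criterion                          glm           joint
-2ML (-2 h)                   439.4516        388.9574  <- joint
cAIC                          459.4516        408.9574  <- joint
AIC                           461.4516        428.9574  <- joint
winner by AIC: joint
```

The full pipeline (descriptives, correlations, optional backward
elimination screen at p < 0.2, both fits, comparison, diagnostics) runs as
`muacglm pipeline --n 163 --seed 42 --out report.json`, and everything is
available as library functions (`muacglm.generate`, `muacglm.fit_joint`,
`muacglm.compare_models`, `muacglm.diagnostics_bundle`, ...).

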