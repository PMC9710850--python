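# mechlearn

Mechanism discovery with uncertainty quantification for cell-invasion
density data.

Scratch-assay experiments measure how a population of cells re-invades a
gap cut into a monolayer: cell densities `u(x, t)` are recorded at a
handful of positions and times, in a few replicates, with substantial
counting noise.  `mechlearn` asks which mechanisms drive the invasion by
fitting reaction–diffusion models of the form

    ∂u/∂t = T(t; α) [ ∂/∂x( D(u; β) ∂u/∂x ) + R(u; γ) ]

where `T` is a post-scratch delay factor in (0, 1], `D(u; β)` a
density-dependent diffusivity (cell migration), and `R(u; γ)` a
proliferation term, with the carrying capacity `K` fixed at its measured
value.  Rather than fitting the noisy data directly, the package fits a
Gaussian-process surrogate jointly over the density field and its
derivatives `∂u/∂t`, `∂u/∂x`, `∂²u/∂x²`, then runs a **parametric
bootstrap**: each of B draws from the surrogate posterior yields one
parameter estimate (minimising a PDE-residual loss plus a generalised
least-squares data loss, solved with a vertex-centred finite-volume
scheme), so the experimental noise propagates into sampling
distributions for every parameter, functional form, and PDE solution.
Candidate models fitted on the *same* surrogate draws are compared
per-draw through the small-sample Akaike criterion (AICc), giving a
probability that each model belongs to the best-fitting class.

It is aimed at quantitative cell biologists and modellers who want, for
sparse noisy spatiotemporal data: parameter estimates with honest
intervals, hypothesis tests on mechanism structure (e.g. "is diffusion
density-dependent?", "is a delay present?"), and bootstrapped model
selection — at a computational cost far below MCMC.

## Worked example

Generate a synthetic scratch assay from known Fisher–Kolmogorov
mechanisms (β₁ = 301 µm²/h, γ₁ = 0.044 /h) and re-estimate them:

```python
from mechlearn import InvasionModel
from mechlearn.synthetic import generate_study, study_presets

data = generate_study(study_presets()[0], seed=1)      # 37 x 5 x 3 table
model = InvasionModel(data, mechanism=1, n_grid=(30, 30))
res = model.fit(B=30, seed=7, restarts=25, Np=50)
print(res.summary())
```

```
Mechanism discovery bootstrap results
======================================================
delay: none   diffusivity: constant   reaction: logistic
draws: 30 (0 failed)   level: 95%
------------------------------------------------------
parameter          lower        mode       upper
beta_1             266.5       289.3       304.3
gamma_1          0.04386     0.04411     0.04456
------------------------------------------------------
PDE error (MAPE, %): (1.48, 1.83)
diffusivities in um^2/h; rates in 1/h; exponents dimensionless
```

The modes sit within a few percent of the generating values and both
95% intervals cover them; the MAPE line is the bootstrap interval of the
median absolute percentage error between each draw's PDE solution and
the replicate-averaged data.  `res.conf_int()`, `res.test_null("beta_1", 0)`,
`res.plot_fit()` and `res.plot_density("beta_1")` expose the intervals,
CI-based hypothesis tests, and the solution/KDE plots;
`model.compare()` fits the standard five-model catalog on shared draws
and returns the evidence-class matrix P.

The same pipeline is available from the shell:

```
mechlearn simulate --study 2 --seed 1 --out assay.csv
mechlearn fit assay.csv --model 2 -B 30 -w 25 --np-mesh 50 --grid 30 30 --out fit.json
mechlearn select assay.csv -B 30 --out selection.json
```

For real assay tables (CSV/TSV with columns
`position,time,density,replicate` in µm/h/cells µm⁻²), add
`--drop-edge` to exclude the inflated left-most column before fitting.

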