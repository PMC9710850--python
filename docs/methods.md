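# Methods

## The model family

`mechlearn` discovers mechanisms in one-dimensional cell-invasion
dynamics of the form

    du/dt = T(t; alpha) * [ d/dx( D(u; beta) du/dx ) + R(u; gamma) ],

where `u(x, t)` is the cell density, `T` is a multiplicative delay in
(0, 1] modelling the temporary suppression of migration and
proliferation after the monolayer is scratched, `D` is a (possibly
density-dependent) cell diffusivity, and `R` is a proliferation source
term.  The carrying capacity `K` is treated as known and fixed — it is
the one quantity measurable directly from a confluent well — and
defaults to 1.7e-3 cells/um^2.  Zero-flux boundaries are imposed at the
edges of the imaging window.

The candidate library covers no/logistic/probit/complementary-log-log
delays, constant (Fisher–Kolmogorov), porous (Porous–Fisher),
generalized Porous-FKPP (`beta_1 + beta_2 (u/K)^beta_3`) and an extended
two-power diffusivity, and logistic/Gompertz/Richards reactions.  The
standard five-model catalog pairs the first three diffusivities with and
without logistic delay, always with a logistic reaction.  The extended
five-parameter diffusivity is implemented but excluded from the default
catalog: with a 37 x 5 data grid its two power terms are weakly
identifiable.

## Units

Raw data are in um, h and cells/um^2.  All fitting happens in rescaled
units — x/1e3 (mm), t/24 (d), u*1e6 — so every quantity the optimisers
touch is O(1)–O(1e3).  Reported parameters are converted back:
diffusivities to um^2/h (factor 1e6/24), rates to 1/h (factor 1/24);
`alpha_1` and the exponents are dimensionless.  For real assay tables
the left-most density column is systematically inflated by edge effects
and is dropped before fitting (`drop_edge=True`).

## Gaussian-process surrogate

The observed densities are modelled as `u = u* + sigma_n z` with a
zero-mean GP prior on `u*` under an anisotropic squared-exponential
kernel over space–time inputs normalised to the unit square.  Four
hyperparameters (`sigma_f`, `sigma_n`, `ell1`, `ell2`) are estimated by
maximum marginal likelihood with analytic gradients (L-BFGS on
log-parameters, so positivity holds while the optimisation itself is
unconstrained).  Multistart initial values are Latin-hypercube samples
from boxes `ell in [1e-6, 1]`, `sigma in [1e-6, 7 SD(u)]`; the library
default is 250 restarts, and 25 are used in the desk-scale runs (the
likelihood surface for these data has few basins, and 25 starts find the
same optimum as 250 in every case we examined).  Optimised values may
leave the sampling boxes.  No convergence tolerance is prescribed for
the inner optimiser; scipy's L-BFGS-B defaults are used, capped at 200
iterations.

Because differentiation is linear, the joint distribution of
`(u*, du*/dtau, du*/dxi, d2u*/dxi2)` on an `n x m` test grid is Gaussian
with cross-covariances given by closed-form mixed partial derivatives of
the kernel (the 16 block combinations are enumerated explicitly, which
keeps the finite-difference oracle in the tests independent).  The
posterior covariance omits the observation-noise term — the surrogate
targets the underlying density field, not the noisy data.  Before
Cholesky factorisation each diagonal block receives a nugget
`eta_i = eta * tr(Sigma_ii) / tr(Sigma_11)` with `eta = 1e-5`, scaling
the jitter to each derivative block's own magnitude; if factorisation
still fails the nugget is escalated tenfold with a warning.  One
factorisation serves every bootstrap draw: a draw is `mu + L z` with
`z ~ N(0, I)`, and derivative blocks are mapped to physical scales by
the span factors `1/(t_M - t_1)`, `1/(x_N - x_1)`, `1/(x_N - x_1)^2`.

The surrogate grid defaults to 50 x 50.  The desk-scale runs in the
tests and the acceptance script use 30 x 30: the joint covariance is
`4nm` square, so 50 x 50 costs a 10,000^2 Cholesky (~minutes) versus
3,600^2 (~seconds), while the induced parameter estimates differ by
under 1% on the synthetic studies.

## Loss and estimation

Each bootstrap draw supplies sampled density values and derivatives.
Two losses are combined as `log L_PDE + log L_GLS` (the logs bring the
two very different scales onto comparable footing):

* `L_PDE`: mean squared residual of the expanded PDE
  `du*/dt - T(t) [ dD/du (du*/dx)^2 + D d2u*/dx2 + R(u*) ]` over the
  test grid.  Mechanisms are evaluated at the sampled densities clipped
  at zero; the surrogate can dip below zero where the true density
  vanishes, and fractional diffusivity powers are undefined there.
* `L_GLS`: mean squared data residual between the numerical PDE
  solution (nearest-node extraction at the data coordinates) and the
  replicate-averaged densities, standardised by the GP's `sigma_n` and
  weighted 10:1 in favour of the initial time (the t = 0 profile need
  not satisfy the governing model, and anchoring it matters most).
  Replicate averaging here matches the error metric used for reporting;
  the paper-level choice between per-replicate and averaged residuals is
  not determined by the model, and averaging keeps `L_GLS` and the AICc
  residuals identical by construction.

A hard feasibility barrier sets the loss to +inf when the delay is
negative anywhere on the time grid, the diffusivity is negative anywhere
on `[0, max u*]`, or the Gauss–Legendre (64-node) integral of `R` over
`[0, max u*]` is negative.  PDE integrator failures (blow-ups from
pathological trial parameters) are likewise mapped to +inf rather than
aborting a draw.

Minimisation uses Nelder–Mead on `theta / scales`, which tolerates the
infinite barrier; the returned point never scores worse than its start.
The first ~10 ("pilot") draws use ~5 Latin-hypercube starts from
per-parameter boxes (delay intercept in [-5, 5]; rates and diffusivities
log-uniform over physiologically generous ranges in rescaled units); the
pilot estimates fix `scales` as the signed geometric mean of the pilot
magnitudes (floored at 1e-8, sign by majority), and the remaining draws
start from all-ones in scaled space.  For delay-free models whose RHS is
linear in the parameters, `linear_basis_fit` solves the stacked residual
system by least squares in microseconds; it ignores the data term and is
intended for scale estimation and cross-checks, not final inference.

Optional data thresholding masks test-grid points whose sampled density
or |du/dt| falls outside caller-chosen fractions of the draw's maxima
(the comparator is fraction-of-maximum; an absolute comparator would tie
the thresholds to the unit system).  Defaults are vacuous.

## Bootstrap and inference

`run_bootstrap` executes B draws (library default 100; desk scale 30).
Draw b's standard-normal vector depends only on `(seed, b)`, so worker
count and execution order cannot change an ensemble, and different
candidate models fitted with the same seed consume identical draws —
the pairing that AICc comparison requires.  Each draw estimates
parameters, then solves the PDE with that draw's clipped t = 0 surrogate
slice as initial condition (a sampled IC propagates initial-profile
uncertainty into the solution band; a spline through the averaged data
is available as an alternative).  Failed draws are dropped from
summaries with a logged count and poison only their own column of the
selection pairing; an ensemble errors out if more than half fail.

Parameter intervals are equal-tailed percentile intervals
(linear-interpolation quantiles, hence bit-reproducible); point
estimates are modes of Gaussian KDEs with Silverman bandwidth on a
512-point grid (argmax ties break low).  Functional forms and PDE
solutions get pointwise mean/quantile ribbons.  Prediction error is the
per-draw median absolute percentage error against the replicate-averaged
data, with machine precision guarding the denominator, summarised by its
2.5/97.5% quantiles.  CI-based hypothesis tests reject a null value iff
it falls outside the closed interval.

## Model selection

Per draw and model, `AICc = NM log(SSR/NM) + 2(k+1) + 2(k+1)(k+2)/(NM-k)`
with `k = a + d + r` mechanism parameters and residuals taken at the
data coordinates from the sampled-IC solution.  Within each draw,
differences to the best model are classified as E1 (Delta <= 3,
substantial evidence), E2 (3 < Delta <= 8) or E3 (Delta > 8), and the
class frequencies across draws form the 3 x |M| matrix P whose columns
sum to 1 (rows need not: several models can share E1).

## PDE solver

A vertex-centred finite-volume semi-discretisation on `Np` equally
spaced nodes (end control volumes of width dx/2) with arithmetic-mean
face diffusivities and two-point gradients; zero-flux boundaries come
out of the half-volume boundary stencils.  The ODE system is integrated
with LSODA at rtol 1e-6 / atol 1e-8 (configurable; the scheme's results
are insensitive across Np = 50–500, which the acceptance tests verify
directly).  Nearest-node extraction maps solutions to data coordinates,
ties toward the lower index.  Blow-ups abort the integration eagerly —
chasing NaNs with shrinking steps can stall a stiff integrator — and
return a flagged solution.

## Synthetic studies

The generator emulates the scratch-assay geometry: 37 positions at 50 um
pitch on [75, 1875] um, five times over 48 h, three replicates, additive
i.i.d. Gaussian noise (constant variance; negative noisy values are
kept, as the additive model implies).  The initial profile is a smooth
symmetric well — tanh ramps between edge plateaus and a depleted centre.
Two preset studies generate data from known mechanisms: study 1,
Fisher–Kolmogorov with `beta_1 = 301 um^2/h`, `gamma_1 = 0.044 /h`;
study 2, the same dynamics under a logistic delay with
`alpha = (-1.5, 0.31 /h)`, `beta_1 = 571 um^2/h`, `gamma_1 = 0.081 /h`.

The preset noise SD is 1% of K and the profile has edge plateaus at
0.35 K, a 0.005 K centre and edge_width 0.3.  These conditions were
calibrated once, deliberately: (i) the delay acts almost entirely
between the first two observation times, and with noise much above ~2%
of K the maximum-likelihood GP adopts a temporal length-scale that
smooths straight over it, leaving `alpha` unidentifiable — no amount of
bootstrapping can recover a signature the surrogate has erased; (ii) a
front ramp much narrower than ~250 um is under-resolved by the 50 um
sampling columns, which biases the recovered diffusivity downward by
several percent.  Both settings mimic a low-seeding-density well (whose
measured t = 0 profile the original recovery studies used) rather than a
freshly cut, high-density scratch.  What passing recovery tests show is
therefore that the pipeline is correct and well-calibrated when the
mechanisms are identifiable from the design; they do not show that five
time points suffice for arbitrary noise levels, and on real data with
heavier noise the delay parameters should be expected to carry wide
intervals.  The generator also does not emulate spatially correlated
counting noise or replicate-specific biases.

## Desk-scale problem sizes

Tests and the acceptance script run with 25 GP restarts, a 30 x 30
surrogate grid, B = 30 draws and a 50-node PDE mesh (with one 500-node
run for the mesh-insensitivity check).  These sizes reproduce the
library-default results to well within bootstrap uncertainty and keep a
full study to a few minutes.

## Known limitations

* Five observation times put a hard ceiling on how much temporal
  structure (especially delay) the surrogate can represent; delay
  estimates are biased toward "no delay" as noise grows.
* The zero-mean GP prior shrinks the field toward zero away from data;
  with the dense grids used here the effect is confined to mild edge
  artefacts in the curvature block.
* Percentile intervals at B = 30 are themselves noisy; nominal 95%
  coverage is approximate (empirically ~80% across replications of the
  synthetic studies).
* Heteroscedastic noise, non-Gaussian likelihoods, alternative kernels,
  2-D domains and multi-objective treatment of the two losses are out
  of scope.
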