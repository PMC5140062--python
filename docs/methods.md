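# Methods

This note records the models, estimators, numerical choices and known
limitations behind `sloppysys`, at the level of detail a user needs to judge
what a passing test suite does and does not establish.

## Statistical model and the discrepancy hyper-model

Observations are modeled as `d_i = y_i(θ) + σ_i ξ_i`, with `ξ_i` independent
standard normal and `σ_i` known (estimated experimentally in practice;
supplied with the dataset here).  Parameters are estimated by weighted least
squares, `χ²(θ) = Σ_i (d_i − y_i(θ))²/σ_i²`, the maximum-likelihood estimate
for this noise model.  All parameter derivatives, FIMs and widths are in
natural-log parameter coordinates, which makes them dimensionless and makes
the manifold-width relation `W_μ ≈ √λ_μ` meaningful.

Model error is represented by inflating the noise: `d_i = y_i + σ_i ξ_i +
f σ_i ξ_i′` with a single scalar hyper-parameter `f`.  Because this choice
leaves the weighted residuals' relative weighting unchanged, the best-fit θ
is the ordinary least-squares fit, and everything about `f` is closed-form:

| quantity | form |
|---|---|
| estimator | `f̂ = √(χ²/(M−N) − 1)`, clamped at 0 when `χ² < M−N` |
| std. deviation | `σ_f = (1+f²)/(f √(2(M−N)))` |
| augmented FIM | `blockdiag(I/(1+f²), 2f²(M−N)/(1+f²)²)` |
| covariance | `Cov(θ) = (χ²/(M−N)) I⁻¹` (inflation `√(1+f̂²)`) |
| acceptable f | fixed point of `σ_f(f) = f`: `f* = (√(2(M−N)) − 1)^{−1/2}` |

These forms interlock (the f-block inverse is `σ_f²`; `f*` solves the fixed
point; the geometric-spectrum `f` below is the estimator applied to the
geometric-spectrum χ²) and the test suite asserts the identities to 1e−10.

Two adequacy rules are exposed: the default compares `f̂` with `f*`; the
alternative asks whether `f̂` is within two standard deviations of zero.
The clamped estimator is biased downward near `f ≈ f*` (about 8% of
replicates clamp to zero at `f = 0.5`, `M−N = 100`), which is visible in the
estimator-calibration tests; `f̂²` is the unbiased quantity.

For a sloppy model missing a geometric tail of eigenvalues with ratio `r`
below its smallest retained eigenvalue `λ₀`, each omitted direction
contributes about its eigenvalue to the squared error, so
`χ² ≈ (M−N) + λ₀ r/(1−r)` and eigenvalues below `(1−r)/r · (M−N)` can be
ignored at `f ≤ 1`.

## Reaction networks and the two tiers

The approximate tier uses the standard Michaelis-Menten rate law
`v = k_cat [E][S]/(K_M + [S])` (the source mechanism names only `K_M` and
the two-step scheme; the reduced law is the field's standard form).  The
mechanistic tier replaces each MM reaction by `E + S ⇌ ES → E + P`, one new
complex species (initialized at zero — it does not pre-exist) and one net
extra parameter.  The exact back-mapping `K_M = (k_r + k_cat)/k_f` leaves
one degree of freedom per reaction; `expand_to_mass_action` fixes it with a
`km_split` fraction (default 0.5), `k_r = km_split·K_M·k_f`.  The validity
ratio `[E]/([S]+K_M)` is exposed directly, and `choose_largeKM_parameters`
draws mechanistic rate constants log-uniformly subject to the ratio
constraint at operating (initial) concentrations, optionally certifying each
accepted draw by co-simulating the isolated reaction and requiring < 10%
product error.

The isolated-reaction error metric (`mm_reduction_error`) co-simulates both
tiers to 95% substrate conversion (horizon from the integrated MM rate law)
and reports `max_t |P_MM − P_MA| / max_t P_MA` — error as a fraction of the
product scale, which avoids the 0/0 at early times.

## DNA-repair kinetics

The composite lesion model tracks repairable lesions `u` and lethal lesions
`v` (per clonogen), with dose rate `r` piecewise-constant from the protocol
(fraction sizes, 1.84 Gy/min reference dose rate, rest intervals; a fraction
of D Gy lasts D/(60·1.84) h).  Time is in hours, lesion-induction rates per
Gy.  Setting `δ₂ = λ₂ = ε = 0` cancels terms exactly to the LPL model;
`δ₂ = λ₃ = 0` gives the RS model — the reductions are term cancellations,
asserted bit-identically against hand-coded LPL/RS right-hand sides.

The survival endpoint is `S = exp(−v(t_∞))`: Poisson zero-class survival
from lethal lesions after repair completes.  `t_∞` is operationalized as a
terminal solver event on `u < 10⁻⁹` capped at 400 h.  The source material
names the LQ analysis but never writes the lesion→survival map, so this
mapping is a package design choice and is isolated in one method
(`DNARepairSimulator`) where it can be replaced.

## Numerics

- ODEs: `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  auto-switching), `rtol = 1e−8`, `atol = 1e−10` by default.  Forward
  sensitivities integrate the augmented system `dS/dt = J_y S + J_p·p`
  (log-parameter chain rule) using analytic Jacobians assembled per reaction
  kind; a central finite-difference fallback (`fd_jacobian`) is used as the
  cross-check oracle (agreement to 1e−3 asserted).
- Fitting: `scipy.optimize.least_squares`, trust-region reflective variant
  of Levenberg–Marquardt, with box bounds `|log θ| ≤ 20`.  The bounds are a
  robustness device: unbounded first trust steps in log space push ODE
  integration into overflow regimes.  Geodesic acceleration is not
  implemented; it affects optimizer robustness, not the location of minima,
  and the bounded trust-region iteration proved robust on every shipped
  scenario.  Reported χ² always excludes the regularization penalty.
  Residual order is dataset row order (bit-reproducibility).
- Scenario fits run the ODEs at `rtol = 1e−6 / atol = 1e−9`
  ("fitting-grade": trajectory errors several orders below the 10% noise
  floor) and optimizer tolerances around 1e−5; fits used for oracle-grade
  comparisons keep the tight defaults.
- Eigen-decompositions by `numpy.linalg.eigh`; eigenvalues below
  `1e−15·λ_max` are reported as zero; singular FIMs fall back to
  pseudo-inverse covariances with a warning (variance along unidentifiable
  directions is then *omitted*, not infinite — callers needing honest
  uncertainty there should flag those parameters with
  `fim.unidentifiable_parameters`, which marks parameters whose loading on
  the numerical null space dominates, or use ensembles).
- Sloppiness is given an operational definition (the field's usage is
  qualitative): positive eigenvalues spanning ≥ 6 decades with max adjacent
  log-gap ≤ 2.5× the mean gap; identifiable iff `λ_min ≥ 1`; the marginal
  band is `[0.1, 10]`.

## Synthetic data

`σ_i = noise_fraction ×` signal scale, with `noise_fraction = 0.10` (10%
fractional measurement accuracy).  The default scale convention is the
per-(experiment, observable) trajectory maximum; survival data use the
per-point convention (constant coefficient of variation, as for
count-derived surviving fractions).  A floor of `1e−6 ×` the overall signal
scale guards silent observables.  All draws are `numpy.random.default_rng`
seeded; a dataset is a pure function of (model, protocols, seed).

What the generator emulates: additive Gaussian noise of known scale,
independence across records, and an optional true discrepancy term
`f_true σ_i ξ_i′` used to calibrate the estimator.  What it does not
emulate: correlated errors within a time series, count statistics at very
low survival, calibration drift between experiments.  Passing tests
therefore establish the estimators' behavior under their own assumptions,
not robustness to structured real-world error — the hyper-model's own
central caveat.

## Shipped scenarios

**Phosphorylation cascade** ("cascade").  Approximate tier: four MM
reactions forming two covalent-modification cycles (kinase K: S→Sp,
phosphatase P1: Sp→S; Sp itself the kinase of T→Tp, phosphatase P2).  Truth
tier: its mass-action expansion, in which complexes couple the cycles
(retroactivity: Sp bound to T is shielded from P1) — mechanisms the MM tier
cannot express.  Every reaction satisfies the validity ratio ≤ 0.01 at the
baseline operating point, so the MM tier is a certified-good approximation
*there*.  A linear (non-cyclic) cascade was deliberately rejected: at steady
state complex occupancy equals flux/k_cat, so a unidirectional chain shows
only brief transient discrepancy under any perturbation.  In a futile cycle,
joint kinase-stimulus + phosphatase over-expression sustains high flux and
keeps a substantial pool fraction enzyme-bound persistently; those push–pull
conditions are where the MM tier degrades, and they are also highly
informative — which is precisely the conflict the pipeline demonstrates.
Baseline: two mild kinase levels observing Sp and Tp at 10 times.
Candidates: kinase levels ×{1,10,100}, phosphatase pairs ×{1,10,100}, pool
rescalings {0.3,3}, all four pools observed at 10 times.

**DNA repair** ("dna").  Truth: the composite six-parameter model with
`δ₁ = 0.5 /Gy, δ₂ = 0.05 /Gy, λ₁ = 1 /h, λ₂ = 0.05 /h, λ₃ = 1 /(lesion·h),
ε = 0.05 /lesion` — survival ~10⁻³–0.8 over the protocol range, repair
halftime ~40 min, and binary misrepair competing with first-order repair at
high lesion loads.  The reference point was selected by inspecting the
noiseless misfit of the RS reduction (the model lacking `δ₂` and `λ₃`):
negligible (χ² floor ≈ 0) over the 19 baseline conditions — seven single
fractions 2–14 Gy plus twelve unequal splits of 14 Gy at 4 h rest — but
structural (floor ≈ 20) over the expanded 35-condition set, which adds nine
conditions exercising the quadratic channel (18–20 Gy acute doses,
short-interval high-dose splits, a three-fraction schedule, protracted
low-dose-rate exposures) and repeats seven of them.  This mirrors the
qualitative finding that a reduction can be adequate for one experiment set
and fail after the conditions are expanded.

**Design scoring.**  Candidate FIMs are evaluated at a fixed parameter point
(design is local).  The default point is the approximate tier's stored
reference values — the analogue of designing for a published model — which
makes the selection deterministic.  Scoring at the baseline best fit is
exposed (`design_point="fit"`) but is erratic when the baseline fit is
deeply unidentifiable: the "best fit" is an arbitrary point of a flat
region.  Ensemble-averaged scoring (`design_point="ensemble"`) averages
candidate FIMs over baseline-consistent refits.  Greedy E-optimal selection
allows repeated conditions (replication doubles information) and is not
guaranteed optimal; on small pools the exhaustive subset optimum is computed
and the gap reported.

**Ensembles.**  Parameter ensembles are generated by repeated regularized
refits from randomized starts (weak penalty centered at each start, so
sloppy directions settle at start-dependent positions while stiff
combinations converge), accepting members within `χ²_best + N`.  This
matches the repeated-regularized-fit methodology rather than MCMC; the
acceptance band is a configurable convention, not a posterior credible
region.

## Problem sizes

The shipped analyses are desk-scale by design: the cascade pipeline fits 8
parameters to 20 baseline + ~120 designed points; the DNA scenario fits 4–6
parameters to 19–35 survival values; estimator calibration uses a linear
model at M−N = 100 with 200 replicates per f.  The full EGFR-scale study
(48↔70 parameters, 7000 points) exercises the same code paths and is
supported by supplying the corresponding network definitions, but no EGFR
model file ships with the package.

## Known limitations

- The discrepancy hyper-model assumes uncorrelated, noise-proportional
  model error; per-time-series or correlated hyper-models are out of scope.
- Identifiability analysis is local (FIM at a point); no profile likelihoods
  or global analysis.
- Stimuli and dose schedules are piecewise constant; no event handling
  beyond that, no delays, no stochastic kinetics.
- The survival mapping `exp(−v(∞))` is a convention (see above).
- SBML import is not provided; networks are defined via the YAML/JSON
  schema.
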