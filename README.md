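# sloppysys

Tools for asking an uncomfortable question about mechanistic ODE models in
systems biology: *when optimal experimental design finally makes a model's
parameters identifiable, does the model itself survive the encounter?*

Kinetic models of signaling networks and DNA repair are typically *sloppy* —
the eigenvalues of their Fisher Information Matrix (FIM) are spread
near-uniformly on a log scale over many decades, so most parameter
combinations are practically unidentifiable.  E-optimal experimental design
cures this by selecting *complementary* experiments that lift the smallest
FIM eigenvalue.  But every model omits mechanisms; under the designed
conditions the omitted mechanisms can become relevant, and the model stops
fitting.  `sloppysys` implements the machinery to build such case studies
end to end and to *quantify* the resulting model error.

## What is in the box

- **networks** — declarative reaction networks at two tiers of realism:
  approximate Michaelis-Menten rate laws (`v = k_cat [E][S]/(K_M + [S])`)
  and their mechanistic mass-action expansion `E + S ⇌ ES → E + P` with
  `K_M = (k_r + k_cat)/k_f`; the validity ratio `[E]/([S] + K_M)`; and the
  six-parameter DNA-repair lesion model that nests Curtis' LPL
  (`δ₂ = λ₂ = ε = 0`) and Kiefer's repair-saturation RS (`δ₂ = λ₃ = 0`)
  kinetics:

  ```
  du/dt = δ₁ r − λ₁ u/(1 + εu) − λ₂ u − λ₃ u²
  dv/dt = δ₂ r + λ₂ u + λ₃ u²,      survival S = exp(−v(∞))
  ```

- **simulate** — stiff-capable ODE integration under experiment protocols
  (stimuli, knockouts, over-expression, split-dose radiation schedules) with
  forward sensitivities in log-parameter coordinates.
- **fitting** — weighted least squares `χ² = Σ (dᵢ−yᵢ)²/σᵢ²` by damped
  Gauss–Newton in log space, with `wᵢ (log xᵢ/xᵢ₀)²` regularizers,
  multistart fits and consistency ensembles.
- **fim** — FIM assembly `I = Jᵀ diag(σ⁻²) J`, reparameterization by
  congruence, manifold widths `W ≈ √λ`, and sloppiness/identifiability
  classification (cutoff λ ~ 1).
- **discrepancy** — a hyper-model of model error,
  `dᵢ = yᵢ(θ) + σᵢξᵢ + f σᵢξᵢ′`, with the closed-form estimator
  `f̂ = √(χ²/(M−N) − 1)`, its uncertainty
  `σ_f = (1+f²)/(f√(2(M−N)))`, the acceptability threshold solving
  `σ_f(f) = f`, the inflated parameter covariance
  `Cov(θ) = (χ²/(M−N)) I⁻¹`, and the geometric-spectrum bound on the χ²
  cost of omitted mechanisms.
- **design** — factorial candidate enumeration and greedy E-optimal
  selection (maximize the smallest eigenvalue of the summed FIM), with an
  exhaustive-search cross-check on small pools.
- **synthgen** — seeded synthetic data (10% fractional noise by default) and
  two shipped truth-vs-approximation scenarios: a two-tier phosphorylation
  cascade (mass-action truth, Michaelis-Menten fit) and the DNA-repair
  scenario (composite truth, RS fit).
- **cli / pipeline** — `sloppysys pipeline` runs
  synth → fit → FIM → design → refit → discrepancy with full artifact and
  manifest output.

## Worked example

```python
from sloppysys import run_pipeline

result = run_pipeline("cascade", seed=0)
print(f"baseline:  f = {result.report_before.f:.2f} "
      f"(acceptable {result.report_before.f_acceptable:.2f}), "
      f"min FIM eigenvalue = {result.design.base_min_eig:.2e}")
print(f"designed:  f = {result.report_after.f:.2f}, "
      f"min FIM eigenvalue = {result.design.min_eig_trajectory[-1]:.4f}")
print("selected:", [p.id for p in result.design.selected_protocols])
```

prints

```
baseline:  f = 0.00 (acceptable 0.38), min FIM eigenvalue = 1.03e-05
designed:  f = 2.70, min FIM eigenvalue = 0.0111
selected: ['cand10_K=0.01_pool3', 'cand11_K=1_pool0.3', 'cand08_K=1_Px100']
```

Read: fitted to its baseline observations the approximate Michaelis-Menten
cascade is adequate (estimated discrepancy factor f = 0, i.e. model error
below the 10% measurement noise) but unidentifiable (smallest FIM eigenvalue
~10⁻⁵, manifold width ~3·10⁻³ noise units).  The greedy design lifts the
smallest eigenvalue by three orders of magnitude by combining substrate-pool
rescalings with a high-flux push–pull condition — and under exactly those
conditions the mechanisms the Michaelis-Menten tier omits (enzyme-substrate
sequestration at high cycle flux) become relevant: the refit has f ≈ 2.7,
meaning the effective error bars are √(1+f²) ≈ 2.9× the experimental noise
and the model is no longer predictive.

The same pipeline runs for the radiation-biology case:

```bash
sloppysys pipeline --scenario dna --seed 0 --out results/dna
```

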