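# Methods

This note documents the statistical model, the gradient machinery, the
numerical choices and their rationale, and the known limitations of
`focesens`.

## Model class and likelihood

An NLME model couples per-individual dynamics `dx/dt = f(x, t, Z, θ, η)`,
`x(t0) = x0(Z(t0), θ, η)` with scalar observation groups
`y = h(x, t, Z, θ, η) + e`, `e ~ N(0, R(x, t, Z, θ, η))` and random effects
`η ~ N(0, Ω(θ))`. Each output group is scalar-valued; multi-output models
declare several groups, which is also what the one-DV-per-row dataset
layout can represent. Ω is parameterized directly by its distinct elements
(variances on the diagonal, covariances off it), carried inside θ. This
keeps dΩ/dθ_m a constant indicator matrix; the price is that positive
definiteness is a runtime check, not a structural guarantee — a trial θ
with non-PD Ω raises an objective failure that the outer line search
absorbs by shrinking its step. ω symbols are variances, not standard
deviations, throughout.

The marginal (population) likelihood integrates η out of the joint
density; the integral has no closed form, so the package maximizes the
Laplacian approximation expanded at the per-individual posterior mode η*:

    log L_F(θ) = Σ_i [ l_i(η*_i) − ½ log det(−H_i(η*_i)/2π) ].

`H_i` is the first-order (second-derivative-free) approximation of the
η-Hessian of `l_i`. FOCEI keeps the dR/dη terms in `H_i`; FOCE sets them
to zero. Everything else — `l_i`, its η-gradient used by the inner
optimizer, and the exact η-Hessian used in the implicit derivative — is
identical between the two methods, so they coincide exactly whenever R has
no η dependence (directly or through states that η influences).

## Exact gradients from sensitivity equations

Differentiating the state equations symbolically yields forward
sensitivity ODE systems at two levels:

* inner: states plus first-order η-sensitivities, n(1+q) equations;
* outer: additionally θ-, mixed η/θ-, and second-order η-sensitivities,
  n(1+q)(1+p+q/2) equations (second-order η blocks stored once per
  unordered pair).

Parameters absent from both f and x0 (typically Ω and residual-model
parameters) are detected symbolically and carry no equations. Each
augmented system is compiled to a single numpy right-hand side with
common-subexpression elimination and always integrated as one combined
system — the sensitivity equations are linear in the sensitivity states,
so they ride along with the base states at little extra stepping cost.

The outer gradient follows the conditional-differentiation rule: a total
θ-derivative after substituting η*(θ) equals the direct θ-derivative plus
the η-derivative times dη*/dθ. Three ingredients:

1. `dη*/dθ = −(d²l_i/dη²)⁻¹ (d²l_i/dη dθ)`, both factors at η*. The
   **exact** Hessian (second-order ε and R terms kept, hence the
   second-order η-sensitivities) is used here, while the **approximate**
   `H_i` appears in the objective and in the trace term below. Conflating
   the two is the easiest way to get a subtly wrong gradient; the code
   keeps them in separately named functions.
2. `d l_i(η*)/dθ` needs only the direct part: the indirect term is
   multiplied by `dl_i/dη(η*) = 0`.
3. `dH_i(η*)/dθ_m` keeps both parts; all starred totals (ε, R, dε/dη,
   dR/dη after η*-substitution) carry a `dη*/dθ` correction. In FOCE the
   pieces of `H_i` that contain dR/dη explicitly are zero and stay zero
   under differentiation, but the totals of the remaining pieces keep the
   full indirect dependence — the result is the exact gradient of the FOCE
   objective, which is what the finite-difference oracle tests verify.

Then `d log L_F/dθ_m = Σ_i [ dl_i(η*)/dθ_m − ½ tr(H_i⁻¹ dH_i/dθ_m) ]`,
with the trace computed via LU solves against `H_i`, never an explicit
inverse. Derivatives of h and R with respect to states and parameters, and
their η/θ mixed second derivatives, are generated by the same symbolic
pipeline as the f-derivatives — including the dR/dη-dθ expansion, which is
structurally identical to the dε/dη-dθ one.

Two derivations in the source material print with sign slips (the Ω prior
term of the mixed derivative d²l/dηdθ, and one trace term of the same
expression); the implementation uses the signs obtained by direct
differentiation of dl/dη, confirmed by central-FD oracles in the test
suite.

## Optimization

Both nested problems use BFGS with Armijo backtracking:

* **Inner** (per individual, over η): objective and exact gradient come
  from one integration each. The initial inverse-Hessian estimate is
  `(−H_i(η0))⁻¹` when positive definite. Steps are capped at twice the
  current η scale (η is a standardized random effect; larger proposals
  only destabilize the integrator), a failed quasi-Newton direction falls
  back to steepest ascent, and convergence at "k digits" means the
  per-component step, the objective change and the gradient are below
  10^−k on a `max(1, |·|)` relative scale. Because the achievable gradient
  norm is floored by ODE-solver noise, the step-based criterion (and a
  stagnation exit on consecutive zero-progress steps) takes over at tight
  digit settings; a grossly non-stationary η* is still rejected by a guard
  in the gradient code.
* **Outer** (over θ): θ is optimized on a normalized scale, each component
  divided by |θ0| (unit scale only where θ0 = 0). An earlier variant
  floored the scale at 1; that made unit steps an order of magnitude
  larger than variance-scale parameters and caused line-search collapse at
  Ω boundaries, so the floor was dropped. Relative steps are capped at 50%
  per component per trial. Objective failures (non-PD Ω or −H_i, inner
  failure, integrator blow-up) shrink the step rather than being mapped to
  penalty values, which would corrupt the BFGS curvature estimate. The
  first evaluation starts all η at zero; later evaluations warm-start the
  inner problems, by default with the first-order Taylor update (mode B)
  `η⁰ = η* + (dη*/dθ)Δθ`. On the bundled benchmark this reduces total
  inner iterations by roughly a third relative to reusing η* unchanged
  (mode A), and by more than half relative to cold starts.

Convergence of the outer loop: relative step and objective change below
10^−3 (inner 10^−4) by default, both configurable as digit counts. These
digit interpretations are declared choices; the notion of "precision in
digits" is otherwise undefined.

Determinism: fits contain no randomness — identical data and config give
bit-identical traces. Seeds only enter simulation and the randomized
starts of the precision sweep.

## ODE integration

LSODA (via scipy's `odeint`) with rtol 1e−6/atol 1e−8 for estimation and
rtol 1e−8/atol 1e−10 (or tighter, per test) for gradient validation. The
original method description names neither solver nor tolerances; these are
package defaults. Covariates are piecewise-constant between records and
integration is segmented at covariate change points. Observation times
enter as solver output points; duplicate times are collapsed for
integration and re-expanded per observation.

## Standard errors

Asymptotic SEs come from a central-FD Hessian assembled column-wise from
the *analytic* gradient (2P gradient evaluations), i.e. finite differences
appear only one derivative order above what is computed exactly. This is
deliberately outside the exact-gradient machinery: second derivatives of
log L_F are not part of the method.

## Benchmarks and the synthetic-data generator

M1–M4 are variants of a two-compartment model with Michaelis–Menten
elimination (states A1, A2; concentrations C1 = A1/V1, C2 = A2/V2; bolus
dose into A1). Random effects are multiplicative log-normal,
p_i = p·exp(η). M1 estimates {Vmax, V1, Km} with diagonal Ω(3) (P=6);
M2 all five ODE parameters, the additive residual SD and full Ω(3)
(P=12); M3 adds a random effect on Q (full Ω(4)), observation of both
compartments, additive+proportional error on C1 and additive on C2
(P=18); M4 is M3 estimated with FOCEI. Each variant verifies at
construction that its structural counts (parameters, inner ODEs 8/8/10/10,
outer ODEs 44/60/80/80) match the declared table. The fourth random
effect's placement on Q is a package choice; any ODE parameter would give
the same counts.

True values are package fixtures chosen as plausible PK magnitudes that
put the concentration range across Km (nonlinear elimination regime):
Vmax=10 mg/h, Km=5 mg/L, V1=10 L, V2=30 L, Q=2 L/h, 100 mg bolus, 8
samples over 0.25–24 h, ω²=0.1 (off-diagonals 0.01 where a full matrix is
estimated), σ_add=0.25 mg/L, σ_prop=0.1, N=20. They are *not* literature
estimates. The generator draws η from N(0, Ω_true), integrates the true
model and adds residual noise from R evaluated on the true trajectory. It
emulates sparse-sampling designs with inter-individual variability and
measurement error; it does not emulate dosing histories (doses enter only
through x0), covariate effects, model misspecification, censoring/BLQ, or
missingness — so passing recovery tests demonstrates estimator
correctness under the assumed model, not robustness on real datasets.

Which residual components M1/M2 fix versus estimate is reconstructed from
the benchmark table's observational-parameter counts (0 and 1): M1 fixes
the additive SD, M2 estimates it.

## The precision/accuracy sweep and cost models

`precision_sweep` reproduces the FD-versus-sensitivity comparison
protocol: at a given θ, each gradient component is finite-differenced with
relative steps 10^−h over a grid (default h = 0.5…7 in steps of 0.5,
covering the behaviors on either side of h≈2–3), with inner problems
solved to 4 digits from starting values redrawn per h as η0 ~ N(0, Ω(θ))
— the randomization decorrelates the numerical error across step sizes;
its distribution is a declared choice. The sensitivity gradient is the
reference, with its relative standard error estimated over repeated
randomized-start evaluations. A central consequence, visible in the
package's own diagnostics: at a converged θ̂ the exact gradient is ~0 and
finite differences return only solver noise, especially in the Ω
directions whose absolute steps are tiny — FD gradient checks are
therefore performed at non-stationary points.

`sfs_cost_percent` implements the evaluation-count model for a mixed
scheme in which the Ω-block of the outer gradient is computed analytically
(it needs only second-order η-sensitivities) and the remaining directions
by FD: forward `100(1+P_θ−P_Ω)/(1+P_θ)`, central
`100(1+2P_θ−2P_Ω)/(1+2P_θ)`. `scheme_evaluation_counts` reports
objective-evaluation and ODE counts per outer gradient for the F-F, S-F,
S-S and S-S-η scheme ladder; wall-clock ratios are hardware-dependent and
are deliberately not asserted anywhere.

## Problem sizes used in the shipped checks

The test suite runs the full recovery study at the design above (M1, N=20
individuals, 20 replicate seeds, 3-SE coverage ≥ 90% with FD-Hessian
standard errors), the gradient oracle checks on N=20 (M1) and N=2–3 (M3)
populations, and exactness checks on a 4-individual affine fixture. These
sizes match the study design the benchmarks define; the affine fixture is
small because its checks are exact identities, not statistics.

## Known limitations

* Doses enter through initial conditions only; no mid-integration dosing
  events, infusion records or DAE constraints.
* Output groups are scalar; vector-valued groups with correlated
  within-time residuals are not supported.
* The inner problem accepts the converged local optimum; no multistart.
  Multimodal individual likelihoods (rare at these noise levels) would go
  undetected.
* Ω is unconstrained beyond a PD check; fits that want a zero variance
  walk to the boundary and stop there (the estimate is reported as ~0
  rather than being reparameterized away).
* The Laplacian approximation itself is unchanged: log L_F is an
  approximate likelihood, and its known biases are inherited, exact
  gradients notwithstanding.
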