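# Methods

## The model

The diffusion-weighted signal of one voxel, measured along unit gradient
directions g at diffusion weightings b (s/mm²), is treated as a Gaussian
process over measurement points x = (g, b).  Because diffusion weighting is
insensitive to the sign of g, the signal is antipodally symmetric, and
angular distance between two measurement points is the *axial* angle

    θ(g, g′) = arccos |g · g′|  ∈ [0, π/2],

i.e. the smaller of the two angles obtained when either vector is extended
through the origin.  Dot products are clipped to [−1, 1] before the arccos.

Two stationary angular covariance families from the Kriging literature are
implemented; both are valid covariances on the sphere:

* **exponential**  C(θ) = exp(−θ/a)
* **spherical**    C(θ) = 1 − 3θ/(2a) + θ³/(2a³) for θ ≤ a, exactly 0 beyond
  the cutoff a.

For a single shell the kernel is K_ij = λ C(θ_ij; a) and the observation
covariance K_y = K + σ²I, giving hyperparameters β = (λ, a, σ²).  For N
shells the kernel is the product of the angular covariance and a
squared-exponential in log-b distance,

    C_b(b, b′) = exp(−(log b − log b′)² / (2ℓ²)),

with one noise variance per shell: β = (λ, a, ℓ, σ₁², …, σ_N²), i.e. 3 + N
free parameters.  Within-shell blocks use the representative shell b-value,
so they are purely angular and a one-shell "multi-shell" kernel reduces
exactly to the single-shell kernel.

Given β, prediction is plain Gaussian conditioning on the per-shell demeaned
signal:

    mean(x*) = k(x*, x)ᵀ K_y⁻¹ (f − f̄) + f̄(x*)
    var(x*)  = k(x*, x*) − k(x*, x)ᵀ K_y⁻¹ k(x, x*)

Shells attenuate very differently, so the mean f̄ is taken per shell and the
queried shell's mean is restored; queries at b-values not acquired get a
mean interpolated linearly in log b and are flagged as extrapolated.  The
kernel factorisation is computed once per (scheme, β) and reused across
voxels — per-voxel prediction is a linear operation.

## Hyperparameter estimation

One β is shared across a voxel population and estimated by maximising, over
unconstrained log-parameters, an objective summed over voxels:

* **ml** — the type-II (marginal) log likelihood
  −½ yᵀK_y⁻¹y − ½ log|K_y| − (n/2) log 2π per voxel (the constant makes the
  value the honest Gaussian log density, comparable across n);
* **cv** — negative mean squared leave-one-out residual;
* **gpp** — mean leave-one-out log predictive density (Geisser's surrogate
  predictive probability).

The LOO quantities come from the closed-form identities on the inverse
kernel diagonal (residual_i = (K_y⁻¹y)_i / (K_y⁻¹)_ii, variance_i =
1/(K_y⁻¹)_ii); tests verify them against literal refit-without-point-i
oracles.  CV cannot identify the overall scale of (λ, σ²) — only their
ratio and a — because the LOO residual is invariant under joint scaling;
GPP and ML identify everything.

Optimisation is Nelder–Mead over log-parameters (positivity for free),
absolute tolerances 1e-4 on parameters and objective, default budget 200·d
evaluations (population fits of several hundred voxels may need a few
thousand; pass `maxfev`).  Default initialisation: a = 1 rad, λ = mean
squared demeaned signal, σ² = 0.1 λ, ℓ = 1; optional restarts perturb the
log-parameters by seeded normal offsets.  Voxel subsampling for fitting
defaults to a seeded uniform 1000-voxel sample.

### Identifiability of σ² (the nugget floor)

Both angular families are non-smooth at θ = 0 (linear slope), so the kernel
itself has eigenvalues extending down to a roughness floor.  When the true
noise variance lies *below* that floor — smooth multi-tensor signals with
modest noise, or sparse angular sampling — the likelihood is flat in σ²
underneath it and the fitted σ² may collapse toward zero while λ and a
absorb the noise as an effective nugget.  Predictions are unaffected (the
sum λC + σ²I is what matters where the data constrain it), but the reported
σ̂² is then not interpretable and its curvature is ~0, which the Laplace
machinery flags (see below).  With noise above the floor (e.g. data drawn
from the GP itself at moderate SNR) all parameters are recovered within a
few percent.

## Model comparison

The evidence p(y|M) = ∫ p(y|β, M) p(β|M) dβ is approximated by Laplace's
method around the summed-ML optimum β₀ in unconstrained coordinates:

    log p(y|M) ≈ L(β₀) + (d/2) log 2π − ½ log |−H|,

with H the central-finite-difference Hessian (relative step 1e-3 per
coordinate, symmetrised).  A flat improper prior over the unconstrained
log-parameters is assumed, so the MAP point coincides with the ML point;
this is the minimal construction consistent with a Gaussian approximation
of p(β|y, M) centred on β₀ with covariance −H⁻¹.  The approximation is
exact for quadratic L and is verified against 1-D trapezoidal quadrature
(< 0.5 nats on a 20-voxel toy).  If −H is not positive definite — typically
the σ² collapse above, a boundary rather than interior maximum — the result
is flagged invalid and no Bayes factor is formed.  Bayes factors
exp(ΔLog-evidence) require the identical voxel set (enforced by
fingerprint).

In two-way model-recovery simulations (60 directions, 500 voxels, λ = 1,
a = 0.8, σ² = 0.15) the generating family wins the Bayes factor in ≥ 95% of
replicates in both directions.  Two effects bound that regime: at low noise
the misspecified family's σ² collapses (invalid Laplace); and per-shell
demeaning projects the data covariance (P K_y P), which at very sparse
angular sampling distorts the two families asymmetrically.

## The synthetic-data generator

The simulator emulates what the GP needs from real diffusion data and
nothing more:

* **Schemes** — one or more b-shells with unit directions placed uniformly
  at random or by electrostatic repulsion on antipodally symmetrised point
  sets (better minimum axial angle); optional b0 volumes.
* **Signals** — the multi-tensor model
  S(g, b) = S₀ [Σ_i f_i exp(−b gᵀD_i g) + f_iso exp(−b d_iso)] with axially
  symmetric tensors.  Defaults: axial 1.7e-3, radial 0.2e-3, CSF 3.0e-3,
  grey matter 0.8e-3 mm²/s (textbook human-brain magnitudes), S₀ = 100.
  Signals are exactly antipodally symmetric and decay monotonically in b.
* **Noise** — Gaussian or Rician (magnitude-MR); Rician is the realistic
  default, Gaussian matches the GP's own error model and is used in
  parameter-recovery settings.
* **Phantom** — voxel classes wm1 (single fibre, f = 0.85), wm2_crossing
  (2 × 0.425, 90° apart), wm3_crossing (3 × 0.3, orthogonal), gm and csf
  (isotropic), with small seeded per-voxel orientation jitter (σ = 0.05 rad).

What the generator does **not** emulate: eddy-current/motion/susceptibility
artefacts, signal dropout, spatial correlation between voxels, Gibbs
ringing, or realistic partial-volume mixtures.  Passing tests therefore
demonstrate the correctness of the GP machinery and its behaviour under the
model's own assumptions, not robustness to scanner artefacts.

## Numerical choices

* Cholesky factorisation of K_y; on failure one retry with jitter
  1e-10 · mean(diag K_y) and a warning, then a conditioning error reporting
  the smallest eigenvalue.  Prior sampling adds a fixed 1e-10 λ jitter to
  the noise-free K.
* Predictive variances in (−1e-9 λ, 0) are clamped to zero with a warning
  (floating-point cancellation); anything more negative raises.
* Shell clustering: greedy 1-D clustering with absolute tolerance
  100 s/mm² around running means; b ≤ 50 s/mm² counts as b0.  Both are
  configurable.
* The angular scale a is not restricted to (0, π/2]; any a > 0 is accepted.
* Interpolation-mode volume prediction rebuilds the reduced system rather
  than down-dating the factorisation — simplicity over speed at the scale
  this package targets.
* Exact diagonal: θ_ii is set to zero identically, so diag(K) = λ exactly.

## Problem sizes used in the validation suite

Parameter recovery uses 120 directions × 500 voxels; model recovery 20
replicates per direction of 60 directions × 500 voxels; the cross-shell
borrowing experiment two 300-direction shells (b = 1000/3000) with
hyperparameters fitted on a lighter 60+60 acquisition; prior-shape
statistics 50,000 draws.  The end-to-end noise-explanation check (LOO RMSE
≈ injected σ within 20%) uses a 150-direction shell: LOO residuals contain
the posterior interpolation variance on top of σ², a contribution that
shrinks with angular density (≈ 14% of σ at 150 directions, ≈ 22% at 90),
so the property is a statement about densely sampled acquisitions.

## Known limitations

* The GP models each voxel independently; no spatial regularisation.
* Per-shell demeaning is the pragmatic mean treatment; a generalised
  least-squares (universal-Kriging) mean would be internally consistent but
  is not what this method family uses.
* Laplace evidence is undefined at boundary optima (collapsed σ²); the
  package flags rather than repairs these.
* Gradient directions are used in the image frame as given; no affine
  reorientation.
* Rician noise makes the Gaussian observation model an approximation at low
  SNR; no Rician likelihood is implemented.
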