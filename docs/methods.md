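# Methods

## Model

A tracked molecule moves in the membrane plane according to the overdamped
Langevin equation

    dr/dt = −(1/γ) ∇V(r) + √(2D) ξ(t),

with isotropic, spatially constant diffusivity D, a confining potential V
(possibly absent), and friction eliminated via fluctuation–dissipation,
γ = k_BT/D.  Potentials are stored in thermal units (k_BT/µm^n), so a force
F = −∇V in k_BT/µm produces a mean drift F·D·Δt over one frame.  Three
model classes are considered: zero force (FREE), a general 2nd-order
polynomial potential (SPRING2; canonical example V = ½k r²), and a general
4th-order polynomial potential (QUARTIC4; canonical example V = u(x⁴+y⁴)).
Constant terms are excluded — they never affect forces — giving 1, 6 and 15
free parameters (D plus 5 or 14 coefficients).

Assumptions worth keeping in mind:

* **Markov steps.** The likelihood multiplies one-step transition
  densities; correlations induced by localization noise between successive
  displacements are not modeled (no motion-blur or Berglund-type covariance
  corrections).
* **Piecewise-constant force.** The trajectory bounding box is divided
  into a 10×10 mesh; within a cell the force is constant, evaluated at the
  cell center (this matches the piecewise-constant-force solution of the
  associated Fokker–Planck equation).  A zero-extent axis is expanded by
  one localization precision (or 1 nm) before meshing.
* **Known noise.** The localization error σ is an instrument property
  supplied by the user, not a fitted parameter; it enters only through the
  effective diffusivity D_eff = D + σ²/Δt.

## Exact MAP by profile least squares

With a flat prior the MAP equals the maximum-likelihood estimate.  Because
the mesh-cell centers are fixed by the data, the per-step drift is *linear*
in the products b = c·D·Δt of the polynomial coefficients, so

1. b̂ is an ordinary least-squares solution of drift-vs-displacement, and
   the minimized residual sum of squares (SSR) does not depend on D;
2. the profile likelihood over D_eff is maximized in closed form at
   D_eff = SSR / (4 N Δt), with N the number of steps;
3. D = max(D_eff − σ²/Δt, 1e−12 µm²/s) and c = b̂/(D·Δt).

This single linear solve reaches the global optimum deterministically — no
iterative optimizer, initialization or convergence heuristics — and makes
the nested-likelihood ordering log L(QUARTIC4) ≥ log L(SPRING2) ≥
log L(FREE) exact by construction (each model's regressor space contains
the previous one's).  The test suite cross-checks it against an independent
quasi-Newton/simplex optimization of the same likelihood.  The polynomial
basis is evaluated about the trajectory centroid for conditioning; the
monomial families are closed under translation, so this only changes the
frame the fitted coefficients are reported in (leading-order terms, e.g.
the spring constant, are unaffected).  A fit is flagged non-converged when
SSR degenerates to zero (e.g. repeated identical positions), in which case
D sits at its floor and any decision built on it is marked unreliable.

## Criteria and the decision tree

AIC, AICc and BIC are computed from the MAP likelihood with N = number of
transitions (the number of factors in the Markov product).  AICc is
reported as +∞ when N ≤ k+1.  The decision tree runs BIC(FREE) vs
BIC(SPRING2) first — the spring model stands in for "confined" generally,
since the BIC maps quartic-confined data onto it — and, only for confined
calls, AIC over {SPRING2, QUARTIC4} with ties toward the lower order.
QUARTIC4 is fitted lazily.  Single-criterion histograms (argmin over all
three fits) are provided separately for building decision maps.

## Temporal variant

A 51-frame window (odd w, configurable) slides along the trajectory; each
central frame receives the stage-1 label of its window.  Only FREE vs
SPRING2 is distinguished — ~50 frames carry far too little information to
resolve the potential order.  The mesh is rebuilt per window.  Labels are
low-pass filtered: a mode switch is accepted only when `persistence`
(default 3) consecutive window positions all carry the new mode.  Maximal
confined runs of at least `min_duration` central frames (default 25, half a
window — suppresses single-window artifacts while keeping 200-frame zones
detectable) become confinement zones.  Detected zones are scored against
ground truth by frame-range overlap, each true zone matchable at most once;
surplus detections count as false positives.

Two change-point utilities are provided: `detect_switch` (strict contract —
exactly one change in the filtered series) and `estimate_switch_frame`, the
maximum-agreement single change point (minimum Hamming distance to a step
profile), which coincides with `detect_switch` on clean series and remains
defined when residual label flips survive filtering.

## Residence-time baseline

For each 51-frame window, R is the maximal displacement from the window's
center position (the arithmetic mean of its positions — the tightest
enclosing radius), and the stay probability of a free walker with known D
is approximated by ψ = 10^(0.2048 − 2.5117·D t_w/R²) (clamped to [0,1],
t_w = w·Δt), accentuated as L = |log₁₀ ψ| − 1 for ψ ≤ 0.1, else 0.  Runs
with L > Lc lasting longer than tc become zones.  The defaults Lc = 1.0,
tc = 2.0 s were selected by a deterministic grid search on the packaged
three-zone ensembles (`scripts/calibrate_residence.py`): maximize recovered
true zones subject to at most one false zone per 5-trajectory ensemble,
ties toward the mildest thresholds.  Note that zone *count* is not monotone
in Lc (raising the cutoff can split one long run into several); zones at a
stricter level are always nested inside zones at a milder one, and count is
monotone in tc.

## Synthetic generator and study conditions

Trajectories are integrated with 1000 Langevin substeps per frame: each
substep adds a random displacement of Gaussian *length* (sd √(4D·Δt_sub))
at a uniform angle, plus the deterministic drift F·D·Δt_sub; only every
1000th position is recorded (never averaged).  Static localization noise —
again Gaussian magnitude (sd σ) at uniform angle — is added to recorded
positions only.  A confining segment's potential is centered on the
particle position at the segment's first frame.  Defaults emulate a
membrane receptor tracked at video rate: D = 0.1 µm²/s, Δt = 50 ms,
σ = 30 nm, spring k = 0.3 pN/µm (≈70 k_BT/µm² at 310 K, k_BT = 4.28·10⁻³
pN·µm), and quartic strength u chosen so the quartic well's stationary
per-axis variance matches the spring's (u = (Γ(¾)/Γ(¼))²k² ≈ 561 k_BT/µm⁴)
so the two confinement models are directly comparable.

Two consequences of the magnitude-based step convention deserve note.
First, it is not an isotropic bivariate Gaussian per substep, but after
1000 substeps the recorded steps are Gaussian to high accuracy by the
central limit theorem, and E|step|² = 4DΔt matches 2-D diffusion exactly.
Second, a noise displacement of Gaussian magnitude σ carries σ²/2 variance
per axis, so it inflates the 2-D per-frame displacement variance by exactly
2σ², whereas the likelihood's σ²/Δt term corresponds to per-axis noise
variance σ².  The factor-2 mismatch shifts only the noise-corrected D̂
reported on noisy data (by σ²/2Δt at most); model selection is unaffected,
because under the exact fitter the selection statistics do not depend on
the assumed σ.

What the generator does *not* emulate about real data: motion blur (finite
exposure), detection gaps and blinking, spatially varying D, hopping
between corrals, and drift of the confining domain itself.  Passing tests
therefore demonstrate correctness of the inference given the model class,
not robustness to these artifacts.

## Numerical choices

* Least squares via `numpy.linalg.lstsq` (SVD, default rcond); rank
  deficiency (e.g. few occupied mesh cells) yields the minimum-norm
  solution without affecting the likelihood.
* D floor 1e−12 µm²/s; AICc of an over-parameterized window is +∞, which
  simply removes that model from any argmin.
* Ties: BIC ties go to FREE, AIC ties to the lower-order model; the label
  ordering FREE < SPRING2 < QUARTIC4 is used solely for tie-breaking.
* All ensembles derive per-trajectory seeds from one base seed through
  `numpy.random.default_rng`; identical settings reproduce identical
  trajectories bit for bit.
* Sliding-window classification reuses array-level fitting kernels; a
  1200-frame trajectory (1150 windows) takes ~2 s on one core.

## Problem sizes

The packaged validation experiments run at reduced but statistically
resolved sizes chosen so the full suite completes in minutes on one core:
threshold scans use 50 replicates per grid point (binomial SE ≈ 0.07, so a
0.5 crossing is resolved at ≥2 SE for the observed fractions), the switch
ensemble 20–50 trajectories, and the zone comparison the full 5-trajectory
design per spring constant.  Decision-map sweeps accept arbitrary
replicate counts for higher-resolution reproduction.

## Known limitations

* **Weak-confinement window regime.** At k = 0.3 pN/µm with D = 0.1 µm²/s
  and Δt = 50 ms (k·D·Δt ≈ 0.35), a 51-frame window carries a stage-1
  signal (≈ n·ln(1 + tanh(kDΔt/2)) + overfit ≈ 21 nats·2) barely above the
  BIC penalty 5·ln 50 ≈ 19.6: per-window confined accuracy is only ~0.67,
  filtered label series retain flips, detected zones fragment, and the
  change-point estimate scatters widely below the true switch frame.  From
  k ≈ 0.6 pN/µm upwards per-window accuracy is ~1 and segmentation is
  clean (switch detected ~9 frames early, all three zones recovered with
  no false positives).  `examples/02` and `03` demonstrate the validated
  regime; the acceptance script reports the weak regime honestly.
* **Quartic resolution needs long trajectories.** Under the default
  conditions the AIC resolves QUARTIC4 from SPRING2 in >50% of
  trajectories only from roughly 600–800 frames; weaker wells help
  slightly, stronger wells and larger σ hurt.
* **Drift-rate estimation bias.** Like any OU-type drift MLE, k̂ is biased
  upward by O(τ_relax/T): negligible when the trajectory spans many
  relaxation times (+4% at 40 relaxations, +13% at the default study
  spring over 2000 frames) but large for weak springs observed briefly
  (+45% at 10 relaxations).  Model *selection* is far less sensitive than
  parameter values.
* The residence-time baseline requires the true D as an input; its
  thresholds were calibrated on the packaged simulation design and are not
  universal.
* 2-D only; no anisotropic or spatially varying D; no localization from
  raw images.
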