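# Methods

`discmech` reimplements, as a tested pipeline, an analysis that links
multi-parametric MRI of isolated bovine intervertebral discs (IVDs) to
their compressive moduli and hydraulic permeabilities.  The original
experiment — four groups (in-situ and trypsin-digested 6 h/18 h/24 h),
two regions (nucleus pulposus NP, annulus fibrosus AF), n = 15 discs per
group — has no deposited raw data, so a first-class synthetic-data
generator stands in for the study: every estimator in the package is
validated by parameter recovery from its own forward model, plus
independent numerical oracles.

## Quantitative MRI

**T1 (inversion-recovery TSE).**  The signal model is

    SI(TI) = S0 [1 − (1 − cos α) E_TI (1 − E_TW f(N) (1 − E_{TE/2})²)]

with `E_x = exp(−x/T1)`, `f(N) = 1 − E_TE^N`, refocusing angle α = 180°,
N = 8 refocusing pulses, echo spacing TE = 6.3 ms, and recovery delay
`TW = TR − TI − N·TE` clamped at zero.  The published rendering of this
model is typographically ambiguous; the package therefore commits to the
reconstruction above as the *single shared forward model* of generator
and fitter, which makes every round trip well-defined regardless of how
the original reference parenthesized it.  Fitting profiles S0 out
analytically (the model is linear in S0) and minimizes over T1 alone,
initialized by a 200-point log grid on [10, 5000] ms and polished by
bounded scalar minimization.  Noiseless recovery is better than 0.5%
across T1 ∈ [200, 3000] ms under the study protocol (15 TIs, 50–1900 ms,
TR 2100 ms).  Signed (real) signals are the default; a magnitude mode
fits the absolute-valued model instead.

**T2 (multi-echo TSE).**  `SI(TE) = SI(0) exp(−TE/T2)`, fit log-linearly
(exact for noiseless data, deterministic); non-positive intensities are
excluded with a warning.  Protocol: 10 echoes every 15 ms.

**MTR.**  `MTR = (M0 − MS)/M0` from the saturation-on/off pair.  The MT
pulse parameters (1100 Hz offset, 620° effective flip) are carried as
metadata only; the synthetic MTR is a free ground-truth fraction rather
than a model of the saturation physics.

**Diffusion.**  Single-shell DTI at b = 1000 s/mm² with 15 directions
plus one b = 0 image.  `ln(SI/SI0) = −b gᵀDg` is linear in the six
unique tensor entries and solved by ordinary least squares; eigenvalues
are not floored at zero (noise-induced negative eigenvalues propagate
transparently into FA, which is clipped to [0, 1] with the clip logged).
ADC is the eigenvalue mean and FA the usual normalized eigenvalue
dispersion.  The gradient scheme is a spherical-Fibonacci hemisphere
set: closed-form, hence bit-reproducible, well spread, and rank-3.
`tensor_from_md_fa` builds axially symmetric ground-truth tensors with
exact prescribed (MD, FA): λ∥ = MD(1 + 2·FA/s), λ⊥ = MD(1 − FA/s),
s = √(3 − 2 FA²).

**Noise.**  Magnitude-MRI noise is Rician: v → √((v+n₁)² + n₂²) with
n₁, n₂ ~ N(0, σ²); σ = 0 is the identity, and all randomness flows
through explicit integer seeds.

## Biomechanics

Specimens are 5 mm-diameter, 1.6 mm-thick punches tested in
stress-relaxation with 5% strain ramps.  Compressive strain is negative
internally; curves and reported stresses are compressive-positive.
Moduli are in MPa and permeabilities in 1e-15 m⁴/(N·s).

**Unconfined compression** (impermeable frictionless platens, radial
exudation).  The linear biphasic problem reduces to a radial diffusion
equation for the dilatation v = (1/r)(ru)_r with diffusivity H_A·k_r and
a nonlocal traction-free boundary condition; its modal characteristic
equation is J1(α)/α = (1−ν)/(1−2ν)·J0(α), and the stress-relaxation
step response is obtained by Laplace-transform residues (instantaneous
response 3μ_s·ε, drained response E·ε — both verified in tests).  Ramps
are handled by Duhamel superposition.  Two viscoelastic overlays
complete the forward model: a quasi-linear reduced-relaxation function
G(t) = 1 + c·S(t), with S a discrete 8-point Maxwell spectrum log-spaced
on the fixed 1–100 s band, convolved with the biphasic stress rate; and
a Maxwell arm of stiffness E and dashpot viscosity μ acting on the
strain rate (standard-linear-solid behaviour, relaxation time μ/E).
With c = μ = 0 the model is exactly the linear biphasic response.
The convolutions are evaluated by O(n) recursive exponential filters on
a uniform internal grid (dt ≈ 1 s), exact for piecewise-constant rates.

Fitting is two-stage: stage 1 reads E from the equilibrium stress–strain
slope (hold tails) and a descriptive SLS relaxation time for μ; stage 2
refines (E, ν, k_r, c, μ) jointly by bounded least squares on the full
transient from three deterministic starting points.  Refining μ in stage
2 (rather than freezing the stage-1 value) is what lets noiseless round
trips recover all five parameters; the stage-1 values remain the
initializers.  A curve with no transient information (equilibrium-only)
returns stage-1 results with the biphasic stage flagged.

**Confined compression** (impermeable chamber and platen, free-draining
bottom filter).  Strain-dependent constitutive laws H_A(ε) = H_A0·e^{βε}
and k(ε) = k_0·e^{Mε} (ε compressive-negative) give the nonlinear
consolidation equation e_t = ∂_z(k(e)H_A(e) e_z) with a prescribed-flux
condition at the draining face equal to the platen speed.  The exponential
forms are a modelling choice: the study names (H_A0, k_0, β, M) without
printing its constitutive equations, and this family is the standard
strain-stiffening/strain-compaction parameterization that yields exactly
those four parameters.  The solver is a mass-conserving finite-volume
Crank–Nicolson scheme (101 nodes, Picard iteration on the coefficient,
geometrically graded steps after each loading discontinuity); fluid mass
balance holds to round-off, and at β = M = 0 the solution matches the
closed-form eigenfunction series of the linear problem to ≤0.1%
(default resolution ~0.07%, refined ~0.02%).  The measured stress is the
elastic stress at the draining face, where pore pressure vanishes.
Fitting (H_A0, k_0, β, M) uses bounded least squares initialized from the
first-ramp equilibrium secant and the first relaxation's exponential time
constant, with β = M = 0 plus two perturbed starts; a single-ramp curve
only identifies the linear model and flags β, M unidentifiable.

**Equilibrium criterion.**  Relaxations are considered complete when the
centered 5-minute rolling slope of force falls below 0.1 g/min
(1 g ≡ 9.80665e-3 N), mirroring the testing machine's stop rule;
segments shorter than the window or never meeting the criterion are
flagged.

**Permeametry.**  Darcy's law k = Q·l·μ/(ΔP·S) at the protocol's 40 kPa
pressure difference.  The generator emits the steady flow consistent
with a prescribed k_a, so estimation inverts it exactly.

**Default protocol scales.**  Simulated tests use 5 (unconfined) or 4
(confined) ramps of 5% strain over 60 s, with fixed holds of 2500 s and
900 s.  For NP in-situ parameters the slowest unconfined radial mode is
≈2600 s, so unconfined equilibria are only approximate at the hold end —
one reason the final estimates come from the full-curve fit rather than
stage 1 alone.  Confined holds span ≈6 consolidation time constants.
Hold lengths are fixed defaults (the source protocol stopped on the
slope criterion but reports no durations); the criterion detector is
available and used by the fitters to locate equilibrium tails.

## Cohort generator and statistics

`simulate_cohort` draws the five MRI variables per group × region from
Gaussians with the study's printed means and SDs (internal units: ms,
fractions, mm²/s), truncates them at zero (MTR also at one), and then
computes each mechanical property from a linear MRI→mechanics linkage

    MP = a0 + a1·T1 + a2·T2 + a3·MTR + a4·ADC + a5·FA + ε,   ε ~ N(0, σ²)

evaluated on the *recorded* (truncated) predictors, so a zero-noise
cohort is exactly linear in the stored table.  Mechanical values are
truncated at zero with clip counts recorded.  The default linkage adds a
per-group intercept offset — the study fits its regressions per group,
so a group-specific intercept is the faithful emulation — with slopes
standardized to explain 55% of the pooled within-group variance (the
study reports 45–80% explained variance), slope signs following each
predictor's across-group association with the property, and residual σ
supplying the remaining 45%.  Custom specs with zero offsets reduce to a
single global linear map.  Because the printed tables put several means
within ~1–2 SD of zero (e.g. FA, E), Gaussian emulation necessarily
truncates some mass at zero; group means therefore sit slightly above
the printed values for those variables.  Tests account for this with
truncated-normal closed forms rather than pretending the truncation away.
What passing tests show is that the estimators recover the generating
process; they do not show that real disc data satisfy the linear
linkage, Gaussianity, or the exponential constitutive laws.

The statistics layer provides: one-way ANOVA from the classical
between/within decomposition (degenerate zero-variance input returns
F = 0, p = 1); pairwise pooled-variance t tests with Šidák adjustment
p′ = 1 − (1 − p)^m over the m = k(k−1)/2 comparisons; OLS of each
mechanical property on the five MRI predictors with R², standard error
of estimate √(SSE/(n−6)), and the power of the overall F test from the
noncentral F distribution (noncentrality λ = n·f² by default,
(n−p−1)·f² switchable, the convention recorded in the output — the
original analysis software's exact convention is unrecoverable);
variance inflation factors 1/(1−R_j²) with iterative elimination of the
highest-VIF predictor above a threshold (default 10) and the ΔR² trace
recorded; correlation PCA (columns standardized with ddof = 1,
eigendecomposition of the correlation matrix, deterministic sign
convention: each component's largest-magnitude loading is positive) with
correlation-circle coordinates loading×√eigenvalue; and Ward
agglomerative clustering by the Lance–Williams recurrence on
within-cluster sum-of-squares increments, ties broken by lowest node
index.  Ward heights are the ESS increments themselves (they sum to the
total sum of squares about the grand centroid, tested to 1e-8), not the
√(2·ΔESS) distance convention some libraries print.  The informal
"natural division" read off a dendrogram is formalized as the cut below
the merge with the maximal height ratio h_i/h_{i−1} over the last 10
merges, with the full ratio table exposed so users can override k.

PCA/clustering layout follows the study: correlation circles are built
per mechanical property (six variables: one property + five MRI
parameters, pooled over the 60 samples of a region — the study does not
say whether it pooled, and pooling is the choice made here), while
clustering runs on the first three principal components of the
mechanical-property set or the MRI set.

## Pipeline

`run_study` executes simulate → fit-mri → fit-mech → analyze into a
fresh run directory, with a manifest (config hash, seed, version) and
the hash embedded as a comment line in every CSV; identical configs
reproduce identical bytes.  The imaging and mechanical-fitting stages run
on representative subsets (a small two-region phantom; one unconfined,
one confined and one permeametry experiment at the NP in-situ ground
truth) — the cohort statistics operate at the table level, where the
per-sample signal stages would only re-demonstrate the round trips the
unit tests already establish — with sizes configurable in `StudyConfig`.
Statistics run on the full simulated cohort (default 15 per group,
120 rows).

## Numerical choices and limitations

- Optimizers are deterministic: fixed grids, fixed multi-start offsets,
  bounded trust-region least squares (`xtol`/`ftol` 1e-10–1e-12).
- Series truncation: the confined eigenfunction series is evaluated via
  Θ(τ) = Σ e^{−λ₁n²τ}/n² with an adaptive term count from the requested
  1e-10 relative tolerance (Θ(0) = π²/6 exactly); the unconfined modal
  series uses 60 Bessel roots by default (3000 for instantaneous-limit
  checks).
- The unconfined ν is bounded in [0, 0.49]; a fit pinned at a bound is
  flagged.  Permeabilities are optimized in log10.
- The generator emulates neither scanner artifacts (B1, eddy currents,
  partial volume) nor specimen-level geometry changes, swelling pressure,
  tissue anisotropy of the solid skeleton, or the chemistry of enzymatic
  digestion; group differences enter only through the printed means/SDs.
- Printed flow rates (20–25 µl/h at 40 kPa) and printed permeabilities
  (~10e-15 m⁴/(N·s)) are mutually inconsistent under Darcy's law with
  the stated geometry; the package computes the law as written and does
  not reconcile the discrepancy (a test pins the hand value ~1.13e-17
  m⁴/(N·s) for the printed flow).
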