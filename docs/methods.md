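# Methods

## The network and the model space

Six regions in fixed order lV1, rV1, lOFA, rOFA, lFFA, rFFA. All coupling
matrices are oriented **rows = target, columns = source**. The endogenous
structure (A) is identical in every model: each V1 projects to the
ipsilateral OFA and FFA (no OFA→FFA hierarchy — the two areas are coupled
bidirectionally within a hemisphere); the only interhemispheric edges are
the homotopic OFA–OFA and FFA–FFA pairs (V1 is treated as acallosal and
heterotopic edges such as lOFA→rFFA are excluded); every region has a
self-connection. Driving input (C) enters V1 only: central stimulation
(CS) drives both V1s, left/right-hemifield stimulation (LS/RS) drives the
contralateral V1 only.

The five models M1–M5 differ only in the modulatory (B) masks, identically
for the three face inputs CF/LF/RF, and are strictly nested:

| model | modulated edges (per modulator) | count |
|---|---|---|
| M1 | homotopic OFA–OFA, FFA–FFA | 4 |
| M2 | + ipsilateral OFA→FFA | 6 |
| M3 | + FFA→OFA | 8 |
| M4 | + V1→OFA | 10 |
| M5 | + V1→FFA | 12 |

Self-connections are never modulatable; B-mask diagonals are forced false.

## Forward model

Neural dynamics are bilinear:

    dz/dt = (A_eff + Σ_j u_j B_j) z + C u_drive

The diagonal of A is stored as unitless log-scalings a_ii with effective
self-decay −0.5·exp(a_ii) Hz, so larger values mean faster decay and the
self-connection can never change sign. Off-diagonal A, B, C entries are
rates in Hz.

Each region's activity drives the four-state balloon/windkessel cascade
(vasodilatory signal s, blood flow f, venous volume v, deoxyhaemoglobin
q), with the standard constants κ = 0.64 s⁻¹ (signal decay), γ = 0.32 s⁻¹
(flow feedback), τ = 2 s (transit time), α = 0.32 (vessel stiffness),
E₀ = 0.4 (resting O₂ extraction), V₀ = 0.04 (resting venous volume), and
the static BOLD observation y = 100·V₀[k₁(1−q) + k₂(1−q/v) + k₃(1−v)]
with k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2, in percent signal change.

### Numerical scheme

Inputs are block boxcars, hence piecewise constant on the microtime grid
(default 16 bins per 1.45 s scan). Within a bin the neural subsystem is
linear-time-invariant, so it is advanced by the **exact** discrete
propagator expm(J·Δt/2) applied twice (the half step also yields the
mid-bin state); there is no neural discretisation error beyond the input
rasterisation itself. The haemodynamic states are advanced by one
classical RK4 step per bin on log-transformed f, v, q (positivity by
construction), using the start/mid/end neural values. Against a
high-accuracy adaptive ODE oracle the sampled BOLD agrees to ~1e-7 RMS;
halving the microtime step (holding the rasterised input fixed) changes
the output by far less than 1e-4 RMS. BOLD sample *s* is the state at the
end of scan *s*.

Two guards make the integrator total: trajectories with |z| > 50 or any
haemodynamic log-state above 8 abort as divergent (the optimiser treats
such parameter vectors as rejected steps), and the log-states are floored
at −4. The floor matters because the balloon model has no lower fixed
point under sustained deep inhibition: when z stays below −γ ≈ −0.32 the
flow equation drives f to zero and ln f to −∞. Flooring f at e⁻⁴ ≈ 0.018
(physiologically: flow cannot fall meaningfully below zero) keeps the
forward model defined on the whole parameter space the optimiser explores;
the floor never binds in the physiological regime the generator produces.

Driving inputs are used as rasterised (no mean-centring); a deliberate
choice, recorded here because centring changes the interpretation of A.

## Priors and inversion

Free parameters per model: masked off-diagonal A entries, the 6 self
log-scalings, masked B and C entries, plus per-region log-scalings of the
haemodynamic decay κ and transit τ (58 neural + 12 haemodynamic for M5).
Priors are zero-mean diagonal Gaussians: variance 1/16 for A (off-diagonal
and self) and B, 1 for C, 1/64 for the haemodynamic log-scalings.
Mask-absent entries are fixed at zero (prior variance 0). The coupling
widths (SD 0.25 Hz) admit effects of several tenths of a Hz while keeping
prior-sampled zero-input dynamics stable with probability well above 0.95
(checked by simulation in the test suite).

Inversion is variational Laplace under Gaussian fixed-form assumptions
with i.i.d. Gaussian observation noise per region (no AR model):

1. Jacobian of the BOLD prediction by forward finite differences
   (step 1e-3), computed in one batched integrator call — one column per
   free parameter. Data and predictions are mean-centred per region, which
   absorbs constant offsets.
2. Per-region observation log-precisions λ_r updated by Newton steps on F
   under a weak log-normal hyperprior (centre: the data's log inverse
   variance; variance 16), interleaved with the posterior covariance fixed
   point — an EM-style hyperparameter update.
3. A Levenberg-regularised Gauss–Newton step on the parameters, accepted
   only if it increases F over the best value so far (otherwise the
   damping is raised tenfold and the step retried, up to 6 times). The
   accepted-step F trace is therefore non-decreasing by construction.

Termination: F improvement below 0.01 nats, a stalled step search, or 32
iterations; the convergence status is recorded on the posterior and a
warning is emitted when the iteration limit is hit. F is reported in nats
up to constants shared across models, which cancel in Bayes factors and
BMS. Explained variance is 100·(1 − RSS/TSS) of the centred data, pooled
over regions, at the posterior mean.

## Group-level inference

**RFX BMS** follows the variational Dirichlet scheme over model
frequencies: uniform Dirichlet(1) prior, expected per-subject assignments
∝ exp(F + ψ(α_k) − ψ(Σα)), iterated to a concentration change < 1e-6.
Exceedance probabilities are Monte-Carlo estimates (default 1e6 seeded
Dirichlet draws) of each model being the most frequent.

**RFX BMA** excludes models outside an Occam's window before averaging.
The window criterion "p < 0.05" is read as an odds ratio — a model is kept
if its posterior frequency is at least 0.05 of the best model's — matching
common practice; an absolute-probability mode is available behind the
`window_mode` switch, and the best model is always retained. The frequency
used is the mean per-subject assignment probability, i.e. the data-driven
estimate (α_k − α₀)/S, **not** the Dirichlet-smoothed expectation
α_k/Σα: the smoothed value is floored at 1/(K + S) by the uniform prior,
so for cohorts smaller than ~19 subjects an odds window on it could never
exclude any model however decisive the evidence. Averaging is by sampling (default 5000 seeded draws): per draw
and subject a model is drawn from the subject's assignment probabilities
(restricted to the window and renormalised) and parameters from that
model's Gaussian posterior; parameters a model lacks contribute zero.
All A/B/C entries are always written to the output tables; the
sign-probability threshold of 0.95 (P(parameter > 0) from the Gaussian
CDF) affects reporting only.

One empirical caveat found while validating the scheme: adding a subject
with perfectly equal evidences does *not* always move the expected
frequencies toward uniform — the variational assignments weight models by
exp(ψ(α_k)), which can slightly sharpen the estimate. The effect is small
(|Δr| < 0.05 in the tested regimes) and leaves rankings unchanged.

## Transfer statistics

For each subject, homotopic pair (OFA, FFA) and stimulus location
(modulator LF→left, CF→central, RF→right):

    D = b(L→R) − b(R→L)          (transfer difference, Hz)
    S = (|b(L→R)| + |b(R→L)|)/2  (transfer strength, Hz; S ≥ |D|/2)

The 2×3 ANOVA is a within-subject two-factor analysis (subjects as the
random blocking factor, factors region pair and location) without
sphericity correction, computed through `statsmodels.AnovaRM` and verified
against textbook sums of squares. Post-hoc location contrasts are paired
t-tests on per-subject location means collapsed over region, uncorrected
by default with a Bonferroni switch.

The power computation uses the exact noncentral-t distribution: power at
sample size n for effect size d is the two-sided rejection probability of
a paired t-test with n−1 degrees of freedom and noncentrality d·√n; the
returned n is the smallest reaching the target. With d = 1.17,
α = 0.0125 (0.05 Bonferroni-corrected over four tests) and power 0.95 this
gives n = 16. Two-sided testing is the default tail convention (an
argument exposes one-sided).

## Synthetic cohorts

The generator emulates the study conditions: six conditions in
pseudo-randomised order (no immediate repeats, implemented as rejection
shuffling), 15.75 s stimulus blocks each followed by a 7.875 s baseline,
TR 1.45 s. Two profiles ship: the full session (8 blocks/condition, 795
analysed scans) and a reduced profile (2 blocks/condition, 200 scans) used
as the default fixture so the whole recovery study runs on a laptop in
minutes. Model recovery (a cohort-level BMS question) works at the reduced
profile; parameter recovery of the individual CF-modulated edges does not —
with two CF blocks the twelve simultaneously modulated connections are not
mutually identifiable and the converged posteriors simply shrink to the
prior — so the parameter-recovery replicates use a half-session profile
(4 blocks/condition, 392 scans).

Ground-truth parameters = template + per-subject jitter + planted effects:

* endogenous template: V1→OFA/FFA 0.3 Hz, OFA→FFA 0.2, FFA→OFA 0.1,
  homotopic 0.05 Hz; self log-scalings 0.8 (V1) and 0.5 (OFA/FFA) —
  positive self-parameters, larger for V1, consistent with reported fits
  and keeping the modulated network comfortably stable;
* driving gains 0.4 Hz; jitter SDs 0.1 (A, self), 0.2 (C), 0 (B);
* planted modulatory effects of 0.3–0.45 Hz on named edges (defaults in
  `DEFAULT_PLANTED`): central faces modulate all twelve M5 edges roughly
  symmetrically; peripheral faces produce excitatory transfer away from
  the stimulated hemisphere and inhibitory return, and only edges whose
  source region is active in those blocks are planted (the undriven V1's
  outgoing modulations would be unidentifiable);
* draws are rejected until the coupling matrix at rest *and* under each
  single face condition has spectral abscissa < −0.15 (at most 1000
  redraws), keeping neural excursions within |z| ≲ 1;
* observation noise is i.i.d. Gaussian per region, default SNR 1
  (per-region noise SD = clean-signal SD).

Every random choice derives from the master seed through per-subject seed
sequences; cohorts regenerate bit-identically, and each subject's manifest
(model, parameters, seeds) suffices to re-simulate its clean series
exactly.

### What the synthetic data does and does not emulate

It reproduces the design geometry, the generative model class, and
known-truth heterogeneity across subjects (including mixed-true-model
cohorts). It does **not** contain scanner drift, physiological or AR(1)
noise, motion, regional haemodynamic variability beyond the estimated
decay/transit scalings, ROI-extraction error, or inter-subject anatomical
variability. Passing recovery tests therefore demonstrates the internal
consistency and identifiability of the pipeline under its own model class
— not performance on real data, whose noise violates these assumptions.

## Known limitations

* Single-state, non-stochastic, bilinear DCM only; no two-state or
  nonlinear (D-matrix) variants.
* Free energies are comparable across models within this implementation
  but not numerically interchangeable with other implementations (different
  constant terms and hyperpriors).
* The BMA sampler uses diagonal-free Gaussian draws from full posterior
  covariances per model but ignores between-model posterior correlation
  (models are sampled independently per draw), as is standard.
* The ANOVA applies no sphericity correction; with three location levels
  this can be mildly anticonservative.
* At the reduced profile the evidence differences between adjacent nested
  models are small (a few nats per subject); model recovery statements are
  about the cohort-level BMS, not per-subject identification.
* Variational Laplace is a local ascent and the free-energy landscape is
  multimodal. In recovery simulations at the full session length, one
  maximally confounded planted effect (the negative CF modulation of
  rOFA→lOFA, whose target also receives two larger positive modulated
  inputs) lands in a locally optimal alternative regime in roughly a
  third of noise realisations, although a basin near the truth has
  measurably higher free energy (~56 nats in a probed case). Tighter
  tolerances, more iterations, partial hyperparameter updates, heavier
  initial damping and seeded multistarts do not change the basin reached
  from the zero start; only informed warm starts (the `mu_init` argument)
  do. Single-subject point estimates of strongly confounded modulatory
  parameters should therefore be treated with caution.
* Posterior shrinkage of confounded parameters is the correct Bayesian
  answer (the free energy at the generating truth is below the optimum),
  but it means marginal 2-SD credible intervals systematically undercover
  such truths as noise decreases — confidence grows around the shrunk
  value, not the truth.
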