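# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of `tcellsim`, at the level of detail a
maintainer or reviewer needs to judge what the package's results do and do
not show.

## Priming model

Retention of a cognate T cell in an antigen-bearing LN is modeled as the
n-th success of a Bernoulli-thinned Poisson contact process: contacts at
rate λ/h, success probability p, so the retention time is
Gamma(shape n, rate μ = λp). Only μ is identifiable from retention
data — the package stores (λ, p, n) for simulation but all analytics
depend on (n, μ). `required_contacts` is an integer in event-level
simulation (`simulate_contact_history`) and real-valued everywhere else
(the incomplete-gamma CDF is continuous in n, which keeps the fitting
objective smooth).

When comparing probabilistic priming to signal integration *at the same
true DC contact rate*, only new-DC contacts count for probabilistic
priming; for a persistent random walk in a large 3D tissue roughly 2/3 of
contacts are unique, and `apply_unique_contact_factor` applies that
conversion exactly once (a guard flag prevents double application). All
default comparisons are at equal *effective* rates; the factor is opt-in,
since the effective rate is what retention data identify.

## Organ geometry

Units: lengths in µm, motility in µm²/min, times returned in hours. Only
R²/M affects any dynamic quantity, so the motility coefficient
M = 60 µm²/min is a labeled convention at the two-photon scale and radii
are derived by calibration:

* LN sphere: R = sqrt(6·M·13.5 h) = 540 µm (anatomically reasonable for a
  murine LN T cell zone). Transit is first passage from the center to the
  absorbing surface.
* Spleen cross-section: disc radius 100 µm with an absorbing arc of
  α = 1.00989 rad opposite the entry point, calibrated by bisection with
  common random numbers (6 000 walks per evaluation, dt = 0.1 min, seed
  20140807) to a 6 h mean transit; an independent-seed rerun with 10⁴
  walks gives 6.00 h. A 150 µm disc was rejected: reaching 6 h would have
  required α ≈ 3 rad, no longer a plausible "aperture".

The eigen-series survival is evaluated with adaptive truncation (next term
< 1e−10, cap 1000 terms); for dimensionless time τ = Mt/R² < 1e−2 the
alternating series converges slowly and loses precision, so the
Jacobi-theta dual (method of images, one image term; the next is a factor
e^(−2/τ) smaller) is used instead. Sampling inverts a 4 200-point monotone
(F, τ) table by linear interpolation with an analytic exponential tail
beyond the table; the table is cached per geometry.

The disc walker takes isotropic Gaussian steps (per-coordinate sd
sqrt(2·M·dt)); a step leaving the disc is absorbed if its angle lies in
the arc, else folded back radially (r → 2R − r). The guard
sqrt(4·M·dt) < R/10 rejects too-coarse steps; halving dt moves the mean by
~2.5%. Inside the circulation event loop, spleen dwells are drawn from an
empirical quantile table built once from 20 000 explicit transits per
geometry — explicit per-visit walks would dominate the runtime — while the
explicit walker remains the public sampler and the validation path.

## Circulation

Single cells are independent (antigen-specific precursors are too rare to
interact), so the simulator is strictly per-cell kinetic Monte Carlo:
exponential blood sojourns with rate Λ(t) = σ_S + Σσ_i(t), organ choice
proportional to rates, organ dwells from the transit laws (or a constant
in deterministic-transit experiments; the constant applies to LNs only).
Defaults σ_S = 1.0/h and Σσ_i = 1.5/h over 39 equal spheres reproduce the
25 min blood residence and 74:23:3 LN:spleen:blood occupancy; the sphere
map (axillary/brachial/inguinal pairs 2 spheres each, mesenteric 4, the
other 23 LNs 1 each) makes entry rate track LN size while egress rate does
not.

Time-varying dLN entry rates (the inflammation ramp, default 9-fold linear
over 4.5 days, also available as a step or disabled) are handled by Ogata
thinning against Λ_max, which is exact; a dt-halving discretization oracle
backs this in the tests. Retention inside a dLN compares one pre-drawn
Gamma retention time against the dwell — equivalent by construction to
event-level contact simulation, which remains available in the priming
module for cross-checks.

Cohorts are initialized by burning in each cell from the blood for 1 + u
weeks (u uniform), which desynchronizes trajectories and delivers
stationary occupancy and residual dwells. A vectorized lockstep cohort
simulator (`simulate_cohort`) handles the constant-rate no-retention case
(occupancy, arrival curves) at ~10⁴ cells × 2 weeks in seconds; ramped or
priming scenarios use the per-cell loop. Cells already inside a target
organ at t = 0 count as arrived at time 0 by default, with the opposite
convention available.

## Capture analytics

For deterministic transit the expectation
E[T_cap] = t0 + E[N](T_det + τ_b) + E[A | A < T_det] is evaluated with

* P = F_A(T_det) and E[N] = (1 − fP)/(fP);
* the truncated mean via E[A·1(A<T)] = (n/μ)·F_{n+1,μ}(T), avoiding
  quadrature;
* τ_b computed analytically from body rates: leaving an LN, the number of
  blood sojourns before the next LN entry is geometric with success
  q = Σσ_i/Λ, so τ_b = (1/q)(1/Λ) + ((1−q)/q)·E[spleen dwell] = 4.67 h at
  baseline (verified against a brute-force simulated gap);
* t0 by short Monte Carlo from the burn-in steady state, cached per
  (body, transit mode, dLN set): the stationary state depends on the
  transit mode (a 4 h deterministic dwell occupies LNs far less than the
  13.5 h first-passage law), and cells starting inside a dLN are excluded,
  matching the derivation's conditioning; cells in an ndLN first finish
  their residual visit. No closed form exists because residual
  first-passage dwells are not exponential.

The per-visit retention probability under stochastic transit uses the
closed form 1 − z·csch(z), z = R·sqrt(μ/M), for n = 1, and quadrature of
the Gamma density against the survival series for n > 1. A
quadrature-based expectation for stochastic-transit capture (same renewal
argument with dwell-conditioning under failure) serves as a fast
deterministic cross-check of the Monte Carlo and as the denominator of the
benefit/risk matrix; Monte Carlo capture remains the reference and the two
agree within a few percent in the tests.

`optimal_transit_time` minimizes the closed form over T_det ∈ (0, 96 h]
with a 400-point log-grid pre-scan plus bounded refinement; t0 is held
fixed during optimization (an additive constant cannot move the argmin).
At baseline τ_b this yields 3.77 h for 2 required contacts and 11.93 h for
8 — the absolute capture times are sensitive to the t0/τ_b conventions at
the ±20–25% level, the optima and fold ratios much less so, which is why
the optima are the tight quantitative outputs.

## Track statistics

The motility estimator M̂ = Σd²ᵢ/(6Σ|tᵢ − t_mid|) (distance to the middle
sample; central-pair average for even length) is exactly unbiased for
Brownian tracks. Two documented caveats: it underestimates short
persistent-walk tracks (velocity correlation subtracts ~6Mτ_p from each
squared displacement), and its per-track variance is large because the dᵢ
share the random midpoint — the ensemble mean over 10³ ideal tracks is
within 5% of truth, the ensemble median within 10%, but individual tracks
scatter with ~30% median relative error. Gating is therefore strictly
relative, as in the source analysis.

The gate is γ·M* with M* the control motility median weighted by track
duration in frames (midpoint convention on the expanded sequence). The in
vivo gating factor is not recoverable; the default γ = 0.25 was fixed once
against synthetic ground truth such that control false-retention stays ~0–5%
and corrected cognate fractions track the generating CDF within ±0.08 on
average, and it is config-exposed. The background correction
r′ = max(0, (r − r_ctrl)/(1 − r_ctrl)) is the unique affine map sending
the control level to 0 and full retention to 1 (a reconstruction; simple
subtraction is available behind a flag). Retention fractions weight each
track by its duration, correcting for motile cells leaving the field of
view sooner; 60-min videos are split into three 20-min windows with
tracks cut at boundaries (duration conserved), and window times are
reported relative to LN entry (1 h after transfer by default). A pooled
1-h-binned variant provides track-level bootstrap 95% CIs.

## Fitting and model selection

Fits minimize duration-weighted squared error between logit-observed and
logit-predicted fractions (logit weighting tames the heteroscedasticity
near 0 and 1); fractions and predictions are clipped to [0.01, 0.99]
before the transform, and weights are normalized to mean 1. Sharing
structures: general = per-experiment (n_e, μ_e) (12 parameters for 6
experiments); pure signal integration = shared μ, per-experiment n_e (7);
pure probabilistic = per-experiment μ_e, n = 1 (6). The general and pure
probabilistic problems decouple per experiment (n-grid multi-start plus
Nelder–Mead refinement; bounded 1D searches); the shared-μ fit profiles μ
in an outer 1D search. BIC uses the least-squares Gaussian convention
N·ln(RSS/N) + k·ln N, and ΔBIC labels follow the usual
weak/positive/strong/very-strong scale.

With observation windows ending ~8 h post entry (CDF ≤ 0.55 observed),
(n, μ) are individually soft along the usual Gamma shape/rate ridge:
medians across fits recover the generating values, and the mean retention
time n/μ is recovered per experiment, but single-experiment (n, μ) pairs
scatter. Model selection is unaffected — on synthetic signal-integration
data the pure probabilistic family loses by ΔBIC ≫ 10 while pure signal
integration stays within 2 of the general model in ≥80% of replicates.

## Synthetic data generator

The generator emulates the structure of the imaging experiments: 6
independent experiments, 3 one-hour videos each at 2, 5 and 8 h post
transfer (LN entry 1 h after transfer), 120 cognate + 120 control cells
per video. Free motion is a velocity-jump walk (speed 9.49 µm/min,
persistence 2 min, isotropic reorientation) whose long-time motility is
v²τ_p/3 ≈ 60 µm²/min; cognate cells switch at their drawn retention time
to Brownian jitter at 2 µm²/min (near-stationary arrest; the contrast
between free and arrested motion is what gating exploits, and the
realized duration-weighted control median is ~30 µm²/min, so the jitter
must sit well below γ·M*). Tracks are censored by a uniform start and an
exponential in-view duration (mean 20 min) truncated to the video, with
the 2-min minimum enforced downstream — this reproduces the
shorter-tracks-for-motile-cells effect that duration weighting corrects.

What the generator does *not* emulate: imaging noise and track-linking
errors, tissue boundaries in the imaging volume, z-anisotropy,
cell-density effects, DC heterogeneity, or any dependence of in-view
duration on arrest beyond geometry. Passing tests therefore show that the
pipeline recovers the assumed kinetics from data with its statistical
structure, not that real videos are free of these additional effects. The
density default (120 + 120 per video) is a 5-fold reduction from the
in vivo corpus (~580 tracks/video); the reduced scale keeps replicate
harnesses fast while retaining enough power for model discrimination.

## Problem sizes and tolerances

Headline quantities are recomputed at these sizes: 10⁵ retention-time
draws; 10⁴-cell cohorts over 2 simulated weeks; 10⁴ explicit Brownian
sphere walks and 10⁴ disc transits at dt = 0.1 min; 1 500–2 000-cell
capture cohorts; 50 replicates of the 6-experiment model-selection
harness. Monte Carlo checks use 2–10% tolerances matched to their standard
errors; the analytic/simulation capture agreement is held to 10%, the
series-vs-walks survival curves to a sup-deviation of 0.02, and the
csch closed form to 0.01 absolute.

## Known limitations

* Egress shutdown after infection (<1 day), lymph-borne entry routes,
  directed egress migration, proliferation after priming, and
  time-varying antigen dose or DC numbers are all outside the model, as
  in the source study's scope.
* The spleen aperture and LN radius are calibrated, not measured; only
  R²/M and the calibration targets are meaningful.
* Absolute capture times depend on the t0/τ_b conventions (±20–25%);
  orderings, optima and fold differences are the robust outputs.
* The pipeline's corrected retention slightly lags the generating CDF
  when many cells arrest mid-window (mixed-motility track pieces); this
  is inherent to motility gating on finite windows and is visible in vivo
  as well.
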