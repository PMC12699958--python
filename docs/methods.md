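# Methods

`deerloop` implements a fully automated planning-and-analysis loop for
double electron–electron resonance (DEER/PELDOR) distance measurements on
nitroxide-labelled proteins, run closed-loop against a built-in virtual
spectrometer. This note documents the models, the reconstructed rules, the
numerical choices, and what the synthetic benchmark does and does not show.

## The virtual spectrometer

`instrument_sim.GroundTruthSample` hides the "true" sample and instrument
from the protocol:

- **EPR line.** A three-component pseudo-Voigt mixture on a frequency-offset
  axis (components at 0/−50/−120 MHz, FWHM 18/70/90 MHz) emulating an
  asymmetric Q-band nitroxide echo-detected line ≈270 MHz wide (at 5% of the
  maximum). This is a parametric stand-in, not a spin-Hamiltonian powder
  average; it carries the features the placement integrals care about
  (asymmetry, a sharp maximum, a long low-frequency shoulder) and nothing
  else.
- **Longitudinal recovery.** Saturation recovery A(1 − e^−(SRT/T₁)^ξ).
- **Transverse decays.** Stretched exponentials for the Carr–Purcell-2 decay
  (five-pulse planning) and the refocused echo (four-pulse planning), with
  an optional planted τ₁-ridge for 2D-map tests.
- **Resonator.** A detuning Lorentzian ν₁(ω) = ν₁max/√(1 + Q²(ω/ω_c −
  ω_c/ω)²); the frequency-swept nutation map is generated from it with a
  decaying-cosine transient (T₂ρ = 500 ns).
- **Pump-induced echo reduction.** A single multiplicative factor per pump
  pulse (default 0.9). No quantitative physical model for the effect is
  available; a global amplitude factor is the minimal phenomenology that
  lets the planner account for it.
- **DEER traces.** Multi-pathway product form (below) with white Gaussian
  noise; noise std per point is `noise_sigma_per_shot/√(shots·scans)`.

Preset samples ("protonated-broad", "deuterated-long-distance",
"narrow-short", "low-labelling") span short vs long phase-memory times
(1.8 µs vs 10 µs), narrow vs broad/bimodal distance distributions (σ from
0.25 to 0.7 nm, means 3.0–5.5 nm), and labelling efficiencies 0.15–0.9.
`noise_sigma_per_shot = 1` (per-acquisition SNR 1 on a normalised echo) was
chosen so that a five-pulse measurement of the deuterated preset reaches a
modulation-to-noise ratio (MNR) near 20 in about two simulated hours — the
regime the initial-measurement stage is designed for. All per-record
randomness derives from one seed; identical request + seed gives
bit-identical records.

**What the simulator does not emulate:** orientation selection, nuclear
modulation (ESEEM), phase noise and drifts, detector filtering, resonator
ring-down, and multi-pathway physics beyond the two dominant pathways.
Passing tests demonstrate that the decision logic and the estimators are
correct under the stated noise model — not that the protocol is robust to
every artefact of real hardware.

## Stage models and reconstructed rules

Some quantitative rules are reconstructed from their printed consequences
and pinned by tests; each reconstruction is exposed in configuration.

- **Field sweep.** Smoothing spline (stiffness by generalised
  cross-validation, `lam` overridable); the field at maximum comes from a
  parabola vertex fitted to the contiguous ≥80%-of-max region of the
  smoothed curve, which locates the peak to well under one field step at 5%
  noise while remaining exact (and unbiased) for noiseless symmetric lines.
  γ_eff = carrier/B_max then fixes the field↔frequency map; frequency
  offsets are γ_eff·B − carrier with the observer carrier at 0 MHz.
- **SRT rule.** Sensitivity per root unit time S(SRT) ∝
  (1 − e^−(SRT/T₁)^ξ)/√SRT. This functional reproduces all five printed
  constants (argmax 1.3 T₁ at ξ=1; 0.7 T₁ and ≈53% recovery at ξ=0.75;
  1.9 T₁ at 80% recovery; 9% sensitivity loss there), which is the evidence
  for the reconstruction. Default operating point: 80% recovery, robust to
  T₁ heterogeneity. At exactly ξ=0.5 the functional loses its interior
  maximum (S → const at the origin); the uniqueness property is therefore
  guaranteed for ξ ∈ (0.5, 1.5].
- **Resonator profile.** Per-frequency transients are fitted with a
  decaying cosine A·cos(2πν₁t_p − φ)·e^(−t_p/T₂ρ) (the free phase absorbs
  the π/4 asymptotic shift of Bessel-like transients, keeping ν₁ unbiased
  within 0.1 MHz) or the J₀-Bessel form; the FFT-maximum estimator is kept
  as the initialiser only. Fits with R² < 0.5 are discarded. The profile is
  fitted with the detuning Lorentzian above; a deviation of the fitted
  centre by more than 100 MHz from the initial guess triggers one repeat of
  the profile and field sweep.
- **Pulse simulation.** Complex ν₁ envelopes on a ≤1 ns grid, filtered by
  the resonator transfer function H(ω) = ν₁(ω)/ν₁max in the frequency
  domain (amplitude only, zero-padded 4× so pulse edges are part of the
  transform), then propagated offset-by-offset as piecewise-constant
  two-level rotations (Rodrigues form; verified against an independent
  `solve_ivp` Bloch integration to 1e-4). Swept rectangular pulses carry a
  quarter-sine edge ramp (default 10% of the length) suppressing the
  Fresnel ripple of abrupt edges, as AWG implementations do; their
  amplitude defaults to the full available ν₁. The inversion band edge of a
  chirp rolls off over ≈ν₁ inside the sweep band — complete (>0.95)
  inversion is guaranteed only on the flat-top region, and tests assert it
  on the central half of the band.
- **Observer lengths.** t_π/2 = 1/(2·0.9·ν₁max) — the "design" bandwidth
  1/(2t) set to 90% of ν₁max, which reproduces the printed 8/12.5/23 ns
  choices for ν₁max = 70/45/25 MHz up to hardware rounding (default
  granularity 2 ns) — capped so the bandwidth does not exceed 40% of the
  available band. π pulses share shape and length at doubled amplitude. The
  "report" bandwidth convention for tables is 1/t_p.
- **Placement.** Exclusivity is product-minus-overlap: P̄_pump =
  p_inv,pump·(1 − p_obs), P̄_obs = p_obs·(1 − p_inv,pump) with the observer
  band the cumulative train profile (π/2 transverse conversion × both π
  inversion factors); spectral fractions are amplitude-weighted integrals.
  F = 2·p_pump·p_obs is maximised over pump centre, observer centre and the
  spectrum-maximum offset (realised by translating the spectrum axis, which
  is equivalent to moving the field through γ_eff) by multi-start
  Nelder–Mead seeded on a coarse grid, with profiles cached per 0.1 MHz
  centre. Pump menu: monochromatic rect (bandwidth equal to the excitation
  pulse) and linear-chirp rect with sweep width min(BW_res, BW_spec) −
  BW_exc; ties break toward the simpler pulse. The pump-length broadening
  bound uses c_pump·r_min³/D with c_pump = ¼ (a configurable placeholder —
  there is no settled value for the proportionality constant), under the
  hard caps
  min(256 ns, 0.1·τ_evo). On the three reference resonator setups the
  optimiser picks a chirp pump in all three cases with sensitivity ordering
  R1 > R2 > R3 and pump centres near −130 MHz — the behaviour practitioners
  report for such hardware.
- **Relaxation and planning.** Decays are fitted as stretched exponentials
  (spline-interpolated empirical evaluators available for non-exponential
  fixtures); Ṽ(τ_evo) is the normalised decay. Time step: r_min =
  (4·D·Δt/0.85)^⅓ with D = 52.04 MHz·nm³ (factor 4 for the Pake shoulders,
  85% Nyquist margin); Δt = 8 ns default, doubled under AWG memory
  pressure, refused past 32 ns in favour of a split measurement. Target
  evolution time: τ_evo = T_ref·(r_max/L)³ with T_ref = 2 µs and L = 6/5/4/3
  nm for presence/mean/width/shape information (T_ref is a reconstruction
  exposed in config and excluded from numeric acceptance). Achievable
  τ_evo: the largest root of SNR(τ) = (Ṽ(τ)/σ)·√(T/(SRT·N_points(τ))) at
  the required SNR = MNR/λ, evaluated on the lower band Ṽ − σ_decay, where
  σ is per-acquisition noise and σ_decay the noise of the measured decay
  trace (two distinct numbers; conflating them makes the lower band
  vanish). Sequence choice follows the three four-pulse preference rules
  (longer τ_evo; similar (within 10%) amplitude at equal τ_evo; mean
  dipolar frequency within a factor 2 — configurable — of 1/τ₁, the last
  only with a known ROI; only the last two when the target τ_evo is fixed).
  Delays: five-pulse τ₁ = τ₂ = (τ_evo + τ₃)/2 with τ₃ = 300 ns; four-pulse
  τ₂ = τ_evo with τ₁ from the 2D ridge or 400 ns; pump sweep from
  t_min = 150 ns before the main refocusing point in steps Δt,
  centre-to-centre throughout, with a collision guard for long pump pulses.
- **DEER model.** K(t,r) = ∫₀¹ cos(2π(D/r³)(1−3z²)t) dz via the Fresnel
  closed form (Gauss–Legendre quadrature as the independent cross-check,
  equal to 1e-8); signal V(t) = V₀·∏ᵢ[(1−λᵢ) + λᵢ(KP)(t−tᵢ)]·∏ᵢ
  e^(−k|t−tᵢ|) — a product over pathways with a homogeneous (3D)
  background per pathway. The five-pulse secondary pathway refocuses at
  (τ_evo − τ₃)/2 on the internal axis (main refocusing at t = 0; the
  experiment-axis offset t_min is kept in metadata).
- **Inversion.** Separable nonlinear least squares: P(r) non-negative on a
  60-point grid from max(1.5 nm, r_min(Δt)) — the excitation-bandwidth
  floor acts as the low-pass filter — to the presence-rule maximum
  6·(t_max/2 µs)^⅓ + 0.5 nm; second-difference Tikhonov penalty with weight
  by GCV on a linearised sub-problem; V₀, background rate and pathway
  depths bounded; soft constraint ∫P dr = 1. The fit runs in two stages:
  first without the compactness penalty (so noise-free data are reproduced
  to solver tolerance, ~1e-6·V₀ at tight `ftol`), then — only when the
  stage-1 residual shows real noise (>1e-4·V₀) — a refit with the
  second-moment compactness penalty ∫P(r)(r−⟨r⟩)² dr at weight 0.05.
  Compactness is on by default in the noisy regime because without it the
  non-negative fit at MNR ≈ 150 moves 8–21% of the mass into the
  unconstrained long-r tail and collapses the background rate, biasing the
  mean by up to +0.6 nm; with it the same traces recover mean, λ and
  background essentially exactly. MNR = λ_main·V₀/σ with σ from the fit
  residuals.
- **Uncertainty.** Residual-resampling bootstrap (default 50 replicates;
  20 inside the protocol) with warm-started refits gives percentile bands
  for P(r). The mean-distance interval is the basic (reflected) bootstrap
  interval, widened by a shrinkage systematic estimated from one refit at
  a third of the regularisation weight and floored at half a grid step
  (the smoothed inversion cannot localise the mean below its resolution).
  Under the simulator's conditions this interval covers the true mean in
  ≥90% of seeded protocol runs.
- **ROI.** Gaussian least-squares fit to the non-parametric P(r)
  (moment-based start), ROI = mean ± α·σ with α = 2 by default (the band
  multiplier is a design choice; α is config-exposed), clipped to the grid;
  a poor Gaussian fit (residual RMS > 20% of the peak) is flagged rather
  than rejected.

## The orchestrator

The protocol state machine runs: insertion (validation only) → field sweep
→ SRT scan → resonator profile (≤1 re-centre loop) → pulse placement →
relaxation (the 2D refocused-echo map is measured only when four-pulse is
preselected from the start; otherwise a 1D decay at τ₁ = 400 ns) → delay
planning → initial DEER → ROI → re-optimisation → final DEER.

Operating targets: MNR 20 within a 2 h budget (4 h hard cap) for the
initial measurement; if the cap is hit below MNR 10 the initial DEER is
repeated once with the labelling-efficiency estimate halved, otherwise the
protocol continues. The final measurement aims at the shape-information
τ_evo for the ROI upper edge, shortened to what the SNR model predicts is
achievable in the remaining time at MNR 150 — but never below the
mean-information floor for the ROI (measuring a too-short trace would make
the headline mean distance meaningless; the protocol accepts a lower MNR
instead). The pump length is re-checked against the ROI lower bound and the
pulses re-set-up if it must shrink. MNR is monitored with a fast
no-bootstrap fit at geometrically spaced scan counts (1, 2, 4, …), a
simple-two-pathway analogue of fitting after every scan at a fraction of
the cost. Scan time is accounted as N_points × shots × phase steps × SRT
(16 phase steps for five-pulse, 8 for four-pulse). Feedback loops are
capped (one resonator re-centre, one initial-DEER retry) so every run
terminates; simulated elapsed time never exceeds the budget plus one scan.

Determinism: all record seeds derive from one `SeedSequence`; rerunning
with the same configuration and seed reproduces the decision log verbatim.

## Known limitations

- The exclusive-probability construction (product-minus-overlap) satisfies
  the pair-fraction identities and the λ algebra exactly, but it is one of
  several defensible definitions of exclusivity; absolute λ values carry
  that model's error.
- Exchange coupling, orientation selection, and multi-spin effects are out
  of scope; distances below the excitation-bandwidth floor are deliberately
  suppressed rather than modelled.
- The SNR planning model's absolute normalisation is a reconstruction
  pinned only to its stated dependencies (Ṽ, σ, T, SRT, N_points); it is
  self-consistent with the simulator's noise bookkeeping but has not been
  calibrated against hardware.
- Hardware control, vendor APIs, GUI, and non-uniform sampling schedules
  are not implemented.
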