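# Methods

This note documents the models implemented in `csmkinetics`, the conventions
and defaults behind them, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## 1. Correlation analysis

**Estimator.** For binned channel intensities F_i, F_j the package computes

    G_ij(τ) = ⟨F_i(t) F_j(t+τ)⟩ / (⟨F_i⟩⟨F_j⟩) − 1 .

The textbook FCS correlation equals 1 for independent signals; the stored
curve subtracts that baseline so uncorrelated channels give 0 and the
zero-lag value is the fluctuation amplitude G₀ — the convention every
diffusion-model fit assumes.  Symmetric normalization is used: the
denominator means are taken over the overlapping segments entering the
numerator at each lag, which suppresses bias from slow drifts.

**Lag grid.** Standard multi-tau scheme: 16 lags in the first cascade at the
native bin width, 8 new lags per subsequent cascade with the bin width
doubling each time, implemented as a cascade of pairwise re-binning steps.  A
brute-force direct-lag correlator evaluates the identical estimator on the
identical grid by direct summation; the two agree to floating-point rounding
(tested at 10⁻¹⁰ relative), which validates the cascaded implementation.

**Diffusion model.** Correlation curves are fitted with free 3D diffusion
through a 3D-Gaussian detection volume,

    G(τ) = G∞ + G₀ · T(τ) · [ f·g(τ;τ_D1) + (1−f)·g(τ;τ_D2) ],
    g(τ;τ_D) = (1+τ/τ_D)⁻¹ (1+τ/(κ²τ_D))^(−1/2),
    T(τ) = 1 + T/(1−T) · e^(−τ/τ_T),

with structure factor κ = z₀/w₀ (default 5, typical for a confocal volume;
always an explicit setting because it is rarely known exactly), optional
second species and optional triplet (dark-state) term.  Weighted nonlinear
least squares (scipy `curve_fit`) with lag bins weighted by √(number of
averaged products) — an approximate inverse-variance weighting.  Freeing κ
together with two diffusion times is refused by default (they are degenerate
on a single curve).  The amplitude reported is the fit-extrapolated G₀, not
the first measured lag bin.

**Sliding-window kinetics.** A reaction time course is cut into consecutive
windows (default 60 s); each window is correlated and fitted; the observable
is either the cross-correlation amplitude (proportional to the concentration
of complexes carrying both labels) or the fraction-weighted mean diffusion
time f·τ_D1 + (1−f)·τ_D2 of a two-species fit (the minimal reading of a
"mean diffusion time of both species").  Per-window fits hold κ and τ_T
fixed (calibrated once on the full trace when needed) for identifiability in
short windows.  Two guards mark diverged window fits as missing (NaN) rather
than dropping them silently: an extrapolated amplitude more than 3× the
measured curve maximum, or a mean diffusion time outside the measured lag
span.  Downstream fits skip NaNs.

**Release models.** Normalized kinetics series (pointwise division by an
enzyme-free control, then scaling the first value to 1) are fitted with

    R(t) = (1−R₀) e^(−t/⟨t⟩) + R₀                     (exponential + plateau)
    τ(t) = A₁e^(−t/⟨t⟩₁) + A₂e^(−t/⟨t⟩₂) + τ₀,  A₁ = 1−A₂−τ₀   (bi-exponential)

Bi-exponential timescales are reported ordered ⟨t⟩₁ < ⟨t⟩₂.  A fitted decay
is flagged unidentifiable when its amplitude does not clear 3× the residual
noise floor, when its timescale standard error exceeds the timescale, or
(bi-exponential) when the two timescales are separated by less than 1.5×.
The plateau is bounded at 1.5 — above any physically meaningful value for a
normalized decay, but tolerant of noisy normalization of a flat series.

**Independence prediction.** For two ends releasing independently with mean
times t_a and t_b, the first release occurs with mean 1/(1/t_a + 1/t_b); for
the measured 84 and 119 min single-end times this predicts a ~49-min
cross-correlation decay.  A measured decay much slower than the prediction
(the observed ~84 min) implies cooperative release; the workflow raises this
flag when the measured time exceeds 1.25× the prediction.

## 2. TIRF survival analysis

Trajectories are smoothed with a centered 3-point moving average (shrinking
to 2 points at the ends, so no frames are discarded from the normalization
window), normalized to the mean of the first 10 smoothed frames, and scored
as disappeared at the first *smoothed* frame below 10 % of the initial
intensity (smoothing precedes thresholding in the processing order).  Spots
surviving the recording are right-censored; the survival estimator is the
empirical fraction (no Kaplan–Meier weighting — there is no mid-trace
censoring in this design).  Bleaching correction divides the with-enzyme
survival by the no-enzyme control, clips the ratio to [0,1] (clipping is
recorded), and truncates with a warning where the control reaches zero; the
corrected curve is deliberately not forced monotone.  For independent
exponential release (mean T_rel) and bleaching, the expectation of the
corrected curve is exp(−t/T_rel).

## 3. DNase kinetic model

Six species (nM): non-activated free complex N, activated free complex A,
their DNA-bound forms NS and AS, free reporter ssDNA S and cleaved product P.
Mass-action rates:

    dNS/dt = k⁺·N·S − k⁻·NS − k_cN·NS + k_d·AS
    dAS/dt = k⁺·A·S − k⁻·AS − k_cA·AS − k_d·AS
    dN/dt  = −k⁺·N·S + k⁻·NS + k_cN·NS + k_d·A
    dA/dt  = −k⁺·A·S + k⁻·AS + k_cA·AS − k_d·A
    dS/dt  = −k⁺·(N+A)·S + k⁻·(NS+AS)
    dP/dt  = k_cN·NS + k_cA·AS

Both complex forms share the DNA binding step (k⁺ = k_bind⁺, k⁻ = k_bind⁻);
cleavage-and-release is a single irreversible step (k_cN, k_cA) — product
release is lumped into it.  Deactivation (RNA-end release, k_d = k_RNA⁻)
applies at equal rate to the free and the DNA-bound activated complex
(A→N, AS→NS): activation is a property of the complex, and end release is
independent of the DNase activity; a supplementary formulation restricting
deactivation to the free form would change AS bookkeeping only marginally at
these occupancies.  RNA binding is treated as instantaneous at t = 0
(A(0) = min(RNA, Csm), N(0) = Csm − A(0)); RNA turnover and competitor
effects enter only through this initial condition plus k_d.  Two totals are
conserved identically: N+A+NS+AS and S+NS+AS+P (verified along trajectories
to 10⁻⁸ relative).

**Observable.** F(t) = signal_scale · (P + β·(NS+AS)) with bound-signal
fraction β ∈ [0,1], default 1: binding alone separates the dye-quencher pair,
producing the fast initial rise before any cleavage.  Raw fluorometer traces
are converted to nM by a linear calibration fitted to saturated endpoints of
known fully-cleaved amounts (≥ 2 points spanning ≥ 2-fold).

**Units.** Concentrations are nM internally; k_bind⁺ is accepted in /(M·s)
at the interface and converted (×10⁻⁹) internally; the conversion is tested
via the hand-computed initial binding flux.

**Global fit.** One parameter set is fitted simultaneously to all traces of
a titration (requires ≥ 2 traces, ≥ 2 DNA concentrations, and — for the
activation parameters — at least one RNA-containing trace; otherwise
k_cleave_A and k_deact are dropped from the free set and reported
unidentifiable).  Residuals are weighted per trace by the point noise level
estimated from the median absolute successive difference (robust to the
smooth kinetic trend).  The optimizer works in log₁₀-parameter space within
bounds spanning 4–6 decades per rate, multi-started from 10 seeded
log-uniform draws plus the user guess; draws are pre-screened by objective
value and the best three polished by trust-region least squares, then the
winner is re-polished at tighter integrator tolerance.  Two numerical
details matter: the finite-difference step (10⁻³ in log₁₀ units) must
dominate the ODE-solver noise floor, and the final polish integrates at
rtol 10⁻⁸ — without these the fit stalls on the shallow valley that trades
k_bind⁺/k_bind⁻/k_cleave_A against each other.  Uncertainties come from the
Jacobian at the optimum (delta method through the log transform); singular
directions below 10⁻⁶ of the leading singular value are reported as flat
directions.  K_d = k_bind⁻/k_bind⁺ sits above the highest DNA concentration
in the titration and is therefore a rough estimate by construction — the
recovery tests demand it only within a factor of ~2.

ODE integration uses LSODA with an analytic Jacobian (rtol 10⁻⁸ for
simulation, 10⁻⁶ during fit exploration); an independent Radau integration
agrees to 10⁻⁶ relative and serves as the cross-check oracle.

## 4. Synthetic data: what it emulates, what it does not

**FCS generator.** Brownian dynamics of point emitters in a periodic cubic
box (edge ≥ 10·w₀, and ≥ 4·z₀ by default, keeping the detection function
negligible at the boundary).  Expected count rate per particle is
b·exp(−2(x²+y²)/w₀² − 2z²/z₀²); expected counts are accumulated per time
step, binned, and Poisson-sampled with a uniform background.  Optional
dark-state blinking is a two-state telegraph process with equilibrium dark
fraction T and relaxation time τ_T (transition rates T/τ_T and (1−T)/τ_T),
generated from exact exponential dwell times.  The generator is photon-binned
rather than photon-by-photon: no TCSPC arrival times, no pulsed interleaving,
no detector afterpulsing, no optical aberrations, no crosstalk.  That is
sufficient to exercise the correlator and every diffusion-model variant; it
does not test crosstalk correction, which the analysis (operating on
channel-separated signals) assumes done upstream.  The Brownian core runs in
single precision (position error ≪ focus size, ~2× faster); traces are
bit-reproducible given the seed on a given platform.  A blinking relaxation
time is only recovered faithfully when it spans ≳ 20 sampling bins —
tests therefore use τ_T ≥ 25 bins rather than the ~10-bin regime, where
triangular bin-smearing biases the triplet fit.

**Release experiment.** A time course is emulated as a sequence of
stationary windows: at window k the dual-labeled (both-ends-bound) fraction
is (1−R₀)e^(−k/τ)+R₀; released complexes are replaced by two independent
single-labeled fast species, so the total per-channel intensity stays
constant and the cross amplitude tracks the bound concentration linearly.
Desk-scale runs compress time (one 0.25–0.5 s analysis window per reaction
minute); per-window amplitude scatter is 10–20 %, so recovered release
times carry 20–30 % error per experiment — the tests use medians over
repeated simulated experiments, mirroring the triplicate averaging of the
real assay.  A green test establishes correct analysis-chain wiring and
unbiased recovery, not the photophysical fidelity of a real measurement.

**TIRF generator.** Unit-intensity spots with independent exponential
release and bleach times (either may be infinite) and i.i.d. Gaussian frame
noise; 20-s frames.  No drift, no blinking, no partial quenching steps.

**Titration generator.** Forward ODE simulation at the assay's composition
(default 2 nM complex, 2 or 0 nM activating RNA, 12.5–100 nM reporter DNA,
300 min from ~10 s after mixing) plus homoscedastic Gaussian noise in
cleaved-DNA units — the simplest model consistent with fluorometer traces;
real traces have mild heteroscedasticity and drift that this does not
emulate.  Default recovery noise is 1 % of the full-scale signal.

## 5. Scenario presets

Each control experiment maps to one preset (see the table in
`csmkinetics/workflow.py`): the activating scenario carries the measured
release times (84 / 119 min ends, 84 min cross decay, 8.7 % plateau,
1 / 25 min internal fragments) and the published rate constants
(k_bind⁺ = 6.6·10³ /(M·s), k_bind⁻ = 1.1·10⁻² /s, k_cN = 1.9·10⁻⁴ /s,
k_cA = 8.5·10⁻³ /s, k_RNA⁻ = 1.9·10⁻⁴ /s).  The RNase-dead preset produces
no internal fragments and no deactivation decay; the no-metal preset no
release at all; the non-activating preset the same release kinetics but
background-level DNase activity; the competitor preset the accelerated
21-min loss.  The mismatch presets (one end never releasing) are package
choices for completeness, not measured values.  The pipelines are seeded
end-to-end and bit-reproducible for fixed configuration.

## 6. Known limitations

* The FCS simulator validates the analysis, not the instrument: PIE,
  spectral crosstalk and detector artifacts are out of scope.
* The sliding-window → release-fit chain has irreducible per-window noise at
  desk scale; single-experiment release times are good to ~25 %, medians
  over repeats to ~5–10 %.
* In the kinetic model, K_d exceeds the probed DNA range, so k_bind⁺ and
  k_bind⁻ are individually soft (only their ratio and the binding-limited
  flux are strongly constrained); k_cleave_A is identifiable only through the
  small bound-complex signal and needs noise ≲ a few % of full scale.
* Re-activation/competitor displacement experiments and cyclic-oligoadenylate
  chemistry are represented only as presets, not mechanistically.
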