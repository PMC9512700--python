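# Methods

## Two-state exchange model

All forward models assume a spin exchanging between a ground state (GS) and
an excited state (ES):

    GS ⇌ ES,  k_GS→ES = (1−p_GS)·k_ex,  k_ES→GS = p_GS·k_ex

with 0 < p_GS < 1 and k_ex > 0, satisfying detailed balance by
construction. Chemical-shift differences are stored as magnitudes in p.p.m.
(dispersion data cannot determine the sign) and converted to rad/s as
Δω = 2π · Δω_ppm · (γ_X/γ_H) · B₀(MHz), with γ ratios 0.25144 (¹³C) and
0.94094 (¹⁹F); the static field is always quoted as the ¹H Larmor frequency.
Radio-frequency pulses are ideal and instantaneous; off-resonance pulse
effects, three-state models and off-resonance R₁ρ are out of scope.

## CPMG propagators

Convention: ν_CPMG = 1/(2τ) with τ the spacing between refocusing-pulse
centers, so N = 2·T_CPMG·ν pulses. Printed acquisition frequencies are
rounded to 0.1 Hz; the propagators therefore derive the realized spacing
from the integer pulse count, τ = T_CPMG/N with N = round(2Tν), and reject
grids where N deviates from an integer by more than 0.02.

**SQ.** Magnetization evolves under the 2×2 complex matrix L (GS at zero
frequency, ES at iΔω, both relaxing at a shared intrinsic R₂⁰ per
probe × field × experiment type); each π pulse is complex conjugation.
One echo is B = U·conj(U·...) with U = exp(L τ/2); two echoes form the
linear cycle operator W = U·Ū·Ū·U. Two definitions of R₂,eff are provided:

- `method="eigen"` (default, used in fitting): −ln|λ_max(W)|/(2τ), the decay
  constant of the dominant cycle mode. For equal intrinsic rates this is
  *identical* to the Carver–Richards closed form (verified to 10⁻⁶ s⁻¹
  across k_ex/Δω from 0.1 to 100 against an independent transcription of the
  closed form).
- `method="propagation"`: propagate the equilibrium vector through the full
  train and return −ln|ΣM(T)|/T. This finite-time definition differs from
  the eigenvalue one by an amplitude factor that can reach ~1 s⁻¹ in slow
  exchange; it is cross-checked against brute-force micro-step propagation.

The eigen definition was chosen as the default because a single averaged
peak is integrated experimentally and because it makes the numerical model
and the analytic limit exactly consistent, which in turn makes simulate→fit
round trips exact.

**MQ.** Zero-quantum and double-quantum amplitude pairs evolve with ES
frequencies Δω_H − Δω_C and Δω_H + Δω_C. A carbon π pulse interconverts
ZQ↔DQ, making one carbon block a linear 4×4 operator; a single proton π
pulse at T_CPMG/2 swaps coherence order with conjugation. The exact timing
of the proton pulse relative to the carbon blocks is not uniquely fixed by
the experiment class; the midpoint-swap scheme is the conventional choice
and is flagged in the code. Detection averages the magnitudes of the two
coherence-order signals, which makes the MQ model reduce *exactly* to SQ
when Δω_H = 0 (asserted to 10⁻⁸ s⁻¹) and to a flat profile when both shift
differences vanish. MQ profiles need not be monotone in ν_CPMG; SQ profiles
are, and converge to R₂⁰ at fast pulsing.

## On-resonance R₁ρ

The rotating-frame evolution matrix is 6×6 ({x,y,z} per state) with the
spin-lock field ω₁ = 2πν_SL along x, residual offsets relative to the
carrier, exchange coupling, and R₁/R₂⁰ relaxation. The carrier is placed at
the observed averaged-peak position, computed as the imaginary part of the
dominant complex eigenvalue of the free-precession exchange matrix
(`carrier_policy="peak"`; "ground" and "population_average" are available).

Two extraction paths are provided and required to agree: the eigenvalue fast
path (decay constant of the spin-locked mode, selected by maximal overlap
with the tilted equilibrium magnetization — at exchange-broadened
conditions this is *not* always the slowest-decaying eigenvalue, since the
precessing transverse modes can decay at ~(R₁+R₂)/2) and a
propagation+mono-exponential-refit path over the T_SL grid. With a hard-tilt
start the refit deviates from the eigenvalue by up to ~4% at the weakest
locks because the start vector mixes in fast-decaying modes; the default
`alignment="adiabatic"` therefore starts the propagation in the spin-locked
mode, the idealization of ramping the magnetization along the effective
field, and the two paths then agree to machine precision. The hard-tilt
start remains available (`alignment="tilt"`) for studying that bias.

R₁ defaults to a fixed 2 s⁻¹: an on-resonance lock at ~90° tilt carries
essentially no longitudinal information, so freeing R₁ only destabilizes
the fit (override with `FitSchema(fit_R1=True)`).

## Global fitting

The objective is Σ((data − model)/σ)² over all profiles, minimized with a
trust-region-reflective least-squares solver. Parameter sharing is
declarative: p_GS and k_ex global, per-temperature, or (p_GS) per-nucleus;
|Δω| per probe, shared across fields and temperatures; R₂⁰ per
probe × field × experiment type and (by default) per temperature, because
sharing intrinsic rates across temperatures is not clearly warranted.
Bounds: p_GS ∈ (0.5, 1) to resolve the p ↔ 1−p symmetry of dispersion data
(overridable), k_ex ∈ [10, 10⁵] s⁻¹, |Δω| ∈ [0, 10] p.p.m.,
R₂⁰ ∈ [0.1, 500] s⁻¹ — plausible ranges for a 100-kDa protein. Two-state
dispersion fits are multimodal in (p, Δω), so the default start policy is a
multi-start grid over k_ex ∈ {10², 10³, 10⁴} s⁻¹ × p_GS ∈ {0.6, 0.9};
explicit start dictionaries override it. Boundary-touching parameters and
profiles whose fitted dispersion amplitude is below the noise level
(unidentifiable exchange) are flagged in the result.

Replicates are averaged to one rate per frequency with σ = sample standard
deviation across replicates, then floored per detected nucleus (0.2 s⁻¹ for
¹³C, 2 s⁻¹ for ¹⁹F, CPMG and R₁ρ alike) to avoid excessive weighting of
points with accidentally small scatter. Zero σ (noiseless synthetic data)
is treated as unit weight. χ²_ν = χ²/(N_points − N_free).

**Monte-Carlo errors** (default 500 cycles, explicit seed recorded in every
result): each cycle perturbs every rate by a centered Gaussian of its σ
(rate-level perturbation, matching how the errors are defined) and refits
from the best-fit solution; the per-parameter spread over cycles is the
reported error. More than 10% failed cycles is an error. Because the σ
floors and the replicate-s.d. convention (not s.e.m.) overstate the
uncertainty of the averaged rates, these errors are deliberately
conservative: empirical coverage of ±1σ intervals on synthetic replicates
sits at or above the nominal 68% rather than below it, and the test suite
asserts coverage ≥ 55% with no upper cap.

**χ²_ν surfaces**: the probed parameter (k_ex, p_GS or |Δω|) is fixed on a
grid while all other parameters are re-optimized from the best fit. Values
are normalized by the *unconstrained* fit's degrees of freedom so the
surface equals the unconstrained χ²_ν at the optimum (asserted to 10⁻⁶).
Failed grid points are flagged, the surface is still returned.

## Synthetic data: what it emulates and what it does not

Generators add Gaussian noise at the intensity level (where noise actually
arises) and re-extract rates exactly as the analysis would: CPMG rates from
per-replicate intensity ratios against the ν = 0 reference plane, R₁ρ from
per-replicate exponential fits over T_SL. Noise is an absolute σ of 0.3% of
the reference intensity, which yields rate scatter of ~0.2–3 s⁻¹ depending
on how far the signal has decayed — at or below the σ floors, so the floors
are active, which is their stated purpose.

Named fixtures encode the emulated study designs:

- `c13_313K` — five methyl probes, SQ+MQ CPMG at 500/600/800 MHz (six
  dataset blocks), T_CPMG = 24 ms, 13 frequencies 83.3–2000 Hz, duplicate
  acquisition; truth p_ES = 0.181, k_ex = 710 s⁻¹. Per-probe Δω_C
  (1–3 p.p.m.), Δω_H (0–0.2 p.p.m.) and intrinsic rates (15–40 s⁻¹) are not
  published values; they are seeded stand-ins recorded in the fixture JSON.
- `f19_multiT` — one ¹⁹F probe, CPMG (13/18-point grids at 500/600 MHz,
  T_CPMG = 16 ms) plus on-resonance R₁ρ (18 spin-lock fields per field,
  T_SL = 0–32 ms), five temperatures 303–313 K, triplicate; truth
  |Δω| = 0.15 p.p.m. at all temperatures, p_GS = 0.50, and k_ex linear in
  temperature between the two reported end points (445 → 913 s⁻¹) since
  only those are recoverable targets. The intrinsic ¹⁹F rate (115.3 s⁻¹) is
  solved so the exchange-broadened apo linewidth is 55 Hz at 313 K/500 MHz;
  R₁ = 2 s⁻¹.
- `f19_313K` — the single-temperature slice, used in fast tests and the
  worked example.

Fixtures regenerate bit-identically from (name, seed). What the generators
do **not** emulate: spectral processing (peak picking, baseline), pulse
imperfections and B₁ inhomogeneity, temperature-dependent intrinsic rates
or shift differences, and correlated noise between frequencies. Passing
recovery tests therefore validate the fitting machinery under the assumed
noise model, not robustness to those experimental artifacts.

Titration curves follow the exact single-site quadratic (saturating at the
labelled-RNA concentration); turnover series accumulate product linearly at
rate·E₀ within the initial-rate window. Default study conditions: protein
grids 0–200 nM or 0–1000 nM with 1–5 nM labelled RNA; 50 µM enzyme with
500 µM substrate, 2% signal noise, 10 time points within 30% conversion.

## Numerical choices

- Batched closed-form 2×2 complex matrix exponentials and integer matrix
  powers (Sylvester form) keep a full multi-temperature global fit in tens
  of seconds; degenerate eigenvalues fall back to first-order series.
- Exponential decay fits (R₁ρ extraction, turnover windows) start from a
  log-linear estimate on the positive intensities and refine with
  Levenberg-Marquardt on the linear scale, so near-zero and slightly
  negative noisy intensities are handled.
- Turnover fits use the product fraction f = product/(product+substrate)
  (invariant to arbitrary units and spectrometer drift) over the f ≤ 30%
  window; rate = slope·S₀/E₀.
- Anisotropy K_D errors come from per-replicate refits when replicates
  exist (s.d. across replicates), otherwise from the fit covariance.
- "Room temperature" for ΔΔG is 298 K (overridable); R = 8.314 J/(mol·K).
- Reported derived rates are conventionally rounded to integers
  (`DerivedRates.rounded()`); raw values are always retained.

## Known limitations

- The p_GS ∈ (0.5, 1) bound assumes the minor state is the excited state;
  data generated at p_GS = 0.5 sit exactly on the symmetry point and the
  fitted population may pin at the bound (flagged in warnings).
- MQ propagation requires an even pulse count so the proton pulse falls
  between carbon blocks (all emulated grids satisfy this).
- R₁ρ rate tables re-read from disk lack the original T_SL grid; the eigen
  fast path (which does not need it) is used for fitting in that case.
- The Monte-Carlo errors inherit the conservatism of the σ floor and
  replicate-s.d. conventions, as discussed above.

## Problem sizes used in the test suite

Recovery tests run the full emulated designs (390-point ¹³C joint fit,
335-point five-temperature ¹⁹F fit). Stochastic-replicate properties
(median recovery, Monte-Carlo coverage/stability) run on a single-field,
single-temperature slice with 20–25 replicates and 50–150 Monte-Carlo
cycles; the acceptance script uses 100 replicates for the turnover median.
These sizes keep the whole suite in a few minutes while leaving every
statistical assertion comfortably powered.
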