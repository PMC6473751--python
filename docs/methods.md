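# Methods

This note records the model, its assumptions, the numerical choices and
the limits of what the test suite demonstrates. Units throughout:
lengths in m (interfaces accept mm/µm/nm/Å), time in s, substrate and
K_M in mM, enzyme in µM, k_cat in s⁻¹, diffusivities in m²/s, moduli in
kPa.

## Network structure

The structural chain maps a swelling measurement to transport properties:

1. q = m_swollen/m_dry (mass swelling ratio);
2. Q = 1 + (ρ_polymer/ρ_water)(q − 1), the volume-additivity conversion of
   absorbed water mass to volume; ν₂,ₛ = 1/Q by construction;
3. M̄c = 2(MW_A/f_A + MW_B/f_B) for an ideal stoichiometric step-growth
   network — every elastic strand is one macromer arm plus half a
   crosslinker, counted from both ends. Peptide crosslinker masses are
   computed from average residue masses plus one water;
4. ξ = Q^⅓ · ℓ · √(3·Cₙ·M̄c/M_r): the swollen mesh size from the
   unperturbed end-to-end distance of a strand of M̄c/M_r repeat units,
   3 backbone bonds each, dilated isotropically by Q^⅓. Defaults
   ℓ = 1.47 Å, Cₙ = 4, M_r = 44 g/mol describe PEG;
5. D_gel = D_sol(1 − R_E/ξ)·exp(−Y/(Q − 1)), the Lustig–Peppas
   obstruction × free-volume correction, with Y = 1 for PEG gels and
   D_gel = 0 (flagged) once R_E ≥ ξ.

For the PEG8NB/CYGGGYC system (20 kDa, 8 arms; peptide 721.8 g/mol) the
chain gives M̄c = 5721.8 g/mol and ξ = 15.2 nm at Q = 18, 18.0 nm at
Q = 30 — an 8-arm gel stays far more open than the 4.5 nm enzyme radius
at all experimentally relevant moduli.

An important caveat: evaluating step 5 with the free-solution diffusivity
of tyrosinase (5.05×10⁻¹⁰ m²/s) predicts in-gel diffusivities near
3.4×10⁻¹⁰ m²/s, roughly ten times the values measured for these gels
(3.80×10⁻¹¹ soft, 3.58×10⁻¹¹ stiff). The free-volume form is a scaling
estimate, not a calibrated predictor, so the transport and coupled
modules take measured in-gel diffusivities as direct inputs
(`constants.D_GEL_SOFT/STIFF`) and the package never claims to derive
them from structure. The 5.8% soft→stiff contrast — the basis for
treating D as constant during stiffening — is computed from the measured
pair.

## Slab transport

Geometry is a 1 mm slab loaded from both faces by a stirred bath at fixed
C_E0 (semi-infinite reservoirs; no edge diffusion; zero initial interior
concentration). Two solvers:

- **Analytic series** (constant D): the odd-harmonic Fourier solution,
  truncated when a term falls below 10⁻¹²·C_E0 (cap 10 000 terms); at
  t = 0 the initial condition is returned directly so Gibbs oscillation
  never appears. Partial sums are clipped to [0, C_E0].
- **Crank–Nicolson** finite differences, conservative form: face
  conductances are harmonic means of nodal D evaluated at the half step,
  so spatially varying diffusivity conserves mass. Unconditionally
  stable, second order; Dirichlet faces, symmetric by construction. The
  default output grid keeps the study's Δx = 1 µm, Δt = 1 s;
  `output_every` (default 60 steps) thins storage only.

On that grid the two solvers agree to < 10⁻⁷·C_E0 at 1–6 h, far inside
the 10⁻³ tolerance the tests assert. The midplane no-flux condition is
monitored by `center_flux` (central difference, zero to round-off for
symmetric fields). `equilibration_time` exposes the saturation fraction
explicitly rather than hard-coding a definition of "equilibrated": the
center of the stiff gel crosses 90% at ~2.0 h and 99% at ~3.8 h.

## Kinetics

Rate laws as in the README; the inhibited law peaks at
C_S = √(K_M·K_i) ≈ 4.1 mM for free L-tyrosine. Shipped constants
(`TABLE_KINETICS`): L-tyrosine 0.93 s⁻¹ / 0.85 mM / K_i 19.85 mM; L-DOPA
8.63 s⁻¹ / 1.02 mM; CYGGGYC peptide 0.60 s⁻¹ / 0.58 mM (no measurable
inhibition). All three satisfy 10 mM ≥ ~10·K_M, which justifies the
high-substrate linearization V_P ≈ k_cat·C_E used for enzyme-titration
analyses.

**Fitting.** Unweighted nonlinear least squares on velocities
(Levenberg–Marquardt via lmfit), starting values k_cat⁰ = max(V)/C_E,
K_M⁰ = C_S at half-max, K_i⁰ = 10·max(C_S). `auto` fits both laws and
keeps the lower small-sample-corrected AIC; the inhibited law needs ≥ 5
distinct substrate levels (standard: ≥ 4). R², per-parameter standard
errors and AICc are reported by `summary()`. Noiseless synthetic data are
recovered to < 10⁻⁴ relative for every constant. Under the assay design
(8 levels ≤ 10 mM, C_E = 0.6 µM, 3 replicates, 5% multiplicative noise)
k_cat and K_M are recovered within 10% in most draws, but K_i is
information-limited — the design's top substrate level is only half of
K_i, and the fit's own standard error for K_i is ~30% — so recovery
claims for K_i are made at the simulation-study level (median over seeded
replicates, which lands within ~1% of truth and is unbiased to within
Monte-Carlo error), never per draw.

**Initial rates from time courses.** OLS slope over an explicit window,
or automatically over the longest initial prefix (≥ 4 points) whose
linear fit keeps R² ≥ 0.9999. The strict default is deliberate: R² is
nearly blind to the downward slope bias of a saturating signal — a linear
fit to 1 − e^(−t/τ) holds R² > 0.99 out to t ≈ 0.8τ where the slope is
already ~30% low, while the 0.9999 threshold stops near 0.07τ with ~3–5%
bias. For noisy signals that cannot reach 0.9999 the threshold is a
parameter (and the fallback — shortest admissible prefix, with a warning
— keeps the estimator defined). Absorbance→concentration calibration is a
required user input; no extinction coefficient is assumed.

**Conversion times.** The integrated law is exact and is verified against
a tight-tolerance ODE integration over conversions 0.01–0.999. "Complete"
conversion is operationalized as 99%: for the peptide at 3 µM enzyme and
10 mM substrate this gives 6984 s = 1.94 h, and any cutoff from 95% to
99.9% stays within ~2 ± 0.35 h, so the headline "about two hours" is
insensitive to the cutoff. Conversion time scales exactly as 1/C_E.

## Coupled diffusion–reaction

Assumptions: the substrate is network-bound (no substrate diffusion); the
enzyme is a true catalyst (not consumed); kinetics are quasi-static in
the local enzyme concentration; transport is one-way coupled (the 5.8%
diffusivity change during stiffening is neglected within a run — a
two-pass re-run with the stiff-gel D brackets the effect); no oxygen
limitation is modelled. Substrate inhibition is excluded from the closed
form (no Lambert-W solution exists for the inhibited law) and the
peptide substrate shows none; `numeric_reference` accepts an optional
K_i for sensitivity studies.

Under these assumptions the local problem separates exactly, giving the
Lambert-W closed form with exposure E(x,t) = ∫₀ᵗ C_E dτ (trapezoidal on
the stored transport levels). A second exposure convention,
E = C_E(x,t)·t, is provided as `exposure_mode="paper"`: it treats the
instantaneous concentration as if it had been present since t = 0, so it
bounds the exact product from above wherever C_E is still rising and
coincides with it once the gel equilibrates. `integrated` is the default;
the test suite quantifies the ordering rather than hiding it.

Numerics: the progress relation is evaluated in log space, with W
computed from ln f by Newton iteration on w + ln w = ln f once e^(ln f)
would overflow, so large C_S0/K_M ratios are safe. The ODE oracle
integrates every node's law (LSODA, rtol 10⁻⁹) against the same
piecewise-linear-in-time enzyme interpolant, making the comparison a
genuine two-route check; agreement is < 10⁻⁴·C_S0 on the default grid.

Default coupled grid: Δx = 10 µm, Δt = 1 s, 8 h horizon, 60 s output
sampling — transport-accuracy tests use the finer 1 µm study grid, while
the coupled runs use this grid, whose discretization error is orders of
magnitude below the tolerances asserted. Under the default protocol the
center reaches half its enzyme saturation at ~0.75 h but half conversion
only at ~1.7 h, and the slab-wide 95% conversion time is 2.7 h
(integrated exposure) — comfortably inside the 6–8 h incubation used in
practice, and the reason product formation, not enzyme arrival, sets the
protocol duration.

## Stiffening power law

G′ = A·ν₂,ₛᵐ is fitted by OLS on logs — the standard choice when the
error is multiplicative, and exactly exponent-invariant to modulus unit
changes. At least 3 distinct volume fractions are required; standard
errors come from the closed-form simple-regression formulas. Exponents in
[0.8, 1.2] are labelled "ideal-like" (rubber-elasticity reference m = 1);
the synthetic generator spans the stiffened-gel ranges (Q 36→12, G′ of
order 0.5–4 kPa) and round-trips exponents to 10⁻¹⁰ noiselessly and
within 0.05 at 3% noise. The source modulus–swelling data behind the
published exponent are not tabulated anywhere machine-readable, so the
package validates the *machinery* by round-trip and makes no claim of
reproducing a particular measured exponent.

## What the synthetic generators do and do not show

The generators draw from the package's own rate laws and transport
solutions with idealized noise (independent, Gaussian, multiplicative for
velocities and moduli, additive for imaged profiles). Passing
recovery tests therefore demonstrates the estimators are correct and
well-conditioned under the stated designs — not that real assays satisfy
those designs: real MBTH time courses have correlated drift, real
profiles have imaging artefacts, and real gels deviate from ideal
step-growth stoichiometry. Fixtures are regenerated at run time from
seeds; nothing is stored.

## Known limitations

- 1-D slab geometry only; no edge diffusion, no finite-bath depletion.
- D_gel is an input, not a prediction (see the Lustig–Peppas caveat).
- No mechanistic monophenol/diphenol cycle and no dissolved-O₂ model;
  the kinetics are lumped Michaelis–Menten.
- No mapping from product concentration to absolute modulus: the coupled
  model predicts *where and when* crosslinks form, and the power-law
  module characterizes measured moduli, but the package does not predict
  G′ from C_P.
- K_i estimates from ≤ 10 mM designs carry ~30% standard errors; designs
  reaching well past √(K_M·K_i) are needed for tight per-experiment K_i.
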