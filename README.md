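# stiffsim

Diffusion–reaction modelling of enzyme-mediated hydrogel stiffening.

Cell-laden PEG–peptide hydrogels can be stiffened on demand by soaking them
in tyrosinase: the enzyme diffuses into the swollen network, oxidizes
network-bound peptidyl tyrosine residues to DOPA, and the resulting DOPA
dimers act as secondary crosslinks that raise the shear modulus. Designing
such a protocol requires knowing *where* and *when* the new crosslinks form
— a competition between enzyme transport and enzyme catalysis. `stiffsim`
implements that full chain as a tested library with a small CLI, for
biomaterials researchers who want quantitative stiffening-protocol design
rather than trial and error.

## The model

**Network structure.** From a swollen/dry mass pair, the mass and
volumetric swelling ratios are q = m_sw/m_dry and
Q = 1 + (ρ_p/ρ_w)(q − 1), with polymer volume fraction ν₂,ₛ = 1/Q. An
ideal step-growth network of an f_A-arm macromer (mass MW_A) and an
f_B-functional crosslinker (MW_B) has strand mass
M̄c = 2(MW_A/f_A + MW_B/f_B), and the mesh size follows the Canal–Peppas
relation ξ = Q^⅓ · ℓ · √(3 Cₙ M̄c / M_r) (ℓ = 1.47 Å, Cₙ = 4, M_r = 44
g/mol for PEG). The in-gel solute diffusivity then follows Lustig–Peppas:
D_gel = D_sol (1 − R_E/ξ) exp(−Y/(Q − 1)).

**Transport.** Enzyme enters a slab of thickness h from both faces held at
constant bath concentration C_E0: ∂C_E/∂t = ∂/∂x(D ∂C_E/∂x), C_E(x,0) = 0.
Solved both by the classical Fourier series (constant D) and by a
conservative Crank–Nicolson scheme (D may vary in x and t); the two agree
to < 10⁻³·C_E0 on the default 1 µm / 1 s grid and serve as mutual checks.

**Kinetics.** Product formation follows V_P = k_cat·C_E·C_S/(K_M + C_S),
with the substrate-inhibited variant (denominator K_M + C_S(1 + C_S/K_i))
for free L-tyrosine. The integrated rate law
k_cat·C_E·t = K_M ln(C_S0/C_S) + (C_S0 − C_S) gives exact conversion
times; fitting is nonlinear least squares with statsmodels-style
model/results objects.

**Coupling.** Because the peptidyl substrate is network-bound and the
enzyme is a catalyst, each position obeys the local integrated law with
enzyme exposure E(x,t) = ∫₀ᵗ C_E dτ, giving the Lambert-W closed form
C_S(x,t) = K_M·W[(C_S0/K_M)·exp((C_S0 − k_cat·E)/K_M)], C_P = C_S0 − C_S.
A per-node ODE integration is the independent oracle (agreement < 10⁻⁴).

**Structure–property scaling.** Stiffened-gel moduli vs. swelling are
summarized by fitting G′ = A·ν₂,ₛᵐ in log–log space; m = 1 is the ideal
rubber-elasticity reference, larger exponents flag network non-ideality.

## Worked example

```python
import stiffsim as ss
from stiffsim import synth

# structural chain at the stiff-gel swelling ratio (Q = 18)
mac = ss.MacromerSpec()                              # PEG8NB, 20 kDa, 8 arms
xl = ss.CrosslinkerSpec.from_sequence("CYGGGYC")
mc = ss.mw_between_crosslinks(mac, xl)
xi = ss.mesh_size(18.0, mc=mc)
# -> M_c = 5721.8 g/mol, xi = 15.2 nm

# how long to convert 10 mM peptidyl tyrosine at 3 uM tyrosinase?
t = ss.integrated_mm_time(ss.TABLE_KINETICS["cygggyc"], 3.0, 10.0, 0.99)
# -> t = 6984 s = 1.94 h  (~2 h)

# fit kinetic constants to noisy synthetic assay data
df = synth.generate_velocity_data(ss.TABLE_KINETICS["cygggyc"],
                                  enzyme_uM=0.6, replicates=3,
                                  noise_sd=0.05, seed=1)
print(ss.fit_kinetics(df, model="auto").summary())
```

```
Michaelis-Menten fit
==============================================
model:          standard
n observations: 24
R-squared:      0.9880
AICc:           -218.56
----------------------------------------------
parameter       estimate     std err
k_cat [1/s]       0.6072    0.006304
K_M [mM]          0.6003     0.02868
==============================================
```

The automatic model selection (corrected AIC) keeps the standard law —
the peptide substrate shows no substrate inhibition — and recovers the
generating constants (0.60 s⁻¹, 0.58 mM) within their standard errors.

Coupled transport–reaction for the default stiffening protocol (1 mm stiff
gel, D = 3.58×10⁻¹¹ m²/s, 3 µM enzyme bath, 10 mM substrate):

```python
sol = ss.closed_form_fields(ss.DRProblem(), "integrated")
ss.stiffening_summary(sol, threshold=0.95).attrs["completion_h"]
# -> 2.68  (hours until even the slab center is 95% converted)
```

The enzyme front reaches half-saturation at the center in ~45 min, but
product formation there lags it by about an hour — transport alone
underestimates the stiffening time, which is why the coupled model exists.

The same operations are scriptable: `stiffsim mesh --Q 18`,
`stiffsim diffuse`, `stiffsim kinetics-fit`, `stiffsim simulate --config
run.yaml`, `stiffsim stiffen-fit`, `stiffsim synth` (see `--help`).

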