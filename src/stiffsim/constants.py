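"""Default physical constants for PEG8NB / CYGGGYC hydrogels and tyrosinase.

All values are overridable through the run configuration; these defaults
describe an 8-arm PEG-norbornene (20 kDa) network crosslinked by the
bis-cysteine, bis-tyrosine peptide CYGGGYC and infiltrated by mushroom
tyrosinase at 37 degC.
"""

# -- network structure -------------------------------------------------------
BOND_LENGTH_ANGSTROM = 1.47     # C-C / C-O backbone bond in an EG subunit
BONDS_PER_REPEAT = 3            # -CH2-CH2-O-
FLORY_RATIO_PEG = 4.0           # characteristic ratio C_n for PEG
PEG_REPEAT_UNIT_MW = 44.0       # g/mol, ethylene glycol repeat unit
PEG_DENSITY = 1.087             # g/cm^3 at 37 degC
WATER_DENSITY = 0.994           # g/cm^3 at 37 degC
PEG8NB_MW = 20_000.0            # g/mol, number-average
PEG8NB_ARMS = 8
PEPTIDE_FUNCTIONALITY = 2       # bis-cysteine crosslinker

# -- enzyme transport --------------------------------------------------------
TYROSINASE_D_SOLUTION = 5.05e-10   # m^2/s, free-solution diffusivity
TYROSINASE_RADIUS_NM = 4.5         # hydrodynamic radius
FREE_VOLUME_Y = 1.0                # free-volume parameter for PEG gels

# In-gel diffusivities measured for soft (G' ~0.5 kPa) and stiff (G' ~5 kPa)
# gels; used directly as transport inputs (the Lustig-Peppas chain from the
# printed D_solution is not self-consistent with them, see docs/methods.md).
D_GEL_SOFT = 3.80e-11              # m^2/s
D_GEL_STIFF = 3.58e-11             # m^2/s

# -- slab geometry / numerics ------------------------------------------------
SLAB_THICKNESS_M = 1.0e-3          # 1 mm hydrogel strip
DEFAULT_DX_M = 1.0e-6              # 1 um spatial step
DEFAULT_DT_S = 1.0                 # 1 s temporal step

# -- default in-gel reaction conditions --------------------------------------
DEFAULT_ENZYME_UM = 3.0            # uM tyrosinase in the bathing solution
DEFAULT_SUBSTRATE_MM = 10.0        # mM peptidyl tyrosine in the network
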