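"""Physical constants and unit conversions shared across the model.

The model currency is nitrogen.  Tracer concentrations are mg N m-3
(oxygen: mg O2 m-3); functional-group biomass is metric tons of wet
weight per box.  A single declared conversion links the two currencies.
"""

#: Molar mass of nitrogen, mg per mmol (used for mmol-NH4 deposition rates).
MG_N_PER_MMOL_N = 14.0

#: Molar mass of molecular oxygen, mg per mmol.
MG_O2_PER_MMOL_O2 = 32.0

#: Nitrogen content of wet biomass: mg N per metric ton wet weight.
#: Wet weight is ~25% dry matter of which ~8% is nitrogen, i.e. ~2% N by
#: wet mass -> 2e7 mg N per ton.  Declared once; every biomass <-> tracer
#: exchange in the model goes through this constant.
MG_N_PER_TON_WW = 2.0e7

#: Oxygen produced (consumed) per unit nitrogen fixed (remineralized),
#: mg O2 per mg N.  From Redfield O2:N = 138:16 by moles:
#: (138 * 32) / (16 * 14) = 19.71.
O2_PER_N = 138.0 * 32.0 / (16.0 * 14.0)

#: Si:N uptake ratio for diatoms, mg Si per mg N (Redfield-Brzezinski
#: Si:N ~ 1:1 molar; 28/14 by mass).
SI_PER_N_DIATOM = 2.0

#: mg O2 per mL O2 at STP (1 mL/L = 1.429 mg/L = 1429 mg m-3).  Used to
#: translate the cod reproductive-volume threshold of 2 mL/L.
MG_O2_PER_ML = 1.429

SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 365
TONS_PER_MG = 1e-9
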