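# baltisim

A desk-scale, end-to-end simulator of the Baltic Sea ecosystem for
exploring how nutrient-load reductions and fishing-pressure changes
propagate from biogeochemistry through the food web to fishery
economics. It is aimed at ecosystem modellers and management-strategy
analysts who want a small, fully synthetic, fully testable analogue of
a whole-of-ecosystem model: every input (physics forcing, river loads,
initial fields) is generated from a seed, every nitrogen flux is
ledgered, and the scenario experiments run in about a minute each.

## The model in brief

The domain is a set of polygon boxes with vertical layers and one
sediment layer; boundary boxes carry prescribed conditions. Nitrogen is
the currency. Primary producers grow by
`μ_max · min(N/(K_N+N), I/(K_I+I)) · space`, with NH4 drawn before NO3;
detritus remineralizes at labile/refractory rates, settles, and is
buried or denitrified under low bottom oxygen. Consumers feed by a
modified Holling type II with shared saturation,

    r_j = C a_j D_j / (1 + (C/g) Σ_k a_k D_k),

where `C` is clearance, `g` the maximum intake rate, `a_j` availability
and `D_j` the effective prey density after habitat refuge, gape window
and vertical overlap. Vertebrates are age-structured (numbers × weights
per cohort) with uniform fishing mortality by stage, forced quarterly
distribution maps, an anoxia-refuge rule, and annual Beverton–Holt
recruitment `R = φ_T φ_S φ_O2 · αS/(β+S)` on ogive-weighted spawning
biomass. Scenarios run 60 years with a 35-year spin-up and change
forcing instantaneously; results are compared as percent changes of
5-year terminal averages. A multi-fleet bio-economic layer (normalised
Cobb–Douglas production, TAC choke rule, exact accounting, discounted
NPV over 2012–2037) evaluates the scenario biomass indices.

See `docs/methods.md` for the full model description, parameter
rationale, and limitations.

## Worked example

Run the pan-Baltic 33% load-reduction experiment against the status quo
on the shipped 8-box test domain and evaluate it economically:

```bash
baltisim compare --geometry mini8 --scenario s5_pan_baltic --seed 1 --out comparison.csv
baltisim econ --comparison comparison.csv --out econ.csv
```

The comparison (excerpt of `comparison.csv`) shows the bottom-up
response: producers and the detritus-fed benthos fall, bottom oxygen
improves, cod benefits through its juveniles' benthic food and better
spawning oxygen, sprat loses both food and its low-oxygen predator
refuge:

```
group      pct_change
PL              -5.5     (diatoms)
ZM             -24.7     (mesozooplankton)
NE             -37.0     (Nephrops-analog)
FSR            -19.9     (sprat)
FCD            +11.5     (cod)
SEA             -1.9     (seals)
NEP_KAWB       -34.8     (stock index, Kattegat + W. Baltic)
```

and the economic step prints the discounted outcome for the four-fleet
configuration:

```
total NPV: 68.7 MEUR; wrote econ.csv
```

(the status-quo NPV is 92.3 MEUR, so the strongest load reduction costs
the synthetic fishery about a quarter of its net present value —
direction, not magnitude, is the meaningful output of this
configuration).

Other entry points: `baltisim synth` writes the generated forcing,
loads and initial conditions as NetCDF/CSV; `baltisim run` writes
annual biomass trajectories; `baltisim report` runs the
calibration-quality checks (equilibrium drift, biomass band, emergent
diets, demography, persistence) on a status-quo run and exits non-zero
if a mandatory check fails.

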