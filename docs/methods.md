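# Methods

`baltisim` is a desk-scale, end-to-end simulator of the Baltic Sea
ecosystem: a box-model nitrogen cycle coupled to an age-structured food
web, driven by synthetic seasonal physics, with a scenario engine for
nutrient-load and fishing-pressure experiments and a downstream
multi-fleet bio-economic model. This note documents the model
equations, the parameter choices that matter, what the synthetic data
emulate, the numerical scheme, and the known limitations.

## Spatial domain

The horizontal domain is a set of polygon boxes joined by faces;
boundary boxes carry externally prescribed tracer concentrations and
receive no internal updates. The vertical is a fixed stack of water
layers (the shipped exemplar uses the eight-layer scheme 0–5, 5–10,
10–30, 30–40, 40–50, 50–100, 100–200, >200 m) over one 0.5 m sediment
layer. The deepest realized layer of each box is truncated at the box
depth; a box deeper than the last interface keeps one open-ended
bottom layer. Two geometries ship with the package: `baltic29`
(29 boxes — 26 dynamic, 3 boundary — and 100 faces, reproducing the
counts and connectivity of the full Baltic domain with schematic
shapes, since true polygon coordinates are not public) and `mini8`
(8 boxes, 1 boundary, 3 layers), the reduced domain used for all
shipped experiments and tests. In `mini8` an extra face closes a deep
circulation loop back to the boundary box; with a single boundary box a
pure chain would leave the deep layer without through-flow after
divergence projection.

## Synthetic forcing

All external inputs are generated, not measured, and are pure functions
of (geometry, parameters, seed):

* **Physics** — one calendar year at 12 h cadence, repeated every
  projection year (so annual periodicity is exact). Temperature is an
  annual sinusoid anchored at the surface layer: coastal boxes span
  `coastal_winter_min` (default −0.1 °C) to about 17 °C, offshore boxes
  have a smaller amplitude; both decay with depth toward a 4 °C deep
  value. Salinity decreases linearly along the configured
  Kattegat→Bothnian axis (22 → 4 psu) with a +4.5 psu increment below
  the 25 m halocline. Face exchange volumes are a seeded seasonal
  template (per-face sinusoid plus noise, damped below the halocline)
  projected onto the divergence-free subspace, so every dynamic box has
  exactly zero net volume flux at every step — a rigid-lid constraint
  that makes tracer conservation exactly testable. Boundary boxes carry
  a fixed seasonal tracer climatology (winter-high nutrients,
  oxygenated surface inflow, oxygen-poor deep water).
* **River loads** — annual totals per coastal box (default 100 kt N/yr
  over the domain, area-weighted with seeded noise), applied daily at
  even rates after basin-specific retention (0.30–0.45). The DIN share
  (default 0.7) enters as nitrate; the bioavailable DON share (default
  0.5 of the remainder) as DON; the rest as refractory detritus, so the
  applied total equals `annual × (1 − retention)` exactly. A spill
  fraction (default 0.3) of each coastal load is redirected to the
  adjacent offshore box.
* **Atmospheric deposition** — spatially uniform, time-invariant
  0.15 mmol NH4 m⁻² day⁻¹ into the surface layer.
* **Initial conditions** — winter nutrient fields (70 mg N m⁻³ surface
  nitrate rising with depth), deliberately low water-column detritus
  (validated to stay below half the plankton standing stock), a
  sediment detritus bank, and group biomass fields placed by habitat
  (bedrock communities on the shoreline fringe, deposit feeders on
  soft bottoms, plankton by volume with a coastal/offshore
  complementarity bias). Age-structured groups start on their
  survivorship curve with reference weights-at-age and seeded quarterly
  distribution maps (juveniles coastal-biased, demersal spawners
  aggregated in deep basins in the spawning quarter).

## Biogeochemistry

Nitrogen is the model currency (tracers in mg N m⁻³; biomass in tons
wet weight with a fixed 2·10⁷ mg N per ton conversion). Primary
production is Liebig-minimum limited,
`growth = μ_max · min(N_lim, I_lim) · space_lim · B`, with
Michaelis–Menten nutrient (`N/(K_N+N)` over NH4+NO3, NH4 drawn first)
and light (`I/(K_I+I)`) terms; the space term applies to the
space-capacity-limited macroalgae only. Light decays exponentially with
depth under background plus biological attenuation from the clear-sky
daily-mean insolation at 56° N; shoreline-fringe producers see the
light at 1.5 m. All producers draw on the same start-of-day nutrient
fields, with joint proportional capping when combined demand exceeds
the available mass — sequential drawdown would starve whichever group
happened to be processed last.

Labile and refractory detritus remineralize to NH4 at first-order rates
(0.04 and 0.003 day⁻¹), consuming oxygen at the Redfield O2:N ratio;
sediment detritus additionally loses a burial fraction
(0.0015 day⁻¹) out of the system. Denitrification removes sediment
nitrate (0.05 day⁻¹) only where bottom-water O2 is below
3000 mg m⁻³. Oxygen gains from photosynthesis and a 3-day linear
air–sea relaxation toward a T,S-dependent saturation in the surface
layer, and is consumed by remineralization and a sediment oxygen demand
proportional to the sediment detritus pool, floored at zero. Silica is
a passive diatom-coupled tracer. Every external nitrogen term —
rivers, deposition, boundary exchange, denitrification, burial, catch,
anoxia removals — is logged to a budget ledger; with all of them
disabled, total nitrogen over water + sediment + biota is conserved to
floating-point round-off.

## Trophic dynamics

Consumers feed by a modified Holling type II with shared saturation:
the intake rate of prey *j* per unit predator biomass is
`C·a_j·D_j / (1 + (C/g)·Σ_k a_k·D_k)`, clearance-limited at low prey
density and capped at the maximum intake `g`. Effective prey `D` is the
prey's box biomass divided by the predator's feeding volume (water
column for pelagic, bottom layer for demersal, a 1 m near-bottom slab
for benthic groups), discounted by availability, habitat refuge, the
predator's gape window (prey:predator weight ratio), and vertical
overlap — the share of the prey field inside the layers the predator
searches. All demands are computed from the same start-of-day state and
capped proportionally at the available prey, so trophic mass closure is
exact: prey debits equal predator growth plus egested detritus (30%
refractory) plus excreted NH4.

Vertebrates (sprat, herring, cod, seals; 10 cohorts each) carry
numbers and individual structural+reserve weights, a hard
juvenile→adult switch, spawning ogives, and forced quarterly
distribution maps; fishing is a uniform continuous mortality split by
stage. Growth is apportioned to cohorts by intake capacity and split
50/50 between reserve and structural weight; intake is modulated by the
reserve:structural condition (clamped to [0.5, 1.5]) and by a satiety
factor that tapers feeding as cohort weights exceed their reference
weights-at-age and stops it at 1.4× — weights cannot shrink (metabolic
costs are implicit in the assimilation efficiency), so satiety is what
keeps weight-at-age near its reference. Recruitment is an annual
Beverton–Holt event `R = φ_T·φ_S·φ_O2 · αS/(β+S)` on ogive-weighted
spawning biomass, with piecewise-linear environmental ramps evaluated
on spawning-habitat-weighted conditions (bottom fields for demersal
spawners, pelagic fields otherwise); temperature and salinity ramps are
switched off for marine mammals, and the cod oxygen ramp is anchored at
the reproductive-volume threshold of 2 mL O2 L⁻¹ (2858 mg m⁻³).
Recruit biomass is debited from the juvenile stage's prey fields
(capped at 30%), which keeps recruitment nitrogen-conserving. Boxes
whose relevant oxygen field falls below a group's refuge threshold are
excluded from its distribution and the displaced share is reallocated
to admissible boxes; if nothing admissible remains the stage is removed
to the loss ledger. Ageing shifts cohorts annually into a terminal
plus-group.

## The shipped exemplar ecosystem

Thirteen groups span the food web: small phytoplankton and diatoms
(complementary coastal/offshore placement), shoreline macroalgae,
mesozooplankton, mysids, hard-substrate filter feeders, deposit feeders
on refractory sediment detritus, polychaetes and a Nephrops-analog on
labile sediment detritus, and the four vertebrates. Defaults were
calibrated in the way such models are: clearances derived from
steady-state targets (`e·C·D* ≈ mortality` at target prey densities),
Beverton–Holt parameters from replacement-level recruitment on the
survivorship equilibrium (baseline adult F: cod 0.32, sprat 0.07,
herring 0.16), and initial biomasses set at the model's own
quasi-equilibrium so terminal/initial biomass factors sit near 1.
Three structural choices were needed for coexistence at this
aggregation level, each the standard theoretical resolution: mysids are
the water-column detritivore (donor-controlled and therefore stable;
a mysid–zooplankton predation link proved overshoot-prone), the
Nephrops-analog shares the labile-detritus strategy of the polychaetes
with identical rate parameters (two consumers cannot coexist on one
resource otherwise), and mobile pools disperse slowly toward their
habitat profile (0.05 day⁻¹ for swimmers, 0.005 for drifting
phytoplankton, 0.0005 for benthic larval dispersal), which reseeds
locally depleted boxes. Emergent adult cod diet is ~75–80% sprat and
~15–20% herring; juvenile cod feed on the benthos; nothing goes extinct
over 60 years.

## Numerics and problem sizes

Ecology advances on a daily explicit-Euler step; transport runs on the
12 h forcing cadence (upwind donor-cell advection with automatic CFL
sub-stepping, interface-damped vertical diffusion, downward-only
settling, linear sediment–water solute exchange, applied in the fixed
order advect → mix → settle → sediment exchange). Uptake and predation
are capped at available mass each step, so concentrations never go
negative. The engine runs a fused, tracer-stacked version of the
transport operators; a test asserts it is numerically identical to the
pure single-operator implementations. All shipped experiments use
`mini8` with 60-year projections, a 35-year spin-up, instantaneous
forcing change, and 5-year terminal averages; a 60-year run takes
about a minute on one core. The full scenario catalog also validates
on `baltic29`.

## Scenario engine and economics

Ten scenarios ship: status quo, four load-reduction designs (three
Danish polygons; 33% on polygons 1–4; a burden-sharing set over ten
polygons; pan-Baltic 33%) and five fishing changes (halved and doubled
adult F for cod and sprat, derived from the baselines by rule, and the
2005–2012 maximum 1.2/0.6). Scenario and baseline share the forcing
seed so differences are attributable to the intervention. Comparisons
are percent changes of terminal averages, with per-stock area indices
computed two ways (plain annual-mean sums, and quarter-weighted sums
respecting the seasonal maps; they coincide when maps are
quarter-invariant).

The bio-economic layer holds stock biomasses constant, rescales them by
the ecosystem scenario's percent indices, produces catch with
normalised Cobb–Douglas functions (intercepts in tons at reference
effort and biomass, exponents 1), enforces TAC quota shares with a
single-factor choke rule, does exact accounting (profit = revenue −
fuel − variable − crew − fixed − capital, with a fixed area key
decomposition), lets effort follow profit with a bounded proportional
rule (λ = 0.1), and discounts profits at 4% yr⁻¹ over 2012–2037. The
shipped four-segment fleet and five-stock configuration is synthetic at
survey magnitudes; only directions of NPV change are meaningful.

## What the synthetic data do and do not capture

The generators reproduce the statistical structure of the real inputs —
seasonal amplitude contrasts, the salinity axis, halocline-damped deep
exchange, retention-discounted loads applied daily, low winter
detritus — but not real 2005 hydrography, river-by-river loads, or
survey distributions. Passing tests therefore demonstrate the
machinery (conservation, functional forms, scenario plumbing) and the
qualitative response structure (bottom-up nutrient responses, top-down
fishing responses, oxygen improvement in treated boxes), not
quantitative agreement with the real calibrated system, whose
parameter tables are not public.

## Known limitations

* Weight-at-age cannot decline (no explicit starvation), so population
  responses to released fishing pressure are larger than in a
  data-calibrated system; recruitment near the Beverton–Holt asymptote
  amplifies this. Directions of change are the meaningful output.
* The pelagic fish–zooplankton complex retains a weak multi-decadal
  oscillation driven by the annual recruitment delay. Biomass factors
  stay near 1 and nothing drifts secularly, but one or two groups can
  exceed a 2%-per-decade linear drift on a 10-year window depending on
  the phase sampled.
* Bottom oxygen in the deep boxes settles near 4–5 g m⁻³ with seasonal
  dips rather than reaching periodic zeros; reproducing true Baltic
  deep-basin anoxia would require the permanent salinity stratification
  of the real >100 m basins, which the 60 m `mini8` domain compresses.
* Phosphorus, cyanobacteria, and bacterial pools are not modelled
  (bacteria are folded into the remineralization rates); silica has no
  independent dynamics; vertebrate movement is forced, not behavioural.
* One declared stand-in each for processes whose published form is not
  public: the gated first-order denitrification, the linear air–sea
  oxygen relaxation, and the fixed-split reserve/structural growth
  increment.
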