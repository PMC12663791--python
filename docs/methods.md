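# Methods

## Model and assumptions

The package bounds the growth of purely osmotrophic cells by molecular
diffusion of dissolved nutrients to the cell surface. The steady-state
solution for an absorbing sphere gives the maximal uptake
ρ = 4πD·r₀·(C∞ − C₀) with the surface concentration C₀ fixed at zero
(perfectly absorbing cell, the most generous assumption for the cell).
The model deliberately excludes Michaelis–Menten transporter kinetics,
transporter-density ceilings and advective or turbulent flux enhancement:
it is an upper bound, not a prediction of realized growth. Concentrations
are carried in nmol L⁻¹ and divided by 1000 inside the flux formula
(nmol cm⁻³), radii in cm, uptake in nmol s⁻¹; the litre→cm³ conversion is
dimensionally forced even though rarely written out.

**Diffusivities.** Freshwater diffusivities of NH₄⁺, NO₂⁻, NO₃⁻ and the
phosphate species are linear in temperature, D₀ = (m0 + m1·T)·10⁻⁶
cm² s⁻¹, using the Boudreau (1997) ion-mobility coefficients shipped as
an auditable CSV (`osmolimit/data/solutes.csv`) and overridable through
`register_solute`. Salinity and pressure enter only through
Stokes–Einstein scaling with the Kukulka-type dynamic-viscosity
correlation: D(T,S,P) = D₀(T)·μ(T,0,P)/μ(T,S,P). No ionic-strength or
activity corrections are applied. The correlation reproduces pure-water
viscosity at 20 °C to <1%, and the sanity checks in the test suite pin
D(NO₃⁻, 25 °C, S=0) to the published ≈1.9×10⁻⁵ cm² s⁻¹. DIP defaults to
HPO₄²⁻ (dominant at seawater pH ≈ 8.1); H₂PO₄⁻ and PO₄³⁻ are selectable
because the field convention varies. Urea is a constant
1.36×10⁻⁵ cm² s⁻¹, and each mole of urea delivers two moles of N
(`ModelConfig.urea_nitrogen_atoms`, configurable).

**Shape.** The prolate-spheroid factor √(E²−1)/ln(E+√(E²−1)) multiplies
the sphere flux computed from the equivalent-spherical radius; at E = 1
the analytic limit 1 is returned rather than evaluating the 0/0 form.
The finite-cylinder factor is computed from the electrostatic-capacitance
analogy: the capacitance of a solid cylinder (flat end caps, length:
diameter = E) is solved with an axisymmetric boundary-element method
(ring discretization of the generating curve, analytic integration of the
log-singular self term, 600 elements by default). The solver reproduces
the exact sphere and prolate-spheroid capacitances to <0.1%, and the
cylinder factor is expressed in units of the cylinder radius so it is a
drop-in replacement for the prolate factor for a cell of given length and
diameter; at E = 10 the swap raises the growth ceiling by ~15%. It is
used only in sensitivity analyses, never in the default per-cell path,
because imaged cells are treated as spheroids throughout.

**Uptake windows.** Nitrate and nitrite are light-dependent and credited
over the 12-h photoperiod (43 200 s); ammonium, urea and phosphate are
credited over the full day (86 400 s). Both sets are configurable; the
urea/phosphate 24-h default is a choice, not a measurement.

**Quotas and growth.** N_cell = 10^(−1.084+0.837·log₁₀BV)/(14.007·1000)
nmol; "log" is base-10 (the underlying allometry is a base-10
regression — a natural-log reading would shift quotas by orders of
magnitude). P_cell = N_cell/16 exactly. GR_N is daily N uptake divided by
N_cell; GR_P analogously. For any fixed aspect ratio GR scales as
esd^(−1.511), 1.511 = 3·0.837 − 1.

**Critical size.** `critical_esd` inverts GR_N(esd) = target. Spheres use
the closed form esd = (GR(1 μm)/target)^(1/1.511); elongated cells use
Brent root-finding on log(esd) over [0.2, 10⁴] μm to relative tolerance
10⁻⁸, with explicit no-solution (all-zero N) and bracket errors. The two
routes agree to <10⁻⁶ relative in a randomized sweep (test suite).

## Track, regions, per-cell application

Stations are ordered along the track; an observation is projected onto
the nearest inter-station segment using great-circle (haversine,
R = 6371 km) distances and each solute is interpolated linearly, clamped
to the terminal station beyond the track ends. Interpolation is 1-D along
the transect rather than 2-D mapping — appropriate for a line cruise, not
for a survey grid. Regions follow the 10/20 °C SST isotherms with the
boundaries assigned to the front. Each imaged cell takes its seawater
state from the nearest-in-time underway record and its nutrients from the
interpolation at its position; cells whose inputs cannot be resolved are
dropped and counted, never zero-filled. Cell biovolume from 2-D features
uses the prolate-spheroid rule BV = (π/6)·major·minor², with E =
major/minor; this is declared per functional group and overridable (a
cylinder rule may suit *Trichodesmium* filaments better). Trophic
strategies come from a substring lookup on the annotation hierarchy
(Dinophyceae → mixotroph; *Trichodesmium*, *Richelia* → diazotroph;
otherwise osmotroph), with a separate reclassification map for putative
diatom–diazotroph associations (*Hemiaulus*, Chaetocerotaceae,
*Haslea*-like, *Mastogloia*); applying it can only increase the
alternative-strategy share, which the tests assert.

## Endemism null

The observed statistic is the proportion of retained taxa (presence =
count ≥ 1, no rarefaction) exclusive to the focal station set. The null
draws uniform k-subsets from all stations — including the focal set, as a
plain Monte-Carlo null; `exclude_focal` is available as a sensitivity
option — i.i.d. across draws, and reports mean, SD and the empirical
p-value (fraction of draws ≥ observed). Monte-Carlo means match
exhaustive subset enumeration on small tables to within 3 standard
errors, and under exchangeable synthetic tables the observed value falls
in the central 95% of the null at the nominal rate (the discreteness of
small counts makes the band conservative).

## Synthetic generators: what they emulate, what they do not

`simulate_cruise` produces a 43-station, 48-day, 2-hourly transect with a
linear SST gradient (25.3 → 2 °C) and a piecewise-log-linear DIN profile:
a flat oligotrophic plateau at 0.02 μmol L⁻¹ over the first 60% of the
subtropical segment, a steep exponential rise to 4 μmol L⁻¹ approaching
the front, and a subantarctic plateau of 20–30 μmol L⁻¹. The plateau/rise
shape mirrors real transects (near-detection-limit DIN across the gyre,
nutricline outcropping at the front) and puts the subtropical *mean* DIN
near 0.25 μmol L⁻¹ while the *median* stays near the plateau — a strongly
right-skewed distribution, which is exactly why regional means and
per-observation size limits tell different stories. DIN splits into
NH₄/NO₂/NO₃ as 15/5/80% (totals only are anchored; the split is a
configurable choice), and DIP follows regional DIN:DIP targets (3.7
north, 14.5 south, linear across the front) so the north carries the
P-excess that makes P-based limits never bind before N-based ones.
Lognormal multiplicative noise (geometric SD 1.10) perturbs
concentrations per station.

Morphology is lognormal in ESD with a gamma-distributed aspect-ratio
excess capped at E = 50 (positive, right-skewed, matching plankton size
spectra); eight default taxon profiles span diatoms, dinoflagellates,
*Trichodesmium*, *Hemiaulus*, Prymnesiophyceae, *Haslea* and
*Mastogloia* with regional abundance weights that move the community from
dinoflagellate/Prymnesiophyceae-dominated subtropics to diatom-dominated
subantarctic water. An optional exclusion rule removes osmotrophs whose
modeled GR_N falls below a threshold with a given probability, emulating
resource-based competitive exclusion for parameter-recovery tests.

What the generators do **not** emulate: the narrowness of the real
subtropical front (the linear SST gradient makes the synthetic front wide,
so many more "frontal" stations exist than on a real transect), sampling
gaps and instrument dropouts, segmentation error in the axis measurements,
taxon-specific thermal performance, and any covariance between morphology
and local nutrients beyond the exclusion rule. Passing tests therefore
demonstrate correctness of the machinery and qualitative regional
contrasts, not quantitative reproduction of any particular cruise's
per-cell numbers.

## Numerical choices and problem sizes

Bisection/Brent tolerances as above; BEM resolution 600 elements (cached
per aspect ratio); growth bins [0, 0.2), [0.2, 0.6), [0.6, 2), [≥2) d⁻¹;
boundary SSTs of exactly 10/20 °C classify as front; concentrations below
detection limits are kept as reported (a DL/2 policy can be applied
upstream). The default test suite and the acceptance script use desk-scale
problem sizes — hundreds to a few thousand synthetic cells, ≤ 2000 taxa,
10⁴ null draws at most — chosen so the full suite runs in well under a
minute while keeping Monte-Carlo tolerances comfortable.

## Known limitations

* The diffusion ceiling ignores uptake kinetics and motility/advection;
  it brackets, rather than predicts, realized growth.
* The coefficient table covers the five modelled solutes only; silicic
  acid and organics other than urea are out of scope.
* Along-track interpolation is 1-D; off-track observations are projected,
  which is meaningless for genuinely 2-D station layouts.
* Under the model's own size scaling, critical sizes at different target
  rates are rigidly linked (ratio (g₁/g₂)^(1/1.511)); empirical size-limit
  pairs that violate that link cannot all be matched simultaneously.
* The per-mole N credit for urea (2 N) assumes full assimilation of both
  amide groups.
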