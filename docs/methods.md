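# Methods

## The model

`diazocomp` integrates a nitrogen-currency NPZD-type ecosystem in a
reduced-complexity global geometry: five latitude bands (southern high
latitudes, southern subtropics, tropics, northern subtropics, northern high
latitudes) split into Atlantic/Pacific/Indian columns, each with a 100 m
surface layer and a 3600 m deep layer.  Six tracers are carried per box:
NO₃ (mmol N m⁻³), PO₄ (mmol P m⁻³), ordinary phytoplankton P_O,
diazotrophs P_D, zooplankton Z and detritus — the organic pools in nitrogen
units at fixed Redfield stoichiometry (N:P = 16, C:N = 106:16).

**Growth.** Ordinary phytoplankton grow at the Liebig minimum of a
prescribed light-limited rate J_IO and Monod-limited nutrient rates,

    J_O = min( J_IO, J_O^max · NO3/(k_N + NO3), J_O^max · PO4/(k_P + PO4) ),

while diazotrophs are insensitive to nitrate scarcity,

    J_D = min( J_IO, J_D^max · PO4/(k_P^d + PO4) ),    J_D^max = C_d · J_O^max,

and are shut off entirely below a 15 °C surface-temperature cutoff.  The
handicap C_d < 1 encodes the metabolic cost of breaking the N≡N bond.
Iron limitation is a static mask: a factor fe ∈ (0, 1] scales both maximum
rates in the Southern-Ocean-like and subarctic columns.

**Nitrogen sourcing of diazotrophs.** Their nitrogen demand J_D·P_D is met
from ambient nitrate in proportion to its Monod availability
NO3/(k_N + NO3); the remainder is logged as N₂ fixation.  Fixation
therefore shuts itself down as nitrate fills in — the niche-closure
feedback at the heart of the DECAY experiment.  (The alternative — letting
diazotrophs ignore nitrate entirely — would decouple fixation from the
nitrogen deficit and destroy that feedback.)

**Grazing.** Zooplankton graze ordinary phytoplankton, diazotrophs and
detritus with fixed preferences θ_o, θ_d, θ_det, linearly in prey:

    Graze_i = mu_max · Z · θ_i · prey_i ,   mu_max = 0.4 d⁻¹.

A saturating multiple-prey denominator, 1 + Σθ_i·prey_i / k_graze, is
available behind `EcosystemParams.holling_saturation` but off by default:
the linear form is the printed one, the saturating variant is provided for
exploring the classical Holling-II behaviour.  Of each grazed unit, 30%
becomes zooplankton, 40% is excreted to nutrients and 30% egested to
detritus.  Zooplankton are closed by a linear plus quadratic loss.

**Recycling, export, denitrification.** Detritus remineralizes in the
surface (0.07 d⁻¹) and deep (0.01 d⁻¹) layers and sinks at 6 m d⁻¹ out of
the surface layer.  In the three tropical deep boxes — flagged
oxygen-minimum-zone (OMZ) boxes — a fraction f_denit of remineralized
nitrogen is denitrified (removed from the budget, NO₃-limited by a small
half-saturation so the flux vanishes gracefully).  Phosphorus is never
removed: total P is exactly conserved, and total N changes only through
fixation minus denitrification.  Living tracers mixed below the photic
layer decay to detritus.

**Physics.** Each column exchanges tracers between its two layers with a
vertical exchange velocity kv (m d⁻¹), the proxy for upwelling plus
mixing; tropical columns upwell strongly, gyres weakly, high-latitude
columns mix deeply.  Horizontal exchange (relaxation to the layer mean) is
available but zero by default — the columns are deliberately coupled only
through their own vertical exchange, which keeps the spatial structure of
the nitrogen deficit (and hence the competitive geography) explicit
rather than diffused.

## The four experiments

* **CONTR** — θ_d = θ_o and k_P^d = k_P: the ability to fix N₂ is the only
  advantage.  Diazotrophs then persist solely where upwelled water carries
  a nitrogen deficit (excess P), i.e. above the OMZ boxes.
* **GRAZ** — grazing refuge: θ_d = 0.1 < θ_o = 0.3.
* **OLIGO** — high-affinity phosphate uptake: k_P^d < k_P.
* **DECAY** — CONTR with the denitrification term nulled: fixation fills
  the global nitrogen deficit and the diazotroph niche closes at the rate
  (excess-P inventory)/(fixation rate).

## Parameters

The printed constants of the formulation are fixed: mu_max = 0.4 d⁻¹,
θ_o = 0.3, θ_d = 0.1 (GRAZ), the 15 °C cutoff, Redfield ratios, and the
1.59 mg Chl a (mmol N)⁻¹ conversion used for the oligotrophy diagnostic
(threshold 0.07 mg Chl a m⁻³).  Everything else is a package calibration
constant, chosen once so that the control run equilibrates near the
canonical global budget — fixation balancing denitrification at
~70 Tg N yr⁻¹ with an excess-P inventory of ~5 Pmol N, hence a
niche-closure timescale near 1100 yr — and so that the qualitative
competitive geography is robust (diazotrophs confined to the OMZ-fed
columns in CONTR, present in the gyres under GRAZ/OLIGO).  The key values:

| parameter | value | role |
|---|---|---|
| J_O^max | 0.5 d⁻¹ | max ordinary growth |
| C_d | 0.33 | diazotroph handicap; window set by CONTR viability vs. GRAZ takeover |
| k_N, k_P | 0.7, 0.044 | half-saturations (k_P = k_N/16) |
| k_P^d (OLIGO) | 0.0122 | below k_P; places the gyre takeover threshold just past the pre-industrial Pacific state |
| mort_phyto | 0.01 d⁻¹ | linear mortality |
| f_denit | 0.38 | OMZ denitrified fraction; sets equilibrium fixation |
| kv (trop/gyre/high-lat) | 0.011 / 0.0007–0.0045 / 0.08 m d⁻¹ | upwelling proxy; tropical value sets the deficit flush time |

The subtropical kv differs by basin (Atlantic 0.0007, Indian 0.003,
Pacific 0.0045 m d⁻¹): the Atlantic gyre is the ultra-oligotrophic,
nearly grazer-free end member in which the high-affinity paradigm pays
off immediately, while the better-ventilated Pacific gyre retains enough
zooplankton that ordinary phytoplankton hold it until stratification
weakens grazing — which is what makes the OLIGO warming response an
expansion rather than a fixture.

## Numerics

Fixed-step RK4 (365 steps per model year by default), compiled with numba;
the same right-hand side backs the plain-`numpy` `tendencies()` API.
Because total phosphorus is a linear invariant of the right-hand side, RK4
conserves it to round-off; the nitrogen budget closes exactly against the
RK4-weighted fixation/denitrification diagnostics.  Negative excursions
smaller than `clip_epsilon` (10⁻⁶ mmol m⁻³) are clipped to zero and the
clipped mass logged; anything larger aborts with advice to shorten the
step.  Halving the step changes a one-year trajectory by less than 10⁻⁶
relative.  All integrations are bit-reproducible for a given
configuration; stochastic routines (the observation generator) take
explicit seeds.

Degenerate inputs: a flat series in the exponential-decay fit returns an
infinite timescale rather than an error; zero fixation marks the
biomass:fixation ratio undefined (NaN); an all-zero field is rejected by
the bloom-intensity percentile; scans of length one report their response
statistic as NaN.

## Spin-up, scenario and the DECAY calibration

Spin-up integrates under fixed pre-industrial forcing until the relative
drifts per century of global fixation and of every tracer inventory fall
below 0.1% (or a year cap is hit, which is reported as a warning, not a
silent success).  The deep nitrogen pool equilibrates on the
deficit-flush timescale (~10³ yr), so the shipped initial condition
places the deficit where the equilibrium wants it: a 16 mmol N m⁻³
deficit under the tropical columns, 0.1 under the gyres, Redfield balance
elsewhere.

The warming scenario (1800–2150) applies a normalized ramp
w(t) = ((t−1800)/350)², scaling a base surface warming of 3 °C (amplified
1.4–1.5× towards the poles, 0.85× in the tropics) and reducing every kv
by a fraction 0.5·w(t) — the box-model proxy for increased stratification.
With the default calibration the oligotrophic area fraction grows from
zero to ~13% as the Atlantic gyre columns cross the 0.07 mg Chl a m⁻³
threshold around mid-century; the coarse box resolution makes this a
stepwise, not smooth, expansion.

The niche-closure experiment (`run_decay_experiment`) (1) spins CONTR to
quasi-equilibrium (600 yr by default), (2) rescales every box's local
NO₃ deficit by one global factor so the excess-P inventory is exactly
5.5 Pmol N in nitrogen equivalents (PO₄ untouched), (3) tunes the global
kv scale in a few 20-year probe runs until the initial fixation is
70 Tg N yr⁻¹ (fixation is linear in kv at fixed inventories), (4) nulls
denitrification and integrates 1600 yr, and (5) fits log(biomass) over
years 100–1500.  Steps (2)–(3) pin the analytic inventory/rate timescale
at 1100 yr; the test is whether the nonlinear simulation actually decays
exponentially at that rate, which it must to within 25%.

## Synthetic observations

`synthetic_obs` stands in for the gridded fixation/biomass climatologies
and the sparse point databases behind them.  A field is a sum of Gaussian
hotspots (random centres in the warm band, lognormal amplitudes) under
mean-one multiplicative lognormal noise, hard-zeroed poleward of 40°
latitude (the habitat constraint) and thinned by a random absence mask —
reproducing the patchiness, positive skew and zero inflation of the real
products, with the noise-free truth returned alongside.  Point sampling is
uniform without replacement over valid cells; regridding is nearest-cell
binning with cell-mean aggregation.  What the generator does *not*
emulate: spatial error correlation, depth structure (biomass is generated
directly as an upper-100 m inventory), seasonal aliasing, and
gene-abundance biases of the underlying assays.  Tests passing against
these fields show the diagnostics are correct and robust to this class of
sampling noise — not that the model matches the real ocean.

## Design choices and limitations

* Grazing is linear in prey as printed; the saturating multiple-prey
  variant is a flag, default off.
* The competitive steady states of a deterministic annual-mean box model
  are knife-edge R*-comparisons; the calibration places the paradigms on
  the intended sides of those edges, and moderate parameter changes can
  cross them (that sensitivity is itself one of the scientific points —
  see the tipping-point scan).
* No seasonal cycle by default; a sinusoidal light modulation
  (`seasonal_J_IO`, usable with the step-level API) is provided for
  exploratory work, while the compiled multi-year integrator uses
  annual-mean light.  No
  prognostic iron or oxygen, no carbonate system, no 3-D circulation;
  denitrification is a prescribed fraction of OMZ remineralization rather
  than oxygen-driven.
* Problem sizes used in the shipped tests and the acceptance script —
  600–1200-year spin-ups, a 1600-year DECAY run, 350-year projections,
  400-year scan members — are the package's chosen desk-scale defaults;
  the e-folding fit is insensitive to lengthening them.
* Global quantities reported: fixation and denitrification in Tg N yr⁻¹
  (14 g mol⁻¹), diazotroph biomass as upper-100 m carbon (Redfield C:N,
  12 g mol⁻¹), the biomass:fixation ratio in Tg C per Tg N yr⁻¹, and the
  area-weighted oligotrophic fraction.
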