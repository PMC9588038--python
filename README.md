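# diazocomp

**Competitive controls on marine nitrogen fixers, in a desk-scale global
box model.**

Diazotrophs — microbes that fix dinitrogen (N₂) into bioavailable
nitrogen — grow more slowly than ordinary phytoplankton, so in theory they
should persist only where surface waters are nitrogen-depleted but still
hold phosphorus, i.e. downstream of denitrifying oxygen-minimum zones.
Observed diazotrophs are far more widespread, which suggests additional
competitive advantages.  `diazocomp` implements the two leading candidates
in one reduced-complexity global ecosystem model so their consequences can
be compared like-for-like:

* **GRAZ** — a grazing refuge: zooplankton partly avoid diazotrophs
  (preference θ_d = 0.1 versus θ_o = 0.3 for ordinary phytoplankton);
* **OLIGO** — high-affinity phosphate uptake: a lower half-saturation
  k_P^d < k_P for diazotrophs;

plus a control (**CONTR**, no advantage beyond fixing N₂) and **DECAY**
(CONTR with denitrification nulled, so fixation gradually erases the
global nitrogen deficit and the diazotroph niche closes).

The model tracks NO₃, PO₄, ordinary phytoplankton, diazotrophs,
zooplankton and detritus in 15 latitude-band × basin columns with two
layers each.  Growth is Liebig/Monod,

    J_O = min(J_IO, J_O^max · NO3/(k_N+NO3), J_O^max · PO4/(k_P+PO4)),
    J_D = min(J_IO, C_d · J_O^max · PO4/(k_P^d+PO4)),      (T ≥ 15 °C)

grazing is `mu_max · Z · θ · P` with `mu_max = 0.4 d⁻¹`, and nitrogen is
conserved up to fixation minus denitrification while phosphorus is
conserved exactly.  A warming scenario (1800–2150) warms the surface and
throttles vertical exchange — the stratification proxy — to ask whether
paradigms that match the present equally well also agree about the
future.  (They don't: that divergence is the point.)  Full model
description: [docs/methods.md](docs/methods.md).

## Worked example

```python
import diazocomp as dz

cfg = dz.build_config("GRAZ", scenario="warming")
eq = dz.spinup_to_equilibrium(cfg, max_years=1200)   # pre-industrial state
d = eq.diagnostics
print(f"fixation  {d.fixation_TgN[-1]:6.1f} Tg N/yr")
print(f"biomass   {d.biomass_TgC[-1]:6.1f} Tg C")
print(f"ratio     {d.biomass_TgC[-1]/d.fixation_TgN[-1]:6.2f} Tg C per Tg N/yr")

proj = dz.run_scenario(cfg, eq)                      # 1800-2150 projection
print(proj.summary())
```

prints (default calibration)

```
fixation    73.8 Tg N/yr
biomass     37.2 Tg C
ratio       0.50 Tg C per Tg N/yr
```

i.e. a pre-industrial equilibrium in which ~74 Tg N yr⁻¹ of fixation
balances denitrification and diazotrophs stand at ~37 Tg C.  The same
spin-up under OLIGO gives a similar fixation but a biomass-to-fixation
ratio of 0.73 — the two paradigms are nearly indistinguishable today.
Under the warming scenario they split: OLIGO's diazotroph biomass climbs
as the oligotrophic gyres expand while its fixation sinks after
mid-century; GRAZ rises and then decays in both quantities.  The same
experiments are available from the shell:

```bash
diazocomp run --paradigm graz --scenario warming --out out/graz
diazocomp scan --paradigm graz --param theta_d --values 0.02,0.07,0.12,0.17,0.22,0.27
diazocomp synth --out out/obs --seed 1          # synthetic observation fields
diazocomp decay-timescale --inventory 5.5 --fixation 70
```

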