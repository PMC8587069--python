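# Methods

## Model structure and assumptions

The body is a 65-node Stolwijk-style network: 16 segments × 4 tissue
layers plus a perfectly mixed central blood pool.  Heat moves between
adjacent layers by constant conductances, between every node and the blood
by perfusion conductances (complete thermal equilibration of the blood with
each node it visits), and leaves the body through respiration (chest core),
evaporation (skin) and the sensible skin path.  There is no counter-current
limb exchange, no explicit vascular tree, and no anthropometric scaling —
the geometry is the published manikin-based segment table (total skin area
1.869 m²).

Clothed segments (trunk, shoulders, arms, thighs, legs — an upper-body
garment modelled as covering the classic "clothed" set; head, hands and
feet are bare) gain two nodes: the inner fabric surface, whose thermal mass
is the gap air film (`A_n·L_nc·ρc_p`, a few J/K), and the outer fabric
surface, which carries the fabric mass (`A_cl·m″·c_f`).  The gap transfers
heat by still-air conduction below a gap Rayleigh number of 10³ and by
enclosure natural convection above it (Catton-form correlation, floored at
Nu = 1 so convection never predicts less than conduction), always in
parallel with grey-body radiation between facing surfaces.  The outer
surface loses heat by vertical-plate natural convection (quarter-power
law in the segment height) to the air temperature and by radiation to the
mean radiant temperature.  Moisture is not stored anywhere: sweat
evaporates at the skin and its latent heat bypasses the dry clothing nodes
through the Lewis-relation vapour path.  No wind penetration, garment
ventilation ("pumping"), or condensation in the gap.

The controller is the classical structure — central (head-core) plus
integrated-skin drives — with configurable gains: sweating
`(190·err_head + 20·(warm−cold))·2^(err_skin/10)` W distributed by segment
weights and clamped to the local evaporative capacity `E_max`; skin blood
flow `(basal + dilation)/(1 + constriction)` with a 0.05 W/K floor;
shivering proportional to the product of core and skin cold errors, capped
at 350 W.  Skin diffusion contributes 6% of `E_max` on the non-sweat-wetted
fraction, so total evaporation never exceeds `E_max`.  A `passive_only`
switch freezes all three effectors at basal for oracle testing.  All laws
are continuous, so the ODE right-hand side is continuous.

## Parameters

* **Published per-segment tables** (areas `A_n`, `A_cl`, heights `H`,
  set-points for all 65 nodes, central-blood capacity 2.610 Wh/°C) ship in
  `src/thermoclo/data/body.toml`.  One tabulated value — the right-foot
  muscle set-point — breaks bilateral symmetry in the source (36.7 °C
  against 34.9 °C on the left); the fixture mirrors the left foot.
* **Reconstructed node parameters.**  Per-node heat capacities, basal
  metabolic rates, basal blood-flow conductances and inter-layer
  conductances are not published for this model variant.  The packaged set
  is built from standard segment masses (≈73 kg total), tissue mass
  fractions per segment class, tissue specific heats (core 3500, muscle
  3800, fat 2500, skin 3680 J/kg·K), a basal metabolism of 84.65 W
  distributed with the viscera/brain dominating, perfusion proportional to
  local metabolism (0.9 W/K per W) for the deep layers, a 7 W/K basal skin
  blood conductance distributed by area, and per-area inter-layer
  conductances of 5–10 W/m²K.  Every value is overridable via the same
  TOML structure.  Steady-state validation: blood 36.3–36.5 °C and mean
  skin 31–33 °C under the reference conditions, which is physiologically
  sensible for light activity at 25 °C in a thin shirt.
* **Surface coefficients.**  Per-segment `h_c` (2.9–4.2 W/m²K, whole-body
  ≈3.5 at 0.25 m/s) and `h_r` (3.9–5.4 W/m²K) follow manikin-style tables.
* **Air and radiation.**  Gap/boundary air properties are fixed at a 300 K
  film temperature (k = 0.0263 W/mK, Pr = 0.707, α = 2.25e-5, ν = 1.589e-5
  m²/s, β = 1/300 K⁻¹); the temperature spans of a few kelvin change Ra by
  far less than the acceptance tolerances, so per-step property updates are
  not worth the cost.  Emissivities default to 0.95 (skin) and 0.90
  (cotton).  Lewis ratio 16.5 K/kPa; vapour permeation efficiency
  i_cl = 0.34.
* **Respiration.**  `RES = 0.0014·M·(34 − T_a) + 0.0173·M·(5.87 − p_a)`
  (M in W, p_a in kPa), clamped at zero — the conventional correlation for
  multi-node models; configurable in the sense that M, T_a and p_a are
  scenario inputs.
* **Saturation pressure.**  Magnus form `0.61078·exp(17.27T/(T+237.3))`
  kPa, within 1% of steam tables from the physiological range up to the
  boiling point; domain-checked on [−20, 110] °C.

## Open design choices

* **Rayleigh length scale.**  The enclosure correlation is driven by the
  *gap-based* Rayleigh number (the physically meaningful choice for a thin
  vertical air space; the aspect-ratio factor `(H/L)^(−1/4)` carries the
  segment height).  A height-based Ra would be ~10⁴× larger, putting every
  garment deep in the "convective" branch and erasing the onset phenomenon
  entirely.
* **Outer radiant sink.**  Radiation from the outer fabric goes to the
  mean radiant temperature (20 °C in the reference room), which the
  scenario distinguishes from the 25 °C air temperature.
* **Serial-resistance forms.**  The evaporative coefficient, the total
  bare-skin coefficient and the diffusion fraction are implemented in
  their standard serial-resistance/fractional forms (see the operation
  docstrings); these are the only dimensionally consistent readings.
* **Evaporative clothing resistance** uses the fabric's intrinsic
  insulation (0.155 clo) — the gap's extra vapour resistance is folded
  into i_cl's role as an ensemble property.  Sweating is capacity-limited
  far above the rates reached here, so this choice does not move the
  energy balance.
* **Thermal neutrality.**  The 10–25% evaporative share of total heat loss
  is a statement about *thermal neutrality*; the package checks it with a
  sedentary (1 Met) subject in the reference environment
  (`thermal_neutrality_scenario()`), where the share is diffusion-dominated
  (≈15%).  The reference activity itself (1.7 Met at 25 °C) is sweating
  territory — the model's evaporative share there is ≈39% of total loss,
  as expected for light exercise.

## Numerics

* **Integration.**  Default fixed-step classical RK4 with dt = 0.1 s.  The
  inner-air clothing node's time constant is ~0.1 s (a few J/K against
  ~50 W/K), so the frequently suggested dt = 1 s is outside the explicit
  stability region; 0.1 s sits safely inside it and halving the step
  changes 30-minute temperatures by < 1e-3 K.  LSODA (rtol = atol = 1e-8)
  is available via `solver="lsoda"` and agrees with RK4 to < 0.01 K.
* **Steady states** are found by damping the transient with LSODA (4 h of
  model time) and polishing with a Newton-type root-find on the full
  right-hand side; the result satisfies max |dT/dt| < 1e-9 K/s and is
  independent of the integration horizon.  The slowest physical mode (the
  weakly perfused foot cores, τ ≈ 1.4 h) is why pure integration needs
  ~12 h of model time to reach the same point.
* **Degenerate inputs.**  E_max = 0 gives zero evaporation (no 0/0);
  Ra = 0 gives Nu = 1; equal temperatures give exactly zero fluxes
  (all ΔT-driven fluxes are antisymmetric); Ra > 10¹⁰ is outside the
  correlation and raises.
* **Problem sizes.**  The coupled system is 87 ODEs (65 body nodes + 22
  clothing nodes).  The onset sweep uses an 8-point gap grid over
  5–19.5 mm with linear interpolation of the Ra = 10³ crossing; the
  five-garment experiment integrates 30 minutes per garment; acceptance
  quantities use full steady states.

## Known limitations and discrepancies with the published experiment

The three quantitative anchors the package is benchmarked against behave
as follows under an energy-consistent model:

* **Flux partition.**  Garment A's chest partition (49% conduction / 51%
  radiation) reproduces the published ≈50/55 split (whose printed pair
  itself sums to 105%).  Garment D gives 24/76 against a published 18/88 —
  the conductive share agrees within tolerance, but a *radiant share of
  88% at a 15.5 mm gap is not physically reachable*: it would require an
  effective radiant coefficient of ≈12 W/m²K between surfaces near 30 °C,
  where the black-body limit is ≈6.4 W/m²K (share ≤ 79% against the gap's
  1.7 W/m²K conduction).
* **Convection onset.**  The model places the Ra = 10³ crossing at
  ≈12.5 mm rather than beyond 15 mm.  The onset position is set by the
  steady skin-to-inner-fabric temperature difference, which here is 5–6 K:
  the gap holds roughly half of the ≈0.28 m²K/W skin-to-environment
  resistance while the skin sits ≈11 K above the effective environment.
  A crossing beyond 15 mm needs a gap ΔT ≤ 3 K, i.e. a skin-to-environment
  resistance of ≈0.6 m²K/W — about 4 clo, which a 0.155 clo shirt with a
  radiating outer surface cannot supply.  (The published clothing-layer
  temperature table is itself not flux-consistent: its fabric temperature
  drop implies ≈96 W/m² through the fabric while its gap drop implies
  ≈22 W/m² through the same series path.)
* **Warming at the loosest fit.**  The published rise of clothing
  temperature at the 1.95 cm garment requires Nu > 1 there.  With the
  enclosure correlation at these aspect ratios (H/L ≈ 28) the convective
  branch only exceeds 1 for Ra ≳ 5.6e3, while the steady gap reaches
  Ra ≈ 4e3 — so the model stays effectively conductive through E and the
  clothing temperatures keep decreasing slightly instead of turning up.

These are reported, not patched: the corresponding acceptance tests fail
honestly, and all physical invariants (energy closure, flux continuity,
blood closure, monotone trends A→D, back cooler than chest) hold.

What the packaged defaults emulate — and do not.  The fixture body is a
single "standard" subject; real bodies vary in mass distribution and
basal rates, and the reconstructed capacities/conductances set transient
time constants that have not been fitted to human cooling/warming curves.
Gap thickness is uniform per garment (the average ease allowance), while
real garments drape with highly non-uniform gaps; per-segment gap maps are
supported but unvalidated.  Passing tests therefore demonstrate the
internal consistency of the coupled physics and its agreement with
hand-computed correlations and the reproducible published quantities — not
predictive accuracy for any individual wearer.
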