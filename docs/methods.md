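# Methods

## Scope and model structure

`sios2` models a corotating twin-screw extruder operated autogenically
(barrel temperature control off downstream of the feeding section) and
answers two questions from material data plus a small calibration campaign:
*how much can be fed* at a given screw speed, and *what melt temperature
results*. The package deliberately does not model the energy balance of the
machine (motor power, heat losses, pressure power): the autogenic
correlations absorb those physics empirically. Entrance-pressure (Bagley)
and elongational (Cogswell) die corrections are likewise out of scope, so
die viscosities are relative quantities; this is sufficient because they
only ever appear inside correlations calibrated on the same die.

## Rheology

Melt viscosity follows the Carreau model with Arrhenius
time-temperature superposition:

    eta(gammadot, T) = eta0 * a_T * (1 + a_T*gammadot/gammadot_c)^(-c)
    a_T = exp((Ea/R) * (1/T - 1/T_ref))

Parameters, units and defaults (reference polymers, refit at T_ref = 473 K):

| parameter | meaning | PVPVA | SOL | bBMA |
|---|---|---|---|---|
| eta0 [Pa s] | zero-shear viscosity | 169.7 | 147.3 | 25.58 |
| gammadot_c [1/s] | critical shear rate | 133.1 | 136.7 | 1688 |
| c [-] | Carreau flow index | 0.387 | 0.411 | 0.561 |
| Ea [J/mol] | activation energy | 198292 | 150773 | 140336 |

The exponent convention is the shear-thinning reading with high-shear
power-law slope −c; it is the only reading consistent with the Ostwald index
relation n = 1 − c used by the shear-rate correction. The Arrhenius (rather
than WLF) shift is appropriate because all relevant temperatures are far
above the polymers' glass transitions; moisture plasticisation is not
modelled.

**Refitting.** `fit_carreau_arrhenius` minimises squared residuals in log
viscosity (viscosity spans decades; log residuals weight all decades
equally, standard rheometry practice), with eta0, gammadot_c and Ea
log-parameterised for positivity and c bounded to [0, 0.999]. T_ref is fixed
by the caller. At least four points over at least two temperatures are
required — Ea is structurally unidentifiable from an isothermal curve and
the fit refuses such designs rather than returning an arbitrary value.

**Temperature inversion.** Viscosity is strictly monotone decreasing in T
for Ea > 0, so `invert_temperature` uses Brent's method on the bracket
T_ref ± 150 K (spanning all extrusion-relevant temperatures) with an
absolute tolerance of 1e-6 K. The physical requirement is only ~0.01 K, but
the tight tolerance makes the simulate → fit → predict loop close to 1e-6
relative error in the fitted parameters, so numerical error never masks a
modelling defect. An unattainable target raises an error carrying the
endpoint viscosities.

## Feeding section

The slip s (fraction of the feeding screws' geometric transport capacity
not realised by the powder) is the single calibrated quantity. It can be
computed from one filled-barrel point (SFL* = 1) or, preferably, from a
regression of maximum conveyable mass flow on screw speed. The regression
is **through the origin** because a resting screw conveys nothing. Slip
estimates outside [0, 1) are rejected (≥ 1) or returned with a warning
(< 0), never silently clamped. For the bundled powders the published slips
are 0.865 (PVPVA), 0.858 (SOL), 0.850 (bBMA): nearly identical, which is
why the maximum-feed-load ranking (SOL > bBMA > PVPVA) simply follows bulk
density.

## Die flow

The die is treated as a single-bore capillary: wall shear stress
dp·r/(2l), apparent shear rate 4V̇/(πr³), their ratio the apparent die
viscosity. The volume flow is mass flow divided by the **true
(pycnometric) density** — the closest available stand-in for the melt
density; a melt-density override is exposed on every routine that uses it.
The Weissenberg–Rabinowitsch factor (4−3c)/(4−4c) corrects the apparent
shear rate for shear thinning; the die viscosity used by the autogenic
correlations is evaluated at the corrected shear rate (a `wr_correction`
switch allows the uncorrected variant for sensitivity analysis). The
correction rescales the shear rate only, not the stress.

## Autogenic correlations

τ_extruder is fitted as the **mean of eta_die·n** over qualifying
observations (reported as mean ± sd), not by nonlinear least squares of
eta_die against 1/n: the mean weights all speeds equally and its dispersion
is directly interpretable. The ratio law is ordinary least squares of
lg(eta_die/eta_calc) on lg(n/n_max) — lg is base 10 throughout — with the
Pearson R of that regression reported. Observations below 100 rpm are
excluded by default (overridable): below roughly 10% of nominal capacity
the melt does not reach autogenic equilibrium and the correlations break
down, so fitting on such points would corrupt the calibration.

Prediction chains the pieces: mass flow at SFLmax, corrected die shear rate
from it, eta_die = τ/n, eta_calc by inverting the ratio law, temperature by
inverting the rheology model. Crossover transfer averages donor fits
(arithmetic mean of τ, slope, intercept) and donor slips, combining them
with the target material's own densities; the averaged parameter set
reports R as NaN since no single regression produced it.

## Extruder constants and package assumptions

Geometry of the bundled ZSE 27 MAXX setup: d = 28.3 mm,
A_free = 4.91e-4 m², die radius 1.5 mm, die length 11.7 mm. Two constants
are not published with the rest of the setup and are package assumptions:

* **l_pitch = 0.06 m** — a standard 60 mm conveying element in the feeding
  section. Chosen because it makes the published slips mutually consistent
  with the documented 3 kg/h first-step feed rate at backlog speeds of
  ~40/20/33 rpm (PVPVA/SOL/bBMA), all inside the documented 20–200 rpm
  search window.
* **n_max = 1200 rpm** — the machine's nominal screw speed, consistent with
  the documented top throughput of ~42 kg/h at constant feed load.

Both are constructor arguments of `zse27_geometry` and can be overridden.

## The virtual extruder

The simulator inverts the prediction chain to generate observation tables
from ground truth (material rheology, slip, τ, slope, intercept): mass flow
at SFL* = 1 (the campaign emulates operation at maximum feed load, as on
the real line), melt temperature by temperature inversion, die pressure by
running the capillary equations backwards. Measurement noise is additive
Gaussian on temperature (default sd 1 K, an IR-camera-like reading error)
and multiplicative Gaussian on pressure (default 1%, gauge error
proportional to reading); set-points (speed, mass flow) carry no noise.
Defaults emulate the reference campaign conditions: PVPVA ground truth
(τ = 399 Pa, slope 0.409, intercept 0.131, slip 0.865) on an 8-speed
100–500 rpm ramp, respecting the ≥ 100 rpm fitting window.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: thermal equilibration transients (the reason real
low-speed points deviate), feeder variability, torque limits, degradation,
Bagley entrance effects, and any mismatch between literature rheology and
the actual batch. Noiseless simulation is an exact fixed point of the
fitting routines by construction, which is what makes it a sharp
correctness oracle for the code, not evidence about the physics.

## Numerical and statistical choices

* All internal quantities are SI (K, 1/s, Pa, kg/s); rpm/°C/bar/kg/h exist
  only at the I/O boundary (`sios2.units`, `sios2.io`).
* Problem sizes: the replicate study in the acceptance suite uses 200
  simulated campaigns of 8 points each; the inversion oracle check uses 100
  random instances against a 0.01 K grid over a 300 K bracket. These sizes
  resolve the quantities of interest well and run in seconds.
* Bias assessment across 200 replicates: the Monte-Carlo standard error of
  the mean is sd/√200 ≈ 0.07·sd, so a bias bound of sd/10 is at the edge of
  what the design can resolve. The acceptance test therefore flags bias
  only when it exceeds both sd/10 and the 99% confidence radius
  2.58·sd/√200 of the bias estimate; the slip, which is noise-free in the
  simulator, is required to come back exact.
* Crossover accuracy is asserted at ≥ 400 rpm of the 100–500 rpm ramp. The
  5 K transfer-accuracy claim holds at high speed/throughput (the desired
  operating range); at 100–200 rpm the bBMA transfer error grows to ~8–11 K,
  which the package reports rather than hides.

## Known limitations

Single-bore cylindrical dies only; no energy/torque prediction; no
residence-time distribution; no start-up or transient behaviour; parameter
transfer assumes the same screw configuration and die — a different setup
needs recalibration of τ, slope and intercept. The bBMA reference material
transfers noticeably worse than the other two polymers (its extrusion
behaviour matches literature rheology less well); the package reproduces
this behaviour but does not explain it.
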