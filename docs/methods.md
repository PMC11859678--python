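# Methods

This note documents the model equations, parameter choices, numerical
methods, and known limitations of `hipecpk`. Everything quantitative
here is computed by the package's own code (tests or
`scripts/acceptance.py`); nothing is asserted that the suite does not
reproduce.

## Scales and scope

The physical problem spans two scales: heated chemoperfusate
circulating through the abdominal cavity (centimeters, minutes) and
drug transport into a 2 mm tumor nodule (tens of micrometres,
seconds). The cavity-scale computational fluid dynamics is *not*
reproduced here; its outputs enter as boundary data:

* **Organ-surface temperatures** — steady plateaus per organ and
  catheter setup (seven peritoneal/retroperitoneal sites; setup 1 with
  maximal transverse, setup 2 with maximal longitudinal inflow–outflow
  distance), shipped verbatim in `data/parameters.yaml`.
* **Organ-surface drug concentration** — emulated by the
  `boundary` module as a first-order rise
  C_surf(t) = C₀(1 − e^(−t/τ)).

Everything downstream — nodule transport, systemic pharmacokinetics,
and the evaluation metrics — is computed by the package.

## The synthetic cavity stage

The time constants τ are surrogate choices: the true surface kinetics
depend on catheter placement and cavity flow, which are out of scope.
Defaults are τ = 180 s (setup 1), 90 s (setup 2, which covers organs
faster), and 300 s for the slow sites of setup 1 (intestine, left
kidney). Every generated series satisfies, and the tests enforce:
concentration non-negative, non-decreasing, bounded by the
administered dose, within 1 % of it by the end of the 30 min schedule
(60 mL/min at 43 °C, 160 µM, 1800 s).

What the surrogate does *not* emulate: spatial heterogeneity over a
single organ surface, transient temperature ramps (plateaus are
applied from t = 0), and any coupling of the concentration rise to the
flow field. Consequently arm-to-arm *fold changes* are the trustworthy
outputs — the suite checks they move ≤ 5 % as τ varies across
[60 s, 300 s] — while absolute single-arm quantities inherit the
surrogate's timing. A lumped, self-consistent alternative is provided
by the `cavity` module (well-mixed cavity with per-organ film
exchange, mass-conserving to 0.1 %); its film coefficients and the
80 mL cavity volume are likewise surrogate values, sized so organ
surfaces reach 95 % of the dose within 15 min.

## Nodule transport

Geometry: a sphere of diameter 2 mm centered on the tissue surface;
the upper hemisphere faces the perfusate (Dirichlet
C = C_oxali(t)), the lower hemisphere is embedded in host tissue
extending five tumor diameters, with zero-gradient far boundaries.
The host surface plane is zero-flux by default — drug enters the
tissue only through the exposed tumor surface; a
`host_surface_exposed` switch applies the perfusate condition to the
host plane as well for sensitivity studies (with the tabulated host
parameters this floods the nodule above the cytotoxic threshold within
the treatment and saturates every penetration metric, so it is not the
default).

Physics: diffusion (D = 3×10⁻⁹ m²/s) with two first-order sinks —
cellular elimination β C and transvascular washout
P_c (S/V) · Pe/(e^Pe − 1) · C · y(T). The Péclet number uses the
standard Starling form Pe = L_p ΔP_eff (1 − σ)/P_c; with the default
tumor parameters (P_v = 2.08 kPa, IFP = 1.4 kPa for the 2 mm nodule,
osmotic terms 2.67/1.33 kPa, c = 0.82, σ = 0.95) Pe ≈ −3.1×10⁻⁴: the
washout is essentially diffusive, and the Pe/(e^Pe − 1) factor is
evaluated with a series expansion below |Pe| = 10⁻⁶. y(T) is applied
to the vascular term only, in both regions. Temperature inside the
nodule is uniform at the organ-surface plateau; there is no thermal
PDE at this scale and no interstitial convection. IFP is uniform per
region (tumor value, host value) — no radial IFP profile.

The tabulated tumor IFP of 2.67 kPa (from larger-nodule literature) is
retained as a documented preset (`transport.tumor_alt_ifp`); the 2 mm
default is 1.4 kPa. β is a single tabulated value applied to both
tumor and host. Baseline tumor S/V = 2×10⁴ 1/m corresponds to MVD
200 1/cm; the collagen-density presets reinterpret the two tabulated
S/V values (2×10⁴ low-collagen/4 %, 1×10⁴ high-collagen/32 %, the
latter with D halved).

### Discretization

The domain is meshed in spherical-polar (r, θ) coordinates centered on
the nodule. Both material interfaces — the tumor surface r = a and
the tissue plane θ = π/2 — are coordinate surfaces, so tumor, host
and fluid regions tile exactly (the discrete tumor volume equals
(4/3)πa³ to round-off, which the tests assert). Fluxes use a
conservative finite-volume form with harmonic face diffusivity
(continuity of flux at the tumor–host interface) and half-cell
Dirichlet closures. The concentration field has a square-root corner
singularity on the contact circle where the Dirichlet exposed surface
meets the zero-flux host plane; the two cells on each side of that
circle are geometrically graded (down to 1/16 of the base spacing in
both r and θ), which restores clean convergence of bulk metrics —
halving the mesh spacing moves tumor AUC by 0.75 % at desk scale and
0.41 % at the default resolution (asserted at < 1 %).

Time integration is backward Euler with the linear sink folded into
the system matrix, factorized once per run (sparse LU); the boundary
value is the only time-varying term. The implicit scheme makes the
discrete balance *influx − sinks = content change* an identity, so the
mass-balance diagnostic (asserted < 0.5 %) holds to machine precision,
and step-size error is separately small (AUC moves < 10⁻³ between
dt = 4 s and 0.25 s).

Verification oracles: (i) with sinks disabled and a constant boundary,
the axis concentration matches C₀ erfc(x/2√(Dt)) within 2 % — checked
on a large-diameter nodule where the exposed pole is locally flat,
because on the 2 mm nodule spherical focusing legitimately raises the
axis concentration above the half-space solution; (ii) a 10-node 1-D
reduction agrees with an independently written forward-Euler stepper
within 0.1 %; (iii) linearity, parameter monotonicity (AUC decreasing
in P_c, β, S/V; increasing in D), and the hyperthermia effect (AUC
rising with T through y(T)) are property-tested.

### Resolutions

Defaults follow the source configuration: 0.05 mm spacing (40 cells
across the diameter), dt = 0.5 s. The study-scale sweeps
(`DESK_SCALE`) use 0.1 mm, dt = 2 s, host block truncated at 4 mm —
beyond the 30-minute diffusion length √(4Dt) ≈ 4.6 mm under sinks —
chosen so a full 42-solve sweep completes in minutes on one CPU;
individual metrics agree with the default resolution within the
grid-convergence tolerance above. Threshold depths are located by
linear interpolation along the axis profile, so d_eff resolution is
finer than the mesh.

## Bioheat verification

The `bioheat` module implements the Pennes equation on a 1-D slab
(implicit stepping, perfusion sink ρ_b w_b c_b (T − T_a)) plus the
lumped arterial update ΔT_a = (q_m + q_therm − q_skin − q_tail)Δt /
(ρ_b c_b V_b). It exists for property-level verification of the
thermal model — the steady sinh profile against the closed form,
discrete energy balance, and the interval property that a perfusate-
heated wall with the 600 W/m² open-abdomen loss settles strictly
between 37 and 43 °C — and optionally to generate temperature
plateaus. It does not reproduce the organ-resolved thermal field; the
shipped plateau fixture is canonical downstream. Skin/tail losses are
configurable linear terms h·A·(T_a − T_env) (the anatomical submodels
are out of scope); metabolic gain defaults to 0 with a config hook.
Blood properties ρ_b = 1050 kg/m³, c_b = 3800 J/kg/K. Perfusion rates
are converted from mL/min/kg using each organ's density; the two rows
without tabulated density use generic soft-tissue values, marked in
the YAML.

## Systemic pharmacokinetics

A linear two-compartment model (K12 = 2.8, K21 = 1.1, Ke = 3.9 1/h,
converted to 1/s) is driven by the transvascular uptake source. The
integrator advances each uniform step with the exact matrix
exponential of the 2×2 rate matrix and the source loading
φ = ∫₀^Δt e^(Aτ)dτ computed via an augmented exponential — exact for
piecewise-constant sources, stiff-safe, and valid without special
cases in the conservative Ke = 0 limit (asserted exactly).

The source has two parts: the tumor-integrated vascular sink from the
nodule solve, plus an arm-independent normal-tissue contribution —
a 1-D host-tissue column bathed by the perfusate, integrated over a
1 mm surface layer and scaled by a rat-scale peritoneal exchange area
of 70 cm² (per-organ boundary kinetics and plateau temperatures).
Blood volume defaults to 16 mL (64 mL/kg × 250 g rat). Both volumes
are surrogate: absolute plasma concentrations are therefore reported
but not asserted; all pharmacokinetic-advantage comparisons are PA
*ratios*, from which V_blood cancels exactly (property-tested).

## Metrics and conventions

* Mean tumor concentration is the volume-weighted average over
  tumor-region cells; AUC is its trapezoidal time integral, stored at
  every step (halving the sampling cadence moves it < 0.5 %).
* d_eff uses the end-of-treatment field by default; the alternative
  any-time-exceedance reading is available (`mode="max"`) and bounds
  the default from above. "Dose exceeding 10 % of IC50" is evaluated
  against the IC50 interpolated at the organ plateau temperature for
  HIPEC and at 37 °C for IPEC.
* Normalization of d_eff is by tumor diameter (2 mm); radius
  normalization would scale all folds identically.
* IC50 interpolation is piecewise-linear on the measured 37–43 °C
  grid; this choice reproduces all 14 tabulated organ-surface IC50
  values within ±1 µM, which is the package's justification for it.
  The thermal enhancement ratio row is stored verbatim and never
  recomputed as a ratio of mean IC50s (the measured TER is a mean of
  per-cell-line ratios and differs from the ratio of means).
* Quartiles across the n = 7 organ sites use linear interpolation
  (the numpy default) — stated because the convention is visible at
  this n.
* Medians for the penetration fold changes and the dose-equivalence
  search are taken over the seven organ sites of catheter setup 1; the
  pharmacokinetic-advantage comparison uses the intestine site
  (40.1 °C), the same site as the permeability sensitivity analysis.
  Monotherapy dose arms reuse the control solve rescaled exactly by
  dose (the PDE is linear in the boundary concentration; the rescaling
  is asserted against a direct solve).

## Design choices made where the design was open

* Spherical-polar rather than cylindrical axisymmetric coordinates, for
  exact interface representation (see Discretization).
* Hemisphere-only drug entry as the default boundary configuration;
  the exposed-host alternative is a switch, not the default, for the
  reason given above.
* End-of-treatment d_eff as the conservative default reading.
* The scenario transforms (`apply_bevacizumab`, `apply_stiffness`) are
  pure functions of the base parameter set, so arms compose
  predictably (pore-size multiplier on baseline P_c first, then the
  dose transform).

## Known limitations

* Boundary kinetics are surrogate; absolute AUC/d_eff values carry
  that caveat, fold changes are robust to it (≤ 5 % across the τ
  range). The flag `surrogate: true` travels with every generated
  series.
* The model chain is linear in dose by construction; saturable uptake,
  protein binding, and platinum speciation are not modelled.
* No interstitial convection, no radial IFP profile, no organ/wall
  deformation, no multi-nodule interaction.
* Absolute plasma concentrations depend on surrogate exchange and
  blood volumes (ratios are the supported outputs).
* The 5 mg/kg arm's penetration-depth contrast achievable in this
  configuration is bounded near √(sink ratio) ≈ 1.8 over control; with
  the surrogate boundaries the simulated fold increases and the
  derived dose-equivalence points sit below the strongest literature
  contrasts for that dose, while the AUC gains (≤ 20 % / ≤ 45 %) are
  reproduced.
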