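# Physical constants for the (H)IPEC drug-delivery model.
# Units noted per block; concentrations cross the API boundary in µM
# (1 µM = 1e-3 mol/m³), internal computations are SI.

thermal_properties:   # w_b in mL/min/kg; rho_t kg/m³; k_t W/m/K; c_t J/kg/K
  Liver:      {w_b: 860,  rho_t: 1079, k_t: 0.52, c_t: 3540}
  Pancreas:   {w_b: 767,  rho_t: 1087, k_t: 0.51, c_t: 3164}
  Intestine:  {w_b: 765,  rho_t: 1088, k_t: 0.54, c_t: 3655}
  Spleen:     {w_b: 1557, rho_t: 1089, k_t: 0.53, c_t: 3690}
  Kidneys:    {w_b: 3795, rho_t: 1066, k_t: 0.53, c_t: 3763}
  Stomach:    {w_b: 460,  rho_t: 1088, k_t: 0.53, c_t: 3690}
  # density/conductivity/heat capacity not tabulated for the two rows
  # below; generic soft-tissue values are supplied (rho 1050, k 0.50,
  # c 3600) and flagged as defaults.
  Skin:            {w_b: 106, rho_t: 1050, k_t: 0.50, c_t: 3600}
  PeritonealWall:  {w_b: 33,  rho_t: 1050, k_t: 0.50, c_t: 3600}

blood:                # lumped arterial compartment
  rho_b: 1050         # kg/m³
  c_b: 3800           # J/kg/K
  V_b: 1.6e-5         # m³ (rat scale, 64 mL/kg x 250 g)

transport:            # SI units throughout
  tumor:
    L_p: 2.10e-11     # m/Pa/s
    S_over_V: 2.00e4  # 1/m  (MVD 200 1/cm baseline; 1.00e4 = high-collagen preset)
    P_c: 1.43e-6      # m/s  (sucrose in mesentery; MW close to oxaliplatin)
    P_v: 2.08e3       # Pa
    P_i: 1.40e3       # Pa   (2 mm nodule; 2.67e3 kept as literature preset below)
    pi_v: 2.67e3      # Pa
    pi_i: 1.33e3      # Pa
    c_osm: 0.82
    sigma: 0.95
    D: 3.0e-9         # m²/s
    beta: 7.32e-4     # 1/s
  tumor_alt_ifp:
    P_i: 2.67e3       # Pa — literature value for larger nodules, not used by default
  normal:
    L_p: 2.70e-12
    S_over_V: 7.00e3
    P_c: 2.2e-9
    P_v: 2.08e3
    P_i: 1.33e2
    pi_v: 2.67e3
    pi_i: 1.33e3
    c_osm: 0.91
    sigma: 0.95
    D: 3.0e-9
    beta: 7.32e-4

pk_rate_constants:    # 1/h
  K12: 2.8
  K21: 1.1
  Ke: 3.9

cytotoxicity:         # CMS4 colorectal cancer (MDST8, COLO320, HUTU80 mean)
  temperatures_c: [37.0, 38.0, 39.0, 40.0, 41.0, 42.0, 43.0]
  ic50_um: [537.7, 353.7, 314.3, 311.3, 245.0, 229.7, 220.0]
  ter: [1.0, 1.43, 1.6, 1.63, 2.07, 2.13, 2.23]   # stored verbatim, never recomputed

# Steady-state organ-surface temperatures induced by the two catheter
# setups (inflow 60 mL/min at 43 °C), with the matching interpolated
# IC50 values. Consumed as a fixture by the nodule-scale model.
organ_surface_plateaus:
  setup1:
    Pancreas:  {temp_c: 41.3, ic50_um: 241}
    Liver:     {temp_c: 40.4, ic50_um: 285}
    Intestine: {temp_c: 40.1, ic50_um: 305}
    L.Kidney:  {temp_c: 38.4, ic50_um: 338}
    R.Kidney:  {temp_c: 40.7, ic50_um: 265}
    Stomach:   {temp_c: 41.7, ic50_um: 234}
    Spleen:    {temp_c: 41.7, ic50_um: 234}
  setup2:
    Pancreas:  {temp_c: 41.8, ic50_um: 232}
    Liver:     {temp_c: 40.6, ic50_um: 271}
    Intestine: {temp_c: 41.0, ic50_um: 245}
    L.Kidney:  {temp_c: 40.5, ic50_um: 278}
    R.Kidney:  {temp_c: 40.9, ic50_um: 251}
    Stomach:   {temp_c: 42.0, ic50_um: 229}
    Spleen:    {temp_c: 41.9, ic50_um: 231}

# Surrogate boundary-kinetics time constants [s]: first-order exponential
# rise of the surface-averaged perfusate drug concentration. Setup 2
# saturates faster (longitudinal catheter placement); the intestine and
# left kidney are the slow sites in setup 1.
boundary_tau:
  setup1:
    default: 180.0
    Intestine: 300.0
    L.Kidney: 300.0
  setup2:
    default: 90.0

systemic_source:      # surrogate normal-tissue exchange geometry (rat scale)
  peritoneal_area_m2: 7.0e-3   # total organ-surface area bathed by perfusate
  exchange_depth_m: 1.0e-3     # surface layer contributing vascular uptake
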