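# hipecpk

Multiscale simulation of oxaliplatin delivery into peritoneal tumor
nodules during 30-minute (hyperthermic) intraperitoneal chemotherapy —
(H)IPEC — with and without bevacizumab-induced vascular normalization.

## The problem

After cytoreductive surgery for peritoneal metastasis of colorectal
cancer, residual nodules are small (R2a, < 2.5 mm) and are treated by
circulating heated chemotherapy (oxaliplatin, 160 µM, 43 °C inflow)
through the abdominal cavity for 30 minutes. Penetration into the
nodules is poor: the hyperpermeable, immature tumor vasculature washes
drug out of the interstitium and elevated interstitial fluid pressure
(IFP) opposes inflow. Anti-VEGF therapy (bevacizumab) transiently
*normalizes* the vasculature — lowering microvascular density (MVD),
permeability and IFP — and may therefore improve intraperitoneal drug
delivery. This package quantifies that effect in silico for tumors of
the CMS4 colorectal subtype.

## The model

For a 2 mm nodule half-embedded in host tissue, with its exposed
hemisphere held at the perfusate concentration C_oxali(t), the
interstitial concentration obeys a diffusion–reaction equation

    ∂C/∂t − ∇·(D ∇C) = −S_c,     S_c = β C  +  P_c (S/V) · Pe/(e^Pe − 1) · C · y(T)

with cellular elimination β, transvascular washout governed by the
Starling/Péclet balance

    Pe = L_p [P_v − P_i − c (π_v − π_i)] (1 − σ) / P_c,

and an empirical hyperthermic washout-reduction factor
y(T) = −0.04715·T + 2.744555 (y ≈ 1 at 37 °C). Organ-surface
temperatures are steady plateaus per catheter setup (consumed as a
fixture of the cavity-scale simulation); surface drug concentration
rises first-order to the administered dose (a documented surrogate for
the cavity flow). The volume-integrated vascular uptake drives a
two-compartment systemic model (K12, K21, Ke), and treatment arms are
compared through

* tumor exposure AUC = ∫ C̄(t) dt,
* effective penetration depth d_eff — the depth along the symmetry
  axis where C exceeds 10 % of the temperature-specific IC50,
* the pharmacokinetic advantage PA = AUC_tumor / AUC_plasma.

Bevacizumab enters as a pure parameter transform: 0.5 mg/kg → MVD
−45 %; 5 mg/kg → MVD −65 %, L_p and P_c ×0.78, IFP 1.4 → 0.25 kPa.
Supporting modules implement the Pennes bioheat equation with lumped
arterial feedback and a well-mixed cavity balance.

## Worked example

```python
from hipecpk import DESK_SCALE, ScenarioRunner, ScenarioSpec, auc, effective_penetration_depth

runner = ScenarioRunner(DESK_SCALE)
control = ScenarioSpec()                      # HIPEC, 160 µM, no bevacizumab
combo = ScenarioSpec(bevacizumab_dose=5.0)    # HIPEC after 5 mg/kg bevacizumab

for name, spec in [("control", control), ("combination", combo)]:
    field = runner.field_for(spec, "Intestine", 1)
    ic50 = runner.ic50_for(spec, "Intestine", 1)
    d = effective_penetration_depth(field, ic50)
    print(f"{name:12s} AUC = {auc(field):6.1f} mol s/m3   "
          f"d_eff = {d*1e3:.2f} mm ({d/2e-3:.2f} of diameter)")
```

prints

```
control      AUC =   96.3 mol s/m3   d_eff = 1.01 mm (0.50 of diameter)
combination  AUC =  131.6 mol s/m3   d_eff = 1.75 mm (0.87 of diameter)
```

i.e. on the intestine surface (40.1 °C plateau, IC50 ≈ 305 µM) the
5 mg/kg vascular-normalization transform raises 30-minute tumor
exposure by ≈37 % and extends the cytotoxic penetration depth from
about half to most of the nodule.

A command-line layer runs whole experiment batches from shipped
configs:

```bash
hipecpk list-scenarios
hipecpk run figure3_organ_sweep --out results/
hipecpk report results/
```

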