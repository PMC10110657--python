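# retropbtk

Physiologically based toxicokinetic (PBTK) modeling of the pyrrolizidine
alkaloid **retrorsine** in mouse and rat: whole-body simulation with an
extended-clearance liver, in vitro-to-in vivo extrapolation (IVIVE) of
hepatic transport and metabolism, Bayesian calibration against in vivo
kinetic data, and reverse dosimetry from hepatocyte cytotoxicity to
benchmark doses (BMD) for acute liver toxicity.

## Who this is for

Toxicokinetic modellers and risk assessors who need a mechanistic,
testable link between in vitro assay read-outs (hepatocyte medium-loss,
liver microsomal depletion, Caco-2 permeability, cytotoxicity
concentration–response) and in vivo dose metrics for a hepatotoxic plant
alkaloid — and a worked, fully reproducible example of the
in-vitro-to-in-vivo reverse dosimetry workflow.

## The model

A 13-compartment whole-body structure (plasma pool, ten perfusion-limited
tissues, gut lumen, liver) with the liver split into a lumped
vascular/interstitial (vi) space and a cellular (c) space. The liver
cellular mass balance is

    dA_c/dt = (CL_act,in + PS_diff)·K_liv^{int,u:vi}·C_vi
            − (CL_act,ef + PS_diff·fn_c/fn_int)·fu_c·C_c
            − CL_bile·fu_c·C_c
            − V_max,liv·fu_c·C_c / (K_M,liv + fu_c·C_c)

with the metabolic flux split into fractions forming DHR:GSH, DHR:PROT and
DHR:DNA adduct pools (mono-/biexponential depletion). Overall hepatic
clearance follows the extended-clearance closed form

    CL_liv = Q_liv·fuP·CL_act,in·(CL_met + CL_bile) /
             [Q_liv·(CL_act,ef + CL_met + CL_bile) + fuP·CL_act,in·(CL_met + CL_bile)],
    CL_met,liv = V_max,liv / K_M,liv .

Tissue-to-plasma partition coefficients come from the Rodgers–Rowland
constituent model; renal clearance is fuP·GFR; gut metabolism follows the
liver/10 rule. Reverse dosimetry inverts the model through
`fu_invitro·C_invitro = fuP·C^vi_max,liv`, and model-averaged BMD analysis
(exponential + Hill families, AIC weights, parametric bootstrap) yields
BMDL5/BMDU5 for a 5% loss of liver integrity. See `docs/methods.md` for
the full account.

## Worked example

```python
from retropbtk import load_parameter_set, simulate, DoseEvent, pbtk

params = load_parameter_set(species="mouse")
result = simulate(params, DoseEvent("po", 1.0, 0.0), t_end=24.0)
summary = pbtk.disposition_summary(result)
print(f"liver metabolism: {100*summary['met_liv_share_of_eliminated']:.1f}%")
print(f"gut metabolism:   {100*summary['met_gut_share_of_eliminated']:.1f}%")
print(f"renal excretion:  {100*summary['urine_share_of_eliminated']:.1f}%")
print(f"liver Cmax(vi):   {result.cmax_liv_vi():.3f} uM")
```

prints

```
liver metabolism: 64.4%
gut metabolism:   10.4%
renal excretion:  25.2%
liver Cmax(vi):   0.811 uM
```

— after a single 1 mg/kg oral dose in the mouse, about two thirds of the
absorbed retrorsine is eliminated by liver metabolism, a tenth by gut
metabolism and a quarter in urine, and the peak total concentration in the
liver vascular/interstitial space is ≈0.8 µM. The same call with
`species="rat"` adds ≈2.7% biliary excretion.

Calibration and reverse dosimetry hang off two objects, in the usual
model/results idiom:

```python
from retropbtk import synthetic
from retropbtk.model import PBTKModel
from retropbtk import dosimetry

params = {s: load_parameter_set(species=s) for s in ("mouse", "rat")}
data = synthetic.generate_invivo_dataset(
    synthetic.SyntheticDesign(truth=params, seed=1))
results = PBTKModel(data, params).fit(n_iter=3000, seeds=(1, 2, 3))
print(results.summary())          # mode, 95% HDI, Gelman-Rubin per parameter

cyto = synthetic.generate_cytotox(153.0, species_id="rat", seed=1)
dr = dosimetry.translate_to_dose_response(cyto, params["rat"], route="po")
bmd = dosimetry.bmd_model_averaging(dr, bmr=0.05, n_boot=1000, seed=1)
print(bmd.bmdl, bmd.bmdu)         # 90% CI for the 5% benchmark dose, mg/kg
```

A thin CLI mirrors the library: `retropbtk simulate`, `retropbtk ivive
medium-loss`, `retropbtk fit`, `retropbtk reverse-bmd`, `retropbtk synth`,
`retropbtk reproduce --seed 1 --out results.json`.

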