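# kroghadc

A mechanistic simulator of antibody-drug-conjugate (ADC) tumor penetration
and response, for pharmacologists and modelers designing ADCs or selecting
targets and xenograft models. ADCs couple a potent cytotoxic payload to an
antibody against a tumor surface antigen; because antibodies are large and
bind avidly, their distribution in solid tumors is often heterogeneous — the
*binding-site barrier* — and efficacy depends on an interplay of receptor
density, endocytic trafficking, linker chemistry and payload kinetics that
is hard to reason about without a quantitative model.

`kroghadc` implements a Krogh-cylinder reaction-diffusion model of a mouse
tumor xenograft. A biexponential plasma profile
C_plasma(t) = C0·(A·e^(−ka·t) + B·e^(−kb·t)) drives permeability-limited
extravasation, D·∂C/∂r|wall = P·(C_plasma − C/ε), into an annulus of tissue
around a single capillary, where the ADC diffuses radially, binds its
receptor reversibly (koff = kon·K_D), internalizes, and releases payload
either on lysosomal degradation (non-cleavable linker) or endosomal entry
(cleavable linker). Cytosolic payload drives a proliferating/quiescent
tumor-mass model

    dP/dt = (γ − α − k_kill·(Cp/Γ)·E50)·P + β·Q,    dQ/dt = α·P − β·Q,

through a steep Hill switch E50 = x^h/(x^h + IC50^h) on the cell-mass-
normalized payload x = Cp/Γ. Growth constants are fixed so the drug-free
tumor doubles at t_d with a constant P/Q = r_t. Outputs are the % change in
volume-averaged tumor mass over time and the maximum achievable shrinkage,
plus full radial profiles of all seven molecular species. See
`docs/methods.md` for the complete model description and numerical scheme.

## Worked example

```python
from kroghadc import TumorPenetrationModel, nominal_parameters

model = TumorPenetrationModel(nominal_parameters())  # 1 mg/kg, 1e5 rec/cell
result = model.run()
print(result.summary())
```

```
Krogh-cylinder ADC simulation
================================================================
dose              1 mg/kg   (C0 = 66.67 nM)
receptors/cell    100000   (Tinit = 77.43 nM)
KD                0.1 nM    cleavage: lysosomal
geometry          Rcap 8 um, RKrogh 72 um, step 1 um (65 nodes)
horizon           30 d, output 721 points
----------------------------------------------------------------
max shrinkage     -1.87 %  (nadir at 1.08 d)
final mass change +339.1 % at 30 d
================================================================
```

Reading the numbers: a 1 mg/kg bolus of a 150 kDa ADC in a 20 g mouse gives
an initial plasma concentration of 66.7 nM; 1e5 receptors per 8 μm cell
correspond to 77.4 nM of receptor in the tissue. At this receptor density
the payload barely clears its 3 nM potency threshold across the cylinder, so
the tumor dips only 1.9% below baseline around day 1 and then regrows,
reaching 4.4× its initial mass by day 30. Dropping `nRec` to 1e4 turns the
same dose into a 55% shrinkage with a nadir around day 17; raising it to 1e6
confines the payload to a thin perivascular shell and the tumor never
shrinks at all — the binding-site barrier in action.

The design-space studies are packaged as sweep presets:

```python
from kroghadc import preset, run_sweep

table = run_sweep(preset("fig10_bystander"))   # payload re-entry study
shrink = table[table.metric == "max_shrinkage"]
print(shrink[["kin_over_kout", "value"]].to_string(index=False))
```

```
 kin_over_kout      value
           0.0  -1.870385
           1.0  -7.012364
          10.0 -61.092248
         100.0 -78.441494
```

Payload re-entry into cells (bystander killing) becomes decisive only once
the re-entry rate exceeds the cytosolic efflux rate: ratio 1 stays near the
no-re-entry baseline while ratios 10 and 100 collapse the tumor.

The same functionality is available from the shell:

```bash
kroghadc run --preset nominal --override dose=10 --outdir out/run10
kroghadc sweep --preset fig7_vascularization --outdir out/fig7
```

`run` writes `timeseries.csv`, per-species radial-profile CSVs and a
`manifest.json` (resolved parameters, config hash, solver diagnostics);
`sweep` writes a tidy long-format `results.csv`. Reruns with the same
configuration are byte-identical.

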