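# Methods

## Model overview

`kroghadc` simulates the pharmacology of an antibody-drug conjugate (ADC)
inside a single Krogh cylinder: an annulus of tumor tissue between a central
capillary of radius R_cap and an outer radius R_Krogh equal to half the mean
intercapillary distance. The model chains five mechanisms:

1. **Plasma kinetics.** A biexponential two-compartment antibody profile
   C_plasma(t) = C0·(A·e^(−ka·t) + B·e^(−kb·t)), A + B = 1, shared by all
   linkers. The initial concentration C0 converts an mg/kg IV bolus to nM
   using the animal's body weight (20 g), plasma volume (2 mL) and the ADC
   molar mass (150 kDa, a typical IgG; the molar mass is a package parameter
   because mg/kg dosing cannot otherwise be expressed in molar units).
   Axial gradients along the capillary are neglected (antibody extravasation
   is slow compared with perfusion), so one plasma value drives the whole
   cylinder. Repeated dosing superposes identical profiles.

2. **Extravasation and interstitial transport.** Free ADC enters the tissue
   through the capillary wall at permeability P and diffuses radially with
   effective diffusivity D. Transport is diffusion-only (tumors lack
   functional lymphatics, suppressing convection) and one-dimensional in r.
   Concentrations of free ADC and free receptor are carried on a
   total-tissue-volume basis; dividing by the void fraction ε gives the
   interstitial concentrations that enter the binding law and the wall flux.

3. **Binding and endocytic trafficking.** At each radius: reversible binding
   Rxn = kon·(C/ε)·(T/ε)·Γ − koff·B with koff = kon·K_D, where the local
   tumor cell mass Γ scales the available receptor. Receptors are
   synthesized at Rs, internalize at kinT, and exit endosomes at keT with
   fraction feT recycling and (1 − feT) degraded; the ADC-receptor complex
   traffics analogously (kinB, keB, feB). Degraded complexes leave the
   receptor pool; recycled complexes return to the surface with payload
   intact (payload release is tied solely to the degradation/endosomal
   release terms).

4. **Payload kinetics.** Lysosomal degradation of the complex (non-cleavable
   linker) releases DAR payload molecules per antibody into the cytosol;
   with a cleavable linker the release term switches to the endosomal entry
   flux kinB·B·DAR and the trafficking equations are otherwise unchanged.
   Cytosolic payload effluxes at kout = ln2/t_p. Interstitial payload
   diffuses with D_p and, when bystander re-entry is enabled, re-enters
   cells at kin_payload acting on the interstitial concentration C_p,ext/ε.

5. **Tumor mass dynamics.** Per node, proliferating (P) and quiescent (Q)
   cell mass follow
   dP/dt = (γ − α − k_kill·(Cp/Γ)·E50)·P + β·Q, dQ/dt = α·P − β·Q, with
   Γ = P + Q normalized to 1 at dosing and E50 a Hill switch on x = Cp/Γ
   with threshold IC50 and Hill coefficient h. Only proliferating cells grow
   and are drug-sensitive. γ and α are fixed by requiring that the
   drug-free system doubles its total mass at the doubling time t_d while
   preserving P/Q = r_t:

       γ = (ln2/t_d)·(r_t + 1)/r_t,      α = (ln2/t_d + β)/r_t.

   With these, (P, Q) ∝ (r_t, 1) is an eigenvector with eigenvalue ln2/t_d,
   which the test suite verifies both algebraically and by integration.

The reported output is the annular volume average ⟨Γ⟩ expressed as a %
change from its value at dosing; the maximum shrinkage is the most negative
value of that curve (clamped to 0 when the tumor never shrinks).

## Closures and unit conventions

Several quantities needed by the equations are not primitive inputs:

* **Initial receptor concentration.** T_init = #Rec/(N_A·V_cell) with
  V_cell = 4/3·π·R_cell³; 1e5 receptors in an 8 μm cell give ≈ 77.4 nM on a
  total-tissue basis.
* **Receptor synthesis rate.** Rs = kinT·(1 − feT)·T_init, the unique value
  that makes the drug-free surface/endosome receptor pool stationary at
  T_init. Any other closure would make the pre-dose system drift.
* **Kill-rate scale.** The kill term (Cp/Γ)·E50 has concentration units; a
  scale k_kill (default 1 per nM per day, exposed as `kill_rate_scale`)
  converts it to a first-order rate. The default makes the nM value of the
  normalized payload act directly as a per-day kill rate.
* **Units.** Inputs are accepted in their conventional mixed units (1/min,
  1/day, cm/s, cm²/s, μm, nM); internally everything is converted once to
  hours/μm/nM. At micrometre scale this keeps diffusivities O(1e4-1e6)
  instead of O(1e-7), away from underflow, and makes every rate directly
  comparable. The conversion is involutive and reversible, and configuration
  files always use the external units.

* **Proliferating-to-quiescent ratio.** The nominal operating point uses
  r_t = 0.1/0.9 (10% of cell mass proliferating); study axes expressed as a
  proliferating *fraction* f are converted by r_t = f/(1 − f).

## Numerical scheme

* **Discretization.** Node-centred radial grid from R_cap to R_Krogh at a
  uniform step (default 1 μm; a short final interval lands exactly on
  R_Krogh when the step does not divide the annulus). The cylindrical
  operator D·(C'' + C'/r) is discretized in finite-volume (flux) form:
  interface fluxes −D·r·∂C/∂r differenced over annular cell volumes ∝ r·Δr.
  On a uniform grid the interior stencil is algebraically identical to
  second-order central differences (exact for quadratics; empirically
  O(step²) on smooth profiles), and the flux form makes the discrete
  annular mean *exactly* conserved under no-flux walls — the conservation
  test asserts the weighted column sums of the operator vanish to rounding.
* **Boundary conditions.** Outer wall: no flux (symmetry between
  neighbouring cylinders). Inner wall for ADC: transcapillary exchange
  P·(C_plasma − C/ε) as a source on the innermost cell, oriented so that
  drug enters the tissue while plasma exceeds the interstitial
  concentration; the uniform state C = ε·C_plasma is an exact discrete
  equilibrium.
* **Payload boundary.** The free payload is a small molecule and exchanges
  with blood far faster than the antibody; its interstitial pool washes out
  through the capillary wall at its own permeability `Pvasc_payload`
  (default 1e-5 cm/s, a typical small-molecule transcapillary permeability,
  ~40-fold above the antibody's). This washout is what terminates bystander
  recycling: with re-entry enabled, payload cycles between cytosol and
  interstitium, and without any leak the cylinder would accumulate payload
  without bound, making even a re-entry/efflux ratio of 1 lethal — contrary
  to the known behavior of bystander payloads, where significant
  neighbour-cell killing requires re-entry faster than efflux. With the
  washout in place the steep decline sets in between ratios 1 and 10. A
  closed-wall variant (`payload_capillary_sink = false`) is retained for
  sensitivity analysis.
* **Integration.** The stacked system (9 species × nodes, 585 states at the
  default grid) is stiff: binding equilibrates within minutes while growth
  acts over weeks, and the steep Hill switch (h = 100) adds sharp temporal
  transitions. It is integrated with BDF (`scipy.integrate.solve_ivp`)
  using the exact Jacobian sparsity pattern (within-node blocks plus
  tridiagonal coupling for the two diffusing species), rtol 1e-6 and atol
  1e-9 nM. Tightening rtol tenfold moves the maximum-shrinkage metric by
  <0.1%, and halving the grid step moves it by <1% (both asserted in the
  test suite, justifying the default resolution).
* **Noise floor.** Shrinkage dips smaller than 1e-9% of initial mass are
  clamped to zero: the volume average of Γ carries one-ulp floating-point
  rounding (~1e-14%), which must not be read as tumor response.
* **Degenerate inputs.** Where local cell mass falls below 1e-12 the
  normalized payload is treated as zero (dead tissue cannot amplify the
  kill); ε is constrained to (0, 1); r_t = 0 is rejected (the growth-rate
  closure divides by r_t); the Hill switch is evaluated as a logistic in
  log space so arbitrarily steep coefficients cannot overflow.

## Spatial resolution of the kill

The kill computation is spatially resolved: Γ is tracked per node, enters
the binding flux locally, and normalizes the local payload in the Hill
switch. This is essential to the binding-site-barrier phenomenology: with
high receptor density the payload is confined near the vessel, distal tissue
escapes killing, and the volume-averaged mass keeps growing. A
cylinder-averaged alternative (`kill_averaging = "global"`) is provided for
comparison; it erases the barrier effect entirely (the highest receptor
density then shrinks *most*, because averaging spreads the near-wall payload
over the whole annulus), which is strong evidence for the resolved reading.

## Study conditions and default choices

The nominal parameter set (see `ParameterSet` defaults) is the package's
operating point: 1 mg/kg single IV dose, KD = 0.1 nM, 1e5 receptors/cell,
lysosomal release, t_p = 7 h, no bystander re-entry, t_d = 10 d,
r_t = 0.1/0.9, β = 0.05/d, IC50 = 3 nM, h = 100, 30-day horizon, 1 μm grid.
Design-space sweeps vary one or two of these at a time; sweep presets use
the published grids (receptor density 1e3-1e6; dose 1/5/10/30 mg/kg; KD
1e-3-1e2 nM; R_Krogh 40/72/120/168 μm; t_p 1/3/7/15/25 h; kin/kout
0/1/10/100) with 13-point log grids where a continuous axis is needed.
The directional test suite uses a 2 μm step for the multi-run studies; the
grid-convergence test ties that resolution to the 1 μm reference.

## What the simulations do and do not show

All experiments are self-contained simulations of an idealized, homogeneous
single-cylinder tumor: no inter-capillary heterogeneity, no convection, no
receptor expression in healthy tissue (hence no target-mediated plasma
disposition), one common plasma profile regardless of linker, no payload
release from lysed cells, and no resistance or cell-cycle structure beyond
the P/Q split. Passing tests therefore demonstrate internal consistency and
the mechanistic logic of penetration/trafficking/kill coupling — not
quantitative prediction for any specific xenograft. Calibration to a real
system would adjust t_d, r_t, R_Krogh, receptor count and IC50 at minimum.

Two caveats surfaced by the simulations themselves:

* At the low-receptor end (1e3 vs 1e4 receptors/cell at 1 mg/kg) the
  maximum-shrinkage curve is nearly flat: both densities deliver payload
  above the IC50 threshold through the whole annulus, and the kill
  saturates. In this regime the model gives 1e4 a slightly (~2 percentage
  points) deeper nadir than 1e3, because the tenfold higher payload stays
  above threshold longer; the qualitative barrier behavior (rapid loss of
  efficacy above ~1e5, none at 1e6) is unaffected.
* The nominal t_p = 7 h sits outside the quoted plausible range (16-22 h)
  of the same table it comes from; both are accepted as given and neither
  is reconciled.
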