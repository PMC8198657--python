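# nephrosim

Steady-state, epithelial-cell-based model of solute and water transport
along the nephrons of a human kidney, built to study glucose and
electrolyte handling in diabetes and under SGLT2 inhibition.

## Who this is for

Renal physiologists and modellers who want a desk-scale, scriptable model
of whole-kidney transport: how the proximal tubule reclaims the filtered
glucose load through the SGLT2/SGLT1 + GLUT system, how diabetic
hyperfiltration and tubular hypertrophy reshape Na⁺ handling, what the
macula densa "sees" (the tubuloglomerular feedback signal, luminal [Cl⁻]
at the cortical TAL outlet), and how all of that shifts when SGLT2 is
pharmacologically inhibited.

## The model

The kidney is represented by six nephron classes — one superficial class
(85% of a million nephrons, SNGFR 100 nL/min) and five juxtamedullary
classes (15% combined, SNGFR 133 nL/min) whose loops of Henle turn at
staggered depths of the inner medulla — giving a single-kidney GFR of
105 mL/min (151.2 L/day). Connecting tubules coalesce 10:1 into cortical
collecting ducts; inner-medullary ducts coalesce successively toward the
papilla.

Each segment is a tubule lined by epithelial cells. At every axial grid
point the cell compartment satisfies an algebraic system — per-solute mass
balance (apical influx = basolateral efflux), cytosolic electroneutrality
against a fixed impermeant anion, and zero net transepithelial current —
solved by damped Newton iteration. Membrane transport uses saturable
reversible carriers (SGLT2/SGLT1 with 1:1 / 2:1 Na:glucose coupling,
GLUT1/2, NKCC2, NCC, NHE3, KCl cotransport), a Michaelis Na⁺/K⁺-ATPase
(3:2 stoichiometry), Goldman–Hodgkin–Katz electrodiffusion for channels
and the paracellular route (plus solvent drag), and osmotic water flux.
Luminal mass balances

    dFv/dx = −2πr·Jv ,   d(Fv·cᵢ)/dx = −2πr·Jᵢ

are integrated segment by segment down each nephron class, through the
coalescing collecting duct, to the urine. Transported solutes are Na⁺,
K⁺, Cl⁻ (the lumped permeant monovalent anion), urea and glucose.

Diabetes scenarios follow the published parameterisation: plasma glucose
8.6 mM (moderate) or 20 mM (severe), SNGFR +27%/+10%
(superficial/juxtamedullary), proximal and distal hypertrophy, SGLT2 +38%,
GLUT2 +50%, NKCC2 +10%, SGLT1 −33%, segment-specific Na⁺/K⁺-ATPase
increases and collecting-duct water-permeability increases. SGLT2
inhibition is 90% capacity blockade (acute: plasma glucose unchanged; GFR
lowered 3% in the non-diabetic kidney and normalised to 151.2 L/day in
diabetes).

Because the baseline human transport parameters are under-determined, a
small set of scale factors is calibrated against published whole-kidney
anchors (non-diabetic proximal glucose fractions, the 40% excretion under
SGLT2 inhibition, macula densa [Cl⁻] 28.3 mM, physiological Na⁺
excretion); every diabetic prediction is held out of the fit. See
`docs/methods.md` for the full account, including the model's known
limitations.

## Worked example

```python
import nephrosim as ns

model = ns.KidneyModel()                       # packaged baseline
report = ns.KidneyReport.from_solution(model.solve(ns.nondiabetic()))
print(report.summary())
```

prints (numbers from the shipped baseline):

```
scenario: nondiabetic (gfr_mode=methods)
GFR: 151.1 L/day
urine volume: 0.48 L/day
filtered loads (mol/day): Na=21.2, K=0.756, Cl=21.9, urea=0.756, glucose=0.756
excretion (mol/day): Na=0.106, K=0.074, Cl=0.18, urea=0.21, glucose=0.00357
fractional excretion: Na=0.0050, K=0.0979, Cl=0.0082, urea=0.2773, glucose=0.0047
macula densa [Cl-] (mM): superficial=27.8, jm1=29.1, jm2=22.2, jm3=17.7, jm4=14.9, jm5=13.3
T_Na total/active/passive (mol/day): 21.05/21.66/-0.60
```

That is: the kidney filters 151 L/day carrying 0.756 mol/day of glucose
and excretes essentially none of it (fractional excretion 0.5%); Na⁺
fractional excretion is 0.5%; the superficial macula densa senses
27.8 mM Cl⁻; total tubular Na⁺ reabsorption is ~21 mol/day, essentially
all pump-driven.

The same from the shell:

```bash
nephrosim arch                 # population/geometry table, GFR
nephrosim run --scenario dm_sev --sglt2i   # severe diabetes + SGLT2i
nephrosim calibrate --out fitted.yaml      # re-run the calibration
nephrosim report --scenario dm_mod --ref nd --out tables/
```

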