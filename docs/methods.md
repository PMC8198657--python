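# Methods

This note documents the model equations, the numerical scheme, the
parameter choices that were genuinely open, and the limits of what the
package reproduces.

## Scope and state variables

The model computes the steady state of tubular fluid flow, hydrostatic
pressure, luminal solute concentrations and — in every segment except the
descending limbs — cytosolic concentrations and membrane potentials, for
six nephron classes and a shared, coalescing collecting duct. Transported
solutes are Na⁺, K⁺, Cl⁻, urea and glucose, plus water. Acid–base
chemistry is out of scope; to keep filtrate, cell and interstitium
electroneutral without carbonate buffers, **"Cl⁻" denotes the total
permeant monovalent anion** (chloride plus the bicarbonate-family anions),
so plasma "Cl⁻" is 145 mM rather than the true ~110 mM. Macula densa
chloride anchors are matched with this lumped anion; the calibration
absorbs the offset. Consistently, NHE3 — physiologically a Na⁺/H⁺
exchanger whose secreted proton titrates luminal buffer — is implemented
as an electroneutral, saturable coupled entry of Na⁺ plus one lumped
anion with a fixed proton-side occupancy factor β.

Filtration is a boundary condition (SNGFR is prescribed per class), and
there is no vasculature: the medullary interstitium is a prescribed
boundary condition (below). Closed-loop tubuloglomerular feedback,
oxygen/metabolic accounting and transient dynamics are not modelled.

## Architecture

One million nephrons: 85% superficial (SNGFR 100 nL/min, loops turning at
the outer–inner medullary boundary) and five juxtamedullary classes with
fractions {6, 4, 2.5, 2, 0.5}% and SNGFR 133 nL/min, turning at
{20, 40, 60, 80, 100}% of the inner-medullary depth — fractions decrease
with depth so most long loops turn in the upper inner medulla. Segment
chain: PCT → S3 → descending limb(s) → ascending limb(s) → DCT → CNT,
then 10:1 coalescence into cortical collecting ducts and pairwise IMCD
merges at 20/40/60/80% of the inner medulla (6,250 papillary ducts).
Default geometry (PCT 1.0 cm × 25 µm, TAL 1.0/0.5 cm × 20 µm, IMCD
1.5 cm × 28 µm, …) lives in `nephrosim/data/default_params.yaml`; nothing
is hard-coded. Juxtamedullary proximal tubules are 33% longer than
superficial ones, matching their higher SNGFR so the proximal load per
membrane area is class-independent.

## Flux laws

* **Carriers** (SGLT2/SGLT1, GLUT1/2, NKCC2, NCC, NHE3, KCl): reversible
  saturable forms `J = vmax (occ_cis − occ_trans)` with Michaelis
  occupancies; Na-coupled glucose flux carries exactly 1 (SGLT2) or 2
  (SGLT1) Na⁺ per glucose. The forms are voltage-independent (a
  deliberate simplification; see Limitations). NKCC2 uses one lumped
  site per substrate with `Km(Cl) = 300 mM`, far above the luminal range,
  so the diluting segment operates first-order in luminal Cl⁻ — its
  outlet concentration then responds exponentially to the
  capacity-to-flow ratio, which is what makes the macula densa signal
  flow-sensitive. Its Na and K sites are nearly saturated
  (`Km(Na) = 3 mM`, `Km(K) = 0.3 mM`, luminal K⁺ maintained by apical
  recycling), so delivery composition does not mask the flow signal.
* **Pump**: `J_Na = vmax (Na/(Na+6))³`, 3 Na⁺ out : 2 K⁺ in.
* **Channels and paracellular diffusion**: Goldman–Hodgkin–Katz
  constant-field flux (Fickian for neutral solutes), plus solvent drag
  `(1−σ) Jv c̄` with the log-mean concentration across the junction.
* **Water**: `Jv = Pf V̄w Σᵢ σᵢ Δcᵢ` with a small van 't Hoff–converted
  hydraulic term at the tight junction. Transcellular water uses a
  composite lumen→interstitium permeability (no cell water balance).
* **Torque**: proximal transcellular transporter density scales with
  `1 + C_T (τ/τ_ref − 1)`, clamped to [0.2, 3]. The microvillous-drag
  proxy is evaluated at reference radius — the density signal responds to
  *flow* relative to a fixed reference profile (linear, inlet → 35% at
  the S3 outlet) — because hypertrophied-radius effects are already
  expressed by the geometry multipliers, and diabetic hyperfiltration
  must augment, not depress, transcellular density. `C_T = 0.9`.

## The epithelial cell problem

Per grid point, unknowns are the five cytosolic concentrations and the
cell and lumen potentials (interstitium grounded). Equations: five mass
balances (apical = basolateral flux), electroneutrality against a fixed
impermeant cytosolic anion, and zero net transepithelial current (open
circuit). NHE3 contributes no current (electroneutral pair entry). The
system is solved in log-concentration / scaled-potential variables by a
damped Newton method with a one-batch finite-difference Jacobian,
Levenberg regularisation on singular iterates, iterate clamping
(10⁻⁴–10⁴ mM, ±150 mV), and warm starts continued along the axis and
across segment boundaries; tolerance 10⁻¹⁰ on the scaled residual. A
transient-ODE cross-check (tests) confirms the root is the dynamically
stable steady state.

## Axial integration

Conservative variables (Fv and per-solute flows) are advanced on a fixed
cell-centred grid (default 40 points/segment) with an explicit
trapezoidal (Heun) predictor–corrector plus deterministic adaptive
sub-stepping, triggered by (i) >20% relative change in a step, (ii) any
solute flow crossing zero beyond a tiny tolerance, and (iii) an analytic
stiffness bound `h · 2πr Pf V̄w · osm/Fv > 1.5` for the osmotic water
equation (which otherwise destabilises high-Pf segments at low flow).
Because the scheme integrates the flux integrals themselves, inlet minus
outlet equals accumulated transmural transport exactly, so whole-kidney
conservation holds to machine precision and the transcellular/paracellular
split sums exactly to the total. Doubling the grid changes every reported
quantity by < 0.2% (asserted in tests). Descending limbs use a
single-barrier transmural law (no cell). Pressure follows Poiseuille flow
(µ = 7.2·10⁻³ g cm⁻¹ s⁻¹) and is diagnostic only. Everything is
deterministic: repeated runs are bit-identical.

## Interstitial boundary condition

Cortex equals plasma. Total osmolality rises to 600 mosm at the
outer–inner medullary boundary (NaCl-driven, with the rise concentrated
in the inner stripe: only +30 mosm across the outer stripe, matching the
shallow outer-stripe gradient of the real corticomedullary profile) and
to 1,200 mosm at the papillary tip (half NaCl, half urea). K⁺ stays at
plasma; interstitial glucose equals plasma glucose at all depths. The
increments are referenced to a nominal 290 mosm plasma and scaled by a
calibration knob.

## Scenarios

Declarative overlays (`scenarios.py`) encode the study conditions listed
in the README. Two interpretation choices matter:

* The published moderate-diabetes GFR is internally inconsistent (+10%
  stated in the results vs ~+24% implied by the per-class SNGFR
  multipliers).
  `moderate_diabetes()` follows the multipliers;
  `gfr_mode="results_text"` rescales to +10%. Macula densa comparisons
  use the results-text variant (the variant consistent with the published
  macula densa values); every report records the variant used.
* "Distal segments" for diabetic diameter hypertrophy are interpreted as
  mTAL through IMCD (length: DCT + CNT). Including the TAL is required
  for diabetic TAL transport capacity — and hence TAL Na⁺ reabsorption —
  to grow despite reduced loop delivery.

## Calibration

Stage 1 (glucose) tunes four scale factors (SGLT2, SGLT1, GLUT, proximal
junctional glucose permeability) against non-diabetic and
inhibition anchors; stage 2 (sodium) tunes NKCC2 and distal-Na scales
against the macula densa anchor and a physiological Na⁺ excretion.
The objective is tolerance-banded weighted least squares: anchors
contribute nothing while inside their published tolerance and grow
quadratically outside. The banding stops the (deterministic, derivative-
free Nelder–Mead) optimiser from sliding along weakly identified
parameter directions once all anchors are acceptable — movement there
would silently trade held-out accuracy for meaningless fit polish. All
diabetic and diabetic-inhibition predictions are held out of both
objectives (asserted by test). Inside the optimisation loop the glucose
stage evaluates a proximal-only surrogate (downstream segments carry no
meaningful glucose transport) at 30 grid points; final reports always
re-evaluate the full kidney at the default grid. The packaged parameter
file ships at the calibrated optimum, so re-running calibration verifies
the anchors in a handful of simplex evaluations.

## Parameter defaults worth knowing

| parameter | default | why |
|---|---|---|
| SGLT2 `vmax` (PCT) | 3.16·10⁻³ µmol cm⁻² s⁻¹ | sized so the non-diabetic PCT reclaims 97% of filtered glucose while the 10% remnant under inhibition leaves ~15–17% |
| SGLT2 `Km(glucose)` | 1 mM | sets the axial approach to the static head; at 2 mM the trailing few percent of filtered glucose escape |
| SGLT `Km(Na)` | 60 mM | with passive GLUT exit, cytosolic glucose cannot fall below interstitial; a weak Na site deepens the lumen-side static head enough for 97% reclamation |
| GLUT1 `Km` | 15 mM | at the classical ~2 mM the carrier saturates at diabetic interstitial glucose and caps S3 basolateral exit |
| S3 junctional glucose permeability | 2·10⁻⁵ cm/s | carries the inhibited-case paracellular glucose reabsorption; bounded above by non-diabetic backleak (< 0.5% excretion) |
| PCT pump `vmax` | 1.8·10⁻¹ µmol cm⁻² s⁻¹ | keeps cytosolic Na⁺ ≈ 5 mM, deepening the SGLT static head |
| NKCC2 `vmax` (mTAL/cTAL) | 2.95/2.53·10⁻² | places the non-diabetic macula densa [Cl⁻] at 28.3 mM in the flow-sensitive kinetic regime |
| TAL junctional Cl⁻ permeability | 10⁻⁶ cm/s | a larger backleak floors the diluting segment and pins the macula densa signal |
| torque `C_T` | 0.9 | balances severe-diabetes glucose excretion (16%) against the macula densa decrease |

## Limitations — what passing tests do and do not show

The synthetic conditions are exactly the published study conditions
(plasma compositions, SNGFR multipliers, hypertrophy and activity
factors); no real patient data enter anywhere, so agreement demonstrates
internal reproduction of the published model family, not clinical
validity. Known reproduction gaps, all held out of calibration and left
red in the acceptance suite with this analysis:

* **Moderate-diabetes + SGLT2i glucose excretion** computes ~60% vs the
  published 53.1%. The published model's S3 reabsorbs *more* glucose at 0.67×
  SGLT1 activity (diabetic) than at full activity (non-diabetic
  inhibition). With a voltage-independent occupancy carrier, S3 transport
  at glucose-saturating loads scales essentially with activity × area, so
  that inversion is not reproducible; the published model's six-state,
  voltage-driven SGLT kinetics evidently behave differently.
* **Diabetic macula densa [Cl⁻] magnitudes** (moderate ~16 mM vs 21.3;
  severe ~11 mM vs 18.6; both monotone and direction-correct, and both
  SGLT2i reversals correct). Two compressions add up: the diabetic PCT
  Na⁺ gain tracks its capacity multipliers (~+40%) where the published
  model reports a gradient-limited +11.8%, so loop delivery does not rise; and
  the descending-limb osmotic equilibration resets part of the flow
  signal before the TAL. The fixed-GFR variants (17.7/15.6 mM published)
  are reproduced within ±2 mM.
* **Diabetic TAL Na⁺ reabsorption** and the moderate-diabetes excretion
  directions (published: K⁺ +48%, Cl⁻ +25%, urine +35% with near-zero
  glucosuria) are the delivery-side face of the same compression: with
  the proximal gain tracking capacity, distal delivery falls slightly in
  moderate diabetes and the model predicts mild antidiuresis instead.
  Severe diabetes, where glucosuria drives the diuresis, shows the
  correct directions.
* Urea handling is phenomenological (no vasa recta recycling); urea
  fractional excretion (~28%) sits below the physiological ~40%.
* The lumen is only as electroneutral as the lumped-anion approximation;
  with ~15 solutes the published model resolves buffer chemistry we do not.
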