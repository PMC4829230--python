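# Methods

`qsdyn` simulates two bacterial quorum-sensing (QS) architectures —
the Lsr/AI-2 system with coupled positive intracellular and negative
intercellular feedback, and the canonical LuxIR/AHL positive-feedback
circuit — as per-cell signaling models embedded in a 2D finite-difference
extracellular environment, with lognormal cell-to-cell parameter
heterogeneity. The question the package is built to answer is how
*desynchronization* of QS commitment across a clonal population produces
bimodal (fractional) Lsr activation and how the two network topologies
produce different spatial activation patterns during colony growth
(outward wave vs dispersed speckles).

## The Lsr/AI-2 cell model

Each cell carries five states (all μM): local extracellular AI-2 `Ae`,
intracellular AI-2 `Ai`, phospho-AI-2 `Ap`, lsr transcript `M`, and Lsr
transporter protein `T`. Every biological influence is a named term,
assembled into

```
dAe/dt = ρ · ( V_ydgG·Ai − basal·Ae/(K_b+Ae) − V_ind·T·Ae/(K_ind+Ae) )
dAi/dt = K_synth + basal·Ae/(K_b+Ae) + V_ind·T·Ae/(K_ind+Ae)
         − V_ydgG·Ai − k_phos·Ai
dAp/dt = k_phos·Ai − d_Ap·Ap
dM/dt  = α0 + α1·Ap^h/(k2^h + Ap^h) − d_M·M
dT/dt  = k_T·M − d_T·T
```

where ρ is the cell-to-extracellular volume ratio (1 μm³ cell against a
24 μm³ grid element in the agent setting; the growing culture volume
fraction in batch). AI-2 is synthesized intracellularly (activated
methyl cycle, Lsr-independent), exported by YdgG/TqsA, re-imported
through low-affinity routes (`basal`, the principal heterogeneity axis)
and through the Lsr transporter itself, and phosphorylated by LsrK.
Phospho-AI-2 sequesters the LsrR repressor; repression is folded into
the increasing Hill term of the transcription equation rather than
carried as an explicit free-repressor state (the explicit-R variant adds
a fast binding equilibrium without changing the slow dynamics, and is
the documented alternative). Transport terms are mole-balanced across
the membrane; synthesis and phospho-AI-2 catabolism are the only
unbalanced AI-2 terms, which the conservation tests exploit.

### Parameters, units, defaults

| parameter | default | units | role |
|---|---|---|---|
| `K_synth` | 60 | μM/min | AI-2 synthesis |
| `V_ydgG` | 4 | 1/min | export rate constant |
| `basal` | 487.8 | μM/min | low-affinity import Vmax (population median) |
| `K_b` | 100 | μM | basal-import half-saturation |
| `k_phos` | 1 | 1/min | LsrK phosphorylation |
| `d_Ap` | 0.2 | 1/min | phospho-AI-2 catabolism |
| `α0`, `α1` | 6×10⁻⁵, 1 | μM/min | leak / induced transcription |
| `k2`, `h` | 480, 4 | μM, – | Hill half-saturation and coefficient |
| `d_M`, `k_T`, `d_T` | 1, 70, 0.7 | 1/min | transcript decay, translation, transporter turnover |
| `V_ind`, `K_ind` | 200, 0.3 | 1/(μM·min), μM | induced import per transporter |
| `activation_fold` | 5 | fold | QS-positive threshold on `T` over its initial value |

The basal-import median 487.8 μM/min and the Fig-6-style reference value
510 μM/min are fixed inputs; the remaining constants were calibrated
once against the uninduced batch-culture phenomenology the model must
reproduce — growth from an OD600-equivalent of 0.03 (8×10⁸ cells/mL/OD,
60 min doubling), extracellular AI-2 accumulating over hours, abrupt
transcription onset with the transporter crossing 5× its initial level
at ≈288 min (i.e. after the 4-hour mark), followed by a ≈100-fold
collapse of the shared pool — and then frozen. Two structural findings
from that calibration are worth recording. First, fractional activation
only emerges when the induction machinery responds quickly (minutes:
`d_M`, `d_T` of order 1/min): if the transporter lags, the shared pool
overshoots past every cell's ignition point and the whole population
commits. Second, synthesis must be routed through the intracellular
pool; if it is lumped as direct secretion, per-cell `K_synth`
heterogeneity has no route to the cell's own phospho-AI-2 and the
`K_synth` desynchronization effect disappears.

The reference batch integrator is LSODA (stiff-capable) at rtol 1e-8 /
atol 1e-10. The agent engine advances cells with an explicit Euler
scheme sub-stepped per engine step; a sub-step that would drive any
intracellular state negative or change it by more than 50% is rejected
and retried at half the step (clipping to zero is never used — it would
silently destroy mole balance). The explicit path is validated against
the implicit reference: with identical, well-mixed cells the two
activation times agree within 5%.

## The LuxIR/AHL cell model

LuxIR is modeled heuristically: cells synthesize AHL at a per-cell
baseline rate (population mean 1 μM/min); once intracellular AHL
*exceeds* 2.9 μM the synthesis rate ramps linearly to 10 μM/min over
30 min (standing in for the circuit's cooperativity and expression lag);
membrane exchange is conductance-driven, 0.6 min⁻¹ times the
intracellular-extracellular concentration difference. The ramp is
latched: a later dip below threshold never resets it. A cell is "active"
when its synthesis rate reaches 5× its own baseline — for a baseline of
1 μM/min that is 40/3 min after crossing. The threshold comparison is
against the instantaneous intracellular concentration (not smoothed).
No AHL degradation is modeled by default (an optional first-order loss
rate is exposed and defaults to 0).

## Heterogeneity and growth

One chosen parameter (`basal`, `K_synth`, `V_ydgG`, or the LuxIR
baseline rate) is assigned per cell from a lognormal distribution at
birth and held for the cell's lifetime. The distribution is specified by
the median (or the mean of its logarithm) and the standard deviation σ
of that logarithm, with the *base* of the logarithm explicit
(`log_base`): σ = 0.0225 applied to the base-10 logarithm gives a
coefficient of variation of 0.052, whereas on the natural logarithm it
gives 0.0225. Both conventions appear in the QS literature; the
colony-study presets use base 10 with σ = 0.0225 (CV 5.2%), the
σ-sweep studies use the natural-log convention with σ up to 0.025.

Growth is a supplied population rate (default ln2/60 min⁻¹) converted to
per-cell doubling times, normally distributed with a relative spread of
0.05 and truncated at a positive floor; each cell carries a countdown
and divides at the first engine step after expiry. Daughters copy the
parent's state variables, QS flag and transporter reference, but redraw
the varied parameter and the doubling time, and are placed by the
motility mode's rule. The daughter's transporter reference is copied
verbatim (protein dilution between daughters is not modeled).

## Environment and numerics

The domain (default 500×500 μm, implied depth 6 μm) is discretized into
square elements (default 2 μm edge, 24 μm³ volume); the master engine
step defaults to 0.0667 s. Diffusion is explicit FTCS with no-flux
(mirror) boundaries, automatically sub-stepped so that
λ = D·dt_sub/dx² ≤ 0.2 — the linear stability bound is 0.25, but at
exactly 0.25 the odd-even (checkerboard) mode has amplification −1 and
never decays, which the analytic-Gaussian oracle exposes immediately.
The scheme conserves mass to round-off and respects the discrete
maximum principle. Cell–element exchange is applied inside the per-cell
update, sequentially in cell index, so that import is supply-limited: a
withdrawal larger than the element's content takes exactly what is
present and the cell's update is scaled accordingly.

The molecular diffusivity default comes from the Wilke–Chang
correlation, `D = 7.4e-8 (φ M_solvent)^0.5 T / (η V_solute^0.6)` cm²/s,
evaluated for a DPD-scale solute (Le Bas molar volume 133 cm³/mol) in
water at 310 K with the revised association factor φ = 2.26, giving
≈1.1×10³ μm²/s.

**Diffusivity regimes.** At the molecular D the extracellular field
mixes across even the full 500 μm domain within a minute, so activation
order is set purely by each cell's parameters and no colony-scale
spatial pattern can form; a scale analysis shows colony-scale gradients
survive only for effective diffusivities below a few tens of μm²/s.
Colony-on-surface transport through a boundary layer is the regime in
which the patterning phenomena exist, so the colony-growth presets use
hindered effective diffusivities (18 μm²/s for the Lsr colony, 6 μm²/s
for the LuxIR wave study, 1 μm²/s for the motility-mode comparison),
all config-exposed. Planktonic and batch work keeps the molecular
default.

## Engine

Per master step, in fixed order: (1) swim motility — step lengths from
Normal(20 μm/s · dt, CV 0.05) truncated at 0, uniform directions,
mirror reflection at the impermeable walls applied per axis (overshoot
d ends d inside), and a hard cap of 3 cells per element (a blocked move
leaves the cell in place); (2) per-cell signaling with local exchange;
(3) field diffusion; (4) division — swim daughters take the parent's
element or a free neighbor; colony daughters at the rim occupy a free
adjacent element uniformly at random, interior daughters push a chain
of cells one element outward along the breadth-first shortest path
through the colony to unoccupied space (equidistant goals tie-broken
uniformly), which covers both phrasings of the pushing rule in the
source material (toward the nearest colony edge / shortest path to
free space) whenever they coincide and prefers the shortest-path
reading when they do not; (5) classification and recording (default
cadence 1 min, field snapshots every 10 min). QS classification is
bookkeeping only and never feeds back on the dynamics; the recorded
flag is latched (commitment is one-way). Four independent seeded
streams (placement, motility, heterogeneity, division) make every run
bit-reproducible from its configuration.

The initial cell count follows OD600-equivalent 0.03 × 8×10⁸
cells·mL⁻¹·OD⁻¹ × domain volume (36 cells at full scale); reduced
configurations override the count explicitly.

## Analysis definitions

* **Activation time** of a population trace f(t): fit a line g(t) over
  the 12–152 min baseline window; the activation time is the first
  sample at or after the window's end with f − g > 2g. The criterion is
  meaningless where g ≤ 0, which is why detection starts at the window's
  end. Applied to the mean phospho-AI-2 trace for population records;
  per-cell activation uses the classification flags directly.
* **Local heterogeneity** at radius r (default 10 μm; the colony
  contrast uses 5 μm): the fraction of cell pairs within r whose QS
  states differ, normalized by 2p(1−p) at activated fraction p, so an
  independent random assignment scores ≈1 and a perfectly sorted
  arrangement 0. The measure is invariant to relabeling active and
  inactive. This discordant-pair definition is this package's choice;
  its null is exactly the probabilistic-assignment control used to
  contextualize it.
* **Induction-center bias**: per replicate, at first-activation time,
  the centers of mass of all cells and of activated cells; across
  replicates, one least-squares line of activation-center on
  colony-center with x and y pooled. A slope above 1 means activation
  begins closer to the nearest no-flux boundary than the colony itself
  sits.
* Median nearest-neighbor distance, activated fraction, extracellular
  autoinducer per induced cell, and first-activator statistics are
  literal implementations of their names; all are recomputable from a
  stored `RunRecord` alone.

## Reduced study conditions

The full-scale configuration (500 μm, 0.0667 s steps, 36 founders,
≥400 simulated minutes) costs hours of compute per run. The shipped
study presets compress it to seconds: domains of 80–200 μm, 30–100
founder cells, 1 s engine steps, and elements of 2–4 μm. Cell density is
therefore well above the OD-derived value and autoinduction happens at
~60–90 simulated minutes rather than ~5 hours. What is preserved — and
what the tests assert — are the mechanisms and orderings: terminal
activated fraction non-increasing in σ for each varied parameter;
near-complete activation at σ = 0; winner-take-all dominance in the
shared pool; colony growth activating earlier and freezing lower than
matched swimmers; the LuxIR wave nucleating inside the colony and
spreading contiguously while Lsr activation stays dispersed; activation
centers skewed toward no-flux boundaries; and Lsr first activators drawn
from the upper tail of the basal distribution.

Known reduced-scale distortions: (i) absolute activation times and
fractions are not those of the full-scale study; (ii) the LuxIR
first-activator *mean* falls slightly below the population mean here —
the shorter ramp-to-5×-fold of low-baseline cells competes with the
earlier threshold crossing of high-baseline cells, and at compressed
time scales the former wins — whereas with slower pool growth the
crossing order dominates; the robust LuxIR signature, a wider
normalized first-activator spread than Lsr's, is scale-stable and is
what the test checks.

## Other limitations

* The two-cell shared-pool competition is knife-edge at long horizons:
  any basal deficit leaves the second cell uninduced, so the
  "threshold" basal value sits just below the first cell's rate.
* The synthetic environment has no autoinducer decay in the medium, no
  chemotaxis, no nutrient fields or death; growth rate is an input, not
  an emergent property; colony mechanics cover only initial, space-
  filling development. None of the tests therefore say anything about
  late-stage colony or biofilm morphology.
* The SBML layer covers the subset of SBML L3 needed to round-trip this
  model (species, parameters, irreversible reactions with content-MathML
  rate laws); it is not a general SBML reader.
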