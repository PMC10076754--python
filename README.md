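# deha-pbk

Physiologically based biokinetic (PBK) modelling of the plasticiser
di(2-ethylhexyl) adipate (**DEHA**) and its monoester metabolite
mono-2-ethylhexyl adipate (**MEHA**), built for interpreting human urinary
biomonitoring of a single oral dose. DEHA is a widely used non-phthalate
plasticiser (food-contact films, PVC, coatings); population exposure is
assessed from spot urine concentrations of its side-chain-oxidised specific
metabolites (5OH-MEHA, 5cx-MEPA, 5oxo-MEHA) and the non-specific hydrolysis
product adipic acid (AA). Turning those urine measurements back into an
ingested dose — reverse dosimetry — requires a kinetic model of absorption,
distribution, metabolism and urinary elimination, with quantified
uncertainty. That is what this package provides, aimed at toxicokinetic
modellers and exposure scientists.

## The model

A parent + metabolite compartmental ODE system (amounts in mg, time in h):

* **Dual oral uptake.** Of an oral dose *D*, a fraction
  `1 − FracAbsorbed` passes to faeces. The absorbed dose splits between a
  **portal route** (`FracDOSEHep`: first-order absorption from the stomach
  and intestinal lumen into splanchnic tissue, draining into the liver and
  hence subject to first-pass metabolism) and a **lymphatic route** (the
  complement: uptake via the intestinal lacteals, held for `Lymphlag` hours
  and then released first-order at `K1_Lymph` directly into venous blood,
  bypassing the liver). The interplay of the fast portal and delayed
  lymphatic routes produces the bimodal urinary excretion profiles seen in
  volunteer data.
* **Flow-limited distribution with arterial binding.** Tissues (adipose,
  liver, gut, stomach, slowly/rapidly perfused, and a blood reservoir with
  plasma/blood-cell partitioning) exchange with a venous mixing node at
  their share of cardiac output; only the free fraction `(1 − FB)` of
  arterial chemical distributes into tissue, and each tissue returns blood
  at `C_tissue / PC`, so binding also governs delivery to the metabolising
  organs.
* **Metabolism.** DEHA → MEHA in liver and gut; MEHA is cleared in the
  liver alone. Whole-organ intrinsic clearances are scaled from depletion
  half-lives by in vitro–in vivo extrapolation:
  `CL = (ln2 / t½) · (1 / C_protein) · MPY · M_organ`, with MPY the
  microsomal protein yield (mg g⁻¹). Fractions `FracMetab_OH` /
  `FracMetab_cx` of metabolised MEHA are routed (molar-mass corrected) to
  two well-mixed blood pools that empty first-order (`K1_OH`, `K1_cx`)
  into urine — the model counterparts of the measured metabolites.
* **Binding predictions.** The plasma fraction unbound is predicted from
  log P(octanol:water) by `fu = 1/(10^x + 1)`, `x = 0.4485·logP − 0.4782`
  (uncharged species at pH 7.4): fu ≈ 1.6×10⁻⁴ for DEHA, 7.2×10⁻³ for
  MEHA.

Around the ODE core the package implements the full analysis chain:

| stage | module |
|---|---|
| parameter/prior tables, fu and IVIVE scaling | `deha_pbk.parameters`, `deha_pbk.priors` |
| ODE simulation, mass balance, RK4 solver oracle | `deha_pbk.model` |
| urine-void processing: deposition rates, FUE, AA background, absorption bounds | `deha_pbk.biomonitoring` |
| Latin hypercube uncertainty analysis, Morris elementary-effects screening | `deha_pbk.gsa` |
| hierarchical Bayesian calibration (blocked Metropolis, truncated-normal error model) | `deha_pbk.calibration`, `deha_pbk.mcmc` |
| synthetic volunteer studies with known ground truth | `deha_pbk.synthetic` |
| command line | `deha_pbk.cli` (`deha-pbk …`) |

The calibration observable is the urinary **deposition rate**: for void *i*
at time *tᵢ*, `rate = conc·volume/(tᵢ − tᵢ₋₁)`, assigned to the interval
midpoint. The error model is a normal distribution truncated at zero,
`R_obs ~ N(μ(θ, ω_j), σ)[0,∞)`, with global parameters θ shared across
volunteers and local parameters ω_j per volunteer (15 + 2 error SDs global,
11 local × 4 volunteers).

## Worked example

```python
import numpy as np
from deha_pbk import default_parameters, simulate, mass_balance

p = default_parameters().with_updates({"BW": 81.0})
out = simulate(p, dose_mg_per_kg=0.123)          # ~10 mg oral dose
r = out.RUrine_cx                                 # 5cx-MEPA, mg/h
print(f"peak {r.max():.2e} mg/h at {out.time[np.argmax(r)]:.2f} h; "
      f"48-h excretion {out.AUrine_cx[-1]:.4f} mg")
print(mass_balance(out, p))
```

prints

```
peak 6.79e-03 mg/h at 0.55 h; 48-h excretion 0.0181 mg
mass balance: dose 9.963 mg, recovered 9.963 mg, relative error 8.915e-16
```

i.e. the urinary 5cx-MEPA deposition rate is bimodal — a sharp portal-route
peak at ~0.6 h and a second, delayed lymphatic mode near 4 h — about
0.018 mg of the ~10 mg dose is excreted as 5cx-MEPA over 48 h (the specific
metabolites carry well under 1% of the dose), and the solver conserves mass
to machine precision.

The `analysis/` directory holds the numbered end-to-end drivers:

```
01_parameterise.py         fu + IVIVE clearance + default table
02_simulate_volunteers.py  forward runs for the four study volunteers
03_uncertainty_lhs.py      200-point Latin hypercube envelopes
04_morris_screening.py     52-parameter, 371-run elementary-effects screen
05_synthesise_study.py     synthetic 4-volunteer urine-void study
06_biomonitoring.py        deposition rates, FUE, AA background, bounds
07_calibrate.py            hierarchical MCMC calibration + posterior bands
```

Each writes its tables under `results/`. See `docs/methods.md` for model
assumptions, parameter provenance, and the design choices.

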