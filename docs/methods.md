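# Methods

This note records the model, its assumptions, the parameterisation, and
the design decisions taken where the problem was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. The PBK model

### Structure

Two coupled flow-limited compartmental systems share one physiology: the
parent diester (DEHA) and its monoester (MEHA). Compartments per chemical:
adipose, liver, gut, stomach, slowly perfused, rapidly perfused, and a
blood reservoir; DEHA additionally has stomach-lumen, gut-lumen and
lymph-buffer compartments for oral uptake. Amounts are in mg, time in h,
volumes in L.

**Oral uptake.** At t = 0 the dose splits three ways: `1 − FracAbsorbed`
to faeces (recorded immediately — transit of unabsorbed material is not
modelled), and the absorbed part between the portal route
(`FracDOSEHep` → stomach lumen) and the lymphatic buffer. Portal-route
kinetics: first-order stomach absorption (`BELLYPERM`) into stomach
tissue, first-order gastric emptying (`k_gastric_emptying`, default
1 h⁻¹) into the gut lumen, first-order intestinal absorption (`GIPERM`)
into gut tissue. Stomach and gut tissues drain into the liver, so
portal-route chemical faces first-pass metabolism. The lymphatic buffer is
a zero-order hold released first-order (`K1_Lymph`) into venous blood
from `t = Lymphlag` onward — a time-shifted first-order compartment that
represents slow lacteal/thoracic-duct transport with a pure ODE rather
than delay-differential machinery. The integrator is restarted at
`t = Lymphlag` so the switch is never interior to a solver step.

**Distribution.** Flow-limited with venous equilibration around a
zero-volume arterial/venous mixing node. Tissue t receives
`Q_t · (1 − FB) · C_art` and returns `Q_t · C_t / PC_t`; binding is
described in arterial blood, so only the unbound fraction distributes.
The vascular pool itself is a storage compartment of volume
`VBldC · BW` exchanging with the node at cardiac output, with an
effective blood-cell factor `fbc = (1 − hct) + hct · P_ba` (haematocrit
0.44): this keeps the calibrated plasma/blood-cell partition coefficients
(`Pbab`, `PbaM`) kinetically meaningful (they set the vascular reservoir
capacity) while remaining a pure ODE. The reported venous concentration
is the reservoir amount over the blood volume.

**Metabolism.** DEHA → MEHA in liver and gut; MEHA cleared in liver only.
All three clearances use the same in vitro–in vivo extrapolation,
`CL = (ln2/t½) / C_protein · MPY · M_organ` (mL/min → L/h), so the
microsomal protein yields are live parameters. Clearance acts on the
venous-equilibrated tissue concentration, `CL · C_t / PC_t` (well-stirred
convention): binding already restricts *delivery* of chemical to the
metabolising organ, so the venous-equilibrated concentration is itself
proportional to `(1 − FB) · C_art` and applying a second `(1 − FB)`
factor inside the clearance term would double-count binding. That
double-counting is not innocuous: it caps hepatic extraction at ~15%
across the tabulated half-life range, which makes the elimination
half-life practically unidentifiable and leaves urinary deposition
curves that never decay — contradicting both the observed urinary
washout and the sharply resolved posterior for the hepatic half-life.
With restricted distribution and unrestricted intrinsic clearance,
extraction spans ~0.3–0.9 over the half-life range. The venous (rather
than arterial) driver also guarantees non-negativity: the metabolic sink
vanishes as the tissue empties.
Each metabolic hand-off carries the stoichiometric molar-mass ratio
(M_MEHA/M_DEHA ≈ 0.697; pool ratios likewise). Molar masses are computed
from the molecular formulae (DEHA C22H42O4 370.57; MEHA C14H26O4 258.36;
5OH-MEHA C14H26O5 274.35; 5cx-MEPA C14H24O6 288.34; 5oxo-MEHA C14H24O5
272.34; adipic acid C6H10O4 146.14 g/mol).

**Urinary pools.** Fractions `FracMetab_OH`/`FracMetab_cx` of metabolised
MEHA enter two well-mixed blood pools with no tissue distribution,
eliminated first-order into urine (`K1_OH`, `K1_cx`). These are the
observables. 5oxo-MEHA and adipic acid are *not* part of the ODE system;
they are handled by the biomonitoring module (and emulated by the
synthetic generator) because they inform absorption bounds but not the
calibration likelihood.

### Physiological bookkeeping

* Flow fractions (which sum to 96% as tabulated) are renormalised by
  assigning the residual cardiac output to the slowly perfused
  compartment; if a sampled set exceeded 100% it would be rescaled
  proportionally.
* Volume fractions are used as drawn unless their sum exceeds the
  vascularised fraction VT = 0.95 of body weight, in which case all are
  rescaled proportionally onto VT. This is needed because the marginal
  distributions (notably the lognormal adipose fraction, median ≈ 31% of
  BW) jointly exceed VT with appreciable probability; rescaling keeps
  every volume parameter active and every draw physical.
* Cardiac output scales linearly with body weight (`QC = QCC · BW`),
  matching the units of the tabulated cardiac-output constant; no
  allometric exponent is applied (configurable at the parameter level).

### Defaults

Defaults ship in `deha_pbk/data/defaults.yaml`. The in vivo DEHA hepatic
half-life default is 3 min: with near-complete first-pass extraction the
default-parameter simulation reproduces the qualitative urinary profile of
the volunteer data (bimodal, terminal 5cx-MEPA rate < 5% of peak at
48 h), whereas slower values leave an unrealistically heavy tail fed by
recirculation from the adipose depot. The calibration prior for this
parameter is nevertheless wide (lognormal, median ≈ 20 min — see
`priors.yaml` comments on its reconstruction).

### Numerics

LSODA (via `scipy.integrate.odeint`) with a numba-compiled right-hand
side; default `rtol 1e-8 / atol 1e-12` for reported simulations and
`1e-6 / 1e-10` inside MCMC. A fixed-step RK4 integrator serves as an
independent solver oracle (agreement asserted to < 0.1% relative on the
parent blood concentration). Mass balance — dose = compartments + faeces
+ metabolised, with the MEHA system converted to DEHA equivalents — is
audited by `mass_balance`; across 100 prior draws the relative error is
at solver precision (≲ 1e-13, asserted < 1e-6). States more negative
than `1e-6 × dose` abort the run; smaller excursions are clipped to zero.

## 2. Biomonitoring processing

Deposition rate of void *i*: `conc_i · volume_i / (t_i − t_{i−1})`,
assigned to the interval midpoint; the first interval starts at the dose
time (configurable). FUE (fraction of ingested parent excreted as a
metabolite) applies the molar-mass correction `M_DEHA / M_metabolite` to
the summed void masses over the dose; for adipic acid a background total
is subtracted first. The AA background rate is the mean AA deposition
rate over voids where 5cx-MEPA has washed out below 1% of its maximum
(within the 24-h AA measurement window), times 24 h. Because the model's
urinary tail decays more slowly than real volunteer data, noise-free
synthetic datasets may contain *no* qualifying voids; `aa_background`
then raises, and explicit time-point selection (`select_times`) is the
supported fallback — the identity tests use it with the last AA voids.
The absorption lower bound is ΣFUE over the four metabolites; per-analyte
fractions of *absorbed* dose are bracketed by (FUE, FUE/ΣFUE).

## 3. Sensitivity screening

A 200-point Latin hypercube (`scipy.stats.qmc`, exact one-per-stratum
marginals) maps uniform strata through each parameter's quantile
function; unbounded physiological distributions are truncated at their
5th/95th percentiles. The Morris elementary-effects screen varies 52
parameters (every model constant with a tabulated distribution, plus the
IVIVE auxiliaries; the two fu reference predictions and VT are retained
in the list for completeness and screen inert by construction) along
r = 7 randomised trajectories on a 4-level grid with jump
Δ = levels/(2(levels−1)) = 2/3, costing r(k+1) = 371 runs over the
2.5th–97.5th percentile ranges. Twelve measures are screened: DEHA and
MEHA venous concentrations at 0.5 and 5 h, and the urinary deposition
rates of the two specific metabolites at 1, 3, 5 and 10 h. Per measure,
each parameter gets μ* (mean |EE|), σ (SD of EEs), the Euclidean distance
√(μ*² + σ²) from the origin, and that distance normalised to the
per-measure maximum; parameters exceeding 0.1 on any measure pass the
screen. The elementary-effect computation is verified against a
brute-force finite-difference oracle on analytic test functions
(equality to 1e-10; exact zero σ for linear functions). The replication
test that compares the screened set with the calibrated-parameter set
uses r = 20 trajectories: at r = 7 several gut parameters sit close
enough to the 0.1 threshold that the retained set varies with the design
seed, and the higher-precision screen makes the comparison stable.

## 4. Hierarchical Bayesian calibration

Parameters split into globals θ (binding, partition coefficients,
half-lives, metabolite-pool constants — 15, plus two error SDs) and
locals ω_j (uptake-route and absorption constants and individual
physiology — 11 per volunteer, four independent prior copies). Priors are
the tabulated distributions (`priors.yaml`; reconstructed bounds are
commented there). The likelihood compares observed deposition rates with
the model's **interval-average** rate over the same void interval
(consistent with how the observation is constructed from urine
collections; instantaneous-at-midpoint prediction is available via
`prediction="midpoint"`), through a zero-truncated normal with
analyte-specific SD and half-normal(1) priors on the SDs.

Sampling is blocked random-walk Metropolis: one block for the model
globals, one log-scale block (multiplicative proposals with the Hastings
correction) for the two error SDs — their posterior scale is orders of
magnitude below the prior scale — and one block per volunteer's locals.
Proposal scales adapt per block toward 25% acceptance during a burn-in
(first 20% of iterations, discarded). Likelihood parts are cached per
volunteer so a block update only re-solves the ODEs it invalidates;
error-SD updates trigger no solves at all. The desk-scale default is
15,000 iterations with every 10th retained (the full-scale 150,000 is a
flag away); a single chain, reproducible bit-exactly from its seed.

Validation of the machinery, in increasing strength: (i) with the
likelihood removed the sampler reproduces all 61 prior marginals
(per-parameter KS, α = 0.01, 10⁴ retained draws; the factorised prior is
sampled with one block per parameter, giving iid-quality draws);
(ii) a conjugate normal-normal toy matches the closed-form posterior
within Monte-Carlo error; (iii) end-to-end recovery — generate a
synthetic study, calibrate at desk scale, and require the 95% credible
intervals to cover the generating `FracAbsorbed` and `FracDOSEHep` for
at least 3 of 4 volunteers. Full-prior-width parameters with weak
identification (e.g. a portal fraction generated near an extreme) can
legitimately miss; the 3-of-4 criterion reflects that.

Posterior outputs: medians and central 95% credible intervals per
parameter; pointwise 2.5/97.5% posterior-predictive bands on the 0–48 h
deposition-rate curves (order statistics over retained draws pushed
through the model, 0.05 h grid) with the central curve at the
posterior-mode draw; and a posterior-mode report comparing measured and
predicted 48-h cumulative excretion per volunteer and analyte.

## 5. Synthetic data generator

The generator emulates the structure of the controlled-dose study the
analysis assumes: 4 volunteers, body weights uniform on 59–91 kg, doses
uniform on 0.107–0.164 mg/kg; inter-void intervals gamma(shape 4,
mean 2 h) truncated to [0.5, 5] h (≈ 20–26 voids in 48 h); void volumes
lognormal (median ≈ 0.185 L, σ_log 0.35; ≈ 3–6 L total). Local
parameters are drawn from their priors per volunteer; globals default to
the package defaults and are shared. Specific-metabolite void masses are
exact interval increments of the model's cumulative urinary amounts at
the true parameters; measurement noise is zero-truncated Gaussian on the
deposition rate (σ_OH = 2×10⁻⁴, σ_cx = 4×10⁻⁴ mg/h — the order of
magnitude consistent with the calibrated error model and ~2–10% of peak
rates). Adipic acid adds a constant dietary background (0.04 mg/h —
a minor share of the AA signal, so that the background correction is a
secondary adjustment as in the emulated study design) to a
dose-proportional component (70% of metabolised MEHA routed through a
fast 3 h⁻¹ pool — AA kinetics are outside the ODE system but needed to
exercise background correction); 5oxo-MEHA is synthesised the same way
at a yield between the two modelled metabolites. AA is only reported for
voids within 24 h.
A TruthRecord (parameters, noise-free masses, seeds) accompanies every
dataset; identical (config, seed) reproduce the CSV bit-exactly.

One consequence of the zero-truncated noise model is worth flagging:
wherever the true deposition rate is small relative to σ (the urinary
tail), `E[max(N(μ,σ),0)] > μ`, so summed *measured* masses are biased
upward relative to the noise-free model. Rate-level calibration accounts
for the truncation and recovers parameters correctly, but cumulative
measured totals systematically exceed model predictions on noisy
synthetic data — which is why mode-fit agreement is asserted on
noise-free data.

What the generator does *not* emulate: analytical-chemistry censoring
(no LOQ), creatinine variation, within-day physiological rhythms, and —
importantly — the faster-than-model terminal decay seen in real
volunteer urine. Passing recovery tests therefore demonstrates that the
inference machinery is correct and well calibrated *under the model's
own assumptions*; it does not certify model adequacy for real data,
where structural misfit (e.g. the second-peak decline) remains.

## 6. Problem sizes used in the shipped analyses

Desk-scale runs are used throughout the repository: 15,000 MCMC
iterations (thin 10, 20% burn-in), 200-point LHS, r = 7 (design-size and
screening) / r = 20 (replication-overlap) Morris trajectories, 100 prior
draws for the conservation audit, 200 posterior draws for predictive
bands. Full-scale iteration counts are available via flags
(`07_calibrate.py --full-scale`, `deha-pbk pipeline` with
`scale: full`).

## 7. Known limitations

* Exhaled-CO₂ elimination and the non-specific metabolite pathway beyond
  adipic acid are not modelled; absorbed dose not excreted in urine
  accumulates in the "metabolised" ledger.
* No enterohepatic recirculation and a single-phase gut, by design.
* The lymphatic delay is a hard switch; real lacteal transport is
  dispersed in time.
* Locals have independent identical priors — no population hyperpriors,
  so the hierarchy shares no strength across volunteers.
* Single-chain inference; convergence is monitored via acceptance rates
  and the log-posterior trace only.
* The plasma/blood-cell partition enters only through the vascular
  reservoir capacity; with the blood pool a small compartment its
  influence is modest.
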