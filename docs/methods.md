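# Methods

## Model

`ctbolus` simulates the transport of iodinated contrast material (CM)
through a whole-body physiologically-based pharmacokinetic (PBPK) network
of 18 organ/vessel compartments connected by blood flow: peripheral
(antecubital) vein → superior vena cava → right heart → lungs → left heart
→ ascending aorta → systemic organs (myocardium, head, upper extremities,
stomach, spleen, pancreas, intestines, liver with portal inflow, kidneys,
lower body) → venous pool → right heart.  The reference network describes
a 60-kg, 1.7-m adult with a left-heart output of 6500 ml/min; the stomach,
spleen, pancreas and myocardium are separate compartments with resting
regional-flow fractions, which the classic contrast-kinetics compartment
models lump together.  Flow, intravascular-volume and
extracellular-volume tables ship as editable TSVs
(`src/ctbolus/data/compartments.tsv`, `topology.tsv`); the exact numeric
values of the original figure are not legible in any published text form,
so the shipped table encodes standard resting regional circulation values
normalised so systemic flows sum to exactly 6500 ml/min.  Users with
better per-organ data can substitute their own tables; the loader
validates flow balance at every node.

Three mechanisms move CM:

1. **Advection.**  Each compartment is divided into K equal well-mixed
   sub-compartments in series (default K = 15), so a vessel's transit-time
   distribution is Erlang(K, K·Q/V) rather than the single-exponential of
   a well-mixed tank.  Inlet concentration is the flow-weighted mixture of
   the feeding compartments' outlet concentrations.
2. **Diffusion in blood.**  Nearest-neighbour exchange between adjacent
   sub-compartments at rate `k_diff` (1/s), a second-difference
   (discrete-Laplacian) form with reflecting ends.  `k_diff` scales in
   direct proportion to the agent's osmotic pressure ratio to saline
   (saline osmolality fixed at 290 mOsm/kg H₂O, configurable); an
   optional mode adds inverse proportionality to viscosity.  The
   calibrated constant `k_ref` is the diffusion speed of the reference
   agent Iopamidol-370 (370 mgI/ml, osmotic ratio 2.76, viscosity
   9.1 mPa·s).
3. **Transcapillary exchange.**  Linear concentration-gradient exchange
   between each organ's vascular sub-units and a single extracellular
   pool, coefficient `k_tc` (1/min) per organ.  The osmotic modulation of
   transcapillary permeation is not quantified in the source material, so
   a plain linear exchange is used; vessels and heart chambers have none.

Patient scaling: all flows and volumes scale in direct proportion to body
weight (reference 60 kg); all flows are then rescaled so the left-heart
output equals the target cardiac output.  The divisor of that adjustment
factor is the *weight-scaled* left-heart output (not the fixed 6500
ml/min), so the post-condition "left-heart output equals the target"
holds for every weight — with the divisor fixed at 6500 the two scalings
would not commute.  When no cardiac output is given it is estimated as
`25.3·H^0.725·W^0.425` ml/min (H in cm, W in kg).  The printed source of
this formula typesets the first exponent ambiguously (a negative exponent
yields a cardiac output of tens of ml/min, which is absurd); the positive
reading is used.  Body surface area uses DuBois
(`0.007184·H^0.725·W^0.425`), chosen for consistency with the same
exponents; since the two power laws share exponents, the *estimated*
cardiac index is size-invariant at 25.3/0.007184/1000 ≈ 3.52 l/min/m².

No renal/hepatic elimination is modelled: simulation horizons are a few
minutes and first-pass/early-recirculation dynamics dominate; total
iodine in the system therefore equals the cumulative injected mass at all
times, which the solver conserves to machine precision (the transport
matrix has exactly zero column sums by construction).

Injections are uniphasic (constant rate) with an optional saline flush at
its own rate.  The pump's volumetric flow is routed through the
peripheral-vein compartment as additional carrier flow during the
contrast and flush phases, modelling bulk push-through of the arm veins;
venous retention beyond bulk transit is not modelled.  Concentration is
per whole intravascular volume (no haematocrit/plasma partitioning).  The
default ROI readout is the compartment's mean intravascular
concentration; an outlet-sub-unit readout is available by flag.

## Numerics

The system is linear and piecewise time-invariant.  It is integrated
with classical fixed-step RK4 on the output grid (default dt = 0.1 s).
Because advection rates reach K·Q/V ≈ 24 1/s in the ascending aorta at
high cardiac output, a fixed 0.1 s step can leave the RK4 stability
region; the integrator therefore sub-steps internally whenever
`dt × max-rate` exceeds a safety bound (0.8), splitting sub-steps at
phase boundaries (injection end, flush end) so that the piecewise-constant
input is integrated exactly.  Output stays on the requested dt grid.
Halving dt changes the simulated peak CT number by well under 0.5 HU
(self-convergence test).  RK4 can undershoot zero by strict floating
noise; masses are not clamped (clamping would break exact conservation).

Batches of subjects that share the network structure (a cohort, or a
cardiac-index grid) are integrated together as columns of one sparse
linear system: weight scaling multiplies volumes and flows by w/60 and
cardiac-output adjustment rescales flows, so each subject enters the
shared operators through two scalars.  Wide batches are split into groups
of similar flow scale so a single fast subject does not force tiny
sub-steps on the whole batch.

Enhancement is `κ · concentration + baseline` with κ in HU per mgI/ml
(default 25, typical of 120 kVp, until calibrated).  Scanner- and
voltage-specific spectral behaviour is deliberately reduced to this one
configurable coefficient.

## Enhancement metrics

On a time-density curve (treated as piecewise-linear between samples):

* **CM-AT** — first time enhancement exceeds baseline + 30 HU (linear
  interpolation between samples), minus a 2 s lead; clamped at 0 with a
  log message.  The source material states both 30 HU (main text) and
  10 HU (figure caption) for the trigger; 30 HU is the default and 10 HU
  is selectable.
* **PT** — time from injection start to the global enhancement maximum;
  ties break to the earliest time (deterministic and physiologically
  conservative).
* **PCTN** — that maximum, in HU.

For *measured* (noisy, 1-Hz) monitoring curves, metrics are extracted
after Savitzky–Golay smoothing (window 5, order 2) with a parabolic
refinement of the peak (quadratic through the samples around the discrete
maximum).  The raw maximum of a noisy sampled curve is biased upward by
roughly the noise amplitude; the vertex estimator removes most of that
bias, which would otherwise contaminate the κ fit.  In the sweep
experiments the same three-point quadratic vertex provides a continuous
(PT, PCTN) estimate free of output-grid quantisation, without which
"strictly decreasing in cardiac index" would fail on 0.1 s ties at high
cardiac output.

## Calibration

Free constants: `k_ref` (1/s), `n_sub` (K), `κ`.  Timing is fitted first:
grid search over n_sub ∈ {1..30} crossed with bounded scalar minimisation
of k_ref ∈ [10⁻⁴, 10] 1/s on a log scale (coarse 7-point log grid, a
3-point bracket pass, then golden-section refinement of every n_sub whose
objective is still in contention — with an additive as well as
multiplicative slack so near-zero objectives on clean data do not starve
the true optimum).  The timing objective is
`Σ_patients |AT_sim − AT_meas| + |PT_sim − PT_meas|` in seconds
(equal-weight L1; an L2 variant by flag) — the source material does not
state a norm or weighting.  κ is then fitted at fixed timing by L2 closed
form `Σ p·y / Σ p²` over simulated peak concentrations p and measured
PCTNs y (exact-enumeration L1 variant by flag).  Patients whose
simulation produces no detectable arrival are excluded with a warning and
counted.  The fitted-sequentially design mirrors the narrative order of
the source procedure; whether the original fit was joint is unknown.

## Synthetic cohort

The generator emulates a 96-patient coronary-CTA test-bolus population:
height ~ U(133.3, 176.6) cm and weight ~ U(31.9, 89.6) kg sampled
independently with BMI rejection-clamped to [13.4, 32.3] (only medians
and ranges of the real cohort are published, so uniform sampling within
ranges is used); cardiac output ~ U(1.5, 6.5) l/min.  Each "measured"
curve is produced by the simulator itself at known truth constants
(k_ref* = 0.15 1/s, n_sub* = 15, κ* = 25) under the clinical timing-bolus
protocol (20 ml Iopamidol-370 at 4.0 ml/s + 20 ml saline flush),
resampled to the 1-Hz monitoring grid starting 10 s after injection, with
N(0, 10 HU) noise per sample and N(0, 0.5 s) jitter on the curve start.
k_ref* = 0.15 1/s makes the diffusive exchange timescale comparable to
sub-compartment transit in the large vessels, so diffusion visibly
shapes the curves without dominating advection; it lies well inside the
search bounds.  A fixed seed reproduces the cohort byte-for-byte; 30
patients form the calibration split, the rest validate.

What the generator does **not** emulate: height–weight correlation,
vascular resistance, collateral circulation, venous pooling of contrast
in the arm, beat-to-beat flow variation, scanner drift.  Passing
recovery and validation tests therefore demonstrates internal
consistency of the pipeline under the stated noise model, not clinical
accuracy on real patients.

### Identifiability of the timing constants

With clean (zero-noise) synthetic curves the full search recovers
(k_ref, n_sub, κ) essentially exactly (k within ~1%, n_sub exact, κ
within 0.1%).  At the default noise level the timing objective develops
a nearly flat ridge in the (k_ref, n_sub) plane: both constants control
bolus dispersion, and the two scalar summaries (AT, PT) per patient
barely separate them.  The per-patient sensitivity of AT/PT to a one-unit
change of n_sub near 15 (or a 10% change of k_ref) is ≈ 0.06 s, against
≈ 0.5 s of per-patient measurement noise (jitter + sampling);
a 30-patient cohort yields a discrimination statistic of order
30·(0.06/0.5)² ≈ 0.4 ≪ 1 between adjacent n_sub values, so the fitted
n_sub scatters over roughly 12–17 and k_ref over a factor of a few,
depending on the noise realisation.  κ is insensitive to position along
the ridge (the ridge preserves curve shape) and is recovered to within a
few percent regardless.  This is a property of the experimental design
being emulated — two timing scalars per patient from 1-Hz noisy
monitoring scans — not of the optimiser.

## Sweep experiments

The sweep subject is a 166-cm, 65.0-kg male; the agent is 350 mgI/ml,
590 mOsm/kg H₂O (osmotic ratio 590/290 ≈ 2.03), viscosity 7.0 mPa·s (a
typical 350 mgI/ml nonionic monomer at body temperature; only used in
the optional viscosity scaling mode).  Protocol families: coronary
(45.5 ml = 245 mgI/kg, durations 8–20 s step 2) read out in the ascending
aorta; abdominal (74.3 ml = 400 mgI/kg, durations 10–40 s step 5 — the
printed duration lists disagree between 10–35 and 10–40; the tabulated
10–40 is used) in the abdominal aorta.  Both include a 20 ml saline
flush at the CM rate, matching the clinical protocol (the simulated-study
description is silent on flushing).  The cardiac-index grid is 0.1–6.0
l/min/m² in 0.05 steps, matching the granularity of the published window
tables; cardiac output = CI × DuBois BSA.  Simulation horizon 240 s with
dt 0.1 s: at the extreme low end of the grid (CI ≲ 0.2) circulation times
exceed any practical horizon, so rows whose enhancement has not peaked
in-horizon are flagged censored — their AT/PT are NaN and their PCTN is
the within-horizon maximum (a valid lower bound for thresholding).
Monotonicity checks run over the non-censored rows.

Qualitative shape checks: PCTN vs cardiac index unimodal per duration
(rises then falls), judged with a slack of 0.1% of the peak value —
recirculation texture produces sub-0.05 HU ripples on several-hundred-HU
peaks, far below anything resolvable in the published figures — and
CM-AT/PT strictly decreasing in cardiac index.  The 350 HU adequacy
windows per duration report the smallest/largest grid cardiac index with
PCTN ≥ 350 HU, printing "> 6.00" when the top of the grid is still above
threshold; window widths must narrow as duration grows.  The *numerical*
window endpoints depend on the authors' unpublished fitted constants and
per-organ values and are explicitly not reproduced — structure,
formatting and qualitative ordering are.

Validation statistics: per cardiac-index bin (≤1.5, 1.6–2.0, 2.1–2.5,
≥2.6 l/min/m²), the mean simulator-estimated metric is compared with the
Student-t 95% CI of the "actual" (measured) population mean; global
agreement uses ICC(2,1) (two-way random effects, absolute agreement,
single rater — the variant is not stated in the source, so the most
conservative absolute-agreement form is used) with 95% CIs via
`pingouin`.

## Problem sizes and runtimes

Default experiment sizes: 96-patient cohort (30 calibration / 66
validation), full n_sub ∈ {1..30} × k_ref search (≈ 300–400 objective
evaluations, each a batched 30-patient simulation), and two
7-duration × 119-point sweeps.  On one CPU the full calibration takes a
few minutes and each sweep under a minute; unit tests use 4–14-patient
cohorts and reduced grids.

## Known limitations

* Per-organ parameter values are literature-informed, not the original
  authors' (unpublished); absolute HU levels and window endpoints shift
  accordingly.
* Diffusion acts only within a compartment's sub-compartment chain, not
  across compartment boundaries (open question in the source; the
  within-compartment reading follows its figure).
* The timing constants are weakly identified from noisy 1-Hz test-bolus
  metrics (see above); calibration on real data would inherit the same
  flat ridge.
* `pulse_rate` is accepted on input for provenance but unused — its role
  is never described in the source material.
* No bolus-tracking trigger simulation, no multi-peak decomposition, no
  PDE-level vascular dispersion, no scanner spectral modelling.
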