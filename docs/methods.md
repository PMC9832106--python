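# Methods

This note records the model, the statistical machinery, the numerical
choices and the known limitations of `hepasens`. Units throughout:
pressures mmHg, flows reported in L/min (mL/s internally), volumes mL,
resistances mmHg·s/mL, elastances mmHg/mL.

## The circulation model

The model is a closed-loop lumped-parameter (0D) circulation with a
two-lobe hepatic sub-circuit. Eleven volume states: four heart chambers
(RA, RV, LA, LV), pulmonary arteries and veins, systemic arteries, a
portal venous compartment, right and left liver lobes, and the vena
cava. Chamber pressures follow a time-varying elastance law

    P = (E_b + E_a · e(t)) · (V − V0),

with a piecewise-cosine activation e(t) ∈ [0, 1] (ventricular systole
0.30 s at the start of the cycle; the atrial kick, 0.17 s, ends exactly
at cycle end, i.e. just before the next ventricular contraction). Heart
rate is fixed at 70 bpm; no chronotropic parameter is varied.

Both ventricles additionally carry an end-diastolic preload reserve,

    P_dia += K_d · (exp((V − V0 − V_knee)/V_d) − 1),

a standard way to encode the steep end-diastolic pressure–volume
relation: filling is nearly linear up to the knee volume and meets an
exponential wall beyond it. This term is what lets a left-ventricular
calibration throttle cardiac output at high filling pressures (the
back-pressure it creates in the pulmonary circuit reins in the right
ventricle) while still allowing hyperdynamic outputs at low ones.

Valves are ideal diodes smoothed with a soft-plus law,
Q = (ΔP + sqrt(ΔP² + ε²)) / (2 R_v) with ε = 0.01 mmHg, so the vector
field is C¹ and a fixed-step integrator is appropriate. Vascular
compartments are linear compliances; branch flows are Ohmic.

The systemic arteries split into three branches: "other organs" (R_OO)
to the vena cava; "digestive organs" (R_DO) into the portal vein; and
the hepatic artery (R_ha) into the liver lobes. Each lobe receives
portal (R_pv) and arterial inflow and drains through its hepatic vein
(R_hv) into the vena cava. Whole-liver resistances R of the parameter
vector are distributed per lobe as R/m for a lobe of mass fraction m
(0.6/0.4 right/left by default), so the parallel combination recovers
the whole-liver value.

**Virtual hepatectomy.** A resected fraction hpx of total liver mass is
taken from the right lobe first, then from the left. A lobe reduced to
the fraction r of original total mass has each of its resistances
scaled by m/r (inversely with remaining mass); a fully resected lobe is
an open circuit. Only resistances are rescaled; lobe compliances and
unstressed volumes are left untouched (an explicitly open modelling
point — the literature does not settle it — and the conservative
choice). The post-resection simulation restarts from the pre-resection
terminal state, modelling an instantaneous intra-operative change.

**Integration and periodicity.** Fixed-step classical RK4 with 1200
steps per cycle (dt ≈ 0.71 ms). A fixed-step scheme was chosen over an
adaptive stiff solver because the smoothed valves remove the stiffness
that would otherwise demand one, it makes runs bit-for-bit
deterministic (an invariant the test suite asserts), and it is roughly
two orders of magnitude faster — the sensitivity and calibration
studies need tens of thousands of model runs. The kernel is compiled
with numba. Cycle-averaged outputs are monitored every cycle; periodic
steady state is declared when all six change by less than 1e-3
(relative) from one cycle to the next, with a 60-cycle budget. The
closed loop conserves total blood volume to floating-point accuracy
(asserted at 1e-6 relative). Cycle averages use the trapezoidal rule on
the final resolved cycle; the portocaval gradient is the difference of
the portal and caval mean pressures; CO is the mean aortic-valve flow.

**Baseline operating point.** The fixed parameters (compliances,
unstressed volumes, right-heart elastances, total stressed volume) were
set once so that the default subject rests at MAP ≈ 91 mmHg,
CO ≈ 5.1 L/min, portal pressure ≈ 9.5 mmHg, portocaval gradient
≈ 6 mmHg and caval pressure ≈ 3.5 mmHg, with portal flow 20 % and
hepatic arterial flow 5 % of CO — textbook resting hemodynamics with
the canonical hepatic flow fractions.  The left-ventricular baseline
elastance sits high enough on the end-diastolic curve that the
population spans hypodynamic (stiff, low-output) through hyperdynamic
(compliant, high-output) phenotypes within its marginal ranges.

## Input distributions and the synthetic cohort

Ten inputs are varied: four elastances (E_a,RA, E_b,RA, E_a,LV,
E_b,LV), five resistances (R_pv, R_ha, R_hv, R_DO, R_OO) and the
resected fraction hpx. Population variability is described by bounded
marginals, treated as mutually independent (a requirement of the
pick-freeze estimator).

Real cohorts enter through kernel density estimation: Gaussian kernels,
Silverman's rule-of-thumb bandwidth, and reflection at the support
bounds so no mass leaks outside the observed range; pdf/cdf/quantile
functions are tabulated on a 2001-point grid and draws go through the
inverse cdf (exact truncation, no rejection).

Because no real cohort ships with the package, a synthetic cohort
generator emulates one. Its per-input families are logistic (E_a,RA),
uniform (E_b,RA), exponential (E_a,LV), normal (E_b,LV), logistic
(R_DO, R_ha) and Cauchy (R_pv, R_hv, R_OO, hpx), each truncated to a
finite support. Locations and scales are this package's own defaults,
chosen once so that (i) the baseline subject sits near the center,
(ii) simulated pre-resection outputs fall predominantly (≈ 85–90 %)
inside the clinical acceptance box, with realistic tails on either
side, and (iii) heavy-tailed families are truncated at clinically
extreme but representable values (e.g. hpx ∈ [0.05, 0.75]). What the
generator does *not* emulate: between-input correlation, measurement
error, and any within-patient variability — so green tests demonstrate
the machinery on a realistic population geometry, not agreement with
any real cohort.

A best-fit selector (maximum likelihood over the five families, AIC
winner, ties broken by parameter count then fixed family order) closes
the loop: it recovers the generating family from the generator's own
large-n draws for all five families.

## Sobol indices

First-order and total indices are estimated by the Saltelli pick-freeze
scheme: a scrambled Sobol' sequence in [0,1]^{2d} supplies base
matrices A and B (N rows each), mapped through the marginal inverse
cdfs; the d hybrid matrices AB_j give (d+2)·N model evaluations for all
first and total indices (120 000 for d = 10 at N = 10⁴). The
first-order estimator is the Saltelli-2010 correlation form
mean(f_B·(f_AB_j − f_A))/V; the total-order estimator is Jansen's
mean((f_A − f_AB_j)²)/(2V). Small negative estimates are reported
unclipped. Convergence is reported as the max-over-inputs absolute
index change between two base sizes, and repeat-based percentile
confidence intervals quantify seed variability. Classification
thresholds (defaults): sensitive S ≥ 0.2; fairly sensitive
0.05 ≤ S < 0.2 with |ST − S| < 0.05; insensitive ST < 0.05; otherwise
intermediate.

## Physiological filter and virtual population

Sampling the marginals does not guarantee physiological outputs. The
clinical acceptance box — MAP 50–130 mmHg, CO 3–10 L/min, portal
pressure 3–20 mmHg, portocaval gradient 1–14 mmHg — is applied to the
*pre-resection* outputs only; intervals are closed (boundary values
retained). Discarding couples breaks the pick-freeze pairing, so Sobol
indices after filtering are computed only through the PCE surrogate,
never by re-running the pick-freeze estimator on the filtered subset.
The retained input–output couples form the virtual population (CSV +
JSON provenance sidecar: seed, filter version, model version, counts).
Per-input retained ranges and pairwise occupancy grids — for
(E_a,LV, E_b,LV) and (E_b,LV, R_OO), the couples the filter visibly
carves — are exported. Grid cells where couples were simulated and
every one was discarded are the *excluded regions*: input combinations
demonstrably incompatible with physiological outputs. Unexplored cells
carry no evidence and are not excluded. The excluded regions are what
the reduced calibration treats as inadmissible.

## Physiologically filtered PCE

The surrogate is a total-degree-q polynomial chaos expansion (q = 4 by
default; C(d+q, q) = 1001 terms for d = 10). Per-input orthonormal
bases are built by the discrete Stieltjes three-term recurrence against
the *empirical measure of the filtered sample* — the point of the
method: the filtered sample is not any textbook distribution.
Each new polynomial is re-orthogonalized against its predecessors
(modified Gram–Schmidt sweeps, up to three passes) before
normalization; the recurrence-generated family must reproduce the
identity Gram matrix on the build sample within 5e-2 per entry
(asserted). Multivariate terms are tensor products over a graded
lexicographic multi-index set. Coefficients are plain least squares,
requiring ≥ 2× overdetermination; condition numbers above 1e10 trigger
a trace-scaled ridge (1e-8) with a warning. Orthonormality gives
Parseval variance decomposition, so first/total Sobol indices are sums
of squared coefficients — no further model runs. Validation is the
predictive squared correlation coefficient Q² = 1 − Σ(Y − Ŷ)²/(N·var Y)
on a held-out test set, filtered through the same box; train/test
disjointness is enforced structurally by hashing training rows.

A caveat carried from the method itself: the filter induces dependence
between inputs, yet the basis is built per marginal and tensorized.
The basis is then orthonormal with respect to the product of marginals,
not the true joint measure; Q² on held-out filtered couples is the
check that the surrogate is nonetheless accurate, and the analytic
Sobol indices inherit this product-measure interpretation.

## Calibration

A patient is six pre-resection targets: MAP, CO, portal pressure,
portocaval gradient, and flows derived as Q_pv = 20 % CO and
Q_ha = 5 % CO. The misfit is the weighted relative error

    Err = sqrt( Σ w_i ((Y_i^target − Y_i^sim)/Y_i^target)² ),

with weights 1 for PCG, MAP, CO; 2/3 for P_pv; 1/3 for the flows.

Calibration runs in two stages. First, algebraic presets: each
hydraulic resistance follows exactly from the target mean pressures
and flows (for linear resistors, mean drop = mean flow × resistance),
with the lobar pressure placed midway across the portocaval gradient;
the mean caval pressure is anchored to P_pv − PCG by a fixed point on
the stressed blood volume whose gain (the venous-side compliance) is
refined by secant updates. Second, a Nelder–Mead simplex in
log-parameter space over the elastances, under a budget of 300 model
evaluations per patient (the caval anchor re-runs inside every
objective evaluation and its simulations count against the budget).
Warm starts (each simulation restarts from the previous terminal
state) keep the cost of an objective evaluation at one to two short
transients.

The *original* strategy frees all four varied elastances; the
*reduced* strategy frees only (E_a,LV, E_b,LV) and rejects proposals
whose (E_a,LV, E_b,LV) or (E_b,LV, R_OO) pair lands in an excluded
region of the filtered occupancy grids — before spending a model run. R_OO itself
stays at its preset value; the ambiguity of whether it should be free
is resolved conservatively (it only shapes the admissible region). A
coarse 3×3 log-grid over the LV pair seeds the simplex. Both
strategies are compared on nine reference virtual patients spanning
hypo-/normo-/hyperdynamic states × low/intermediate/high
portal-hypertension risk, under matched budgets; the report carries
per-patient errors, model-evaluation counts and the relative count
reduction.

## Problem sizes used by the shipped tests

The acceptance-style tests run the whole method at desk scale, chosen
to exercise every stage at meaningful accuracy on one CPU: analytic
oracles at N = 2^14 (pick-freeze) and 5·10⁴ samples (degree-8 chaos fit
of the Ishigami function); the model study on 12 500 quasi-random
subjects (→ ≈ 10 200 retained couples; 9 000 train / 1 000 disjoint
test — at 1 001 basis terms the least-squares estimation variance is
still visible at a few thousand training rows, so the surrogate is
trained on most of the retained set); the estimator-convergence
comparison at N = 10⁴ vs 2·10⁴
evaluated through the fitted surrogate (3.6·10⁵ ODE runs would be
needed to do this against the full model — the surrogate stands in for
it, which is precisely the surrogate's job description, but the reader
should know the convergence figure inherits surrogate error);
calibration at the full budget of 300 evaluations per patient and
strategy.

## Known limitations

- The circulation model is a reconstruction: topology and parameter
  roles are faithful to the closed-loop hepatic 0D literature, but the
  coefficients are this package's own, so absolute outputs (and
  derived quantities like surrogate fidelity at a fixed degree) need
  not match any particular published model.
- Single heart rate; no baroreflex; no peroperative events (blood
  loss, vasodilation); no liver regeneration. Post-resection liver
  compliance is not rescaled.
- Inputs are sampled independently; real cohorts correlate (e.g.
  contractility with vascular tone).
- The PCE basis tensorizes marginal bases over a dependent (filtered)
  sample; see above.
- Cauchy/exponential families are truncated hard at their supports;
  tail behaviour beyond the truncation is unrepresented.
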