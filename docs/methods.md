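# Methods

`emtsig` implements a single-cell analysis of EGF signaling in the ERK and AKT
pathways across an epithelial–mesenchymal transition (EMT): statistical
network inference from snapshot data, a mechanistic single-cell ensemble
model fit by distribution matching, and a reconciliation procedure that asks
whether one reaction network with near-constant parameters explains both
phenotypes. This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The unified pathway model

One fixed reaction structure covers both phenotypes. Receptor-level events
are not modeled explicitly; each pathway receives an aggregated input

    u(t) = 1                                   for t < tau
    u(t) = 1 + (I - 1) * exp(-d * (t - tau))   for t >= tau

with magnitude `I` (dimensionless, resting level 1), onset delay `tau`
(minutes) and decay rate `d` (1/min). Two unmeasured modifiers couple the
inputs to the measured cascade: pRAF (capacity `RT`, co-activated by active
PI3K — the RAC-mediated crosstalk) and active PI3K (pure power-law
production). All reactions are canonical generalized-mass-action terms:

    d(pRAF)/dt   = kR*u1^gR*(PI3K*)^gc1*(RT - pRAF) - gammaR*pRAF^hR
    d(PI3K*)/dt  = kP*u2^gP - gammaP*(PI3K*)^hP
    d(pMEK)/dt   = k1*pRAF^g1*(T_MEK - pMEK)     - gamma1*pMEK^h1
    d(ppERK)/dt  = k2*pMEK^g2*(T_ERK - ppERK)    - gamma2*ppERK^h2
    d(pRSK)/dt   = k3*ppERK^g3*(T_RSK - pRSK)    - gamma3*pRSK^h3
    d(pAKT)/dt   = k4*(PI3K*)^g4*(T_AKT - pAKT)  - gamma4*pAKT^h4
    d(pGSK3b)/dt = (k5*pAKT^g5 + k12*pRSK^g12)*(T_GSK - pGSK3b) - gamma5*pGSK3b^h5
    d(pS6)/dt    = (k6*pRSK^g6 + k13*pAKT^g13)*(T_S6 - pS6)     - gamma6*pS6^h6

The `(T - x)` factors enforce conservation (0 <= phospho <= total per cell);
pGSK3b and pS6 integrate two branches (AKT + RSK crosstalk, RSK + AKT
convergence). The population-level parameter inventory is exactly 38 entries:
6 input parameters, 6 for the pRAF block, 4 for PI3K, 3 activation-side
parameters per measured species (k, g, h; 12 total), and 5 each for the
two-branch species GSK3b (k5, g5, h5, k12, g12) and S6 (k6, g6, h6, k13,
g13). `h5` is the kinetic order of pGSK3b dephosphorylation — its reference
value 0.3 means the reaction is near zero-order (close to saturation) — and
`k13` is the AKT-branch S6 activation rate.

### Cell-specific closure

Cell-to-cell variability enters only through measured quantities. Each cell
carries its measured totals `T_i,c` and baseline phospho levels `x_i,0,c`
(clamped into `(1e-6*T, (1-1e-6)*T)` so closures stay finite). One
deactivation rate per species and cell is then solved from the requirement
that the cell's own baseline is an exact steady state under resting input,
e.g.

    gamma_MEK,c = k1 * xR0^g1 * (T_MEK,c - m0,c) / m0,c^h1

and, for the two-branch species, with the summed production term. The
activation rates `k` stay population-level; this split gives exactly one
closed-form equation per species per cell. The two unmeasured modifiers are
shared across the population: their resting levels are `xP0 =
(kP/gammaP)^(1/hP)` in closed form and `xR0` by bracketed root finding on
`(0, RT)` (relative tolerance 1e-12; a root always exists for positive
parameters because the capacity form changes sign on that interval).

### Reference parameter values

The packaged configuration (`emtsig/defaults.yaml`) carries a documented
epithelial reference set producing realistic dynamics on the 50-minute
horizon: an ERK-branch peak around 5 minutes, a slower AKT response, and a
slowly accumulating pS6. The mesenchymal reference differs in exactly four
entries — I1: 5.3 vs 1.9, I2: 8.1 vs 55, h5: 0.3 vs 0.05, k13: 10^-7.8 vs
10^-9.5 — which are the phenotype-defining parameters the recovery
experiments are built around. Totals are in arbitrary intensity units
(means 90–200 a.u.); rates are per minute.

One regime choice matters for identifiability: the reference RAF activation
is sub-saturated (kR·I1·xP0^gc1 well below gammaR at the epithelial input).
If the reference system operated near RAF saturation, a high-I1 /
strong-saturation parameter combination would reproduce the measured
response shapes to within the distribution-matching noise floor and the
input magnitude — the quantity the cross-phenotype analysis hinges on —
would be unidentifiable from snapshot data. The same reasoning sets the
prior on kinetic orders (below): inputs enter the model only as u^g, so
unconstrained order freedom trades directly against input magnitude.

### Numerical integration

The ensemble (2 shared modifiers + 6 equations per cell) is integrated as one
system by an adaptive Dormand–Prince 5(4) method with a compiled (numba)
inner loop, relative tolerance 1e-6 and per-state absolute tolerance
1e-9 * T. The input onsets `tau1, tau2` are inserted as mandatory step
boundaries because the right-hand side has a kink there; with that, halving
the tolerances changes reported states by < 1e-5 relative. The model is
non-stiff in the parameter regimes of interest, so an explicit method is the
right default — a stiff implicit solve of the 6N-dimensional ensemble with
dense finite-difference Jacobians would be prohibitively slow. Stiff regimes
do occur at extreme sensitivity-grid offsets (kinetic orders scaled up to
8-fold); there the integrator's failure triggers a fallback that exploits
the equations' structure: every measured equation has the form
``dx = a(t)(T - x) - gamma x^h``, so with coefficients frozen over a small
substep (0.02 min) and the deactivation term linearized at the current
state, the update ``x <- x* + (x - x*) exp(-B dt)`` is exact for the
linearized step and unconditionally stable — its cost is fixed and bounded
no matter how stiff the parameters are (the shared modifiers share the same
equation structure and are stepped the same way, so the fallback involves
no adaptive solver at all). The fallback's accuracy class is ~0.3% relative
on tame problems, ample for the sensitivity grid's percent-scale entries;
cells producing non-finite states are flagged instead of aborting the run. During parameter search the
fallback is disabled and the step budget reduced (`robust=False`), so
pathological random draws fail fast to an infinite cost instead of burning
time; the sensitivity and reconciliation stages use `robust=True`. A SciPy
RK45 path is retained as a cross-checked reference implementation and as the
fallback when numba is unavailable. Times at or before stimulation report the
baseline directly — the resting state is a steady state by construction, and
the simulation confirms drift below 1e-4 relative over 50 minutes for 1000
cells.

## Synthetic snapshot data

The generator emulates a mass-cytometry EGF time course so every analysis
stage has known answers. Per phenotype and snapshot it draws an independent
cell population (destructive sampling; cell identity never persists across
time points): totals from an equicorrelated multivariate lognormal (default
CV 0.30, pairwise log-scale correlation 0.30), baselines as configured
fractions of totals times lognormal jitter (CV 0.20), bimodal E-cadherin /
vimentin markers (well-separated lognormal modes, CV 0.50), and a
cleaved-PARP count channel in which a configured fraction of cells (default
5%) exceeds the 20-count viability cutoff. Each population is simulated from
its own steady state to the snapshot time and multiplicative lognormal
measurement noise (default CV 0.15) is applied to all intensity channels.
The default design is 1000 cells per snapshot, 3 replicates, sampling times
{-10, -5, 0, 1, 3, 5, 8, 12, 15, 20, 30, 50} minutes, plus unstimulated
controls at 4 times. Totals are constant within a cell over the one-hour
horizon (no synthesis or degradation — appropriate for the time scale).

What the generator does not emulate: spike-in beads, barcoding/debarcoding,
doublets, acquisition drift, non-multiplicative detector noise, or any
TGF-beta/SMAD signaling. Passing recovery tests therefore demonstrates the
correctness and identifiability of the method under its own assumptions, not
robustness to instrument artifacts.

## Preprocessing

Dead/apoptotic cells are removed where cleaved-PARP counts exceed 20 (strict
inequality; the cutoff is configuration, not data-derived). Phenotypes are
gated with fixed rectangular gates on E-cadherin/vimentin (threshold 110
a.u., between the generator's modes); fixed thresholds rather than visual
gating keep the pipeline reproducible. Phospho channels are linearly
rescaled per phenotype so the 0.999 quantile of the pooled phospho/total
ratio is <= 1 (one global factor per channel; residual violators are clamped
just below their total) — the quantile makes the factor robust to outliers
while enforcing the biological constraint, and the operation is idempotent.
Cells entering the cost are subsampled to 500 per time point across
replicates, allocated proportionally to replicate sizes with
largest-remainder rounding. Network inference uses natural log(1 + X);
fitting and marginal displays use log2(x + 1).

The scale factors are part of the observation model, not a cosmetic
adjustment: for channels that saturate (phospho approaching total),
measurement noise pushes the ratio quantile well above 1 and the factor
substantially below 1 — on the synthetic mesenchymal arm the pAKT factor is
about 0.63. The factors are therefore recorded on the preprocessed dataset,
applied to simulated observables before any model-vs-data comparison, and
un-applied when measured baselines initialize model cell states (the model
state lives on the latent intensity scale). Comparing unscaled simulations
to rescaled data would mis-estimate exactly the strongly-responding
channels.

## Network inference

Full-order partial correlation: for each phosphoprotein pair the remaining
panel variables form the conditioning set, residuals come from least-squares
regressions with intercept, and `rho_XY.Z` is the Pearson correlation of the
residual pair. Edges are called at |rho| >= 0.1 (configurable); values are
Fisher z-transformed (atanh) for display; the display ordering is
single-linkage hierarchical clustering of the rho-matrix rows under
Euclidean distance. A per-timepoint variant computes each listed edge within
each replicate's cells at each time and reports across-replicate mean and
sample SD. Implementation choices: the residual-regression definition is the
primary code path; tests verify it against both an explicit normal-equation
oracle and the precision-matrix identity `rho_ij.rest = -p_ij /
sqrt(p_ii*p_jj)` to 1e-8. Rank-deficient conditioning sets are handled by
least squares (the residual projection is unique) with a warning; exactly
collinear variables yield NaN with a warning.

## Distribution-matching cost and the two-stage fit

The cost is a sum over post-stimulation time points of the squared maximum
mean discrepancy between the simulated ensemble and the measured snapshot on
the six phospho channels, log2(x+1)-transformed:

    F(theta) = sum_t w_t * MMD^2(sim_t(theta), data_t)

with a Gaussian kernel whose bandwidth is the median pairwise distance of the
pooled measured data (capped, seeded subsample; frozen before fitting so F is
deterministic). The biased V-statistic is used inside the cost so F >= 0 and
percent-increase sensitivities are well defined; the unbiased U-statistic is
available for reporting. The simulated ensemble is initialized from a fixed,
seeded subsample of the measured pre-stimulation cells (t <= 0 pooled), 100
cells by default — simulated trajectories carry no measurement noise, so F
has a small positive floor on noisy data even at the true parameters.
The ensemble must not be too small: with very few simulated cells the
optimizer can push F below its value at the true parameters by exploiting
idiosyncrasies of the particular ensemble (an overfitting margin that scales
inversely with ensemble size) and estimates drift along shallow cost
directions; 100 cells keeps that margin below the cost differences
separating genuinely distinct parameter regimes at the default data sizes.
Inside the cost the ensemble is integrated at relative tolerance 1e-5 —
integration error is then ~1e-5 relative, four orders of magnitude below
the MMD floor — while stand-alone simulation keeps the tighter 1e-6
default. Unstimulated controls do not enter the cost (they contain no
dynamic information under the model; configurable).

The search: (1) a log-uniform global sample within per-parameter ranges
(delays uniform on the linear scale) keeps the lowest-cost sets; (2) each
survivor is refined by rounds of Nelder–Mead (log10-transformed scale
parameters, linear delays; the simplex is rebuilt each round, which acts as
the restart that derivative-free search needs), with another round started
only while the end-of-round cost improved by at least 2%; (3) the overall
best gets a final refinement until the relative improvement per round falls
below 1e-4. The global stage is multi-fidelity: candidate draws only need a
rough ranking, so they are scored with a reduced simulated ensemble (40
cells, same data and bandwidth) and a tighter integration-step budget;
survivors are rescored at full fidelity before refinement and discarded if
they fail there. Budgets are configuration: the `desk` budget (2000 samples,
keep 10, 100 iterations/round, round counts capped at 2 per survivor and 8
for the final refinement) runs in minutes on one core and is what the tests
use; the `paper` budget (50000/200/300) is the same procedure scaled up.
Search ranges are a prior centered on the reference values, with the width
set by what each parameter represents: input magnitudes log-uniform on
[1, 64] (upstream receptor-level state plausibly varies widely across an
EMT), ±2 log2 units for rates and capacities, ±0.25 log2 units for kinetic
orders (canonical GMA analyses center orders on the mass-action value 1;
wide order freedom both makes the equations needlessly stiff and renders
the aggregated input magnitudes unidentifiable, since an input appears only
as u^g — and, measured on this synthetic study, freeing individual orders
re-opens compensation ridges that degrade input recovery), pulse decay
rates within a factor two of the reference (receptor-level signal decay
timescales are well characterized), and delays linear on [0, 3] minutes.
A consequence worth stating: mesenchymal reference values that fall outside
this box (h5 = 0.05, k13 = 10^-9.5) cannot be recovered verbatim; their
effects surface through neighboring GSK3β/S6 parameters instead. The Nelder–Mead stages are bounded to
the same prior box — compensated parameter ridges through implausible
corners of parameter space are suppressed rather than explored. Each
surviving global candidate gets one restarted simplex round with a large
initial simplex (0.15 decades per coordinate; the solver's default 5%
perturbation descends far too slowly from rough candidates); the top three
then receive additional deep rounds, where stalled basins exit early
through the 2% improvement rule, so the refinement budget flows to
whichever basin keeps improving; the overall best gets the final
refinement.

## Sensitivity grid

For each parameter j and offset delta in {-8, -7.75, ..., 3} (45 values),
parameter j of each phenotype's best fit is replaced by `theta_E*_j * 2^delta`
— anchored to the epithelial best fit so both phenotypes are scanned over the
same absolute values — and the percent increase of that phenotype's cost over
its reference is recorded. The delta = 0 column of the epithelial grid is
exactly zero by construction; entries are bounded below by -100 because F >=
0. Grid points that break the integrator (extreme kinetic orders) evaluate
through the stiff fallback; a genuinely failed simulation records an infinite
entry.

## Reconciliation

Given best fits `theta_E*, theta_M*`, reconciliation minimizes the L1
distance in log2 space between the pair subject to neither cost exceeding
`(1 + slack)` times its bound (slack 0.01 by default — "at least 99% model
fitness"; slack 0 gives the strict constraints). The epithelial anchor is
held fixed (so its certificate equals its bound exactly) and the
mesenchymal parameters are pulled toward it as far as the mesenchymal cost
permits:

1. per-parameter line search, smallest class-weighted gaps first — each
   parameter scans 11 candidate values from the anchor's value toward the
   current mesenchymal value and takes the anchor-nearest feasible one;
2. continuation polish — all still-differing parameters slide jointly
   toward the anchor by bounded simplex search on
   `F_M + lambda_c * sum_j w_j |log2 theta_j - log2 theta_E*_j|` with a
   hard penalty above the cost cap, so any cost headroom is spent on
   closeness;
3. backward elimination with re-polish — one differing parameter at a time
   is snapped exactly to the anchor's value while the remaining differing
   parameters re-adjust by bounded simplex search to restore the fit;
   passes repeat until nothing more can be eliminated.

The class weights w_j make input-magnitude changes cheap and kinetic-order
changes expensive, encoding the analysis's own biochemical premise:
reaction chemistry should be phenotype-invariant while the aggregated
inputs absorb upstream state. Every move is accepted only if the
mesenchymal certificate stays within its cap and the total L1 distance
decreases, so the number of differing parameters can never grow. An
optional phase-0 "transfer refit" — an L1-penalized sparse refit of the
mesenchymal cost started from the epithelial anchor (greedy coordinate
selection with subset polish) — is available for best-fit pairs that
landed in unrelated compensation basins; it is off by default because the
staged fits land in the same basin. Delays are compared as
log2((tau+1)/(tau'+1)) so zero delays are representable. The
differing-parameter report lists entries with |log2 difference| above 0.1
(configurable), annotated input-related vs kinetic.

## Scales used by the tests and the acceptance script

The test suite runs the full recovery experiment at the fitting design (1000
cells generated per snapshot, 3 replicates, 500 cells per time point in the
cost, 100 simulated cells, desk budget) once per phenotype and reuses the
fits for reconciliation; the sensitivity contract also runs at 100 simulated
cells. The acceptance script runs the same chain at a further reduced scale
(400 cells per snapshot, 800 global samples, keep 5) chosen to keep a full
serial re-run within a modest time budget; these sizes are package defaults
for the script, not statements about the method's limits.

## Known limitations

* The reaction structure is a reconstruction honoring the pathway chains,
  crosstalk links, input aggregation, and the 38-parameter inventory; kinetic
  orders beyond the named ones default to 1 and are fit from data.
* Simulated cells carry no measurement noise inside the cost, biasing the
  MMD floor upward on noisy data; recovery tolerances (±1 log2 unit on input
  magnitudes) absorb this.
* Univariate sensitivity cannot expose compensating multi-parameter moves —
  that is exactly what reconciliation is for.
* The greedy merge order is deterministic but not provably optimal; a
  different order could isolate a slightly different differing set. The
  phase-2 polish mitigates order dependence.
* The differing-parameter report is only as sharp as the fits feeding it:
  desk-budget fits leave scatter of ±0.1–0.9 log2 units in sloppy
  directions, and the 1% cost slack cannot absorb merging many such
  parameters, so reports built from desk fits overstate the
  physiologically required differences. Reconciling converged reference
  sets isolates exactly the four generating parameters
  (`examples/05_sensitivity_and_reconciliation.py` demonstrates this).
* With a single replicate the per-timepoint edge SD is undefined and reported
  as missing rather than zero.
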