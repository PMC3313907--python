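# Methods

## Model representation and SBML support

A `ReactionNetwork` is an explicit list of species (id, name, initial
amount, compartment), reactions (integer stoichiometry, an infix rate-law
expression, optional local parameters and modifiers) and global parameter
values. Rate laws are parsed with sympy, with every known id bound
explicitly to a symbol so ids like `I` or `E` are never hijacked by
sympy's built-ins. The ODE right-hand side is assembled as
N·v(y), with N the stoichiometry matrix and v the per-reaction flux
vector; fluxes are compiled once per network (production-rate parameters
kept symbolic) and cached, so constructing the RHS for each of thousands
of cells costs microseconds.

SBML support covers the ODE fragment of level 2: compartments, species
(amounts or concentrations), global and local parameters, reactions with
content-MathML kinetic laws (arithmetic operators, `exp`/`ln`, time
csymbol). Constructs that would change the ODE semantics — events, rules,
function definitions, constraints, initial assignments, SBML level 3 —
raise an explicit unsupported-feature error. Silent degradation of the
model would corrupt every downstream number, so there is no fallback.
Stoichiometric coefficients must be positive integers; fractional values
are rejected at parse time. The writer emits level 2 version 4 with
default namespaces and round-trips parameter maps, stoichiometry and
rate-law semantics; package-level conventions SBML cannot express (TNF
species id, dose conversion, death readout, equilibration flag) travel in
a model annotation.

## Production-rate identification

The distributed parameters are the rate constants of the zeroth-order
protein synthesis reactions, identified structurally: a production
reaction has no reactants; its rate constant is the unique parameter in
which the rate law is numerically homogeneous of degree one (doubling the
parameter doubles the flux at random probe states, and zeroing it
silences the flux). Zero or multiple qualifying parameters raise rather
than guess. Ordering follows document order in the model file, which also
fixes the column order of sampled populations. The nominal TNF-R1 model
exposes 19 such rates; the pipeline's config validation warns when a
loaded model exposes a different count.

## Heterogeneity model

Each cell scales every distributed production rate by an independent
lognormal multiplier. The underlying normal has standard deviation
σ = 0.148 on the natural-log scale, and its location is shifted so the
multiplier's mean is exactly 1 (μ = −σ²/2): the population averages to
the nominal cell. Two documented switches exist because the convention is
genuinely ambiguous at this σ: median centering (μ = 0; differs from mean
centering by ~1.1% at σ = 0.148) and a log10 reading of σ. Natural log
and mean centering are the defaults. The final slope statistic is
invariant to the log base, which the tests check to 1e-12.

Sampling uses one `numpy` Generator per population, drawing cell-major
with parameters in document order, so a population is bitwise
reproducible from (n, σ, seed, id order) and independent of any execution
parallelism downstream.

## Stimulation protocols and washout

A protocol is a TNF dose in ng/ml plus a mode. Dose conversion to model
units is linear, with the factor declared by the model (`tnf_units_per_ng_ml`);
a missing factor is a configuration error, never a silent default. Continuous
stimulation sets the free-TNF amount at t = 0 and leaves it to the model's
dynamics. Pulse stimulation adds a washout event at 30 min (configurable):
the solver is stopped, free TNF is set to exactly 0, and integration
restarts. The washout is a hard reset, not a fast degradation term — this
keeps runs bit-reproducible and adds no stiffness. Receptor-bound
complexes are untouched (washing removes only free ligand; bound and
internalized signaling continues), and the free-ligand species is clamped
to zero afterwards: ligand returned by complex dissociation is considered
instantly removed by the washed medium, so the free-TNF course is
identically zero after washout. Bound-complex continuity at the washout
time is a tested invariant.

## Equilibration and the death event

Each cell's initial condition is its own unstimulated steady state: the
model with TNF = 0 is integrated over exponentially growing windows until
the largest relative derivative falls below 1e-9, within a default budget
of 1e5 h of model time. A converged state must also be a *resting* state:
species declared as death-pathway activity markers (for the full model,
the active caspases, each measured against its zymogen's nominal amount;
threshold 1e-6) must be negligible, otherwise equilibration fails loudly.
Pure source models such as the toy timer declare that no steady state
exists and raise immediately.

Integration uses `scipy.integrate.solve_ivp` with the BDF method
(rtol 1e-8, atol 1e-12 by default, configurable), mirroring the
variable-order stiff-solver family the problem calls for. The death event
is a terminal root of g(t, y): for the full model
g = cleavedPARP − ½·(PARP + cleavedPARP)|t=0 — the total pool is
evaluated per cell at t = 0 so the criterion remains meaningful if the
model turns PARP over — and for toy fixtures g = X − θ. `solve_ivp`
locates the root by bracketed root-finding on the step, well inside the
0.01 h accuracy the downstream slope estimates need; a 10× tolerance
tightening moves death times by far less than 0.05 h (tested). Cells with
no event before the horizon (default 100 h) are censored survivors;
extending the horizon never changes an already-found death time.

Population runs simulate cells independently and in order. Individual
failures are collected with full cell context; the run aborts only if
more than 1% of cells fail, and partial failures are surfaced through a
warning and the result's `kept_indices`, never dropped silently.

## Robust sensitivity estimation

The population sensitivity per distributed parameter is the slope of an
iteratively reweighted least-squares line with Tukey bisquare weights
(tuning constant 4.685) and median-absolute-deviation scale — the
standard defaults of robust regression routines — fit to
(log multiplier, log ToD) over dying cells only. Survivors are excluded
from the fit and reported alongside (`n_survivors`); no censored-regression
correction is attempted, keeping the estimator faithful to the plotted
convention of placing survivors in a separate "> 100 h" zone.

Two numerical choices matter. First, IRLS is started from a Theil–Sen
(pairwise-median) line rather than from OLS: with a gross outlier at high
leverage, an OLS start can put bisquare reweighting in the wrong basin and
converge to the outlier-dominated line; the resistant start fixes this,
and for n > 1000 the start is computed on a 1000-point stride subsample
(pairwise medians are O(n²)). Second, an exactly linear relation is
detected up front and returned with zero residual scale, because the MAD
estimate degenerates at zero residuals. Convergence tolerance is 1e-12 so
slopes are identical under ln vs log10 axes to that precision.

The nominal sensitivity perturbs one parameter of the single nominal cell
by ×1.1 and ×1/1.1 and takes [log ToD↑ − log ToD↓]/(2·log 1.1). If either
perturbed cell survives, the slope is flagged undefined — never silently
zero. Parameters are classified into three groups by the population
slope: "later death" (slope > 0.1), "earlier death" (slope < −0.1),
"negligible" otherwise; the 0.1 cutoff is a reporting choice and is
configurable.

## Knockouts and population comparison

A knockout replaces one reaction's rate law by the constant 0 in a copy
of the network (idempotent; the original is untouched). For the nominal
model the NF-κB knockout zeroes the IKKa-mediated release-and-degradation
of bound IκBα, abolishing TNF-induced NF-κB activation. Wild-type and
knockout populations share the same sampled multiplier matrix (common
random numbers) so every reported delta isolates the reaction's effect.
Because the resting steady state does not depend on the stimulation
protocol, each cell is equilibrated once per genotype and the state is
reused across the dose × mode grid.

Summaries report: death rate (fraction dying before the horizon — the
evaluation window is the horizon by default and configurable); median ToD
over dying cells; and relative std, defined as the sample standard
deviation (ddof 1) of ToD over dying cells divided by the mean ToD — a
coefficient of variation, with a median normalizer available as a switch
and the chosen definition stamped into each summary. Deltas follow the
comparison-table convention: death rate in percentage points, median and
relative std as relative percent change (KO − WT)/WT·100; the relative
death-rate change is stored as well so either convention can be compared.
Box-plot components use type-7 (linear-interpolation) quartiles and
whiskers at the most extreme datum within 1.5 × IQR.

## Validation fixtures and what they do (and do not) show

The deposited full signaling model is distributed separately, so the test
suite and the acceptance script validate the machinery on fixtures with
analytically known answers:

* **Toy death timer** — dX/dt = m·k, death at θ, ToD = θ/(m·k). The
  population slope and the nominal ×1.1 slope are both exactly −1; an
  optional decoupled second production rate provides an exact zero-slope
  control.
* **Synthetic receptor/inhibitor network** (labelled synthetic
  throughout) — TNF + R ⇌ C, complex-driven production of a death marker
  X, a constitutively produced protector that clears X, death at
  X = 0.35. Parameters (k_on = 10, k_off = 1, R_total = 1, all other
  rates 1, 0.1 model units per ng/ml) were chosen once from the
  closed-form steady states so that the nominal cell survives at
  1–3 ng/ml and dies at 10–30 ng/ml, giving partial death rates at
  intermediate doses under σ = 0.148 heterogeneity. It exercises dose
  conversion, washout, equilibration, knockout pairing and slope signs
  (pro-death rate negative, protector positive).
* **Regression-stage generator** — log ToD = a + b·log m + noise with a
  censored fraction; the Monte-Carlo-calibrated sampling SD of the robust
  slope at n = 2500, noise 0.1, 20% censoring is 0.016, and recovery
  tests use a 4-SD band.

These fixtures validate the estimator chain, not the biology: they
reproduce the *structure* of the full model's behavior (dose-monotone
viability, pulse protection, protective-arm heterogeneity) but none of
its quantitative endpoints. Quantitative reproduction of the published
population statistics requires running the pipeline on the deposited SBML
model, for which the loader, the 19-rate identification check and the
knockout-by-reaction-id interface are in place.

Problem sizes used in the shipped tests and acceptance script (2500
cells for closed-form fixtures, 60–150 cells for the stiff receptor-model
ensembles) are the package's own choice of smallest sizes at which the
checked properties are stable; all are configurable upward.

## Known limitations

* Only the ODE fragment of SBML level 2 is supported; models using
  events, rules or function definitions must be pre-flattened.
* No stochastic (SSA) kinetics, no delay equations, no spatial effects;
  heterogeneity is purely parametric and uncorrelated across parameters.
* Survivor censoring biases the fitted slopes when the dying subset is
  strongly selected; the per-parameter survivor counts are reported so
  the bias is visible, but no Tobit-style correction is applied.
* The dose–model-unit conversion must be declared by the model or config;
  the package does not infer ligand unit conventions.
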