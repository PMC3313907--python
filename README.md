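# tnfpop

Cell-ensemble modeling of TNF-R1-induced apoptosis signaling: heterogeneous
populations of deterministic ODE "cells", time-of-death detection, global
population sensitivity analysis, and in-silico knockouts of the NF-κB
survival arm.

## The problem

The cytokine TNF triggers two opposing programs through its receptor
TNF-R1: caspase-mediated apoptosis and NF-κB-mediated survival signaling.
Clonal cells respond heterogeneously — under the same stimulus some die
within hours, others days later, others not at all. `tnfpop` implements the
cell-ensemble approach for analyzing this behavior:

* each cell is a deterministic ODE reaction network (loaded from SBML);
* cell-to-cell variability enters as independent lognormal multipliers on
  every protein production ("expression") rate, with log-scale spread
  σ = 0.148 and the multiplier mean anchored at 1;
* each cell starts from its own unstimulated steady state (no activated
  caspases), is stimulated with TNF — continuously or as a 30-minute pulse
  followed by washout of free ligand — and is integrated with a stiff BDF
  solver;
* a cell's **time of death** (ToD) is the event time at which its death
  readout crosses threshold (for the full signaling model, 50% cleavage of
  the Caspase-3 substrate PARP); cells with no event within 100 h are
  censored survivors.

The package's central statistic is the **population (global) sensitivity**
of the time of death: for each distributed production rate *k* with
per-cell multiplier *m*, the slope

&nbsp;&nbsp;&nbsp;&nbsp;*S(k)* = d log ToD / d log m

of a robust linear fit (bisquare IRLS, c = 4.685, MAD scale) of log ToD
versus log m over the ensemble's dying cells. It is compared against the
**nominal sensitivity**, the central log-log difference of the single
nominal cell's ToD under ×1.1 up/down perturbation of one parameter.
In-silico knockouts (setting one reaction's rate identically to zero) with
common random numbers quantify what a pathway contributes to death rate,
median ToD and the relative spread (std/mean) of death times.

Because the full nominal signaling model is distributed separately as an
SBML file, the package ships closed-form validation fixtures: a toy death
timer (dX/dt = k, death at X = θ, so ToD = θ/(m·k) and *S* = −1 exactly), a
synthetic receptor/inhibitor network with ligand binding and a protective
arm, and a regression-stage dataset generator with known slope, noise and
censoring.

## Worked example

```sh
python examples/toy_timer_sensitivity.py
```

```
cells simulated:        2500
median time of death:   5.069 h (nominal cell: 5.000 h)
population slope:       -1.000000
nominal ±x1.1 slope:    -1.000000
```

A 2500-cell ensemble (σ = 0.148) of the toy timer is simulated to its
death events and the robust log-log regression recovers the analytically
exact elasticity −1, as does the ×1.1 nominal perturbation — the whole
estimator chain (sampling → ODE integration → event detection → robust
fit) reproduces a known ground truth.

Other examples: `dose_response_viability.py` (viability curves across
doses, pulse vs continuous), `knockout_comparison.py` (paired wild-type vs
knockout populations), `pipeline_run.py` (config-driven run from an SBML
file with a provenance manifest). A thin CLI wraps the same pipeline:
`tnfpop simulate|sensitivity|knockout|toy-validate`.

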