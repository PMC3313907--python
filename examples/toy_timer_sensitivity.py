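"""Recover the closed-form time-of-death elasticity on the toy death timer.

The timer is the simplest possible "cell": a death marker X produced at
constant rate k, with death declared when X reaches θ.  Its time of death
is θ/(m·k) for a production multiplier m, so the log-log slope of time of
death versus multiplier is exactly −1.  A 2500-cell lognormal ensemble
(σ = 0.148) plus the robust regression must recover that value.
"""

import numpy as np

import tnfpop as tp

network = tp.make_toy_timer(k=1.0, theta=5.0)
spec = tp.EnsembleSpec(n_cells=2500, sigma=0.148, seed=1, distributed_ids=("k_x",))
population = tp.sample_population(spec)
protocol = tp.StimulusProtocol(dose_ng_ml=0.0, horizon_hours=100.0)

result = tp.simulate_population(network, population, protocol)
(record,) = tp.population_sensitivity(result.kept(population), result.fates)
(nominal,) = tp.nominal_sensitivity(network, protocol, factor=1.1)

tods = [f.time_of_death_h for f in result.fates]
print(f"cells simulated:        {len(result)}")
print(f"median time of death:   {np.median(tods):.3f} h (nominal cell: 5.000 h)")
print(f"population slope:       {record.population_slope:+.6f}")
print(f"nominal ±x1.1 slope:    {nominal.nominal_slope:+.6f}")
print()
print("Both slopes are the elasticity d log ToD / d log k; the closed form")
print("ToD = θ/(m·k) makes the ground truth exactly -1, so any deviation is")
print("estimator error (here: none beyond numerical tolerance).")
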