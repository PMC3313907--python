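"""In-silico knockout of the survival arm, with common random numbers.

Knocks out the protector-production reaction of the synthetic
receptor/inhibitor network (the analogue of abolishing NF-κB-driven
expression of caspase inhibitors) and compares the SAME sampled
population with and without it: death rate, median time of death, and
the relative spread of death times.
"""

import tnfpop as tp

network = tp.make_toy_receptor_model()
protocols = [
    tp.StimulusProtocol(dose, "continuous", horizon_hours=100.0)
    for dose in (3.0, 10.0, 30.0)
]
spec = tp.EnsembleSpec(n_cells=80, sigma=0.148, seed=11)

records, _ = tp.knockout_experiment(network, "prod_Inh", protocols, spec)

header = f"{'dose':>10} {'ΔdeathRate':>11} {'ΔmedianToD':>11} {'ΔrelStd':>9}"
print(header)
for rec in records:
    print(
        f"{rec.dose_ng_ml:>7g} ng {rec.delta_death_rate_pp:>+10.1f}pp "
        f"{rec.delta_median_tod_pct:>+10.1f}% {rec.delta_relative_std_pct:>+8.1f}%"
    )

print()
print("Positive Δdeath-rate: the knockout kills cells the survival arm would")
print("have rescued.  Negative Δmedian ToD: knockout cells die earlier.")
print("Negative Δrelative-std: the knockout population is more homogeneous —")
print("the survival arm is a source of cell-to-cell variability.")
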