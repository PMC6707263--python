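"""Transient epidemics: event-driven simulation versus mean-field theory.

Runs a small ensemble of non-Markovian SIS realizations on an Erdos-Renyi
graph (Weibull infection and recovery times, type-II edge activation) and
integrates the age-structured mean-field equations under the same
conditions, printing the infected density I(t) side by side.
"""

import numpy as np

from nmsis import (AgeGrid, SimulationConfig, Weibull, erdos_renyi,
                   integrate_mean_field, run_ensemble, uniform_initial)

net = erdos_renyi(500, 10.0, seed=1)
inf, rec = Weibull(2.0, 1.0), Weibull(2.0, 0.5)

cfg = SimulationConfig("type2", inf, rec, initial_infected_fraction=0.01,
                       t_max=15.0, sample_times=15, seed=7)
ens = run_ensemble(net, cfg, 30)

grid = AgeGrid.for_recovery(rec, 0.01)
init = uniform_initial(net.n, 0.01, grid)
mf = integrate_mean_field(net, "type2", inf, rec, init, grid, 15.0,
                          sample_times=cfg.sample_times)

print("   t   sim I(t) (+- SE)   mean-field I(t)")
for t, s, se, m in zip(ens.times, ens.infected_density, ens.stderr,
                       mf.infected):
    print(f"{t:5.1f}   {s:.4f} (+-{se:.4f})      {m:.4f}")
print("\nThe simulated ensemble mean and the theory track each other through"
      "\nthe outbreak and into the endemic plateau; the residual offset is"
      "\nthe first-order closure's neglect of neighbor-age correlations.")
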