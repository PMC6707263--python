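"""When is a non-Markovian epidemic equivalent to a Markovian one?

Computes the effective rates of a Weibull-clock process, builds its
Markovian reference, and compares stationary densities from: the
non-Markovian type-II simulation, the Markovian simulation, and the
quenched mean-field fixed point.
"""

from nmsis import (SimulationConfig, Weibull, effective_rates,
                   epidemic_threshold, erdos_renyi, markovian_reference,
                   run_ensemble, solve_qmf_fixed_point, stationary_density)

net = erdos_renyi(500, 10.0, seed=2)
inf, rec = Weibull(2.0, 0.8), Weibull(2.0, 0.5)

rates = effective_rates(inf, rec, want_series=False)
print(f"delta_eff = {rates.delta_eff:.4f} (reciprocal mean infectious period)")
print(f"lambda_eff = {rates.lambda_eff:.4f} (transmissions per period/edge)")
print(f"threshold 1/Lambda_max = {epidemic_threshold(net):.4f}")

mk_inf, mk_rec = markovian_reference(rates)


def stationary(i_dist, r_dist, seed):
    cfg = SimulationConfig("type2", i_dist, r_dist,
                           initial_infected_fraction=0.1, t_max=60.0,
                           sample_times=120, seed=seed)
    return stationary_density(run_ensemble(net, cfg, 8), burn_in=30.0)


a, a_se = stationary(inf, rec, seed=1)
b, b_se = stationary(mk_inf, mk_rec, seed=2)
c = solve_qmf_fixed_point(net, rates.lambda_eff).network_density

print(f"\nstationary density, non-Markovian type-II: {a:.4f} +- {a_se:.4f}")
print(f"stationary density, Markovian reference:   {b:.4f} +- {b_se:.4f}")
print(f"stationary density, QMF fixed point:       {c:.4f}")
print("\nUnder type-II activation the steady-state equations coincide with"
      "\nthe Markovian ones at (lambda_eff, delta_eff); residual differences"
      "\nbetween the two simulations are finite-size/sparse-graph correlation"
      "\neffects outside the mean-field description.")
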