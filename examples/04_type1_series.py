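"""Type-I activation: the inverse-mass series and its breakdown.

Under type-I activation the susceptible side resets edge clocks, temporal
correlations appear on active edges, and the stationary state obeys an
asymptotic series in the inverse neighborhood infected mass instead of the
simple Markovian relation.  This script prints the series coefficients,
solves the fixed point both by optimally truncated summation and by exact
Laplace-integral resummation, and shows the gap to the Markovian
prediction closing as the density rises.
"""

import numpy as np

from nmsis import (BetaSigma1, Network, Weibull, effective_rates,
                   solve_qmf_fixed_point, solve_type1_fixed_point)

ring = Network(200, np.array([(i, (i + d) % 200) for i in range(200)
                              for d in range(1, 6)]))  # 10-regular
rec = Weibull(2.0, 0.5)

rates = effective_rates(BetaSigma1(2.0), rec, n_max=12)
print("theta^(n)(0):", np.array2string(rates.theta_derivs[:6], precision=3))
print(f"lambda_eff* = {rates.lambda_eff_star:.4f} "
      f"(approximately gamma/delta_eff)")

series = solve_type1_fixed_point(ring, rates)
exact = solve_type1_fixed_point(ring, rates, method="integral")
print(f"type-I density: series {series.network_density:.6f}, "
      f"integral {exact.network_density:.6f}")

print("\ngamma   type-I   Markovian   gap")
for gamma in (0.8, 1.2, 1.8, 2.6):
    rates = effective_rates(BetaSigma1(gamma), rec, n_max=12)
    t1 = solve_type1_fixed_point(ring, rates, method="integral")
    qmf = solve_qmf_fixed_point(ring, rates.lambda_eff_star)
    print(f"{gamma:4.1f}   {t1.network_density:.4f}   "
          f"{qmf.network_density:.4f}      "
          f"{abs(t1.network_density - qmf.network_density):.4f}")
print("\nThe non-Markovian type-I state approaches the Markovian prediction"
      "\nonly at high infected density, where the higher-order series terms"
      "\nbecome negligible.")
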