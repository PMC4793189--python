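"""How measurement error degrades the test.

Latent X ~ N(100, 10^2) with follow-up exactly 0.8 X (true null) plus
independent normal errors on both variables.  Error breaks the k = 1
invariance of the observed CVs, inflating the type-I error of the proposed
test — and far more so the conventional zero-null test.
"""

from pctchange import MeasurementErrorDGP, run_rejection_study

print("relation = proportional (true null), alpha = 0.05, 10,000 reps/cell")
print(f"{'error_sd':>9} {'n':>5} {'proposed':>9} {'conventional':>13}")
for error_sd, n, seed in ((1.0, 20, 11), (3.0, 100, 12), (5.0, 500, 13)):
    tab = run_rejection_study(MeasurementErrorDGP(
        "proportional", error_sd=error_sd, n=n, seed=seed), reps=10_000)
    prop = tab.loc[tab["method"] == "proposed", "rate"].iloc[0]
    conv = tab.loc[tab["method"] == "conventional", "rate"].iloc[0]
    print(f"{error_sd:>9.0f} {n:>5d} {prop:>9.3f} {conv:>13.3f}")

print("\npower, quadratic relation Y = 0.8X - 0.002X^2 at n = 100:")
for error_sd, seed in ((1.0, 14), (5.0, 15)):
    tab = run_rejection_study(MeasurementErrorDGP(
        "quadratic_c0.002", error_sd=error_sd, n=100, seed=seed), reps=10_000)
    power = tab.loc[tab["method"] == "proposed", "rate"].iloc[0]
    print(f"  error_sd = {error_sd:.0f}: {power:.3f}")
print("Type-I error grows with error SD and n for both tests, but the"
      "\nconventional test reaches ~100% while the proposed test stays"
      "\nnear 30%; error also erodes power against genuine relations.")
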