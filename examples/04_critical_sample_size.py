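"""Critical sample sizes: the fixed-N analogue of a power analysis.

Finds the smallest per-group n at which BF10 > 5 is reached with 80%
probability for several true effect sizes (and BF10 < 1/5 when the null is
true), using the semi-analytic scan.
"""

from bfda import PlanningConfig, critical_n, get_prior

prior = get_prior("default")

print("target: P(BF10 > 5) >= 0.80 with the default analysis prior")
plan = PlanningConfig(boundary=5.0, n_grid=range(2, 1201))
for delta in (0.8, 0.5, 0.35, 0.2):
    n = critical_n(delta, prior, plan, side="upper")
    print(f"  true delta = {delta:4.2f}  ->  n = {n} per group")

plan_null = PlanningConfig(boundary=1 / 5, n_grid=range(2, 601))
n0 = critical_n(0.0, prior, plan_null, side="lower")
print("target: P(BF10 < 1/5) >= 0.80 when the null is true")
print(f"  true delta = 0.00  ->  n = {n0} per group")

# Small effects demand disproportionately large samples, and evidence for
# the null accrues more slowly still: planning for both hypotheses means
# budgeting for the larger of the two critical sizes.
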