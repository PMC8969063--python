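"""Success rates and exact tests for a glucanase-inhibitor graft experiment.

Three arms: water (27 successes of 35 grafts), glucose control (27/28),
and the beta-1,4-glucanase inhibitor D-glucono-1,5-lactone (0/31).
Pairwise two-sided Fisher exact tests show whether establishment rates
differ between arms.
"""

from grafttx import GraftTrialRow, pairwise_fisher, success_rate
from grafttx.stats import trials_report

arms = [
    GraftTrialRow("water", trials=35, successes=27),
    GraftTrialRow("glucose", trials=28, successes=27),
    GraftTrialRow("gluconolactone", trials=31, successes=0),
]

for arm in arms:
    rate = success_rate(arm)
    print(f"{arm.label:<16} {arm.successes}/{arm.trials} grafts = {rate.rounded}% "
          f"(exact {rate.exact:.1f}%)")

result = pairwise_fisher(arms)
print("\ntwo-sided Fisher exact p-values:")
print(result.raw.round(10).to_string())
p = result.raw.loc["gluconolactone", "glucose"]
print(f"\ninhibitor vs glucose: p = {p:.2e} (< 0.01)")
print("Blocking beta-1,4-glucanase abolishes graft establishment; glucose does not.")
print(trials_report(arms).round(1).to_string(index=False))
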