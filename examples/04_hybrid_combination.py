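"""Combine a human-like and a machine-like agent with concordance ranks.

Both simulated agents have modest, independent skill, and their per-record
scatter grows on records they tend to get wrong.  Ranking records by
concordance (1 = the agent's unitary predictions agree most, 0 = most
scattered) and weighting each agent's forecast by its squared rank lets the
momentarily surer agent dominate each record.
"""

from hybridms import (
    CohortConfig,
    combine_forecasts,
    mann_whitney_auc,
    simulate_cohort,
    simulate_ensemble_agent,
)

horizon = 360
cohort = simulate_cohort(CohortConfig(seed=3))
human = simulate_ensemble_agent(cohort, seed=3, name="human")[horizon]
machine = simulate_ensemble_agent(cohort, seed=3, name="machine")[horizon]
y = cohort.outcomes[f"T_{horizon}"].to_numpy()

print(f"{'mode':<14} {'AUC':>6}")
print(f"{'human only':<14} {mann_whitney_auc(human.mean, y):6.3f}")
print(f"{'machine only':<14} {mann_whitney_auc(machine.mean, y):6.3f}")
for mode in ("weighted", "linear_ranks", "unranked"):
    hyb = combine_forecasts(human, machine, mode=mode)
    print(f"{mode:<14} {mann_whitney_auc(hyb.scores, y):6.3f}")
print("Every consistency-weighted combination beats both single agents here; "
      "with this generator's clean dispersion signal the three weighting "
      "variants perform almost identically (see docs/methods.md).")
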