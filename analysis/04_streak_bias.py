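#!/usr/bin/env python
"""Multi-trial build-up of choice history bias across streaks.

Extracts choice-repetition sequences (length 1-5, ending in a repetition or
an alternation), quantifies the repeating bias as the SDT criterion shift
toward the final choice on the following trial, and tests the length x end
interaction within each subgroup plus the three-way interaction with
subgroup in a split-plot ANOVA.
"""

import json

import pandas as pd

from choicehist.streaks import (extract_streaks, mixed_streak_anova,
                                repeating_bias_curve, streak_anova)

trials = pd.read_csv("results/cohort/trials.csv")
agents = json.loads(open("results/cohort/generator_params.json").read())["agents"]
labels = {int(s): a["subgroup"] for s, a in agents.items()}

events = extract_streaks(trials)
bias = repeating_bias_curve(events, trials)
bias["group"] = bias["subject_id"].map(labels)
bias.to_csv("results/streak_bias.csv", index=False)

print(bias.groupby(["group", "end", "length"])["repeating_bias"]
      .mean().round(3).to_string())

for grp in ("repeater", "alternator"):
    sub = bias[bias["group"] == grp]
    res = streak_anova(sub).set_index("Source")
    print(f"\n{grp}s: length x end interaction "
          f"F = {res.loc['length * end', 'F']:.2f}, "
          f"p = {res.loc['length * end', 'p_unc']:.2g}")

mixed = mixed_streak_anova(bias, labels)
mixed.to_csv("results/streak_anova.csv", index=False)
row = mixed.set_index("effect").loc["length*end*group"]
print(f"\n3-way interaction length x end x subgroup: "
      f"F({row['df1']:.0f},{row['df2']:.0f}) = {row['F']:.2f}, p = {row['p']:.2g}")

# outcome-conditioned variant
for cond in ("correct", "error"):
    b = repeating_bias_curve(events, trials, condition_on_outcome=cond)
    print(f"after-{cond} repeat-ending slope: "
          f"{b[b['end'] == 'repeat'].groupby('length')['repeating_bias'].mean().diff().mean():.4f}")
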