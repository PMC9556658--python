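#!/usr/bin/env python
"""Simulate the study cohort and write it to disk.

60 observers, 2 sessions of 600 trials in blocks of 100, a mix of repeater
and alternator agents (34:26 expected), plus aligned single-trial neural
power-modulation values. Output: tidy CSVs and a JSON sidecar with every
generator parameter under results/cohort/.
"""

import sys
from pathlib import Path

from choicehist.synthetic import generate_cohort, write_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/cohort")

trials, signals, agents = generate_cohort(
    n_subjects=60, repeater_fraction=34 / 60, trials_per_session=600,
    n_sessions=2, block_size=100, seed=SEED)
write_cohort(trials, signals, agents, OUT, generator_config={
    "n_subjects": 60, "repeater_fraction": 34 / 60,
    "trials_per_session": 600, "n_sessions": 2, "block_size": 100,
    "seed": SEED})

n_rep = sum(a.subgroup == "repeater" for a in agents.values())
acc = (trials["outcome"] == "correct").mean()
print(f"cohort: {trials['subject_id'].nunique()} subjects, "
      f"{len(trials)} trials, {n_rep} repeater agents")
print(f"accuracy {acc:.3f}, mean RT {trials['rt'].mean():.3f} s")
print(f"written to {OUT}/")
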