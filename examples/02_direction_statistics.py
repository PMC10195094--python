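"""Saccade direction statistics: absolute/relative angles and sectors.

Processes a small synthetic experiment and tabulates absolute gaze and
head movement directions into the four 90-degree sectors (right = 0,
up = 90, left = 180, down = 270 degrees), per condition.
"""

import pandas as pd

from vrsearch.pipeline import included, process_experiment
from vrsearch.saccades import tabulate_directions
from vrsearch.synthgen import GeneratorConfig, generate_experiment

exp = generate_experiment(GeneratorConfig(n_participants=4), seed=2)
metrics, saccades = process_experiment(exp)
inc_ids = set(included(metrics)["trial_id"])
sac = saccades[saccades["trial_id"].isin(inc_ids)].copy()

sac["channel"] = "gaze"
head = sac.copy()
head["channel"] = "head"
head["abs_angle_deg"] = head["head_abs_angle_deg"]
both = pd.concat([sac, head], ignore_index=True)

counts = tabulate_directions(both)
table = counts.pivot_table(index=["channel", "condition"], columns="sector",
                           values="proportion", aggfunc="mean")
print(table.round(3))

fwd = (sac["rel_angle_deg"].dropna() % 360 < 45) | (sac["rel_angle_deg"].dropna() % 360 >= 315)
back = abs(sac["rel_angle_deg"].dropna() - 180) < 45
print(f"\nrelative gaze directions: {100 * fwd.mean():.1f}% forward continuations, "
      f"{100 * back.mean():.1f}% return (backward) saccades")
print("Rightward and horizontal movements dominate in both conditions; "
      "inverted scenes shift vertical gaze traffic downward in scene "
      "coordinates (upward in world coordinates).")
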