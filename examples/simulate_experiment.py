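"""Generate a desk-scale synthetic experiment and run the study statistics.

Uses a reduced design (8 + 8 listeners) so it finishes in seconds.  Printed
numbers: trial counts, the DD-vs-TD trait comparison (DD should score higher
on every measure except sensation seeking), the paired Recollection-vs-Easing
rating comparison (Easing should be lower on all five items), and the
per-listener reproducibility of repeated stimuli.
"""

import soundease as se
from soundease.evaluation import (
    compare_task_ratings,
    group_profile_comparison,
    reproducibility_from_trials,
)

design = se.ExperimentDesign(n_dd=8, n_td=8, missing_participant=None)
stimuli, participants, trials = se.generate_experiment(design, seed=7, keep_audio=True)

scored = trials[~trials["is_repeat"]]
print(f"scored trials per task: {(scored['task'] == 'recollection').sum()}")

print("\nDD vs TD traits (Mann-Whitney U):")
for _, row in group_profile_comparison(participants).iterrows():
    print(f"  {row['measure']:<26s} p={row['p']:.4f} {row['stars']:<3s} {row['direction']}")

print("\nRecollection vs Easing ratings (paired t-test):")
for _, row in compare_task_ratings(trials).iterrows():
    print(
        f"  {row['item']:<12s} mean diff {row['mean_difference']:+.2f} "
        f"p={row['p_ttest']:.2g} -> {row['direction']} in Easing"
    )

rep = reproducibility_from_trials(trials, "recollection")
print(f"\n{rep}")
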