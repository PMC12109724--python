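"""End-to-end WM-TIER pipeline on a small synthetic cohort.

Generates a cohort with the default qualitative group patterns (healthy
controls gain parietal theta coupling from rest to task, the AD group loses
coupling diffusely, MCI changes centrally), extracts FB-PLI features for
rest and the memory-encoding phase, forms the rest-to-task inter-state
change (the task-induced response), and runs Fisher-score selection with
leave-one-participant-out LDA for the 3-class problem.
"""

from wmtier import band_contribution, default_cohort_spec, gen_cohort
from wmtier.pipeline import evaluate_framework

spec = default_cohort_spec(
    group_sizes={"HC": 7, "MCI": 6, "AD": 6},
    n_channels=17, fs=250.0, rest_duration=44.0,
    n_trials=5, n_sessions=1, seed=11,
)
cohort = gen_cohort(spec)
print(f"generated {len(cohort)} participants, "
      f"{len(cohort[0].channels)} channels at {int(spec.fs)} Hz")

report, selection = evaluate_framework(
    cohort, framework="ME-TIER", feature_type="PLI", task="3class",
    classifier="LDA", dc=40, seed=0,
)

print(f"\n3-class LOPO accuracy : {report['accuracy']:.3f} "
      f"(chance level 0.333)")
print(f"optimal subset size d : {report['d']}")
print(f"channels involved Nc  : {report['n_channels']}")
print("top-ranked features   :",
      ", ".join(f"{b}:{c1}-{c2}" for b, c1, c2 in selection.optimal_features[:5]))
print("band contribution     :",
      {k: round(v, 2) for k, v in band_contribution(selection).items()})
print("\nA high accuracy with a small d means a few rest-to-task coupling")
print("changes separate the groups; the band contribution shows where.")
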