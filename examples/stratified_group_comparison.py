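"""Stratified mixed-model comparison of two simulated cohorts.

Simulates per-step data for 6 vehicle and 7 lesioned fish where the lesion
slows the tail only in the most vigorous steps (those in each fish's top
quartile of speed change).  An unstratified comparison dilutes the effect;
stratifying each fish's steps at its own quartiles isolates it in the
high-speed-change stratum.
"""

import numpy as np
import pandas as pd

import fishgait as fg

rng = np.random.default_rng(0)
rows = []
for group, n_fish in (("vehicle", 6), ("lesion", 7)):
    for f in range(n_fish):
        fish = f"{group}{f}"
        intercept = rng.normal(0, 1.0)          # fish-level variation
        speed_change = rng.gamma(3.0, 25.0, 150)  # mm/s per step
        bend_duration = 1.0 + intercept * 0.1 + rng.normal(0, 0.2, 150)
        if group == "lesion":  # deficit only in vigorous steps
            top = speed_change >= np.quantile(speed_change, 0.75)
            bend_duration = bend_duration + 0.3 * top
        for sc, bd in zip(speed_change, bend_duration):
            rows.append(dict(fish=fish, group=group,
                             speed_change=sc, bend_duration_total=bd))
table = pd.DataFrame(rows)

results = fg.batch_compare(
    table, ["bend_duration_total"], stratifier="speed_change"
)
print(results[["parameter", "stratum", "estimate", "pvalue", "n_steps", "n_fish"]]
      .to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
print("The group estimate is the vehicle-minus-lesion difference in total")
print("bend duration (s): the lesioned fish spend ~0.27 s longer bending in")
print("their most vigorous steps, visible only in the high stratum.")

asym = fg.stats.asymmetry_by_fish(
    pd.DataFrame(dict(fish="demo",
                      direction=["left"] * 6 + ["right"] * 4,
                      value=np.r_[rng.uniform(1, 2, 6), rng.uniform(1, 2, 4)])),
    "value",
)
print(f"\nleft-right asymmetry of the demo fish: {asym.asymmetry[0]:+.3f}")
print("(asymmetry index (R - L)/(R + L): +1 fully right-biased, -1 left)")
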