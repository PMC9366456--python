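"""Evolutionary rates through time by 1-Myr tree slicing.

Attaches an early-burst rate profile (exponential decline, 10-Myr
half-life, mammal-line branches 2x faster) to a dated 60-tip tree, then
collates the rates of all branches crossing each 1-Myr slice between
320 and 272 Ma, takes per-slice medians, and smooths them with a loess
curve — overall and per clade.
"""

import numpy as np

import charsat as cs
from charsat import synthetic as syn

scenario = syn.SyntheticScenario(
    seed=5,
    tree=syn.TreeConfig(n_tips=60),
    characters=syn.CharacterConfig(
        rate_profile="exponential", half_life=10.0,
        group_rate_multipliers={"Synapsida": 2.0}),
)
time_tree = syn.simulate_tree(scenario)
groups = syn.assign_clades(time_tree)
rated_tree, truth = syn.generate_rate_burst_tree(time_tree, scenario,
                                                 tip_groups=groups)

series = cs.slice_rates(rated_tree, from_ma=320, to_ma=272, step=1.0)
trend = cs.loess_trend(series, span=0.75)
print("slice (Ma)  n branches  median rate  loess trend")
for t, bucket, med, fit in list(zip(series.slice_times, series.slice_rates,
                                    series.medians, trend.fitted))[::6]:
    print(f"{t:9.0f} {len(bucket):10d}  {med:.5f}      {fit:.5f}")

by_group = cs.rates_by_group(rated_tree, groups, ["Synapsida", "Reptilia"],
                             from_ma=320, to_ma=272)
late = slice(-10, None)
ratio = np.nanmedian(by_group["Synapsida"].medians[late] /
                     by_group["Reptilia"].medians[late])
print(f"\nLate-window median rate ratio Synapsida/Reptilia: {ratio:.2f}")
print("The medians fall ~2x every 10 Myr (the built-in half-life) and the "
      "mammal-line clade runs ~2x faster, as constructed.")
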