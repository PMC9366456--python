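"""Single- vs multi-regime Mk models of body-size category.

Simulates a 4-category body-size trait on a 150-tip tree under two
regimes — the mammal-line regime permits only increases, the reptile-line
regime is bidirectional and biased toward decreases — then fits the four
candidate models (single/multi regime x equal rates/all rates different),
compares them by Akaike weight, and reconstructs ancestral states under
the best model.
"""

import numpy as np

import charsat as cs
from charsat import synthetic as syn

scenario = syn.SyntheticScenario(seed=1, tree=syn.TreeConfig(n_tips=150))
time_tree = syn.simulate_tree(scenario)
groups = syn.assign_clades(time_tree)
table, true_spec, truth = syn.simulate_size_dataset(time_tree, scenario,
                                                    tip_groups=groups)
trait = dict(zip(table["taxon"], table["size_category"]))
print(table["size_category"].value_counts().to_string())

fits = cs.fit_candidate_models(time_tree, trait, true_spec.regime_of,
                               state_order=true_spec.state_order, seed=1)
comparison = cs.model_comparison_table(fits)
print("\n" + comparison.to_string(index=False,
      float_format=lambda v: f"{v:.3f}"))

best_name = comparison.set_index("model")["akaike_weight"].idxmax()
best = fits[best_name]
print(f"\nBest-supported model: {best_name} "
      f"(weight {comparison.set_index('model').loc[best_name, 'akaike_weight']:.3f})")

asr = cs.marginal_ancestral_states(time_tree, trait, best.spec, best.rates)
root_id = time_tree.tree.seed_node.node_id
probs = {s: float(round(p, 3)) for s, p in zip(best.spec.state_order, asr[root_id])}
true_root = best.spec.state_order[truth.trait_history[root_id]]
print(f"Root state probabilities under the best model: {probs}")
print(f"True (simulated) root state: {true_root}")
print("At this tree size the regime contrast is detectable but the "
      "24-parameter multi-regime ARD model does not always out-weigh "
      "simpler models; recovery is reliable by ~600 tips.")
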