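"""Constraint analysis of a clade: saturation asymptote vs an equal-rates null.

Builds a synthetic 60-tip amniote-style dataset in which one of the two
major clades evolves inside a restricted 2-state character space (strong
constraint, high homoplasy) while the rest explores 6 states, then asks
whether the constrained clade's saturation asymptote (Michaelis-Menten
Vmax of dissimilarity vs patristic distance) falls below the null band.
"""

import charsat as cs
from charsat import synthetic as syn

scenario = syn.SyntheticScenario(
    seed=7,
    tree=syn.TreeConfig(n_tips=60),
    characters=syn.CharacterConfig(
        n_chars=300, k_background=6, clade_k={"Reptilia": 2},
        base_rate=0.03, rate_profile="constant"),
    missingness=syn.MissingnessConfig(fraction=0.3),
)
time_tree = syn.simulate_tree(scenario)
groups = syn.assign_clades(time_tree)
matrix, changes_tree, truth = syn.simulate_constrained_matrix(
    time_tree, scenario, tip_groups=groups)

for clade in ("Reptilia", "Synapsida"):
    scope = [t for t, g in groups.items() if g == clade]
    call = cs.constraint_test(matrix, changes_tree, time_tree,
                              scope=scope, n_sims=200, seed=1)
    lo, hi = call.observed.vmax_ci84
    nlo, nhi = call.null.central84
    print(f"{clade:10s} observed Vmax {call.observed.vmax:.3f} "
          f"[84% CI {lo:.3f}-{hi:.3f}]  null {call.null.median:.3f} "
          f"[central 84% {nlo:.3f}-{nhi:.3f}]  -> {call.call}")

# The constrained clade (true accessible states k=2) saturates well below
# the null band -> "strengthened"; the unconstrained clade overlaps -> "none".

print("\nNode-wise scan (no prior hypothesis about where constraint shifts):")
calls = cs.scan_all_nodes(time_tree, changes_tree, matrix, n_sims=100, seed=2)
frame = cs.scan_to_frame(calls)
print(frame[frame.call != "untestable"].to_string(index=False,
      float_format=lambda v: f"{v:.3f}"))
print("\nEach row is one internal node tested with only its descendant tip "
      "pairs; 'strengthened' rows mark clades saturating below the null.")
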