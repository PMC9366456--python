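# charsat

Rates and constraints of discrete morphological character evolution on
time-calibrated phylogenies.

`charsat` is a Python library for macroevolutionary analysis of discrete
character matrices of the kind assembled for fossil groups — taxa scored
for hundreds of skeletal characters, with abundant missing data, on a
dated tree whose branches carry inferred rates of character change.  It
was built around the analysis style used to compare the early mammal-line
(Synapsida) and reptile-line (Reptilia) amniote radiations, but every
component is generic.

It provides:

- **Saturation / constraint analysis.**  Morphological dissimilarity
  between two taxa (MORD: the proportion of characters scored in both that
  differ) is compared with their patristic morphological distance
  *P* (summed branch lengths in expected character changes).  A
  Michaelis–Menten curve *D* = *V*<sub>max</sub>·*P* / (*K* + *P*) is fitted; the
  asymptote *V*<sub>max</sub> is the saturation level — low *V*<sub>max</sub> means homoplasy
  re-explores a small accessible character state space (strong
  constraint).  Significance comes from simulating null matrices under an
  equal-rates Mk model on the same tree, with the empirical missing-data
  mask re-applied: constraint is *strengthened* when the observed 84%
  confidence interval of *V*<sub>max</sub> falls entirely below the central 84%
  interval of the null *V*<sub>max</sub> distribution, *relaxed* when entirely above.
  (84% intervals of two identical estimators overlap ~95% of the time, so
  non-overlap is an effective 0.05 test.)  The test runs for a named clade
  or, with `scan_all_nodes`, for every internal node without prior
  hypotheses.
- **Rates through time.**  Per-branch rates are collated across 1-Myr time
  slices (a branch with child age *c* and parent age *p* crosses slice *t*
  iff *c* ≤ *t* < *p*), summarized by per-slice medians and a loess trend,
  overall or per clade.
- **Mk models of a discrete trait.**  Maximum-likelihood fitting of
  single- and multi-regime Mk models (equal-rates or all-rates-different)
  for a trait such as 4-category body size, with Akaike-weight model
  comparison, marginal ancestral-state reconstruction, and forward
  simulation.
- **Synthetic data with ground truth.**  Birth–death trees with fossil
  tips, matrices evolved with clade-specific accessible-state restriction,
  declining-through-time rate paintings, and regime-dependent trait
  evolution — every generator is seeded and stores its ground truth, so
  the whole pipeline can be scored end to end.

File formats are handled with `dendropy` (NEXUS matrices with
polymorphisms, MrBayes-style annotated trees, Newick) and `pandas`
(metadata, partition tables, tidy exports).

## Worked example

`examples/01_constraint_test.py` simulates a 60-tip, 300-character dataset
in which one major clade is restricted to 2 accessible states per
character while the rest of the tree explores 6, then runs the constraint
test per clade:

```
Reptilia   observed Vmax 0.569 [84% CI 0.560-0.577]  null 0.978 [central 84% 0.937-1.023]  -> strengthened
Synapsida  observed Vmax 1.069 [84% CI 1.044-1.094]  null 1.039 [central 84% 0.987-1.095]  -> none
```

The constrained clade saturates well below its null band (strengthened
constraint detected); the unconstrained clade's interval overlaps the
null.  The node-wise scan in the same script prints one row per internal
node, flagging the constrained clade and the nodes nested inside it.

The other examples cover rate-through-time slicing with a loess trend
(`02`), the four-model body-size comparison with Akaike weights and
ancestral states (`03`), and the CI-overlap calibration behind the 84%
rule (`04`):

```
84% CIs of identical estimators overlap 95.31% of the time
95% CIs of identical estimators overlap 99.43% of the time
```

## Documentation

`docs/methods.md` describes the models and procedures, the default
parameters and why they were chosen, what the synthetic-data generator
does and does not emulate, and known statistical caveats.
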