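"""Pairwise cobinding: count summit-proximal peaks and test significance.

Builds a small synthetic compendium in which TFB shares 30% of its binding
slots with TFA while TFC binds independently, then runs the pairwise
colocalization test for every ordered pair against the accessible-slot null.
"""

from cobindkit import (
    CobindRelation,
    ExperimentSpec,
    FixtureSpec,
    NullModel,
    all_pairs,
    generate,
    results_table,
)

spec = FixtureSpec(
    seed=2024,
    n_slots=10_000,
    experiments=(
        ExperimentSpec("expA", "TFA", 800),
        ExperimentSpec("expB", "TFB", 800),
        ExperimentSpec("expC", "TFC", 800),
    ),
    cobind=(CobindRelation("expA", "expB", fraction=0.3),),
)
bundle = generate(spec)
null = NullModel(N=spec.n_slots)  # here N is known exactly from the fixture

results = all_pairs(list(bundle.experiments.values()), null)
print(results_table(results).to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\nEach row tests one ordered pair: k cobinding peaks (summits within "
    "150 bp)\nagainst the Poisson expectation lambda = n*m/N. The planted "
    "expA/expB pair is\nstrongly enriched (large positive score = -log10 p); "
    "expC pairs sit near 0."
)
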