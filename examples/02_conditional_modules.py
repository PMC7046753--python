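"""Conditional module discovery: which TF pairs co-occur inside a base TF?

Plants two separate modules tethered to disjoint subsets of a base TF's
peaks, then tests every candidate pair conditionally within the base and
clusters the resulting score matrix — each planted module forms its own
cluster with positive within-module scores.
"""

from cobindkit import (
    ExperimentSpec,
    FixtureSpec,
    NullModel,
    TetherRelation,
    conditional_heatmap,
    conditional_table,
    generate,
    iterate_module,
)

spec = FixtureSpec(
    seed=7,
    n_slots=10_000,
    experiments=(
        ExperimentSpec("base", "NFY", 1000),
        ExperimentSpec("m1a", "FOS", 700),
        ExperimentSpec("m1b", "USF1", 700),
        ExperimentSpec("m2a", "SIX5", 700),
        ExperimentSpec("m2b", "ZNF143", 700),
    ),
    tether=(
        TetherRelation("base", ("m1a", "m1b"), 0.30),
        TetherRelation("base", ("m2a", "m2b"), 0.25),
    ),
)
bundle = generate(spec)
e = bundle.experiments
null = NullModel(N=spec.n_slots)

M, tree, results = conditional_heatmap(
    e["base"], [e["m1a"], e["m1b"], e["m2a"], e["m2b"]], null, theta=1e-10, cut=2
)
print("conditional score matrix (within base peaks):")
print(M.to_frame().round(1).to_string())
print("\ncluster labels:", dict(zip(M.ids, tree.labels.tolist())))
print(conditional_table(results).to_string(index=False, float_format=lambda x: f"{x:.3g}"))

# extend the first module with a fourth factor
r = iterate_module([e["base"], e["m1a"], e["m1b"]], e["m2a"], null)
print(
    f"\nextending module base+m1a+m1b with m2a: k_b'={r.k_b} joint regions, "
    f"k={r.k_ij} hit by m2a (lambda={r.lam:.2f}, p={r.p_raw:.3g}, {r.direction})"
)
print(
    "\nPositive scores mean the pair shares more of the base's peaks than "
    "the\nk_i*k_j/k_b expectation; the two planted modules separate into two "
    "clusters,\nand the unrelated fourth factor shows no iterated enrichment."
)
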