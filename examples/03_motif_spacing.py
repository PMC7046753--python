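"""Motif enrichment and spacing: which sites recruit the module to DNA?

Plants an anchor motif with a partner motif 17 bp downstream at one
experiment's summits, scores a three-motif library on the summit windows,
and re-anchors on the best anchor instance to expose the fixed spacing.
"""

from cobindkit import (
    ExperimentSpec,
    FixtureSpec,
    SpacingRelation,
    generate,
    interpret_pair,
    motif_centered_rescan,
    pwm_from_consensus,
)
from cobindkit.motifs import enrichment_report, report_table

spec = FixtureSpec(
    seed=11,
    n_slots=600,
    experiments=(ExperimentSpec("expA", "TFA", 400),),
    motifs=(("EBOX", "CACGTGAC"), ("CCAAT", "TTGACCAATCA")),
    spacing=(SpacingRelation("expA", "EBOX", "CCAAT", distance=17, fraction=0.9),),
)
bundle = generate(spec)
exp = bundle.experiments["expA"]
regions = [("chr1", int(s)) for s in exp.summit_positions]

# background: windows centered on unbound accessible slots
bound = set((int(s) - spec.gap) // (spec.slot_width + spec.gap) for s in exp.summit_positions)
background = [
    ("chr1", int(s) + spec.slot_width // 2)
    for i, s in enumerate(bundle.slot_starts)
    if i not in bound
]

decoy = pwm_from_consensus("DECOY", "GATAAGGAT")
library = [bundle.pwms["EBOX"], bundle.pwms["CCAAT"], decoy]
reports = enrichment_report(regions, bundle.genome, library, background)
print(report_table(reports).to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("pair interpretation:", interpret_pair(reports, "EBOX", "CCAAT"))

res = motif_centered_rescan(regions, bundle.genome, bundle.pwms["EBOX"], [bundle.pwms["CCAAT"]])
arr = res["CCAAT"]
print(
    f"\nmotif-centered rescan on EBOX: {arr.n_regions} regions kept "
    f"({arr.n_discarded} low-quality anchors discarded)"
)
print(f"modal CCAAT distance: {arr.modal_distances} bp, positional bias p = {arr.positional_bias_p:.3g}")
print(
    "\nBoth planted motifs rank above the decoy on the global test ('both "
    "bound'),\nand the rescan recovers the planted +17 bp spacing as the "
    "histogram mode with\na tiny positional-bias p: a recruitment rule with "
    "fixed site arrangement."
)
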