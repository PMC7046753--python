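# cobindkit

Discovery of genome-wide transcription-factor (TF) regulatory modules from
ChIP-Seq peak summits: summit-proximity colocalization with a statistical
model over accessible-chromatin "slots", conditional higher-order module
tests anchored on a base TF, coassociation-score clustering, and PWM motif
enrichment with motif-centered spacing analysis to derive DNA recruitment
rules.

It is written for regulatory genomicists who have peak/summit calls for many
TFs and cofactors in one condition (e.g. an ENCODE-style compendium) and want
to know: which factors co-occur on DNA more than chance predicts, which
groups form recurring modules, and which binding-site arrangements recruit
them.

## The model

Two peaks from different experiments *cobind* when their summits — the best
proxies for the protein–DNA contact points — lie within **d_s = 150 bp** of
one another. For experiments with *n* and *m* peaks and *k* observed
cobinding peaks, significance is assessed against a null in which binding
events fall independently into **N** genome-wide accessible regions of width
d_s (≈250,000 in somatic human cell lines from digital genomic footprinting;
≈500,000 in embryonic stem cells):

- Poisson (default, more conservative): p(k; n, m, N) = e^(−λ) λ^k / k!,
  with **λ = n·m/N**, summed over the tail on the observed side;
- or the exact hypergeometric with population N, successes n, draws m.

p-values are Bonferroni-corrected by **T²** for T experiments
(329² = 108,241 in a 329-dataset compendium) and converted to signed
coassociation scores **−log₁₀ p** (enriched) / **+log₁₀ p** (depleted); the
score matrix is clustered with 1 − Pearson r as distance to expose modules.

Choosing a base TF_b with k_b peaks refines pairs into triplets: if TF_i and
TF_j cobind k_i and k_j of the base's peaks, their joint count k_ij is
tested against **λ = k_i·k_j/k_b**, and the procedure iterates to
quadruplets and beyond by shrinking the base to the current joint
cobinding-region set.

The motif layer scans 150-bp summit-centered windows with JASPAR-style
frequency matrices (score of an instance = sum of per-position frequencies,
min/max-normalized to [0, 1]), reports global enrichment (vs. accessible
background), local enrichment (vs. immediate flanks) and positional bias
(vs. uniform placement), and can re-anchor regions on the best instance of a
chosen motif to reveal fixed spacing and orientation between partner sites.

## Worked example

`examples/01_pairwise_colocalization.py` builds a seeded synthetic
compendium of three 800-peak experiments over 10,000 accessible slots, in
which TFB shares 30% of its binding slots with TFA while TFC binds
independently, and runs the pairwise test on every ordered pair:

```
exp_a exp_b factor_a factor_b   n   m   k  lambda    p_raw direction  p_corrected  score
 expA  expB      TFA      TFB 800 800 268      64 2.61e-80  enriched     2.35e-79   79.6
 expA  expC      TFA      TFC 800 800  73      64    0.144  enriched            1   0.84
 expB  expA      TFB      TFA 800 800 280      64 6.65e-88  enriched     5.99e-87   87.2
 expB  expC      TFB      TFC 800 800  57      64     0.21  depleted            1 -0.677
 expC  expA      TFC      TFA 800 800  73      64    0.144  enriched      1   0.84
 expC  expB      TFC      TFB 800 800  56      64    0.175  depleted            1 -0.758
```

The planted pair shows k ≈ 270 cobinding peaks against an expectation of
λ = 64 and a score near +80 (p ≈ 10⁻⁸⁰); the independent pairs sit at
|score| < 1. The other scripts demonstrate conditional module discovery
(`02`), motif enrichment and the recovery of a planted 17-bp anchor–partner
spacing (`03`), and dataset redundancy filtering (`04`).

The same pipeline is available from the shell:

```bash
cobindkit simulate --seed 3 --out bundle/
cobindkit pairwise --metadata bundle/metadata.tsv --peaks-dir bundle/ \
    --out results/ --n-mode counted_from_bed --accessible-bed bundle/slots.bed
cobindkit conditional --base expA ... ; cobindkit motifs ... ; cobindkit filter ...
```

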