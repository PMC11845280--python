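# netrewire

Condition-specific protein–protein interaction networks from expression
data, and statistics for detecting *rewired* interactions between two
groups of conditions.

A reference interactome describes which proteins *can* interact, not
which interactions are realized in a given tissue, cell state or
patient sample. `netrewire` is aimed at systems biologists who have a
reference protein–protein interaction network (PPIN) and per-sample
RNA-seq quantifications (TPM/FPKM, gene- or transcript-level) and want
to (1) prune the reference network to each sample's expression state at
domain resolution, (2) test which interactions are gained or lost
between two groups of samples, and (3) trace those changes back to a
small set of transcriptomic events.

## Method

**Contextualization.** Every interaction (u, v) of the reference PPIN
is resolved into domain–domain edges: all pairs of domain instances on
u and v whose Pfam-style families are documented to interact in a DDI
library. Proteins (or pairs) without documented domains fall back to an
artificial *dummy* domain so every interaction stays representable. Per
sample, each protein is assigned its **major** feature — the most
abundant gene or annotated transcript above an expression threshold
(default 1.0) — and a domain edge survives only if both owners are
expressed *and* both families occur in the chosen feature's domain
architecture. The condition-specific PPIN is the set of interactions
explained by at least one surviving domain edge. This gives the
procedure isoform resolution: an isoform switch that drops the sole
backing domain removes an interaction even though both proteins remain
expressed.

**Rewiring statistics.** For two groups A and B of condition-specific
networks, each of the N = |A|·|B| inter-group sample pairs (i, j) gives
a pairwise rewiring probability — the fraction of edges appearing or
vanishing between the two networks. Their mean P̄ is the success rate
of a binomial null. An edge alteration observed in |Δ(u,v)| of the N
comparisons is scored

    p(u,v) = P[X ≥ |Δ(u,v)|],   X ~ Bin(N, P̄)
           = 1 − Σ_{j=0}^{|Δ(u,v)|−1} C(N,j) P̄^j (1−P̄)^{N−j},

p-values are Benjamini–Hochberg adjusted, and alterations with
q ≤ FDR (default 0.05) form the differential network.

**Attribution.** Each significant alteration, in each comparison where
it occurs, may be explained by a transcriptomic change of an endpoint:
an expression loss/gain or an isoform switch consistent with the
alteration's direction. A candidate reason i covering r_w instances
across p_w comparisons gets score s_i = p_w·r_w and weight
w_i = s_max − s_i; a small explanatory set is found by greedy weighted
set cover (Chvátal's ratio rule).

## Worked example

The built-in generator plants ground-truth rewiring into a synthetic
two-group study (here: one expression loss, one gain, one isoform
switch; no background noise):

```python
from netrewire import ScenarioSpec, generate_scenario, run_scenario

spec = ScenarioSpec(
    planted=("expression-loss", "expression-gain", "isoform-switch"),
    background_flip_rate=0.0,
    seed=42,
)
scenario = generate_scenario(spec)
result = run_scenario(scenario)

print(f"P_rewired = {result.diff.null.p_rewired:.4f} over "
      f"N = {result.diff.null.n_pairs} comparisons")
for alt in result.diff.significant:
    print(f"{alt.edge.u}--{alt.edge.v}\t{alt.direction}\tsupport={alt.support}"
          f"\tp={alt.p_value:.3g}\tq={alt.q_value:.3g}")
for r in result.cover.selected:
    print(f"reason: {r.protein} {r.kind} (r_w={r.r_w}, p_w={r.p_w}, "
          f"s={r.score}, w={r.weight})")
```

prints

```
P_rewired = 0.0063 over N = 9 comparisons
P0195--P0196	lost	support=9	p=1.57e-20	q=1.57e-20
P0197--P0198	gained	support=9	p=1.57e-20	q=1.57e-20
P0199--P0200	lost	support=9	p=1.57e-20	q=1.57e-20
reason: P0195 expression-loss (r_w=9, p_w=9, s=81, w=0)
reason: P0197 expression-gain (r_w=9, p_w=9, s=81, w=0)
reason: P0199 isoform-switch (r_w=9, p_w=9, s=81, w=0)
```

All three planted alterations rewire in every one of the 3×3 = 9
comparisons (support 9) against a background rewiring rate of 0.63%, so
each is overwhelmingly significant, and the greedy cover attributes
each one to exactly the planted transcriptomic change.

The same analysis runs from the shell on files:

```bash
netrewire simulate --seed 42 --spec scenario.json --outdir sim/
netrewire ppixpress --ppin sim/reference_ppin.txt --annotation sim/annotation.txt \
    --ddi sim/ddi_library.txt --level transcript \
    --expr sim/group1_s1.txt --expr sim/group1_s2.txt --expr sim/group1_s3.txt \
    --outdir group1/
# ... same for group2, then:
netrewire ppicompare --group1 group1/ --group2 group2/ --fdr 0.05 --outdir diff/
```

`ppixpress` writes `<sample>_ppin.txt.gz`, `<sample>_ddin.txt.gz` and
`<sample>_major_transcripts.txt.gz` per sample; `ppicompare` consumes
those and writes `differential_network.txt` and `reasons.txt`.

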