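# Methods

## Model and assumptions

The pipeline treats an interactome as a two-layer object: a
protein-level network (PPIN) and its domain-level resolution (DDIN).
The central assumption is that a physical interaction is mediated by a
pair of interacting domains, so expression changes that remove the
mediating domain — by silencing the gene or by switching to an isoform
that lacks it — remove the interaction. Three simplifications follow:

- Interactions are undirected and unweighted. Input edge weights are
  carried through to output files verbatim but never enter any
  statistic.
- Domain mediation is resolved at the family level: all occurrence
  copies of a family on a protein rise and fall together with the
  chosen isoform's architecture. Copies are still expanded into
  distinct domain-instance nodes (`protein|family|occurrence`) so the
  DDIN is a faithful graph.
- A protein pair with no documented interacting family pair is backed
  by a single artificial edge between reserved *dummy* domains, applied
  per edge: the fallback fires exactly when an interaction has zero
  documented support, including when only one endpoint is annotated.
  This guarantees every reference interaction is representable at the
  domain level, at the cost of giving such edges pure expression
  (on/off) semantics.

## Contextualization

Per sample, each protein's **major feature** is selected:

- *gene-only* mode: the protein's gene, if its abundance (the value at
  gene level; the sum over the gene's transcripts at transcript level)
  exceeds the threshold. The canonical isoform supplies the domain
  architecture.
- *transcript-preferred* mode: the annotated isoform with maximal
  abundance, if that abundance exceeds the threshold. Ties break
  lexicographically by transcript id so runs are reproducible.

"Expressed" means **strictly greater** than the threshold (default 1.0
on the TPM/FPKM scale); the direction of the comparison is a
documented convention of this package. Missing expression records count
as zero. Optional length normalization divides transcript abundances by
transcript length and rescales the sample to a total of 10^6
(FPKM-style input to TPM-style values); an all-zero sample stays zero.

A domain edge survives when both owner proteins have a major feature
and both families occur (with sufficient copy number) in the chosen
architecture; dummy domains occur in every architecture of their owner.
The condition PPIN is the set of interactions with at least one
surviving backing edge — by construction a subset of the reference,
monotone in the threshold, and exactly the reference in the limit of
gene-only mode with everything expressed and all edges dummy-backed.

## Rewiring statistics

The pairwise rewiring probability of samples (i, j) is
|E_i △ E_j| / |E_i ∪ E_j| — symmetric difference over the **pair's own
union**. The phrase "all edges" could also be read as the union over
every sample; that global reading is available as an option
(`union="global"` / `--global-union`) but the per-pair denominator is
the default because it makes each probability a self-contained property
of its pair. P̄ (`P_rewired`) is the arithmetic mean over all
N = |A|·|B| inter-group pairs.

Each edge altered in at least one comparison is tested with the
one-tailed binomial upper tail P[X ≥ support], X ~ Bin(N, P̄), computed
with `scipy.stats.binom.sf` (equivalent to, and regression-tested
against, exact term-by-term summation at ≤1e-12 relative error). The
alteration's direction is the majority direction over comparisons
(gained vs lost, oriented group A → group B); ties resolve to "lost"
with a warning and a single alteration record is always emitted per
edge. Benjamini–Hochberg adjustment uses
`scipy.stats.false_discovery_control`; significance is q ≤ FDR
(inclusive), default FDR 0.05.

## Attribution (weighted set cover)

The universe is the set of (alteration, comparison) instances of the
significant alterations, so that p_w — "the number of comparisons where
a reason's alterations are found" — is well defined. For each instance
and each endpoint protein, a candidate reason is recorded when the
protein's major feature differs between the two samples consistently
with the direction: present→absent (expression loss) or absent→present
(gain) matching the edge's disappearance/appearance, or two different
major features (isoform switch). This attribution rule is this
package's operationalization; reasons are keyed by (protein, change
kind), and the features involved are reported alongside. Instances with
no candidate (e.g. an alteration whose endpoints show identical majors)
are reported as uncoverable rather than silently dropped.

Scores are s_i = p_w·r_w with weight w_i = s_max − s_i, s_max taken
once over the initial candidate pool (weights are not rescored between
iterations, keeping the stated formula intact). Because the best
candidate always has weight 0, plain minimum-weight selection would be
degenerate; the greedy step therefore uses the classical
cost-effectiveness ratio (weight divided by newly covered instances),
which preserves the preference for high-score reasons while
guaranteeing coverage progress. Ties break by lower weight, then larger
new coverage, then lexicographic key. On small instances the greedy
solution is regression-tested against the exhaustive optimum within the
Chvátal H_d bound.

## Synthetic data generator

`ScenarioSpec` defaults define the reference study conditions used by
the test suite and the acceptance script: 200 proteins, Erdős–Rényi
edge density 0.025 (mean degree ≈ 5, chosen as a desk-scale stand-in
for sparse interactomes), 50% of interactions backed by documented
domain pairs, 10% of proteins unannotated (dummy-backed), two isoforms
per protein, three samples per group, background flip rate 0.02 per
protein per sample, and log-normal abundances (σ = 0.4) around a scale
of 50 — log-normal being the conventional abundance model; any strictly
positive law interacts identically with the threshold semantics. Minor
isoforms are generated at 10% of the canonical scale so spontaneous
isoform switches are vanishingly rare and the background noise level is
governed by the flip rate alone.

Planted alterations are realized on dedicated protein pairs that carry
no background edges, each with a private interacting family pair:
expression loss/gain toggles one endpoint's expression between groups;
an isoform switch makes the domain-less minor isoform dominant in group
B. Keeping planted endpoints out of the random background is what makes
the zero-noise ground truth exact — a planted expression loss on a
protein with background neighbours would legitimately rewire those
edges too. Background noise toggles whole-protein expression
independently per sample and propagates through contextualization, so
the null process is the one the statistics actually face.

What the generator does **not** emulate: scale-free interactome
topology, real Pfam architectures and their occurrence statistics,
correlated expression across genes, compositional (library-size)
artifacts, and partially expressed isoform mixtures. Passing tests
therefore demonstrate correctness of the machinery and its behaviour
under idealized noise, not performance on real cohorts.

## Error control: a known limitation

The binomial null treats the N = |A|·|B| inter-group comparisons as
independent trials. They are not: a transcriptomic change in **one**
sample rewires each affected edge in all comparisons involving that
sample (support ≥ 3 in a 3×3 design) while contributing little to P̄.
At the reference conditions a single background flip yields support-3
alterations with p ≈ 0.02–0.03 < 0.05, so under a pure-noise null
essentially every run reports significant edges, and with planted
signal the empirical FDR among discoveries (~0.5) exceeds the nominal
0.05. This is a property of the method's formula, reproduced
faithfully; the acceptance suite measures and reports it rather than
masking it (`null_any_significant_rate`, `empirical_fdr_noise` in
`scripts/acceptance.py` output, and one deliberately failing acceptance
test documenting the discrepancy). Practical reading: the q-values rank
alterations usefully and power for consistent group-wide changes is
excellent (recall 1.0 at the reference conditions), but q ≤ 0.05 should
not be read as calibrated FDR control when per-sample noise is
non-negligible; the attribution step exists precisely because
alterations arrive in correlated bundles explained by few transcriptomic
events.

## Numerical and degenerate-input choices

- All file outputs are sorted; floats are written with `repr` so
  read∘write is exact; gzip members are written with a fixed mtime so
  equal inputs give byte-identical files.
- An empty edge union defines a pairwise rewiring probability of 0; a
  degenerate null (alterations observed at P̄ = 0) is impossible when
  the same samples define both and is asserted as an internal check.
- Duplicate expression rows sum; duplicate network rows collapse
  keeping the first weight; comment lines (`#`) are skipped and a first
  row with a non-numeric value column is treated as a header.
- `bh_adjust` of an empty vector is empty; p-values outside [0, 1] are
  rejected.
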