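# Methods

This note records the models, parameter choices and numerical decisions
behind `bgckit`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinate and annotation model

Genes are 1-based inclusive intervals on scaffolds (GFF3 convention), kept
on the forward axis regardless of strand; all positional logic (ordering,
windows, gaps) ignores strand because real clusters mix genes from both
strands and are treated positionally. The intervening distance between two
genes excludes both gene bodies (`start2 − end1 − 1`), so adjacent genes
have gap 0 and overlapping genes clamp to 0 rather than erroring — overlap
is tolerated as annotation noise. Functional roles ride on a GFF3 `role`
attribute from a fixed vocabulary (backbone NRPS/PKS, tailoring, regulator,
transport, racemase, aminotransferase, cyclophilin, hypothetical,
housekeeping); unknown values degrade to `hypothetical` with a warning
because real clusters contain unannotatable members.

## Negative-binomial differential expression

Counts are NB with quadratic variance μ + φμ². The published analyses this
package emulates used an NB model of the power-variance (NBP) family; the
quadratic form is used here because no dispersion parameters are published
for that family and the quadratic φ is directly interpretable and
configurable.

* **Normalization**: median-of-ratios size factors over genes expressed in
  every sample, rescaled to geometric mean 1. A pseudo-reference fallback
  (genes expressed in *some* sample) exists for sparse matrices but is
  opt-in. This estimator assumes most genes are not differentially
  expressed; the simulated genomes therefore carry a 150-gene housekeeping
  background scaffold — with only a few dozen genes, induced cluster genes
  contaminate the per-column medians and bias fold changes noticeably.
* **Dispersion**: per-gene method of moments, `(s² − m̄)/m̄²` pooled across
  every condition × timepoint replicate cell (weights = per-cell degrees of
  freedom), clamped at 1e−8. Pooling across the whole series rather than a
  single timepoint's 6 samples stabilises the estimate enough to keep the
  exact test calibrated; no information is borrowed across genes (no trend
  or shrinkage, by design).
* **Testing**: a two-sided exact conditional test per timepoint. Group sums
  are approximated as NB with mean μF_g (F_g the summed size factors) and
  size (ΣF)²/(φ Σf²) — exact for equal factors, a moment-matched
  approximation otherwise. Conditioning on the total makes the null law
  parameter-free in the equal-factor case. The p-value sums the conditional
  probabilities of all splits no more likely than the observed one; a
  relative tolerance of 1e−12 absorbs floating-point ties, and the tail sum
  is clipped at 1. A zero total returns p = 1. Measured type-I error at
  α = 0.05 under the null (μ = 100, φ = 0.1, 3 vs 3) is ≈ 0.049.
* **Multiple testing**: Benjamini–Hochberg within each timepoint,
  reported as q-values. Whether a q-value should be computed within or
  across timepoints is genuinely open for this design; within-timepoint
  matches the per-timepoint testing structure and is recorded in the output
  metadata. BH is a conservative stand-in for a Storey-type estimator.
* **Fold changes**: log₂ of normalized group means with pseudocount 0.5 on
  both sides — cluster genes are near-silent in the control condition and
  must not produce infinities. "Upregulated" always means q < α *and*
  log₂FC > 0 (two-sided test, directional post-filter).
* **RPKM**: depth is the column sum of the counts matrix; the package has
  no alignment stage, so "mapped reads" cannot mean anything else here.

## Rule-based cluster prediction

One extension algorithm, parameterized: seeded at each backbone gene,
extended in both directions while neighbours carry cluster-associated
roles, tolerating `max_gap_genes` consecutive non-associated genes and
intergenic gaps up to `max_gap_bp`; trailing non-associated genes are
trimmed so both call ends are cluster-associated. Two presets ship —
`rule_A` (tight: 1 gap gene, 10 kb) and `rule_B` (permissive: 3 gap genes,
20 kb) — chosen to reproduce the qualitative situation of a smaller call
nested in a larger one on the reference layout. They are explicitly *not*
re-implementations of SMURF or antiSMASH, whose internals (HMM backbone
detection, domain parsing) are out of scope; roles arrive as annotation
input.

## Transcriptional boundary delineation

Defaults: α = 0.001, `min_timepoints` = 1 (a gene qualifies if upregulated
at any timepoint), `gap_tolerance` = 1. The gap tolerance exists because
clusters can contain constitutively expressed members that fail the
upregulation filter without interrupting the cluster; 1 is the smallest
value that covers such genes appearing singly. A call whose backbone fails
the filter is emitted with a `backbone_not_significant` flag rather than
suppressed; a call that swallows its whole scaffold is flagged `saturated`
(a symptom of a mis-specified α), never truncated.

## Orthology, synteny and origin classification

Local alignment is Smith–Waterman with match +2 / mismatch −1 and affine
gaps where a gap of length L costs 3 + (L − 1); the implementation is
Biopython's `PairwiseAligner`, validated in the tests against an
independent Gotoh dynamic program. Orthology is the unique reciprocal best
hit, with ties broken lexicographically and logged, a score floor of 30,
and a self-score-ratio filter (score ≥ 0.3 × self-score of the shorter
sequence). The ratio filter replaces an e-value cutoff, which has no direct
analog in raw scores.

Flank synteny uses 10 genes per side by default. The intervening gap is
measured between the *innermost mapped flank orthologs* — not the closest
genes of any kind — and is undefined (flagged) when those orthologs land on
different scaffolds, which is how inversions/rearrangements surface. Order
conservation is the longest collinear subsequence of mapped flank orthologs
(computed per comparator scaffold, maximised over scaffolds) divided by the
number found; LCS-style scoring degrades gracefully under inversion where
adjacency counting would not.

Origin labels are assigned by a rule cascade evaluated in order, with all
thresholds in `OriginThresholds`: conserved cluster (cluster-ortholog
fraction ≥ 0.8 with ≥ half inside the flank span), candidate transfer
(fraction ≥ 0.8 but flank conservation < 0.5), lineage-specific (flank
conservation ≥ 0.7 on both sides, cluster fraction ≤ 0.3, intervening gap
≤ 5,000 bp — the published empirical observation for this locus class),
rearranged (flanks conserved, gap undefined or exceeded, nothing inside),
else unresolved. The 5 kb default is a threshold on an observable, not a
tuned constant; it is configurable.

## Synthetic data: what it emulates and what it does not

The generator plants a contiguous cluster (default 12 genes: one backbone
NRPS forming the 5′ boundary, one PKS, racemase, P450-like tailoring,
aminotransferase, dehydrogenase-like tailoring, regulators, a
cyclophilin-like gene, hypotheticals) between 10-gene housekeeping flanks,
plus a 150-gene housekeeping background scaffold. Counts follow the NB
model with defaults chosen to mirror the inducing-culture study design the
package targets: T = 6 timepoints, 3 replicates per condition, induction as
a step at timepoint 3, control baseline 5 for cluster genes (near-silent),
500 for the cyclophilin-like gene (high constitutive expression), 50 for
housekeeping, φ = 0.1, and class log₂ fold changes of 9 (strongly induced
accessory genes), 5 (backbone class) and 3.18 (cyclophilin class). Library
size factors default to 1; per-gene dispersions and library sizes of the
motivating study are not published, so these are documented stand-ins, not
estimates. Optionally, accessory genes can be given high constitutive
baselines (`n_constitutive_accessory`) to emulate clusters with additional
constitutive members.

Comparator genomes realise four scenarios by construction: lineage-specific
(syntenic flanks, flank-to-flank gap planted exactly — default 3,000 bp —
and 3 cluster homologs dispersed on another scaffold), conserved cluster
(whole locus copied in order), inversion (3′ flank on a second scaffold in
reversed order), and HGT candidate (intact cluster block with flank synteny
destroyed). Ortholog proteins are derived by per-site substitution at
divergence 0.1; unrelated genes get independent random sequences.

Determinism: every artifact draws from a fixed, labelled sub-stream of the
seed, so adding outputs never perturbs existing ones and equal seeds give
byte-identical files.

What passing tests do **not** show about real data: no genome-wide DE
background beyond NB noise (real transcriptomes have correlated programs
and batch effects), no ramped induction (step only), no indels or domain
shuffling in proteins (substitution only), random sequences rather than
homologous families (making RBH easier than in genomes with paralogs), and
no transcript/isoform structure. Boundary-recovery and origin-accuracy
rates measured here are therefore upper bounds on field performance.

## Problem sizes

Defaults are sized so the whole test suite and the acceptance script each
run in a couple of minutes on one CPU: 192-gene genomes, 36 samples,
10,000-gene null calibration, 100 (suite) / 50 (script) boundary-recovery
seeds, 20/10 scenario seeds, 50-protein proteomes for the orthology
oracle. All sizes are arguments, not constants.

## Known limitations

* The exact test assumes equal dispersion in the two groups and
  approximates group sums as NB when size factors are unequal.
* Method-of-moments dispersion is noisy for genes with very low means; the
  floor (1e−8) makes such genes effectively Poisson, which is
  anticonservative if the true dispersion is large. The directional filter
  and BH adjustment mitigate the effect on boundary calls.
* RBH orthology collapses under recent paralogy; ties are logged, not
  resolved.
* The origin cascade is a screen, not a phylogenetic test: `candidate_transfer`
  labels a pattern consistent with transfer and requires gene-tree evidence
  (out of scope) for confirmation.
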