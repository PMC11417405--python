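# Methods

`corec` implements the computational side of cofactor-recruitment (CoRec)
profiling: protein-binding-microarray (PBM) experiments in which a nuclear
extract is applied to a double-stranded DNA array and a target cofactor
(COF — e.g. a lysine acetyltransferase, KAT) is fluorescently labeled. The
DNA sites a COF is recruited to, and how strongly, identify the DNA-binding
transcription factors (TFs) that recruit it in that cell state.

## Array design

Each reference TF model is collapsed to a consensus sequence (per-position
argmax of the probability matrix; ties resolved A<C<G<T for determinism —
the collapsing rule is otherwise unconstrained). Consensus sites are
de-duplicated greedily in input order: a candidate is dropped only when
both its best ungapped alignment identity (matches / shorter length, over
all offsets, forward strand by default) and its shorter/longer length
ratio exceed 0.9. The length condition deliberately keeps composite
two-TF site models alongside their half-site models.

A probe set for a consensus of length L holds the consensus probe plus all
3L single-nucleotide variants (SVs), so motif inference sees every
one-substitution neighbor. Probes are 60 nt — a 2-nt `GC` cap, a 34-nt
binding-site window, and a 24-nt common primer. Sites shorter than 34 nt
are centered in the window with a repeating `TA` flank (a configurable
constant; the flank depends only on site length, so all probes of a set are
identical outside the variable position; an odd leftover base goes 3′).
Background probes are 34-nt windows sampled uniformly from a genome FASTA,
rejecting windows with ambiguous bases; 261 per array by default.

## From fluorescence to recruitment motifs

Per experiment (one COF, condition, array replicate):

1. **Aggregation** — per-probe median over replicate spots (5 by default),
   then natural log. The median is robust to single-spot artifacts. "log"
   is unqualified in the field's usage; any base works as long as it is
   used consistently for f, μ_bg and σ_bg, so natural log is fixed
   globally.
2. **z-scores** — `z = (f − μ_bg)/σ_bg`, with μ_bg and σ_bg the mean and
   sample SD (ddof=1) of the background-probe log fluorescence *of the same
   array and channel*. Backgrounds therefore have mean z = 0 and SD 1
   exactly, and z is invariant to rescaling the scanner units.
3. **Δz motif** — an L×4 matrix z_ik takes the SV probe's z at each variant
   cell and the consensus probe's z at every consensus-base cell; μ_i is
   the median of the 4 values at position i and Δz_ik = z_ik − μ_i. The Δz
   matrix behaves like a binding energy matrix: deleterious substitutions
   fall below the position median.
4. **Motif strength (MS)** — median z of the probe set's 10 top-scoring
   probes (~15% of a 31-probe set). Sets with fewer than 10 probes use all
   probes with a warning so short sites (L=3) remain usable.
5. **Boltzmann PPM** — `P_ik = exp(β z_ik)/Σ_k exp(β z_ik)` per position,
   computed with row-max stabilization; identical whether z or Δz is used
   (shift invariance). β adapts to motif strength: 4 for MS ≤ 0, 4 − 0.5·MS
   for 0 < MS < 6, and 1 for MS ≥ 6 — continuous and non-increasing. Weak
   motifs have compressed z ranges and need sharpening; strong motifs are
   used nearly raw.
6. **Quality filter** — keep motifs with MS > 0.4 whose per-position
   information content (IC_i = 2 + Σ_k P_ik log2 P_ik, uniform-background
   2-bit convention), averaged over every window of 5 consecutive
   positions, stays above 1.0 in the worst window. Motifs shorter than the
   window average over all positions.

## Motif comparison and significance

The distance between two aligned probability matrices is the per-column
Euclidean distance averaged over aligned columns ("mean-per-column ED").
The mean (rather than sum) normalization makes the replicate (ED < 0.4)
and cross-condition (ED < 0.25) thresholds length-independent; a
`normalization="sum"` switch is provided since the original normalization
behind those two constants is not published.

Reference matching slides the query over every ungapped offset of each
target on both strands (reverse complement = reversed rows with A↔T, C↔G
column swap), requires ≥ 5 aligned columns, and keeps the lowest ED.
Overhangs are not penalized; only overlapping columns contribute.

Significance comes from a seeded Monte-Carlo null: the query's columns are
shuffled n_null times (default 10 000) and re-scored against the target at
the observed best offset and orientation. Two design choices here matter
and are deliberate:

* The null is evaluated at the *fixed* observed alignment rather than
  re-optimized per shuffle. Re-optimization lets any shuffle containing a
  consistent run of ≥ 5 columns re-align exactly to the target, putting
  irreducible ~10⁻³ mass at ED ≈ 0 for true matches and destroying the
  resolution the downstream cutoffs need.
* The reported p is the lower tail of a Gaussian fitted to the null ED
  sample, not the add-one empirical count. The empirical estimator floors
  at 1/(n_null+1) — and, for near-one-hot motifs whose base composition
  admits dominant-pattern-preserving permutations, at the probability of
  those permutations — which can never survive Bonferroni correction over a
  realistic library and can rank a short-overlap coincidence above a
  perfect full-length match. The Gaussian tail gives continuous p-values on
  the scale the significance threshold (adjusted p = p × library size
  < 0.01) and the cluster distance (below) expect. If the null sample is
  degenerate (zero variance), the empirical estimator is used. Calibration
  against an exact null is not claimed; p-values are comparison scores, as
  in the tool they emulate.

Replicate motifs (same probe set, same COF/condition) are *replicated* when
any pair has ED < 0.4; a replicated group is assigned to the TF cluster of
its single best significant match (lowest adjusted p over all members, ties
by lower ED then lexicographic target id). Across two conditions, a motif
is *conserved* when any cross-condition member pair has ED < 0.25.

## TF clusters

Reference motifs are clustered by agglomerative complete linkage on
d = max(15 + log10(p), 0), where p is the pairwise comparison p-value above
(directional comparisons symmetrized by the larger distance). Merging stops
when every inter-cluster complete-linkage distance exceeds the user-supplied
cut height; there is no default cut because curated cluster sets in this
field additionally involve manual review, which is out of scope. Note the
scale: under the Gaussian-tail Monte-Carlo p-values, even an exact motif
match reaches z of only about −(4–6), i.e. d around 7–10, while unrelated
high-information motifs sit above ~10.5 — cut heights must be chosen on
this compressed scale rather than near 0. Ties in merge order
break toward the lexicographically smallest combined member set, so the
result is independent of input order. External motifs map onto clusters by
best match with raw p < 0.0005.

## The recruitment network

Each (COF, condition, TF cluster) cell of the network holds the maximum
motif strength over the contributing probe sets. Across a condition pair,
an interaction is *gained* (present only after), *lost* (present only
before), or *conserved* (present in both with the cross-condition ED filter
met). An interaction present in both conditions whose motifs fail the
ED < 0.25 filter is split into one gained and one lost call — the two
conditions recruit through motifs too dissimilar to be one interaction —
which preserves gained + lost + conserved = total.

Per-cluster response classes across KATs use Δmotif strength (condition 2 −
condition 1 on the max-MS cells, absence counted as 0) with threshold 1.5:
*strongly induced* (all recruiting KATs Δms > 1.5), *partially induced*
(≥ 2 induced plus ≥ 1 constitutive), *diminished* (≥ 2 with Δms < −1.5 plus
≥ 1 constitutive), *KAT-specific* (exactly one recruiting KAT), else
*none*. "Constitutive" means conserved with |Δms| ≤ 1.5 — implied but not
defined in the source figure prose, so it is explicit and configurable
here. Constitutive promiscuous clusters are those with more than 4 KATs at
MS > 3 in both conditions (strict inequalities).

Novelty against public PPI data: a (COF, cluster) interaction is
*previously reported* iff any TF mapped to that cluster has a PPI edge with
that COF. Cell-type specificity of the presence matrix is assessed by a
permutation z-score: the statistic is the number of clusters whose
presences are confined to exactly one cell type; the null permutes each
cluster's row of presence entries across the experiment columns
independently and uniformly. The statistic's exact form is this package's
documented choice.

## Genome scanning and promoter acetylation

PPMs become log-odds models against a uniform 0.25 background with
pseudocount 0.01 (log2((P + 0.01·0.25)/1.01/0.25); zero-probability cells
with pseudocount 0 are floored at −50 bits). Every window on both strands
is scored ("max-strand"); the best window's score gets an exact single-site
p-value by dynamic-programming convolution of the integer-discretized
column score distributions (granularity 10⁻³ bits). A region's score is
−log10(p) of its best occurrence, or 0 when the best p exceeds 10⁻⁵; a TF
cluster's score on a region is the maximum over member motifs. Note a
deterministic 8-mer cannot clear the floor (4⁻⁸ ≈ 1.5·10⁻⁵), which is the
intended behavior of the floor. Ambiguous bases score as the column's worst
base (conservative). Site counts are greedy, left-to-right,
non-overlapping occurrences with p ≤ 10⁻⁵ (the counting rule is not
published; greedy non-overlap is this package's choice).

Promoters are the strand-aware window from 500 bp upstream to 100 bp
downstream of each gene's first TSS (0-based half-open, clipped at contig
bounds with a warning). Promoter acetylation is the maximum −log10 p score
of overlapping H3K27ac peaks; ATAC-open promoters with no H3K27ac peak
score 0; promoters with neither are excluded. Promoters are *induced* when
overlapping a differential region with log2FC ≥ 1.5 and *unchanged* at
log2FC ≤ 0.1; overlap with both kinds is induced (multi-peak rule).
Heterotypic content of a promoter is the number of distinct TF clusters
with at least one member motif scoring > 0 in it. Group differences in
scores use the two-sided Wilcoxon rank-sum test (exact for small samples
without ties, normal approximation with tie correction otherwise, via
scipy).

## Synthetic data

The generator defines the conditions every recovery test runs under. For
the PBM side, a planted probability matrix under each probe set induces a
mismatch-additive energy E(probe) = Σ_i −log(P_i,base_i / max_k P_ik), and
spot fluorescence is B · (1 + g·e^(−E)) · η with B lognormal (μ = log 300
arbitrary units, σ = 0.3), η multiplicative spot noise (10% CV), 5 spots
per probe, and g a per-(probe set, COF, condition) recruitment gain. Gain 0
probe sets — and all background probes — are true negatives. Defaults:
planted motifs 9–14 nt with one dominant base per position at probability
0.80–0.95 (sharp core positions typical of curated vertebrate TF models;
9 nt is also the shortest length whose deterministic consensus clears the
10⁻⁵ scanning floor), gain ladder {0, 1, 4, 16, 64} with 64 as the
high-gain regime. Condition plans set gains so *gained* means g≈0 before
and high after, *lost* the reverse, *conserved* high in both.

The genome simulator plants cluster consensus sites at non-overlapping
random positions inside promoter windows on a random background contig and
draws each promoter's H3K27ac peak score as 3 + 2·k + N(0, 0.5) (floored
at 0.1), k = number of distinct planted clusters; every promoter also gets
an ATAC peak, and a random 20% get a differential region at log2FC 2.

What the simulation does *not* emulate: spatial array artifacts, dye
chemistry and saturation, sequence-composition biases of real backgrounds,
correlated probe noise, mixtures of TFs binding one motif, and chromatin
context. Passing recovery tests therefore demonstrates the pipeline's
statistical machinery is correct and well-calibrated under its own noise
model — not performance on real arrays.

## Numerical and scale choices

Test and example simulations use 8–21 probe sets, 2 replicates, 1–2
conditions and Monte-Carlo nulls of 1 500–2 000 shuffles; these sizes give
stable recovery statistics while keeping the full suite in seconds.
Reported Monte-Carlo quantities are bit-reproducible under a fixed seed.
Known limitations: comparison p-values are scores, not calibrated
probabilities; cluster boundaries from the Monte-Carlo distances will not
reproduce a TomTom-derived, manually curated cluster set; the equivalence
filter's published semantics ("cutoff > 0.9" for identity and relative
length) are interpreted as the same strict cutoff on both quantities.
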