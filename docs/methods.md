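# Methods

`metamerge` implements a desk-scale pipeline for integrated
metagenome/metatranscriptome analysis of a gut microbial community sampled
at several ordered intestinal sites (cecum → transverse colon → feces) in
two or more individuals. This note documents the models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Cross-site reference reconstruction

Per-site assemblies of the same community fragment each genome differently,
so scaffolds from different sites overlap at their ends. The merger
(`metamerge.merge`) reconstructs a single common reference:

1. Scaffolds shorter than 1,000 bp are discarded; scaffolds are split at
   runs of ≥ 10 `N` so assembly gaps cannot seed false anchors.
2. Overlap candidates are found by shared 21-mer seeding, grouping of
   co-diagonal anchors, and gapless extension trimmed to the max-scoring
   run (+1 per match, −3 per mismatch). Alignment is substitution-only by
   design: the inputs are assemblies of the same community, where
   small-indel divergence between sites is not part of the model. Both
   orientations are considered.
3. A candidate is *containment* when it covers ≥ `containment_cov` (default
   0.90) of the query at ≥ `c` percent identity — the query is dropped.
   Otherwise it must be end-anchored: alignment length ≥ `mL` (default
   1000 bp), identity ≥ `c` (default 95), and inner overhang ≤ `hco`
   (default 100 bp) on both scaffolds.
4. Candidates are accepted greedily in (length desc, identity desc, ids)
   order; each scaffold end joins at most once, joins never close a cycle
   (union–find), and a query scaffold's orientation is fixed by its first
   accepted join. Accepted chains are spliced keeping the reference-side
   bases inside each overlap; per-base provenance (source site, scaffold,
   interval, orientation) tiles every merged scaffold exactly.
5. Multi-site merging is a left fold over the site sets in descending order
   of total assembly size — the largest assembly is the best backbone.

The knob names `mL` / `c` / `hco` mirror the roles (merge length cutoff /
alignment confidence / overlap confidence) of external contig mergers, but
their semantics here are this package's own: `c` is percent identity over
the overlap and `hco` is an overhang in bp, because those are the precisely
testable versions of "confidence". With simulated overlap identity of 97%,
merging succeeds at `c=95` and is refused at `c=99`.

## Gene catalogue

Gene calling is a deliberate stand-in for a statistical gene finder: all
maximal ORFs (ATG → stop, both strands, three frames, ≥ 300 nt), with
same-strand overlaps resolved longest-first. External GFF3 gene models are
accepted interchangeably. Cross-assembly gene identity uses banded edit
distance (substitutions + indels, via edlib) with a 3-edit budget; "common
to all sites" is operationalised as greedy one-to-one matching of the
first (sorted) site's genes into every other site. Edit distance rather
than Hamming was chosen because it subsumes the Hamming reading and is
robust to length slips at ORF boundaries.

Unknown proteins (no KO and no COG label) are clustered greedily
longest-first: a protein joins the first centroid reached at ≥ 90% identity
over the shorter sequence with a length ratio ≥ 0.85 (5-mer prefilter,
infix alignment); these defaults echo the 85% query-cover convention of
standard annotation alignments and are configurable. Known genes are
grouped into one cluster per COG label; genes carrying several COG labels
join each cluster and are flagged.

## Quantification

The read mapper is a deterministic k-mer seed (k = 31, disjoint seeds so a
read with fewer substitutions than seeds always retains a clean anchor) and
gapless extension; the best locus is kept only if unique and within a 5%
mismatch budget, ambiguous reads are unmapped. Pairs are properly paired
when mates map to one scaffold on opposite strands within a 2,000 bp
fragment. External SAM is accepted in place of the built-in mapper.

Counting is HTSeq-style union mode on fragments: a pair counts for gene *g*
iff the union of genes overlapped by either mate is exactly {*g*};
counting is strand-agnostic because the stand-in ORF caller does not
guarantee strand fidelity (configurable).

Two expression layers:

* **Whole-community**: TPM. rate_g = c_g / l_g(kb), tpm_g = 10⁶ ·
  rate_g / Σ_h rate_h. Σ tpm = 10⁶ per sample by construction.
* **Per-cell**: reads-per-kilobase divided by the gene's mean per-base DNA
  depth, d_g = (aligned DNA bases overlapping the gene)/l_g, optionally
  with a pseudodepth. Genes with zero effective depth are masked (NaN),
  not zero — without DNA evidence a per-bacterium rate is undefined. The
  DNA depth is proportional to species abundance, so the ratio cancels
  abundance: equal per-cell activity at 10× abundance gives equal per-cell
  values while TPM shifts. This realisation of "normalise mRNA counts by
  DNA coverage" was chosen for that exact cancellation property.

KO-level differential calls between a site pair use log2 differences with
a scale-adaptive pseudocount (half the smallest positive value in the
layer) and the two-fold same-direction rule: significant iff |log2
difference| > 1 with equal sign in every individual.

## Spatial covariation (Lee's L)

Cluster expression profiles are length-*n* vectors over the samples
(individual × site; n = 6 in the default two-individual, three-site
design), built as the sum (configurable mean) of member-gene expression
and log2(1+x) transformed. The spatial weights V are block-diagonal across
individuals; within an individual, v_ij = 1 for the same or chain-adjacent
sites, then row-standardised. This is the minimal structure consistent
with "spatial relevance between ordered gut sites"; self-inclusion is on
by default.

Lee's bivariate spatial association statistic:

L(x, y) = [n / Σ_i (Σ_j v_ij)²] · Σ_i (Σ_j v_ij (x_j − x̄)) (Σ_j v_ij (y_j − ȳ)) / (‖x − x̄‖ ‖y − ȳ‖)

With V = I it reduces to Pearson correlation; it is symmetric and
invariant to positive affine transforms of either argument; constant
profiles are undefined and excluded. Note that L of an *identical* pair is
the profile's spatial-smoothing scalar, which is < 1 for any profile that
is not constant within individuals — thresholds must therefore be
calibrated empirically, which is exactly what the ROC benchmark does.

**Benchmark and threshold.** Over all unordered pairs of known clusters
with reaction labels, positives share ≥ 1 KEGG-style reaction. The ROC is
swept over all distinct L values; AUC is the trapezoid (equal to the
tie-corrected Mann–Whitney pair-counting estimator); the transfer
threshold θ is the smallest L with empirical FPR ≤ the target (default
0.05). Unknown clusters linked to known clusters at L ≥ θ inherit the
union of their labels. Label enrichment between unknown-linked and known
clusters uses two-sided Fisher's exact tests with Benjamini–Hochberg
adjustment at 0.01 (sidedness is a package choice).

## Assembly evaluation

* **N-statistics**: N10..N100, Nx = length of the scaffold at which the
  descending cumulative length first reaches x% of the total.
* **Chimera index (CI)**: length-weighted fraction of aligned scaffolds
  whose truth-alignment blocks span ≥ 2 species (count-weighted variant
  configurable; the length-weighted form matches the other length-based
  metrics here).
* **Nonchimeric rate**: percent of assembled length attributable to a
  single species, from merge provenance + simulator labels when available,
  otherwise from truth alignments.
* **MAL/TAL**: maximum / total aligned block length.
* **CPM**: this package's own composite — N50_broken × (1 − CI) ×
  (TAL / assembly bp), where N50_broken is the N50 after splitting
  scaffolds at species-switch midpoints. It is monotone in contiguity,
  accuracy and completeness, which is the behaviour the evaluation tests
  require; it is *not* numerically comparable to other published composite
  scores.

## Synthetic communities

The generator is first-class, tested code; all outputs are pure functions
of (parameters, seed).

* **Genomes**: i.i.d. nucleotides at a target GC (default 0.45), with
  non-overlapping ORF-valid genes (length a multiple of 3 in [300, 3000]
  nt, ATG…stop, no internal in-frame stop, random strand) at a default
  density of one gene per 2.5 kb.
* **Abundance**: per-species log-normal with a smooth per-individual
  gradient over the ordered site chain.
* **Expression**: each designed covariant pair shares a latent profile —
  per-individual activity levels drawn as a random permutation of
  equispaced levels scaled by `effect_size` (plus jitter), plus linear and
  (down-weighted) quadratic gradients over the site chain with
  individual-level coefficient noise. Non-covariant genes draw spatially
  unstructured (i.i.d. per sample) profiles of matching scale: functional
  covariation is spatially coherent, background variation is not — the
  premise the L statistic exploits. With six observations a smooth-profile
  family spans only ~3 directions, so smooth-family nulls would collide by
  chance and no FPR-controlled threshold could reach high power; the
  unstructured null is the explicit alternative hypothesis. Expression =
  exp(baseline + latent + N(0, noise_sd)). Pair members receive a shared
  hidden reaction label for scoring.
* **Unknown designation**: 30% of genes lose their KO/COG labels (echoing
  the observed fraction of database-absent gut genes), stratified over the
  covariant pairs so small communities still contain known–known benchmark
  positives and known–unknown transfer truth.
* **Fragmentation**: each genome is cut into chunks of ~[min_frag,
  2·min_frag); chunk *i* goes to sites i mod S and (i+1) mod S (just
  i mod S for two sites) and same-site runs coalesce, so fragments are
  disjoint within a site but overlap across sites by ≥ the merge cutoff —
  the union of any two sites tiles the genome. Fragments < 1,000 bp are
  discarded.
* **Reads**: paired-end, fragment length N(400, 40) clamped to the
  template, 150 nt mates (a desk-scale choice; overlapping mates are
  handled), constant Q40 qualities, i.i.d. substitution errors. DNA pairs
  are uniform within genomes at depth ∝ abundance; mRNA pairs are confined
  to gene bodies at depth ∝ abundance × expression with deterministic
  per-gene rounding. No indels, strain mixtures, rRNA contamination or
  quality modelling.

What passing tests show about real data is correspondingly limited: exact
reconstruction and 100% gene retention hold for substitution-only,
designed-overlap communities, not for assemblies with structural
disagreement between sites; covariation power is measured against the
generator's own notion of spatially coherent signal.

## Problem sizes and determinism

The default demo simulates 6 genomes of 30–50 kb in 2 individuals × 3
sites at DNA/RNA depth 2×; the reconstruction benchmark uses 6 genomes of
80–120 kb (~600 kb); the covariation power/calibration study uses 500
designed pairs among 3,000 genes at the expression level. These sizes were
chosen so the full property suite, including five demo replicates, runs in
well under an hour on one core while every property is measured with
non-trivial statistics. All stages take explicit seeds; reruns are
byte-identical.

## Known limitations

* The merger and truth-aligner are gapless: indel divergence between sites
  breaks overlaps into shorter blocks and can prevent merging.
* The mapper guarantees sensitivity only up to (seeds − 1) substitutions
  per read and drops multi-mapping reads entirely.
* With two individuals the L statistic has few effective dimensions;
  AUC/θ values depend strongly on the weight construction, so no numeric
  equivalence with any particular published AUC or threshold is claimed —
  the FPR-control contract is what is tested.
* CPM and CI definitions are this package's own realisations of
  "composite performance" and "chimerism" and are not comparable across
  tools.
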